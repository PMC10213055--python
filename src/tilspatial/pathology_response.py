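"""Pathological response classification and TLS density.

Response to neoadjuvant therapy is scored from the pathologist-estimated
percentage of viable tumor on each H&E slide: the per-slide values are
averaged into the patient's final viable percentage, and the patient is
classed pCR (0% viable), MPR (<= 10% viable) or non-MPR (> 10%). pCR is a
subset of MPR, so pCR patients count toward MPR rates.

TLS density is the number of tertiary lymphoid structures per mm^2 of
evaluated tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ContractError, ValidationError
from .io_model import ClinicalRecord, TLSAnnotation


@dataclass
class ResponseCall:
    """Per-patient pathological response."""

    patient_id: str
    mean_viable_percent: float
    category: str  # "pCR" | "MPR" | "non-MPR"


def mean_viable_percent(slide_percents: Sequence[float]) -> float:
    """Average the per-slide viable-tumor percentages (1-5 slides)."""
    if not len(slide_percents):
        raise ContractError("no slide percentages given")
    for v in slide_percents:
        if not (0.0 <= v <= 100.0):
            raise ValidationError(f"viable percent {v} outside [0, 100]")
    return float(sum(slide_percents)) / len(slide_percents)


def classify_response(mean_viable: float) -> str:
    """0% -> pCR; (0, 10]% -> MPR; > 10% -> non-MPR (boundary 10.0 is MPR)."""
    if not (0.0 <= mean_viable <= 100.0):
        raise ValidationError(f"mean viable percent {mean_viable} outside [0, 100]")
    if mean_viable == 0.0:
        return "pCR"
    if mean_viable <= 10.0:
        return "MPR"
    return "non-MPR"


def response_calls(clinical: Iterable[ClinicalRecord]) -> list[ResponseCall]:
    """Score every patient from their per-slide viable percentages."""
    calls = []
    for rec in clinical:
        mv = mean_viable_percent(rec.viable_percent_per_slide)
        calls.append(ResponseCall(rec.patient_id, mv, classify_response(mv)))
    return calls


def _round_half_away(x: float, ndigits: int = 1) -> float:
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def arm_response_rates(
    calls: Sequence[ResponseCall], arm_by_patient: Mapping[str, str]
) -> pd.DataFrame:
    """Per-arm MPR and pCR rates as percentages (one decimal, half away from zero).

    A pCR patient satisfies the MPR definition and is counted in both
    numerators.
    """
    rows = []
    arms = sorted(set(arm_by_patient.values()))
    for arm in arms:
        members = [c for c in calls if arm_by_patient.get(c.patient_id) == arm]
        if not members:
            raise ContractError(f"arm {arm!r} has no patients")
        n = len(members)
        n_pcr = sum(c.category == "pCR" for c in members)
        n_mpr = n_pcr + sum(c.category == "MPR" for c in members)
        rows.append(
            {
                "arm": arm,
                "n": n,
                "n_mpr": n_mpr,
                "n_pcr": n_pcr,
                "mpr_rate_percent": _round_half_away(100.0 * n_mpr / n),
                "pcr_rate_percent": _round_half_away(100.0 * n_pcr / n),
            }
        )
    return pd.DataFrame(rows)


def tls_density(annotation: TLSAnnotation) -> float:
    """Tertiary lymphoid structures per mm^2 of evaluated area."""
    if not annotation.evaluated_area_mm2 > 0:
        raise ContractError(
            f"{annotation.specimen_id}: evaluated area must be positive"
        )
    return annotation.tls_count / annotation.evaluated_area_mm2
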