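"""Synthetic mIHC fields and two-arm cohorts with known ground truth.

The generator emulates the structure of a neoadjuvant NSCLC mIHC study:
paired pre/post specimens for two arms (chemotherapy alone, NAC, n=30;
chemotherapy plus PD-1 blockade, NAPC, n=35), ten 669 x 500 um fields per
specimen, seven TIL phenotypes plus an unlabelled "other" population,
arm-specific post/pre density fold-changes (NAC raises only B cells; NAPC
raises B cells, CD4 and CD8 T cells and the CD127+/KLRG1+ CD8 subsets,
leaving Tregs flat), spatial attraction of CD8 subsets toward CD4/CD20
cells in post-NAPC tissue only, MPR/pCR labels from a logistic model on the
post-treatment CD8 change, and exponential DFS/OS with log-hazard linear in
the same quantity.

Spatial attraction is modelled as a Neyman-Scott (Thomas-type) process:
offspring cells are displaced from uniformly placed parent cells by an
isotropic Gaussian (default dispersion 15 um, concentrating the effect
inside the 30 um analysis radius), with a fraction ``background_fraction``
of offspring placed uniformly instead. The expected total offspring count
always matches the configured intensity, so attraction changes geometry,
never abundance.

All randomness flows from a single integer seed via
``numpy.random.default_rng``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .io_model import (
    CELL_COLUMNS,
    DEFAULT_FIELD_HEIGHT_UM,
    DEFAULT_FIELD_WIDTH_UM,
    MARKER_PANEL,
    ClinicalRecord,
    Field,
    Specimen,
    TLSAnnotation,
)

logger = logging.getLogger("tilspatial")

#: Markers set positive for each generator phenotype key.
PHENOTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "other": ("DAPI",),
    "B_cell": ("DAPI", "CD20"),
    "CD4_T": ("DAPI", "CD4"),
    "CD4_T+CD127": ("DAPI", "CD4", "CD127"),
    "CD4_T+FoxP3": ("DAPI", "CD4", "FoxP3"),
    "CD8_T": ("DAPI", "CD8"),
    "CD8_T+CD127": ("DAPI", "CD8", "CD127"),
    "CD8_T+KLRG1": ("DAPI", "CD8", "KLRG1"),
}

#: Baseline (pre-treatment) intensities, cells per um^2 of tissue field.
#: At 669 x 500 um these give ~1150 DAPI cells per field with TIL fractions
#: of a few percent each, typical of segmented 20x mIHC fields.
DEFAULT_BASELINE_INTENSITIES: dict[str, float] = {
    "other": 0.0025,
    "B_cell": 0.00012,
    "CD4_T": 0.00025,
    "CD4_T+CD127": 0.00010,
    "CD4_T+FoxP3": 0.00006,
    "CD8_T": 0.00025,
    "CD8_T+CD127": 0.00008,
    "CD8_T+KLRG1": 0.00006,
}

#: Post/pre density fold-changes per arm. NAC raises only B cells; NAPC
#: raises B cells and the CD4/CD8 compartments, leaving Tregs unchanged.
DEFAULT_FOLD_CHANGE: dict[str, dict[str, float]] = {
    "NAC": {"B_cell": 1.8},
    "NAPC": {
        "B_cell": 2.0,
        "CD4_T": 1.6,
        "CD4_T+CD127": 1.8,
        "CD8_T": 1.7,
        "CD8_T+CD127": 2.0,
        "CD8_T+KLRG1": 2.0,
    },
}

CD8_PHENOTYPES = ("CD8_T", "CD8_T+CD127", "CD8_T+KLRG1")
PARENT_PHENOTYPES = ("CD4_T", "CD4_T+CD127", "CD4_T+FoxP3", "B_cell")


@dataclass
class AttractionConfig:
    """Thomas-process attraction block for :func:`simulate_attraction_field`."""

    parent_phenotypes: tuple[str, ...]
    offspring_phenotype: str
    parent_intensity: float  # kappa, parents per um^2
    mean_offspring: float  # mu, expected offspring per parent
    dispersion_um: float = 15.0  # sigma of the Gaussian displacement
    background_fraction: float = 0.3  # rho, offspring placed uniformly

    def __post_init__(self) -> None:
        if self.dispersion_um <= 0:
            raise ValidationError("attraction dispersion must be positive")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValidationError("background_fraction must be in [0, 1]")
        if self.parent_intensity < 0 or self.mean_offspring < 0:
            raise ValidationError("attraction intensities must be non-negative")


@dataclass
class FieldSimConfig:
    """One synthetic field: geometry, phenotype intensities, optional attraction."""

    width_um: float = DEFAULT_FIELD_WIDTH_UM
    height_um: float = DEFAULT_FIELD_HEIGHT_UM
    intensities: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_BASELINE_INTENSITIES)
    )
    attraction: AttractionConfig | None = None
    boundary: str = "clipped"  # "clipped" (redraw) or "toroidal" (wrap)
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.intensities.values()):
            raise ValidationError("intensities must be non-negative")
        unknown = set(self.intensities) - set(PHENOTYPE_MARKERS)
        if unknown:
            raise ValidationError(f"unknown phenotype keys {sorted(unknown)}")
        if self.boundary not in ("clipped", "toroidal"):
            raise ValidationError(f"unknown boundary {self.boundary!r}")


def _build_field(
    placements: Mapping[str, np.ndarray],
    width_um: float,
    height_um: float,
    field_id: str,
) -> Field:
    """Assemble a Field from per-phenotype (n, 2) coordinate arrays."""
    keys = [k for k in PHENOTYPE_MARKERS if k in placements]
    counts = [len(placements[k]) for k in keys]
    total = int(sum(counts))
    xy = (
        np.concatenate([placements[k] for k in keys])
        if total
        else np.zeros((0, 2))
    )
    data: dict[str, object] = {
        "cell_id": np.arange(total),
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
    }
    for m in MARKER_PANEL:
        data[m] = np.zeros(total, dtype=np.int8)
    start = 0
    for k, c in zip(keys, counts):
        for m in PHENOTYPE_MARKERS[k]:
            data[m][start : start + c] = 1
        start += c
    cells = pd.DataFrame(data, columns=list(CELL_COLUMNS))
    # construction guarantees the invariants; skip the validation scan
    return Field(
        field_id=field_id,
        width_um=width_um,
        height_um=height_um,
        cells=cells,
        validate=False,
    )


def _rng(config_seed: int | None, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config_seed)


def simulate_csr_field(
    config: FieldSimConfig,
    rng: np.random.Generator | None = None,
    field_id: str = "csr",
) -> Field:
    """Homogeneous Poisson (CSR) field: the null model for spatial analysis.

    Each phenotype receives a Poisson(intensity * area) number of cells
    placed uniformly at random; marker flags follow the phenotype key.
    """
    rng = _rng(config.seed, rng)
    area = config.width_um * config.height_um
    placements = {}
    for ph, lam in config.intensities.items():
        n = int(rng.poisson(lam * area))
        pts = np.empty((n, 2))
        pts[:, 0] = rng.uniform(0, config.width_um, n)
        pts[:, 1] = rng.uniform(0, config.height_um, n)
        placements[ph] = pts
    if sum(len(p) for p in placements.values()) == 0 and all(
        v == 0 for v in config.intensities.values()
    ):
        logger.warning("field %s: all intensities zero, empty field", field_id)
    return _build_field(placements, config.width_um, config.height_um, field_id)


def _place_offspring(
    parents: np.ndarray,
    n_offspring: int,
    sigma: float,
    rho: float,
    width: float,
    height: float,
    boundary: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thomas offspring: Gaussian displacement from random parents, with a
    uniform background fraction; clipped points are redrawn, toroidal wrap."""
    if n_offspring == 0:
        return np.zeros((0, 2))
    is_bg = rng.random(n_offspring) < rho
    n_bg = int(is_bg.sum())
    pts = np.empty((n_offspring, 2))
    pts[is_bg, 0] = rng.uniform(0, width, n_bg)
    pts[is_bg, 1] = rng.uniform(0, height, n_bg)
    n_cl = n_offspring - n_bg
    if n_cl:
        if len(parents) == 0:
            pts[~is_bg, 0] = rng.uniform(0, width, n_cl)
            pts[~is_bg, 1] = rng.uniform(0, height, n_cl)
        else:
            anchors = parents[rng.integers(0, len(parents), n_cl)]
            off = anchors + rng.normal(0.0, sigma, (n_cl, 2))
            if boundary == "toroidal":
                off[:, 0] %= width
                off[:, 1] %= height
            else:  # clipped: redraw the displacement until inside
                for _ in range(200):
                    out = (
                        (off[:, 0] < 0)
                        | (off[:, 0] > width)
                        | (off[:, 1] < 0)
                        | (off[:, 1] > height)
                    )
                    if not out.any():
                        break
                    k = int(out.sum())
                    anchors_out = parents[rng.integers(0, len(parents), k)]
                    off[out] = anchors_out + rng.normal(0.0, sigma, (k, 2))
                else:
                    still = (
                        (off[:, 0] < 0)
                        | (off[:, 0] > width)
                        | (off[:, 1] < 0)
                        | (off[:, 1] > height)
                    )
                    off[still, 0] = rng.uniform(0, width, int(still.sum()))
                    off[still, 1] = rng.uniform(0, height, int(still.sum()))
            pts[~is_bg] = off
    return pts


def simulate_attraction_field(
    config: FieldSimConfig,
    rng: np.random.Generator | None = None,
    field_id: str = "attraction",
) -> Field:
    """Neyman-Scott field: offspring cells clustered around parent cells.

    Parents are placed as a Poisson(kappa * area) uniform pattern and split
    evenly at random among ``parent_phenotypes``; each parent emits
    Poisson(mu) offspring displaced by an isotropic Gaussian (sigma =
    ``dispersion_um``), except that a fraction ``background_fraction`` of
    offspring is placed uniformly. Entries of ``config.intensities`` naming
    a parent or the offspring phenotype are ignored (kappa and mu govern
    those populations); remaining phenotypes are CSR.
    """
    att = config.attraction
    if att is None:
        raise ContractError("simulate_attraction_field: no attraction block")
    rng = _rng(config.seed, rng)
    area = config.width_um * config.height_um
    placements: dict[str, np.ndarray] = {}
    skip = set(att.parent_phenotypes) | {att.offspring_phenotype}
    for ph, lam in config.intensities.items():
        if ph in skip:
            continue
        n = int(rng.poisson(lam * area))
        pts = np.empty((n, 2))
        pts[:, 0] = rng.uniform(0, config.width_um, n)
        pts[:, 1] = rng.uniform(0, config.height_um, n)
        placements[ph] = pts
    n_parents = int(rng.poisson(att.parent_intensity * area))
    parents = np.empty((n_parents, 2))
    parents[:, 0] = rng.uniform(0, config.width_um, n_parents)
    parents[:, 1] = rng.uniform(0, config.height_um, n_parents)
    assignment = rng.integers(0, len(att.parent_phenotypes), n_parents)
    for k, ph in enumerate(att.parent_phenotypes):
        placements[ph] = parents[assignment == k]
    n_off = int(rng.poisson(att.mean_offspring * n_parents)) if n_parents else 0
    placements[att.offspring_phenotype] = _place_offspring(
        parents,
        n_off,
        att.dispersion_um,
        att.background_fraction,
        config.width_um,
        config.height_um,
        config.boundary,
        rng,
    )
    return _build_field(placements, config.width_um, config.height_um, field_id)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class AttractionEffect:
    """Arm-level attraction applied to post-treatment fields: CD8 phenotypes
    placed as Thomas offspring around the field's CD4/CD20 cells."""

    dispersion_um: float = 15.0
    background_fraction: float = 0.3


@dataclass
class MprModel:
    """Logistic model for MPR: P = sigmoid(intercept_arm + slope * z_CD8),
    where z_CD8 is the patient's standardised post-treatment CD8 density
    change. Intercepts are calibrated numerically (Gauss-Hermite) so the
    marginal MPR rate per arm equals ``rate_by_arm``."""

    rate_by_arm: dict[str, float] = dc_field(
        default_factory=lambda: {"NAC": 0.20, "NAPC": 0.657}
    )
    slope: float = 1.5
    pcr_given_mpr: dict[str, float] = dc_field(
        default_factory=lambda: {"NAC": 0.0, "NAPC": 16 / 23}
    )

    def intercept(self, arm: str) -> float:
        """Solve E[sigmoid(a + slope Z)] = rate for a, Z ~ N(0, 1)."""
        target = self.rate_by_arm[arm]
        nodes, weights = np.polynomial.hermite_e.hermegauss(64)
        wnorm = weights / weights.sum()

        def marginal(a: float) -> float:
            return float(wnorm @ (1.0 / (1.0 + np.exp(-(a + self.slope * nodes)))))

        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if marginal(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2


@dataclass
class SurvivalModel:
    """Exponential DFS/OS with log-hazard linear in the post-CD8 change.

    hazard = ln(2)/median * exp(slope * z_CD8); negative slope means higher
    post-treatment CD8 infiltration lowers the hazard. Censoring times are
    exponential with rate tuned to the requested approximate censoring
    fraction.
    """

    median_dfs_months: float = 24.0
    median_os_months: float = 40.0
    log_hazard_slope: float = -0.8
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValidationError("censoring_rate must be in [0, 1)")


@dataclass
class CohortSimConfig:
    """Full two-arm cohort: sizes, densities, effects, outcome models."""

    n_per_arm: dict[str, int] = dc_field(
        default_factory=lambda: {"NAC": 30, "NAPC": 35}
    )
    fields_per_specimen: int = 10
    width_um: float = DEFAULT_FIELD_WIDTH_UM
    height_um: float = DEFAULT_FIELD_HEIGHT_UM
    baseline_intensities: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_BASELINE_INTENSITIES)
    )
    fold_change: dict[str, dict[str, float]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FOLD_CHANGE.items()}
    )
    patient_sigma: float = 0.35  # lognormal sd of per-patient baseline noise
    fold_sigma: float = 0.25  # lognormal sd of per-patient fold-change noise
    attraction: dict[str, AttractionEffect] = dc_field(
        default_factory=lambda: {"NAPC": AttractionEffect()}
    )
    mpr_model: MprModel = dc_field(default_factory=MprModel)
    survival_model: SurvivalModel = dc_field(default_factory=SurvivalModel)
    tls_density_per_mm2: dict[str, float] = dc_field(
        default_factory=lambda: {"pre": 0.2, "post_NAC": 0.3, "post_NAPC": 0.5}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_arm.values()):
            raise ValidationError("n_per_arm entries must be >= 1")
        if self.fields_per_specimen < 1:
            raise ValidationError("fields_per_specimen must be >= 1")
        for arm, fc in self.fold_change.items():
            unknown = set(fc) - set(PHENOTYPE_MARKERS)
            if unknown:
                raise ValidationError(f"fold_change[{arm}]: unknown phenotypes {unknown}")
            if any(v <= 0 for v in fc.values()):
                raise ValidationError(f"fold_change[{arm}]: fold-changes must be > 0")


@dataclass
class CohortData:
    specimens: list[Specimen]
    clinical: list[ClinicalRecord]
    tls: list[TLSAnnotation]
    truth: dict


def _csr_placements(
    intensities: Mapping[str, float],
    width: float,
    height: float,
    rng: np.random.Generator,
    skip: set[str] = frozenset(),
) -> dict[str, np.ndarray]:
    area = width * height
    placements = {}
    for ph, lam in intensities.items():
        if ph in skip:
            continue
        n = int(rng.poisson(lam * area))
        pts = np.empty((n, 2))
        pts[:, 0] = rng.uniform(0, width, n)
        pts[:, 1] = rng.uniform(0, height, n)
        placements[ph] = pts
    return placements


def _simulate_specimen_fields(
    intensities: Mapping[str, float],
    config: CohortSimConfig,
    attraction: AttractionEffect | None,
    rng: np.random.Generator,
    prefix: str,
) -> list[Field]:
    fields = []
    area = config.width_um * config.height_um
    for i in range(config.fields_per_specimen):
        if attraction is None:
            placements = _csr_placements(
                intensities, config.width_um, config.height_um, rng
            )
        else:
            placements = _csr_placements(
                intensities,
                config.width_um,
                config.height_um,
                rng,
                skip=set(CD8_PHENOTYPES),
            )
            parents = (
                np.concatenate(
                    [placements[p] for p in PARENT_PHENOTYPES if p in placements]
                )
                if any(p in placements for p in PARENT_PHENOTYPES)
                else np.zeros((0, 2))
            )
            for ph in CD8_PHENOTYPES:
                lam = intensities.get(ph, 0.0)
                n_total = int(rng.poisson(lam * area))
                placements[ph] = _place_offspring(
                    parents,
                    n_total,
                    attraction.dispersion_um,
                    attraction.background_fraction,
                    config.width_um,
                    config.height_um,
                    "clipped",
                    rng,
                )
        fields.append(
            _build_field(
                placements,
                config.width_um,
                config.height_um,
                f"{prefix}_f{i:02d}",
            )
        )
    return fields


def simulate_cohort(
    config: CohortSimConfig | None = None,
    rng: np.random.Generator | None = None,
    timepoints: Sequence[str] = ("pre", "post"),
) -> CohortData:
    """Simulate a full two-arm cohort with ground truth.

    Per patient: pre-treatment intensities are the baseline scaled by
    lognormal patient noise; post intensities multiply in the arm-specific
    fold-change with additional lognormal noise; post-treatment fields of
    arms listed in ``config.attraction`` use Thomas-process placement of
    CD8 cells around CD4/CD20 cells. MPR/pCR labels, per-slide viable
    percentages (pCR: 0, MPR: U(0,10], non-MPR: U(10,90]) and exponential
    DFS/OS follow the configured outcome models. ``timepoints`` restricts
    which specimens have their point patterns materialised (both labels are
    always drawn, keeping the random stream and ground truth identical).
    """
    config = config or CohortSimConfig()
    rng = _rng(config.seed, rng)
    bad = set(timepoints) - {"pre", "post"}
    if bad:
        raise ContractError(f"unknown timepoints {sorted(bad)}")
    # Separate streams so labels/ground truth are invariant to which
    # timepoints get their (randomness-hungry) point patterns materialised.
    label_rng, field_rng = rng.spawn(2)
    specimens: list[Specimen] = []
    clinical: list[ClinicalRecord] = []
    tls: list[TLSAnnotation] = []
    truth: dict = {"patients": {}}
    surv = config.survival_model
    mpr_model = config.mpr_model
    intercepts = {arm: mpr_model.intercept(arm) for arm in config.n_per_arm}
    for arm, n_patients in config.n_per_arm.items():
        fc_arm = config.fold_change.get(arm, {})
        for k in range(n_patients):
            pid = f"{arm}{k + 1:03d}"
            lam_pre = {
                ph: lam * math.exp(label_rng.normal(0.0, config.patient_sigma))
                for ph, lam in config.baseline_intensities.items()
            }
            z_fold = {ph: float(label_rng.normal()) for ph in config.baseline_intensities}
            lam_post = {
                ph: lam_pre[ph]
                * fc_arm.get(ph, 1.0)
                * math.exp(config.fold_sigma * z_fold[ph])
                for ph in lam_pre
            }
            z_cd8 = z_fold["CD8_T"]
            p_mpr = 1.0 / (1.0 + math.exp(-(intercepts[arm] + mpr_model.slope * z_cd8)))
            is_mpr = bool(label_rng.random() < p_mpr)
            is_pcr = bool(
                is_mpr and label_rng.random() < mpr_model.pcr_given_mpr.get(arm, 0.0)
            )
            n_slides = int(label_rng.integers(1, 6))
            if is_pcr:
                viable = [0.0] * n_slides
            elif is_mpr:
                viable = list(np.round(label_rng.uniform(0.0, 10.0, n_slides) + 1e-6, 2))
            else:
                viable = list(np.round(label_rng.uniform(10.0, 90.0, n_slides), 2))
            # survival predictor: standardised log post-treatment CD8 density
            # relative to baseline, so the arm fold-change (1.7x in NAPC)
            # translates into an arm-level DFS/OS benefit
            s_comb = math.sqrt(config.patient_sigma**2 + config.fold_sigma**2)
            x_cd8 = (
                math.log(lam_post["CD8_T"] / config.baseline_intensities["CD8_T"])
                / s_comb
            )
            h_dfs = math.log(2) / surv.median_dfs_months * math.exp(
                surv.log_hazard_slope * x_cd8
            )
            h_os = math.log(2) / surv.median_os_months * math.exp(
                surv.log_hazard_slope * x_cd8
            )
            c = surv.censoring_rate
            t_dfs = float(label_rng.exponential(1.0 / h_dfs))
            t_os = float(label_rng.exponential(1.0 / h_os))
            if c > 0:
                cens_rate_dfs = math.log(2) / surv.median_dfs_months * c / (1 - c)
                cens_rate_os = math.log(2) / surv.median_os_months * c / (1 - c)
                c_dfs = float(label_rng.exponential(1.0 / cens_rate_dfs))
                c_os = float(label_rng.exponential(1.0 / cens_rate_os))
            else:
                c_dfs = c_os = math.inf
            dfs_time, dfs_event = min(t_dfs, c_dfs), t_dfs <= c_dfs
            os_time, os_event = min(t_os, c_os), t_os <= c_os
            clinical.append(
                ClinicalRecord(
                    patient_id=pid,
                    arm=arm,
                    viable_percent_per_slide=viable,
                    dfs_time=round(dfs_time, 3),
                    dfs_event=bool(dfs_event),
                    os_time=round(os_time, 3),
                    os_event=bool(os_event),
                )
            )
            for tp in ("pre", "post"):
                attraction = (
                    config.attraction.get(arm) if tp == "post" else None
                )
                lam = lam_pre if tp == "pre" else lam_post
                if tp in timepoints:
                    fields = _simulate_specimen_fields(
                        lam, config, attraction, field_rng, prefix=f"{pid}_{tp}"
                    )
                    specimens.append(
                        Specimen(
                            patient_id=pid, arm=arm, timepoint=tp, fields=fields
                        )
                    )
                tls_key = "pre" if tp == "pre" else f"post_{arm}"
                tls_lambda = config.tls_density_per_mm2.get(tls_key, 0.0)
                area_mm2 = float(label_rng.uniform(20.0, 60.0))
                tls.append(
                    TLSAnnotation(
                        specimen_id=f"{pid}_{tp}",
                        tls_count=int(label_rng.poisson(tls_lambda * area_mm2)),
                        evaluated_area_mm2=round(area_mm2, 3),
                    )
                )
            truth["patients"][pid] = {
                "arm": arm,
                "lambda_pre": lam_pre,
                "lambda_post": lam_post,
                "z_cd8": z_cd8,
                "x_cd8_survival": x_cd8,
                "p_mpr": p_mpr,
                "mpr": is_mpr,
                "pcr": is_pcr,
                "hazard_dfs": h_dfs,
                "hazard_os": h_os,
                "attraction_post": arm in config.attraction,
            }
    truth["config"] = {
        "n_per_arm": dict(config.n_per_arm),
        "fields_per_specimen": config.fields_per_specimen,
        "attraction_arms": sorted(config.attraction),
        "mpr_rates": dict(mpr_model.rate_by_arm),
        "log_hazard_slope": surv.log_hazard_slope,
    }
    return CohortData(specimens=specimens, clinical=clinical, tls=tls, truth=truth)


# ---------------------------------------------------------------------------
# fixture bundle


def make_fixture_bundle(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete miniature dataset in the package's input schemas.

    2 arms x 4 patients x pre/post x 3 fields, plus clinical, TLS,
    field-geometry tables and a ground-truth manifest. Byte-identical
    across runs at a fixed seed.
    """
    out = Path(out_dir)
    cells_dir = out / "cells"
    try:
        cells_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    config = CohortSimConfig(
        n_per_arm={"NAC": 4, "NAPC": 4}, fields_per_specimen=3, seed=int(seed)
    )
    cohort = simulate_cohort(config)
    paths: dict[str, Path] = {}
    geometry_rows = []
    for sp in cohort.specimens:
        for f in sp.fields:
            df = f.cells[list(CELL_COLUMNS)].copy()
            df["x_um"] = df["x_um"].map(lambda v: f"{v:.4f}")
            df["y_um"] = df["y_um"].map(lambda v: f"{v:.4f}")
            p = cells_dir / f"{f.field_id}.csv"
            df.to_csv(p, index=False)
            geometry_rows.append(
                {
                    "field_id": f.field_id,
                    "width_um": f.width_um,
                    "height_um": f.height_um,
                }
            )
    paths["cells"] = cells_dir
    geo = out / "fields.csv"
    pd.DataFrame(geometry_rows).to_csv(geo, index=False)
    paths["fields"] = geo
    clin_rows = [
        {
            "patient_id": r.patient_id,
            "arm": r.arm,
            "viable_percent": ";".join(f"{v:g}" for v in r.viable_percent_per_slide),
            "dfs_time": r.dfs_time,
            "dfs_event": int(r.dfs_event),
            "os_time": r.os_time,
            "os_event": int(r.os_event),
        }
        for r in cohort.clinical
    ]
    clin = out / "clinical.csv"
    pd.DataFrame(clin_rows).to_csv(clin, index=False)
    paths["clinical"] = clin
    tls_rows = [
        {
            "specimen_id": a.specimen_id,
            "tls_count": a.tls_count,
            "evaluated_area_mm2": a.evaluated_area_mm2,
        }
        for a in cohort.tls
    ]
    tls = out / "tls.csv"
    pd.DataFrame(tls_rows).to_csv(tls, index=False)
    paths["tls"] = tls
    manifest = out / "truth.json"
    manifest.write_text(json.dumps({"seed": int(seed), **cohort.truth}, sort_keys=True, indent=1))
    paths["truth"] = manifest
    return paths


def bundle_checksum(out_dir: str | Path) -> str:
    """SHA-256 over every file of a fixture bundle (sorted relative paths)."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(out)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
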