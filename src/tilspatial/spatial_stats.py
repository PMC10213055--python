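"""Spatial statistics for cell point patterns: cross-type K(r) and proximity.

The bivariate (cross-type) K function estimates the expected, area-normalised
number of target-phenotype cells within radius r of a reference-phenotype
cell,

    K_hat(r) = (alpha / D) * sum_{i in ref} sum_{j in target, j != i}
               I(d_ij <= r) * e_ij

where alpha is the field area, d_ij the Euclidean distance between nuclear
centres, and I(.) the indicator (the distance threshold is inclusive,
d <= r). Two normalisations D are available: ``"cross"`` (default),
D = n_ref * n_target, the standard bivariate form; and ``"as_printed"``,
D = n * (n - 1), the univariate form, valid only when reference and target
are the same point set. Two edge treatments e_ij are available: ``"none"``
(e = 1, the literal sum) and ``"translation"`` (default), the translation
correction for rectangular windows, e_ij = WH / ((W - |dx|)(H - |dy|)),
which makes K_hat unbiased under complete spatial randomness
(E[K_hat(r)] = pi r^2).

Proximity density is the companion neighbourhood measure: the mean number of
target cells within a fixed radius (30 um by default) of each reference
cell, reported as raw uncorrected counts. When the same physical cell
appears in both the reference and target sets (nested subsets), it is
excluded from its own neighbourhood by cell id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ContractError, UndefinedResultError
from .io_model import Field, Specimen
from .phenotyping import ensure_phenotyped, phenotype_mask

logger = logging.getLogger("tilspatial")

#: Radii (um) of the standard multi-scale sweep.
DEFAULT_RADII: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0)

#: Radius (um) defining the proximity neighbourhood.
PROXIMITY_RADIUS_UM = 30.0

#: Default reference x target phenotype pairs for cohort proximity analysis.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("CD4_T", "CD8_T"),
    ("CD4_T", "CD8_T+CD127"),
    ("CD4_T", "CD8_T+KLRG1"),
    ("B_cell", "CD8_T"),
    ("B_cell", "CD8_T+CD127"),
    ("B_cell", "CD8_T+KLRG1"),
    ("B_cell", "CD4_T"),
    ("B_cell", "CD4_T+CD127"),
)


@dataclass
class KFunctionEstimate:
    """Cross-type K(r) estimates over a radius sweep for one field."""

    ref_phenotype: str
    target_phenotype: str
    radii: list[float]
    k_values: list[float]
    normalization: str
    correction: str
    n_ref: int
    n_target: int
    area_um2: float


@dataclass
class ProximityResult:
    """Specimen-level proximity density for one phenotype pair."""

    specimen_id: str
    ref_phenotype: str
    target_phenotype: str
    radius_um: float
    per_field_mean_counts: list[float]
    specimen_mean_count: float
    arm: str | None = None
    timepoint: str | None = None
    patient_id: str | None = None


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Distance between two nuclear centres: sqrt((px-qx)^2 + (py-qy)^2)."""
    return math.hypot(p[0] - q[0], p[1] - q[1])


def count_within_radius(
    ref_points: np.ndarray,
    target_points: np.ndarray,
    r: float,
    ref_ids: Sequence | None = None,
    target_ids: Sequence | None = None,
    boxsize: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-reference-cell counts of target cells with distance <= r.

    When ``ref_ids``/``target_ids`` are given, a reference cell that is also
    present in the target set (same cell id) is not counted as its own
    neighbour. ``boxsize=(W, H)`` switches to toroidal (periodic) distance.
    The k-d tree search returns exactly the brute-force result.
    """
    if r <= 0:
        raise ContractError(f"radius must be positive, got {r}")
    ref_points = np.atleast_2d(np.asarray(ref_points, dtype=float))
    target_points = np.atleast_2d(np.asarray(target_points, dtype=float))
    if len(ref_points) == 0:
        return np.zeros(0, dtype=int)
    if len(target_points) == 0:
        return np.zeros(len(ref_points), dtype=int)
    tree = cKDTree(target_points, boxsize=boxsize)
    counts = np.asarray(
        tree.query_ball_point(ref_points, r, return_length=True), dtype=int
    )
    if ref_ids is not None and target_ids is not None:
        tset = set(target_ids)
        self_hits = np.fromiter(
            (rid in tset for rid in ref_ids), count=len(ref_points), dtype=bool
        )
        counts[self_hits] -= 1
    return counts


def proximity_density(
    field: Field,
    ref_phenotype: str,
    target_phenotype: str,
    r: float = PROXIMITY_RADIUS_UM,
    periodic: bool = False,
) -> float:
    """Mean number of target cells within r um of each reference cell.

    Raw (uncorrected) counts; the reference cell itself is excluded when it
    also belongs to the target phenotype. Raises
    :class:`UndefinedResultError` when the field has no reference cell.
    """
    ensure_phenotyped(field)
    ref_mask = phenotype_mask(field, ref_phenotype)
    if not ref_mask.any():
        raise UndefinedResultError(
            f"field {field.field_id}: no {ref_phenotype} reference cells"
        )
    tgt_mask = phenotype_mask(field, target_phenotype)
    ids = field.cells["cell_id"].to_numpy()
    counts = count_within_radius(
        field.points(ref_mask),
        field.points(tgt_mask),
        r,
        ref_ids=ids[ref_mask],
        target_ids=ids[tgt_mask],
        boxsize=(field.width_um, field.height_um) if periodic else None,
    )
    return float(counts.mean())


def _pairs_within(
    field: Field, ref_mask: np.ndarray, tgt_mask: np.ndarray, rmax: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (i, j) cross pairs with d <= rmax, self-pairs removed.

    Returns (distances, |dx|, |dy|) arrays over the retained pairs.
    """
    ref_xy = field.points(ref_mask)
    tgt_xy = field.points(tgt_mask)
    ids = field.cells["cell_id"].to_numpy()
    rid, tid = ids[ref_mask], ids[tgt_mask]
    pairs = cKDTree(ref_xy).sparse_distance_matrix(
        cKDTree(tgt_xy), rmax, output_type="ndarray"
    )
    if len(pairs) == 0:
        z = np.zeros(0)
        return z, z, z
    i, j, d = pairs["i"], pairs["j"], pairs["v"]
    keep = rid[i] != tid[j]  # a cell is never its own neighbour
    i, j, d = i[keep], j[keep], d[keep]
    dx = np.abs(ref_xy[i, 0] - tgt_xy[j, 0])
    dy = np.abs(ref_xy[i, 1] - tgt_xy[j, 1])
    return d, dx, dy


def bivariate_k(
    field: Field,
    ref_phenotype: str,
    target_phenotype: str,
    radii: Sequence[float] = DEFAULT_RADII,
    normalization: str = "cross",
    correction: str = "translation",
) -> KFunctionEstimate:
    """Estimate the cross-type K function on one field.

    See the module docstring for the estimator. ``normalization=
    "as_printed"`` (D = n(n-1)) is only defined when reference and target
    are the same point set with n >= 2; requesting it for distinct
    phenotypes raises :class:`ContractError`.
    """
    radii = _check_radii(radii)
    if normalization not in ("cross", "as_printed"):
        raise ContractError(f"unknown normalization {normalization!r}")
    if correction not in ("none", "translation"):
        raise ContractError(f"unknown correction {correction!r}")
    ensure_phenotyped(field)
    ref_mask = phenotype_mask(field, ref_phenotype)
    tgt_mask = phenotype_mask(field, target_phenotype)
    n_ref, n_target = int(ref_mask.sum()), int(tgt_mask.sum())
    if n_ref == 0 or n_target == 0:
        raise UndefinedResultError(
            f"field {field.field_id}: empty phenotype set "
            f"({ref_phenotype}: {n_ref}, {target_phenotype}: {n_target})"
        )
    if normalization == "as_printed":
        if not np.array_equal(ref_mask, tgt_mask):
            raise ContractError(
                "normalization 'as_printed' uses n(n-1) and is only defined "
                "when reference and target are the same point set; use "
                "normalization='cross' for distinct phenotypes"
            )
        if n_ref < 2:
            raise ContractError("'as_printed' requires n >= 2")
        denom = n_ref * (n_ref - 1)
    else:
        denom = n_ref * n_target
    d, dx, dy = _pairs_within(field, ref_mask, tgt_mask, max(radii))
    if correction == "translation":
        w = field.area_um2 / ((field.width_um - dx) * (field.height_um - dy))
    else:
        w = np.ones_like(d)
    k_values = [
        float(field.area_um2 / denom * w[d <= r].sum()) for r in radii
    ]
    return KFunctionEstimate(
        ref_phenotype=ref_phenotype,
        target_phenotype=target_phenotype,
        radii=list(map(float, radii)),
        k_values=k_values,
        normalization=normalization,
        correction=correction,
        n_ref=n_ref,
        n_target=n_target,
        area_um2=field.area_um2,
    )


def _check_radii(radii: Sequence[float]) -> list[float]:
    radii = list(map(float, radii))
    if not radii or any(r <= 0 for r in radii):
        raise ContractError("radii must be positive")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ContractError("radii must be strictly increasing")
    return radii


@dataclass
class SweepResult:
    """Multi-radius K estimate plus per-radius proximity densities."""

    k: KFunctionEstimate
    proximity: dict[float, float]  # radius -> mean within-r target count


def radius_sweep(
    field: Field,
    ref_phenotype: str,
    target_phenotype: str,
    radii: Sequence[float] = DEFAULT_RADII,
    normalization: str = "cross",
    correction: str = "translation",
) -> SweepResult:
    """K(r) and proximity density at every sweep radius in one pass.

    Pairwise distances up to max(radii) are computed once and thresholded
    per radius; values agree exactly with independent single-radius calls.
    """
    radii = _check_radii(radii)
    k = bivariate_k(
        field, ref_phenotype, target_phenotype, radii, normalization, correction
    )
    ensure_phenotyped(field)
    ref_mask = phenotype_mask(field, ref_phenotype)
    tgt_mask = phenotype_mask(field, target_phenotype)
    d, _, _ = _pairs_within(field, ref_mask, tgt_mask, max(radii))
    n_ref = int(ref_mask.sum())
    proximity = {r: float((d <= r).sum()) / n_ref for r in radii}
    return SweepResult(k=k, proximity=proximity)


def cohort_proximity(
    specimens: Iterable[Specimen],
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    r: float = PROXIMITY_RADIUS_UM,
) -> list[ProximityResult]:
    """Specimen-level proximity densities for the configured phenotype pairs.

    For each specimen and (reference, target) pair the per-field mean
    within-r counts are averaged over fields that contain at least one
    reference cell; specimens with no eligible field for a pair are excluded
    from that pair with a log entry.
    """
    results: list[ProximityResult] = []
    for sp in specimens:
        # one mask/point/tree computation per field per phenotype, shared
        # across all pairs; equals pair-wise proximity_density calls exactly
        phenos = sorted({p for pair in pairs for p in pair})
        field_cache = []
        for f in sp.fields:
            ensure_phenotyped(f)
            xy = f.cells[["x_um", "y_um"]].to_numpy(dtype=float)
            masks = {ph: phenotype_mask(f, ph) for ph in phenos}
            points = {ph: xy[masks[ph]] for ph in phenos}
            trees = {ph: cKDTree(points[ph]) if len(points[ph]) else None
                     for ph in phenos}
            field_cache.append((masks, points, trees))
        for ref_ph, tgt_ph in pairs:
            per_field: list[float] = []
            for masks, points, trees in field_cache:
                ref_pts = points[ref_ph]
                if len(ref_pts) == 0:
                    continue
                tree = trees[tgt_ph]
                if tree is None:
                    per_field.append(0.0)
                    continue
                counts = np.asarray(
                    tree.query_ball_point(ref_pts, r, return_length=True),
                    dtype=float,
                )
                # nested phenotypes: a cell is never its own neighbour
                overlap = masks[tgt_ph][masks[ref_ph]]
                counts[overlap] -= 1
                per_field.append(float(counts.mean()))
            if not per_field:
                logger.info(
                    "specimen %s: no field with %s reference cells; pair "
                    "(%s, %s) excluded",
                    sp.specimen_id,
                    ref_ph,
                    ref_ph,
                    tgt_ph,
                )
                continue
            results.append(
                ProximityResult(
                    specimen_id=sp.specimen_id,
                    ref_phenotype=ref_ph,
                    target_phenotype=tgt_ph,
                    radius_um=float(r),
                    per_field_mean_counts=per_field,
                    specimen_mean_count=float(np.mean(per_field)),
                    arm=sp.arm,
                    timepoint=sp.timepoint,
                    patient_id=sp.patient_id,
                )
            )
    return results


def proximity_frame(results: Sequence[ProximityResult]) -> pd.DataFrame:
    """Tidy one-row-per-specimen-pair frame of proximity densities."""
    return pd.DataFrame(
        [
            {
                "specimen_id": p.specimen_id,
                "patient_id": p.patient_id,
                "arm": p.arm,
                "timepoint": p.timepoint,
                "ref_phenotype": p.ref_phenotype,
                "target_phenotype": p.target_phenotype,
                "radius_um": p.radius_um,
                "n_fields": len(p.per_field_mean_counts),
                "specimen_mean_count": p.specimen_mean_count,
            }
            for p in results
        ]
    )
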