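"""Phenotype gating and infiltration densities.

Lineage is assigned by exclusive gating on the lineage markers: CD20+ cells
are B cells, else CD4+ cells are CD4 T cells, else CD8+ cells are CD8 T
cells, else "other". A cell positive for more than one lineage marker is
flagged ambiguous and assigned "other" rather than being given a fabricated
lineage (and never silently dropped). Differentiation subsets ride on top of
the lineage: CD127/FoxP3 for CD4 T cells, CD127/KLRG1 for CD8 T cells.

Infiltration level is the ratio of phenotype-positive cells to all
DAPI-segmented cells in a field; subset phenotypes are nested (a
CD8+CD127+ cell counts toward both CD8_T and CD8_T+CD127).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedResultError, ValidationError
from .io_model import CellRecord, ClinicalRecord, Field, Specimen

logger = logging.getLogger("tilspatial")

LINEAGES = ("B_cell", "CD4_T", "CD8_T", "other")

#: Subset markers admissible per lineage.
SUBSET_MARKERS = {"CD4_T": ("CD127", "FoxP3"), "CD8_T": ("CD127", "KLRG1")}

#: The TIL phenotypes analysed by default (lineages and their subsets).
DEFAULT_PHENOTYPES = (
    "B_cell",
    "CD4_T",
    "CD4_T+CD127",
    "CD4_T+FoxP3",
    "CD8_T",
    "CD8_T+CD127",
    "CD8_T+KLRG1",
)


@dataclass(frozen=True)
class PhenotypeLabel:
    """A lineage plus the differentiation subsets the cell carries."""

    lineage: str
    subsets: frozenset[str] = dc_field(default_factory=frozenset)
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValidationError(f"unknown lineage {self.lineage!r}")
        allowed = set(SUBSET_MARKERS.get(self.lineage, ()))
        if not set(self.subsets) <= allowed:
            raise ValidationError(
                f"subsets {set(self.subsets)} not admissible for {self.lineage}"
            )

    def __str__(self) -> str:
        if not self.subsets:
            return self.lineage
        return self.lineage + "+" + "+".join(sorted(self.subsets))


def parse_phenotype(spec: str) -> tuple[str, tuple[str, ...]]:
    """Split a phenotype spec like ``"CD8_T+CD127"`` into (lineage, subsets)."""
    parts = spec.split("+")
    lineage, subsets = parts[0], tuple(parts[1:])
    if spec != "DAPI" and lineage not in LINEAGES:
        raise ContractError(f"unknown phenotype {spec!r}")
    allowed = set(SUBSET_MARKERS.get(lineage, ()))
    if not set(subsets) <= allowed:
        raise ContractError(f"subsets {subsets} not admissible for lineage {lineage}")
    return lineage, subsets


def assign_phenotype(cell: CellRecord) -> PhenotypeLabel:
    """Gate a single cell into its phenotype label.

    Cells positive for more than one of CD20/CD4/CD8 are returned as
    "other" with ``ambiguous=True`` and a warning is logged.
    """
    m = cell.markers
    pos = [mk for mk in ("CD20", "CD4", "CD8") if m.get(mk, False)]
    if len(pos) > 1:
        logger.warning(
            "cell %s positive for multiple lineage markers %s; assigned 'other'",
            cell.cell_id,
            pos,
        )
        label = PhenotypeLabel("other", frozenset(), ambiguous=True)
    elif pos == ["CD20"]:
        label = PhenotypeLabel("B_cell")
    elif pos == ["CD4"]:
        subs = frozenset(s for s in SUBSET_MARKERS["CD4_T"] if m.get(s, False))
        label = PhenotypeLabel("CD4_T", subs)
    elif pos == ["CD8"]:
        subs = frozenset(s for s in SUBSET_MARKERS["CD8_T"] if m.get(s, False))
        label = PhenotypeLabel("CD8_T", subs)
    else:
        label = PhenotypeLabel("other")
    cell.phenotype = label
    return label


def assign_phenotypes(field: Field) -> Field:
    """Vectorised gating: adds ``lineage`` and ``ambiguous`` columns in place."""
    df = field.cells
    cd20 = df["CD20"].to_numpy(dtype=bool)
    cd4 = df["CD4"].to_numpy(dtype=bool)
    cd8 = df["CD8"].to_numpy(dtype=bool)
    n_pos = cd20.astype(int) + cd4.astype(int) + cd8.astype(int)
    ambiguous = n_pos > 1
    lineage = np.full(len(df), "other", dtype=object)
    lineage[cd20 & ~ambiguous] = "B_cell"
    lineage[cd4 & ~ambiguous] = "CD4_T"
    lineage[cd8 & ~ambiguous] = "CD8_T"
    if ambiguous.any():
        ids = df.loc[ambiguous, "cell_id"].tolist()
        logger.warning(
            "field %s: %d cell(s) with conflicting lineage markers assigned "
            "'other': %s%s",
            field.field_id,
            int(ambiguous.sum()),
            ids[:5],
            "..." if len(ids) > 5 else "",
        )
    df["lineage"] = lineage
    df["ambiguous"] = ambiguous
    return field


def ensure_phenotyped(field: Field) -> Field:
    if "lineage" not in field.cells.columns:
        assign_phenotypes(field)
    return field


def phenotype_mask(field: Field, phenotype: str) -> np.ndarray:
    """Boolean row mask of cells counting toward ``phenotype``.

    ``"DAPI"`` selects every segmented cell. Subset specs are nested: the
    mask for ``"CD8_T+CD127"`` is a subset of the mask for ``"CD8_T"``.
    """
    if phenotype == "DAPI":
        return np.ones(field.n_cells, dtype=bool)
    ensure_phenotyped(field)
    lineage, subsets = parse_phenotype(phenotype)
    mask = (field.cells["lineage"] == lineage).to_numpy()
    for s in subsets:
        mask &= field.cells[s].to_numpy(dtype=bool)
    return mask


def field_density(field: Field, phenotype: str) -> float:
    """Ratio of phenotype-positive cells to DAPI cells in one field."""
    if field.n_cells == 0:
        raise UndefinedResultError(
            f"field {field.field_id}: density undefined for empty field"
        )
    return float(phenotype_mask(field, phenotype).sum()) / field.n_cells


def _field_counts(field: Field, phenotype: str) -> tuple[int, int]:
    return int(phenotype_mask(field, phenotype).sum()), field.n_cells


@dataclass
class DensityResult:
    """Per-specimen infiltration level for one phenotype."""

    specimen_id: str
    patient_id: str
    arm: str
    timepoint: str
    phenotype: str
    per_field_ratios: list[float]
    specimen_ratio: float


def specimen_density(
    specimen: Specimen, phenotype: str, aggregate: str = "mean"
) -> DensityResult:
    """Aggregate per-field ratios into one specimen-level infiltration value.

    ``aggregate="mean"`` (default) takes the unweighted mean of per-field
    ratios; ``"pooled"`` divides summed phenotype counts by summed DAPI
    counts across fields.
    """
    if aggregate not in ("mean", "pooled"):
        raise ContractError(f"unknown aggregation {aggregate!r}")
    nonempty = [f for f in specimen.fields if f.n_cells > 0]
    if not nonempty:
        raise UndefinedResultError(
            f"specimen {specimen.specimen_id}: all fields empty"
        )
    ratios = [field_density(f, phenotype) for f in nonempty]
    if aggregate == "mean":
        agg = float(np.mean(ratios))
    else:
        counts = [_field_counts(f, phenotype) for f in nonempty]
        agg = sum(c for c, _ in counts) / sum(n for _, n in counts)
    return DensityResult(
        specimen_id=specimen.specimen_id,
        patient_id=specimen.patient_id,
        arm=specimen.arm,
        timepoint=specimen.timepoint,
        phenotype=phenotype,
        per_field_ratios=ratios,
        specimen_ratio=agg,
    )


def specimen_density_table(
    specimens: Iterable[Specimen],
    clinical: Sequence[ClinicalRecord] | None = None,
    phenotypes: Sequence[str] = DEFAULT_PHENOTYPES,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """One row per specimen x phenotype with aggregated infiltration ratios.

    When ``clinical`` is given, each row is joined to the patient's mean
    viable-tumor percentage and response category.
    """
    from .pathology_response import classify_response, mean_viable_percent

    rows = []
    for sp in specimens:
        for ph in phenotypes:
            res = specimen_density(sp, ph, aggregate=aggregate)
            rows.append(
                {
                    "specimen_id": res.specimen_id,
                    "patient_id": res.patient_id,
                    "arm": res.arm,
                    "timepoint": res.timepoint,
                    "phenotype": ph,
                    "n_fields": len(res.per_field_ratios),
                    "specimen_ratio": res.specimen_ratio,
                }
            )
    df = pd.DataFrame(rows)
    if clinical is not None:
        cmap = {}
        for rec in clinical:
            mv = mean_viable_percent(rec.viable_percent_per_slide)
            cmap[rec.patient_id] = (mv, classify_response(mv))
        df["mean_viable_percent"] = df["patient_id"].map(
            lambda p: cmap[p][0] if p in cmap else np.nan
        )
        df["response"] = df["patient_id"].map(
            lambda p: cmap[p][1] if p in cmap else None
        )
    return df
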