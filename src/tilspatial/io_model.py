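"""Data model and tabular I/O for multiplex-IHC cell tables and clinical data.

The in-memory containers follow the study design they describe: a
:class:`Field` is one 20x multispectral image region holding segmented cells
with binary marker calls; a :class:`Specimen` is one patient-by-timepoint
sample holding (nominally ten) fields; :class:`ClinicalRecord` carries the
per-slide viable-tumor percentages and DFS/OS follow-up used downstream.

Cells are stored column-wise in a :class:`pandas.DataFrame` (one row per
cell) so that spatial and phenotype operations stay vectorised;
:class:`CellRecord` is the single-cell view used for record-level APIs.

Conventions: coordinates are continuous micrometres with the origin at the
field's lower-left corner; fields are axis-aligned rectangles (default
669 x 500 um, configurable); marker calls are binary 0/1; inputs are
comma-separated UTF-8 with a header, outputs are tab-separated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger("tilspatial")

#: Marker panel: nuclear stain plus the six surface/transcription-factor markers.
MARKER_PANEL: tuple[str, ...] = ("DAPI", "CD4", "CD8", "CD20", "CD127", "KLRG1", "FoxP3")

#: Required columns of a per-field cell table, in canonical order.
CELL_COLUMNS: tuple[str, ...] = ("cell_id", "x_um", "y_um") + MARKER_PANEL

#: Default field geometry in micrometres (rectangular 20x field).
DEFAULT_FIELD_WIDTH_UM = 669.0
DEFAULT_FIELD_HEIGHT_UM = 500.0

ARMS = ("NAC", "NAPC")
TIMEPOINTS = ("pre", "post")


@dataclass
class CellRecord:
    """One segmented cell: position, binary marker calls, optional phenotype."""

    cell_id: str
    x_um: float
    y_um: float
    markers: dict[str, bool]
    phenotype: object | None = None


@dataclass
class Field:
    """One imaged region: axis-aligned rectangle plus its cell table.

    ``cells`` must contain :data:`CELL_COLUMNS`; phenotype columns may be
    added later by :mod:`tilspatial.phenotyping`.
    """

    field_id: str
    width_um: float
    height_um: float
    cells: pd.DataFrame
    validate: bool = dc_field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValidationError(
                f"field {self.field_id}: non-positive dimensions "
                f"{self.width_um} x {self.height_um}"
            )
        if self.validate:  # trusted internal constructors may skip the scan
            validate_cell_frame(self.cells, self.width_um, self.height_um, self.field_id)

    @property
    def area_um2(self) -> float:
        """Observation-window area alpha in square micrometres."""
        return self.width_um * self.height_um

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def points(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n, 2) array of cell coordinates, optionally row-masked."""
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        return xy if mask is None else xy[np.asarray(mask, dtype=bool)]

    def records(self) -> Iterable[CellRecord]:
        for row in self.cells.itertuples(index=False):
            yield CellRecord(
                cell_id=str(row.cell_id),
                x_um=float(row.x_um),
                y_um=float(row.y_um),
                markers={m: bool(getattr(row, m)) for m in MARKER_PANEL},
            )


@dataclass
class Specimen:
    """One patient-by-timepoint sample and its imaged fields."""

    patient_id: str
    arm: str
    timepoint: str
    fields: list[Field]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r} (expected one of {ARMS})")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r} (expected one of {TIMEPOINTS})"
            )
        if not self.fields:
            raise ValidationError(f"specimen {self.specimen_id}: no fields")

    @property
    def specimen_id(self) -> str:
        return f"{self.patient_id}_{self.timepoint}"


@dataclass
class ClinicalRecord:
    """Per-patient response inputs and survival follow-up.

    ``viable_percent_per_slide`` holds the pathologist-estimated percentage
    of viable tumor per H&E slide (1-5 slides per patient); DFS/OS times are
    months from surgery, with event=True meaning recurrence/death observed.
    """

    patient_id: str
    arm: str
    viable_percent_per_slide: list[float]
    dfs_time: float
    dfs_event: bool
    os_time: float
    os_event: bool
    covariates: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"{self.patient_id}: unknown arm {self.arm!r}")
        if not self.viable_percent_per_slide:
            raise ValidationError(f"{self.patient_id}: no slide viable percentages")
        for v in self.viable_percent_per_slide:
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{self.patient_id}: viable percent {v} outside [0, 100]"
                )
        for name, t in (("dfs_time", self.dfs_time), ("os_time", self.os_time)):
            if t < 0:
                raise ValidationError(f"{self.patient_id}: negative {name} {t}")


@dataclass
class TLSAnnotation:
    """Tertiary-lymphoid-structure count over an evaluated tissue area."""

    specimen_id: str
    tls_count: int
    evaluated_area_mm2: float

    def __post_init__(self) -> None:
        if self.tls_count < 0:
            raise ValidationError(f"{self.specimen_id}: negative TLS count")
        if not self.evaluated_area_mm2 > 0:
            raise ValidationError(
                f"{self.specimen_id}: evaluated area must be positive, "
                f"got {self.evaluated_area_mm2}"
            )


def validate_cell_frame(
    df: pd.DataFrame, width_um: float, height_um: float, field_id: str = "?"
) -> None:
    """Check a cell table against the data-model invariants.

    Raises :class:`SchemaError` for missing columns, :class:`ParseError`
    for non-binary marker values and :class:`ValidationError` for
    out-of-rectangle coordinates, DAPI-negative rows or duplicate cell ids.
    """
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"field {field_id}: missing column {col!r}")
    for m in MARKER_PANEL:
        vals = pd.unique(df[m])
        bad = [v for v in vals if v not in (0, 1, True, False)]
        if bad:
            raise ParseError(
                f"field {field_id}: marker {m} has non-0/1 value(s) {bad[:3]}"
            )
    x = df["x_um"].to_numpy(dtype=float)
    y = df["y_um"].to_numpy(dtype=float)
    out = ~((x >= 0) & (x <= width_um) & (y >= 0) & (y <= height_um))
    if out.any():
        cid = df["cell_id"].iloc[int(np.flatnonzero(out)[0])]
        raise ValidationError(
            f"field {field_id}: cell {cid} at "
            f"({x[out][0]}, {y[out][0]}) outside {width_um} x {height_um} rectangle"
        )
    if len(df) and not df["DAPI"].astype(bool).all():
        cid = df.loc[~df["DAPI"].astype(bool), "cell_id"].iloc[0]
        raise ValidationError(f"field {field_id}: cell {cid} is DAPI-negative")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"field {field_id}: duplicate cell_id {dup!r}")


def read_cell_table(
    path: str | Path,
    width_um: float = DEFAULT_FIELD_WIDTH_UM,
    height_um: float = DEFAULT_FIELD_HEIGHT_UM,
    field_id: str | None = None,
) -> Field:
    """Read one per-field cell CSV into a validated :class:`Field`.

    The CSV must carry the header ``cell_id,x_um,y_um,DAPI,CD4,CD8,CD20,
    CD127,KLRG1,FoxP3`` with marker positivity encoded as 0/1. Row order is
    preserved and coordinates are parsed as decimal micrometres.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str})
    if field_id is None:
        field_id = path.stem
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    for col in ("x_um", "y_um"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path.name}: column {col} is not numeric: {exc}") from exc
    for m in MARKER_PANEL:
        vals = pd.unique(df[m])
        if not set(map(str, vals)) <= {"0", "1", "True", "False"}:
            raise ParseError(f"{path.name}: marker {m} has non-0/1 values {list(vals)[:3]}")
        df[m] = df[m].astype(int).astype(np.int8)
    df = df[list(CELL_COLUMNS)]
    return Field(field_id=field_id, width_um=width_um, height_um=height_um, cells=df)


def read_field_geometry(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a field-geometry CSV (field_id,width_um,height_um) into a map."""
    df = pd.read_csv(Path(path), dtype={"field_id": str})
    for col in ("field_id", "width_um", "height_um"):
        if col not in df.columns:
            raise SchemaError(f"field geometry: missing column {col!r}")
    geo: dict[str, tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        w, h = float(row.width_um), float(row.height_um)
        if not (w > 0 and h > 0):
            raise ValidationError(f"field {row.field_id}: non-positive geometry")
        geo[str(row.field_id)] = (w, h)
    return geo


_CLINICAL_REQUIRED = (
    "patient_id",
    "arm",
    "viable_percent",
    "dfs_time",
    "dfs_event",
    "os_time",
    "os_event",
)


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read the per-patient clinical CSV.

    ``viable_percent`` is a semicolon-delimited list of per-slide viable-tumor
    percentages (e.g. ``"5;10;8"``). Any additional columns are kept as
    string covariates. Duplicate patient ids are rejected.
    """
    df = pd.read_csv(Path(path), dtype=str)
    for col in _CLINICAL_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"clinical table: missing column {col!r}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"clinical table: duplicate patient_id {dup!r}")
    extra = [c for c in df.columns if c not in _CLINICAL_REQUIRED]
    records = []
    for row in df.itertuples(index=False):
        try:
            viable = [float(v) for v in str(row.viable_percent).split(";") if v != ""]
        except ValueError as exc:
            raise ParseError(
                f"{row.patient_id}: bad viable_percent {row.viable_percent!r}"
            ) from exc
        records.append(
            ClinicalRecord(
                patient_id=str(row.patient_id),
                arm=str(row.arm),
                viable_percent_per_slide=viable,
                dfs_time=_parse_time(row.dfs_time, "dfs_time", row.patient_id),
                dfs_event=_parse_bool(row.dfs_event, "dfs_event", row.patient_id),
                os_time=_parse_time(row.os_time, "os_time", row.patient_id),
                os_event=_parse_bool(row.os_event, "os_event", row.patient_id),
                covariates={c: getattr(row, c) for c in extra},
            )
        )
    return records


def _parse_time(raw: object, name: str, pid: object) -> float:
    try:
        return float(raw)  # negative values rejected by ClinicalRecord
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{pid}: bad {name} {raw!r}") from exc


def _parse_bool(raw: object, name: str, pid: object) -> bool:
    s = str(raw)
    if s in ("0", "1"):
        return s == "1"
    raise ParseError(f"{pid}: {name} must be 0/1, got {raw!r}")


def read_tls_table(path: str | Path) -> list[TLSAnnotation]:
    """Read the TLS annotation CSV (specimen_id,tls_count,evaluated_area_mm2)."""
    df = pd.read_csv(Path(path), dtype={"specimen_id": str})
    for col in ("specimen_id", "tls_count", "evaluated_area_mm2"):
        if col not in df.columns:
            raise SchemaError(f"TLS table: missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        count = float(row.tls_count)
        if count != int(count):
            raise ParseError(f"{row.specimen_id}: non-integer tls_count {row.tls_count}")
        out.append(
            TLSAnnotation(
                specimen_id=str(row.specimen_id),
                tls_count=int(count),
                evaluated_area_mm2=float(row.evaluated_area_mm2),
            )
        )
    return out


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            d = dataclasses.asdict(r)
        elif isinstance(r, Mapping):
            d = dict(r)
        else:
            raise ContractTypeError(r)
        rows.append(
            {
                k: (";".join(repr(x) for x in v) if isinstance(v, (list, tuple)) else v)
                for k, v in d.items()
                if not isinstance(v, (dict,))
            }
        )
    return pd.DataFrame(rows)


class ContractTypeError(TypeError):
    def __init__(self, obj: object) -> None:
        super().__init__(f"cannot serialise record of type {type(obj).__name__}")


def write_result_table(records: Sequence | pd.DataFrame, path: str | Path) -> Path:
    """Write any result collection to TSV with deterministic order.

    Booleans are serialised as 0/1, floats with ``repr`` round-trip
    precision; rows are sorted by the leading identifier columns so two
    writes of the same collection are byte-identical. An empty collection
    yields a header-only file when the columns are known.
    """
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"directory {path.parent} does not exist")
    df = _records_to_frame(records)
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    key_cols = [c for c in df.columns if df[c].dtype == object]
    if len(df) and key_cols:
        df = df.sort_values(by=key_cols, kind="mergesort").reset_index(drop=True)
    for col in df.columns:  # repr is bit-exact on round-trip; str() is not
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, sep="\t", index=False)
    return path


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_result_table`."""
    return pd.read_csv(Path(path), sep="\t", float_precision="round_trip")


def read_config(path: str | Path) -> dict[str, object]:
    """Parse a flat ``key = value`` run-configuration file.

    Values are coerced to int, then float, then left as strings; lines
    starting with ``#`` and blank lines are ignored.
    """
    cfg: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"config line {lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        raw = raw.strip()
        val: object = raw
        for cast in (int, float):
            try:
                val = cast(raw)
                break
            except ValueError:
                continue
        cfg[key.strip()] = val
    return cfg
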