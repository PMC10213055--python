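import numpy as np
import pandas as pd
import pytest

from tilspatial.io_model import CELL_COLUMNS, MARKER_PANEL, Field


def make_field(
    cells_by_phenotype: dict[str, list[tuple[float, float]]],
    width_um: float = 100.0,
    height_um: float = 100.0,
    field_id: str = "f1",
) -> Field:
    """Hand-built field: phenotype key -> list of (x, y) coordinates."""
    from tilspatial.synthetic_data import PHENOTYPE_MARKERS

    rows = []
    i = 0
    for ph, coords in cells_by_phenotype.items():
        markers = PHENOTYPE_MARKERS[ph]
        for (x, y) in coords:
            row = {"cell_id": f"c{i}", "x_um": x, "y_um": y}
            for m in MARKER_PANEL:
                row[m] = 1 if m in markers else 0
            rows.append(row)
            i += 1
    cells = pd.DataFrame(rows, columns=list(CELL_COLUMNS)) if rows else pd.DataFrame(
        {c: [] for c in CELL_COLUMNS}
    )
    return Field(field_id=field_id, width_um=width_um, height_um=height_um, cells=cells)


def random_field(
    rng: np.random.Generator,
    n_by_phenotype: dict[str, int],
    width_um: float = 200.0,
    height_um: float = 200.0,
) -> Field:
    coords = {
        ph: [
            (rng.uniform(0, width_um), rng.uniform(0, height_um))
            for _ in range(n)
        ]
        for ph, n in n_by_phenotype.items()
    }
    return make_field(coords, width_um, height_um)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
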