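"""End-to-end run on a miniature on-disk dataset.

Writes a fixture bundle (2 arms x 4 patients x pre/post x 3 fields) in the
package's input schemas, reads it back through the validating I/O layer,
and runs phenotyping, proximity analysis and an arm comparison — the same
path a real study export would take.
"""

import tempfile
from pathlib import Path

import numpy as np

import tilspatial as ts
from tilspatial.synthetic_data import make_fixture_bundle

out = Path(tempfile.mkdtemp()) / "bundle"
paths = make_fixture_bundle(seed=23, out_dir=out)
print(f"bundle written to {out}")

geo = ts.read_field_geometry(paths["fields"])
clinical = ts.read_clinical_table(paths["clinical"])
arm = {r.patient_id: r.arm for r in clinical}
by_specimen: dict[str, list] = {}
for p in sorted((out / "cells").glob("*.csv")):
    sid = p.stem.rsplit("_f", 1)[0]
    w, h = geo[p.stem]
    by_specimen.setdefault(sid, []).append(ts.read_cell_table(p, width_um=w, height_um=h))
specimens = [
    ts.Specimen(sid.rsplit("_", 1)[0], arm[sid.rsplit("_", 1)[0]],
                sid.rsplit("_", 1)[1], fields)
    for sid, fields in by_specimen.items()
]
print(f"validated {sum(len(s.fields) for s in specimens)} fields "
      f"across {len(specimens)} specimens")

densities = ts.specimen_density_table(specimens, clinical=clinical)
post_cd8 = densities[(densities.phenotype == "CD8_T") & (densities.timepoint == "post")]
for a, g in post_cd8.groupby("arm"):
    print(f"post-treatment CD8_T density, {a}: "
          f"{g.specimen_ratio.mean():.4f} +/- {g.specimen_ratio.std():.4f}")

prox = ts.proximity_frame(
    ts.cohort_proximity([s for s in specimens if s.timepoint == "post"],
                        pairs=[("CD4_T", "CD8_T"), ("B_cell", "CD8_T")])
)
for (rp, tp), g in prox.groupby(["ref_phenotype", "target_phenotype"]):
    means = {a: gg.specimen_mean_count.mean() for a, gg in g.groupby("arm")}
    print(f"proximity {tp} within 30 um of {rp}: "
          + ", ".join(f"{a} {m:.2f}" for a, m in sorted(means.items())))
print("Higher NAPC values reflect the attraction and fold-change effects "
      "the generator plants in the post-NAPC arm (n=4/arm here, so "
      "specimen-level noise is large).")
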