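import math

import numpy as np
import pytest

from tilspatial.errors import ContractError, UndefinedResultError
from tilspatial.spatial_stats import (
    DEFAULT_RADII,
    bivariate_k,
    cohort_proximity,
    count_within_radius,
    euclidean_distance,
    proximity_density,
    proximity_frame,
    radius_sweep,
)
from tilspatial.io_model import Specimen

from conftest import make_field, random_field


def brute_force_counts(ref, target, r, ref_ids=None, target_ids=None):
    """Exhaustive O(n^2) within-radius counts (the oracle)."""
    counts = []
    for i, p in enumerate(ref):
        c = 0
        for j, q in enumerate(target):
            if ref_ids is not None and target_ids is not None:
                if ref_ids[i] == target_ids[j]:
                    continue
            if euclidean_distance(p, q) <= r:
                c += 1
        counts.append(c)
    return np.array(counts)


def brute_force_k(field, ref_ph, tgt_ph, r, normalization, correction):
    """Literal double-sum evaluation of the K estimator."""
    from tilspatial.phenotyping import ensure_phenotyped, phenotype_mask

    ensure_phenotyped(field)
    rm, tm = phenotype_mask(field, ref_ph), phenotype_mask(field, tgt_ph)
    ref, tgt = field.points(rm), field.points(tm)
    ids = field.cells["cell_id"].to_numpy()
    rid, tid = ids[rm], ids[tm]
    W, H, area = field.width_um, field.height_um, field.area_um2
    total = 0.0
    for i, p in enumerate(ref):
        for j, q in enumerate(tgt):
            if rid[i] == tid[j]:
                continue
            d = euclidean_distance(p, q)
            if d <= r:
                if correction == "translation":
                    e = area / ((W - abs(p[0] - q[0])) * (H - abs(p[1] - q[1])))
                else:
                    e = 1.0
                total += e
    n_ref, n_tgt = len(ref), len(tgt)
    denom = n_ref * (n_ref - 1) if normalization == "as_printed" else n_ref * n_tgt
    return area / denom * total


@pytest.mark.parametrize(
    "p, q, expected",
    [
        ((0, 0), (3, 4), 5.0),
        ((7, 7), (7, 7), 0.0),
        ((10, 10), (90, 90), math.sqrt(80**2 + 80**2)),  # 113.1370849898476
    ],
)
def test_euclidean_distance(p, q, expected):
    assert euclidean_distance(p, q) == pytest.approx(expected, abs=1e-12)
    assert euclidean_distance(q, p) == euclidean_distance(p, q)


def test_count_within_radius_boundary_inclusive():
    ref = [(0.0, 0.0)]
    targets = [(10.0, 0.0), (0.0, 29.0), (31.0, 0.0)]
    assert count_within_radius(ref, targets, 30).tolist() == [2]
    assert count_within_radius(ref, targets, 31).tolist() == [3]  # d <= r
    with pytest.raises(ContractError):
        count_within_radius(ref, targets, 0)


def test_count_within_radius_matches_brute_force(rng):
    for _ in range(25):
        n_ref, n_tgt = rng.integers(1, 120), rng.integers(1, 120)
        ref = rng.uniform(0, 200, (n_ref, 2))
        tgt = rng.uniform(0, 200, (n_tgt, 2))
        r = float(rng.uniform(5, 80))
        fast = count_within_radius(ref, tgt, r)
        assert np.array_equal(fast, brute_force_counts(ref, tgt, r))


def test_proximity_density_examples():
    # two reference cells with 2 and 4 target neighbours -> mean 3.0
    f = make_field(
        {
            "CD4_T": [(50, 50), (150, 50)],
            "CD8_T": [(55, 50), (45, 50), (145, 50), (155, 50), (150, 45), (150, 55)],
        },
        width_um=200,
        height_um=100,
    )
    # first ref: 2 within 30; second: 4 within 30
    assert proximity_density(f, "CD4_T", "CD8_T", r=30) == pytest.approx(3.0)


def test_proximity_self_exclusion():
    # one cell that is both CD8_T and CD8_T+CD127; alone it has 0 neighbours
    f = make_field({"CD8_T+CD127": [(50, 50)]})
    assert proximity_density(f, "CD8_T", "CD8_T+CD127", r=30) == 0.0
    assert proximity_density(f, "CD8_T", "CD8_T", r=30) == 0.0
    with pytest.raises(UndefinedResultError):
        proximity_density(f, "CD4_T", "CD8_T", r=30)


def test_bivariate_k_hand_enumeration_cross():
    f = make_field(
        {"CD4_T": [(10, 10), (90, 90)], "CD8_T": [(10, 20), (90, 80)]},
        width_um=100,
        height_um=100,
    )
    est = bivariate_k(f, "CD4_T", "CD8_T", radii=[15.0], normalization="cross", correction="none")
    # exactly 2 of the 4 cross pairs lie within 15 um: K = 10000/(2*2) * 2
    assert est.k_values[0] == pytest.approx(5000.0)


def test_bivariate_k_hand_enumeration_as_printed():
    f = make_field({"CD8_T": [(2, 2), (2, 12)]}, width_um=5, height_um=20)
    est = bivariate_k(
        f, "CD8_T", "CD8_T", radii=[10.0], normalization="as_printed", correction="none"
    )
    # n=2, area=100, both ordered pairs at distance 10: K = 100/(2*1) * 2
    assert est.k_values[0] == pytest.approx(100.0)


def test_as_printed_rejected_for_distinct_phenotypes():
    f = make_field({"CD4_T": [(10, 10)], "CD8_T": [(20, 20)]})
    with pytest.raises(ContractError, match="as_printed"):
        bivariate_k(f, "CD4_T", "CD8_T", radii=[10.0], normalization="as_printed")
    with pytest.raises(UndefinedResultError):
        bivariate_k(f, "CD4_T", "B_cell", radii=[10.0])


def test_k_matches_brute_force_oracle(rng):
    for _ in range(10):
        f = random_field(
            rng, {"CD4_T": int(rng.integers(2, 40)), "CD8_T": int(rng.integers(2, 40))}
        )
        for correction in ("none", "translation"):
            est = bivariate_k(f, "CD4_T", "CD8_T", radii=[25.0], correction=correction)
            oracle = brute_force_k(f, "CD4_T", "CD8_T", 25.0, "cross", correction)
            assert est.k_values[0] == pytest.approx(oracle, rel=1e-12)


def test_k_monotone_and_sweep_consistency(rng):
    f = random_field(rng, {"CD4_T": 30, "CD8_T": 40})
    sweep = radius_sweep(f, "CD4_T", "CD8_T", correction="none")
    assert sweep.k.radii == list(DEFAULT_RADII)
    assert len(sweep.k.k_values) == 6
    # uncorrected K is non-decreasing in r
    assert all(b >= a for a, b in zip(sweep.k.k_values, sweep.k.k_values[1:]))
    # sweep equals six independent single-radius calls
    for r, k, prox in zip(sweep.k.radii, sweep.k.k_values, sweep.proximity.values()):
        single = bivariate_k(f, "CD4_T", "CD8_T", radii=[r], correction="none")
        assert single.k_values[0] == pytest.approx(k, rel=1e-12)
        assert proximity_density(f, "CD4_T", "CD8_T", r=r) == pytest.approx(prox)
    with pytest.raises(ContractError):
        radius_sweep(f, "CD4_T", "CD8_T", radii=[30, 20])


def test_k_symmetry_under_swap(rng):
    f = random_field(rng, {"CD4_T": 25, "CD8_T": 35})
    a = bivariate_k(f, "CD4_T", "CD8_T", radii=[40.0], correction="none")
    b = bivariate_k(f, "CD8_T", "CD4_T", radii=[40.0], correction="none")
    assert a.k_values[0] == pytest.approx(b.k_values[0], rel=1e-12)


@pytest.mark.parametrize("c", [2.5])
def test_scale_equivariance(rng, c):
    f = random_field(rng, {"CD4_T": 20, "CD8_T": 30}, width_um=100, height_um=80)
    scaled_cells = f.cells.copy()
    scaled_cells["x_um"] *= c
    scaled_cells["y_um"] *= c
    g = type(f)("scaled", f.width_um * c, f.height_um * c, scaled_cells)
    r = 20.0
    k1 = bivariate_k(f, "CD4_T", "CD8_T", radii=[r], correction="translation")
    k2 = bivariate_k(g, "CD4_T", "CD8_T", radii=[c * r], correction="translation")
    assert k2.k_values[0] == pytest.approx(c**2 * k1.k_values[0], rel=1e-9)
    assert proximity_density(g, "CD4_T", "CD8_T", r=c * r) == pytest.approx(
        proximity_density(f, "CD4_T", "CD8_T", r=r)
    )


def test_csr_calibration_small():
    """Translation-corrected cross-K is unbiased under CSR (pi r^2)."""
    from tilspatial.synthetic_data import FieldSimConfig, simulate_csr_field

    rng = np.random.default_rng(5)
    cfg = FieldSimConfig(intensities={"CD4_T": 0.0005, "CD8_T": 0.0005})
    vals = []
    for i in range(150):
        f = simulate_csr_field(cfg, rng, field_id=f"f{i}")
        try:
            est = bivariate_k(f, "CD4_T", "CD8_T", radii=[30.0])
        except UndefinedResultError:
            continue
        vals.append(est.k_values[0])
    vals = np.array(vals)
    target = math.pi * 30**2
    se = vals.std(ddof=1) / math.sqrt(len(vals))
    assert abs(vals.mean() - target) <= 3 * se


def test_cohort_proximity_matches_field_calls(rng):
    fields = [random_field(rng, {"CD4_T": 8, "CD8_T": 12, "other": 20}) for _ in range(4)]
    sp = Specimen("p1", "NAPC", "post", fields)
    res = cohort_proximity([sp], pairs=[("CD4_T", "CD8_T")], r=30)
    assert len(res) == 1
    expected = np.mean([proximity_density(f, "CD4_T", "CD8_T", r=30) for f in fields])
    assert res[0].specimen_mean_count == pytest.approx(float(expected))
    assert res[0].per_field_mean_counts == pytest.approx(
        [proximity_density(f, "CD4_T", "CD8_T", r=30) for f in fields]
    )
    df = proximity_frame(res)
    assert df.loc[0, "arm"] == "NAPC" and df.loc[0, "n_fields"] == 4


def test_cohort_proximity_excludes_refless_specimen(rng, caplog):
    f = random_field(rng, {"CD8_T": 10, "other": 10})  # no CD4 reference cells
    sp = Specimen("p1", "NAC", "post", [f])
    res = cohort_proximity([sp], pairs=[("CD4_T", "CD8_T")])
    assert res == []
    # single field specimen mean equals the field value
    g = random_field(rng, {"CD4_T": 5, "CD8_T": 10})
    sp2 = Specimen("p2", "NAC", "post", [g])
    res2 = cohort_proximity([sp2], pairs=[("CD4_T", "CD8_T")])
    assert res2[0].specimen_mean_count == res2[0].per_field_mean_counts[0]
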