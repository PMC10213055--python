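import itertools
import math

import numpy as np
import pytest
from scipy import stats

from tilspatial.errors import ContractError, UndefinedResultError, ValidationError
from tilspatial.cohort_stats import (
    chi_square_test,
    kaplan_meier,
    kruskal_wallis,
    logrank,
    mann_whitney,
    median_split,
    optimal_cutoff_split,
    spearman,
    two_way_anova,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# enumeration oracles (independent of the implementations under test)


def mw_exact_oracle(x, y):
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(pooled)
    mu = nx * len(y) / 2
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        total += 1
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return hits / total


def wsr_exact_oracle(diffs):
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = m * (m + 1) / 4
    hits = 0
    for signs in itertools.product([0, 1], repeat=m):
        w = sum(r for s, r in zip(signs, ranks) if s)
        hits += abs(w - mu) >= abs(w_obs - mu) - 1e-12
    return hits / 2**m


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_fully_separated():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2 of 20 labelings as extreme


def test_mann_whitney_identical_multisets():
    res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
    assert res.p_value >= 0.99


def test_mann_whitney_matches_enumeration(rng):
    """Both branches agree with the labeling-enumeration oracle at n=8+8."""
    for _ in range(5):
        x = rng.normal(size=8)
        y = rng.normal(0.8, size=8)
        exact = mw_exact_oracle(x, y)
        assert mann_whitney(x, y).p_value == pytest.approx(exact, abs=0.005)
        # force the asymptotic branch on the same data
        approx = mann_whitney(x, y, exact_max_n=4).p_value
        assert approx == pytest.approx(exact, abs=0.02)


def test_mann_whitney_with_ties_matches_enumeration(rng):
    x = rng.integers(0, 4, size=6).astype(float)
    y = rng.integers(1, 5, size=6).astype(float)
    assert mann_whitney(x, y).p_value == pytest.approx(mw_exact_oracle(x, y), abs=1e-12)


def test_mann_whitney_empty_sample():
    with pytest.raises(ContractError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def test_wilcoxon_uniform_shift():
    pre = np.arange(6, dtype=float)
    res = wilcoxon_signed_rank(pre, pre + 1)
    assert res.p_value == pytest.approx(2 / 64)  # 0.03125, smallest possible


def test_wilcoxon_all_zero_differences():
    with pytest.raises(UndefinedResultError):
        wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


def test_wilcoxon_matches_enumeration(rng):
    for _ in range(5):
        pre = rng.normal(size=9)
        post = pre + rng.normal(0.4, 1.0, size=9)
        exact = wsr_exact_oracle(post - pre)
        assert wilcoxon_signed_rank(pre, post).p_value == pytest.approx(exact, abs=1e-12)
        approx = wilcoxon_signed_rank(pre, post, exact_max_n=4).p_value
        assert approx == pytest.approx(exact, abs=0.04)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def test_kruskal_wallis_identical_groups():
    g = [1.0, 2.0, 3.0]
    res = kruskal_wallis([g, g, g])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_kruskal_wallis_hand_formula():
    groups = [[1, 2], [3, 4], [5, 6]]
    # ranks 1..6, rank sums 3, 7, 11: H = 12/(6*7) * sum(R^2/2) - 3*7
    h_expected = 12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21
    res = kruskal_wallis(groups)
    assert res.statistic == pytest.approx(h_expected)
    assert res.p_value == pytest.approx(float(stats.chi2.sf(h_expected, 2)))


def test_kruskal_wallis_monotone_invariance(rng):
    groups = [rng.normal(size=7), rng.normal(1, 1, size=5), rng.normal(size=6)]
    a = kruskal_wallis(groups)
    b = kruskal_wallis([np.exp(g) for g in groups])  # strictly monotone map
    assert a.statistic == pytest.approx(b.statistic)
    with pytest.raises(ContractError):
        kruskal_wallis([groups[0]])


# ---------------------------------------------------------------------------
# two-way ANOVA


def test_anova_pure_main_effect_zero_interaction():
    # zero-noise data with a pure time effect: interaction F = 0
    values = [1, 1, 3, 3, 1, 1, 3, 3]
    a = ["NR", "NR", "NR", "NR", "R", "R", "R", "R"]
    b = ["pre", "pre", "post", "post", "pre", "pre", "post", "post"]
    res = two_way_anova(values, a, b)
    assert res.interaction.statistic == 0.0
    assert res.main_a.statistic == 0.0
    assert res.interaction.p_value == 1.0


def _textbook_ss(values, fa, fb):
    """Balanced-design sums of squares from cell/marginal means."""
    import pandas as pd

    df = pd.DataFrame({"y": values, "a": fa, "b": fb})
    grand = df["y"].mean()
    n_cell = len(df) / 4
    ss_a = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("a")
    )
    ss_b = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("b")
    )
    ss_cells = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby(["a", "b"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((g["y"] - g["y"].mean()) ** 2).sum() for _, g in df.groupby(["a", "b"])
    )
    df_err = len(df) - 4
    return (ss_a, ss_b, ss_ab, ss_err, df_err, n_cell)


def test_anova_balanced_matches_textbook(rng):
    values = rng.normal(size=16)
    fa = ["NR"] * 8 + ["R"] * 8
    fb = (["pre"] * 4 + ["post"] * 4) * 2
    ss_a, ss_b, ss_ab, ss_err, df_err, _ = _textbook_ss(values, fa, fb)
    res = two_way_anova(values, fa, fb)
    mse = ss_err / df_err
    assert res.main_a.statistic == pytest.approx(ss_a / mse)
    assert res.main_b.statistic == pytest.approx(ss_b / mse)
    assert res.interaction.statistic == pytest.approx(ss_ab / mse)


def test_anova_unbalanced_matches_normal_equations(rng):
    """Type II F for each effect = (RSS_reduced - RSS_full-effect) / mse via
    direct least squares, computed independently with numpy.lstsq."""
    n_cells = {"NR pre": 3, "NR post": 5, "R pre": 4, "R post": 6}
    values, fa, fb = [], [], []
    for key, n in n_cells.items():
        a, b = key.split()
        mu = {"NR pre": 0, "NR post": 1, "R pre": 0.5, "R post": 2.5}[key]
        for v in rng.normal(mu, 1.0, n):
            values.append(v)
            fa.append(a)
            fb.append(b)
    x_a = np.array([1.0 if v == "R" else 0.0 for v in fa])
    x_b = np.array([1.0 if v == "post" else 0.0 for v in fb])
    one = np.ones(len(values))
    y = np.array(values)

    def rss(*cols):
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return ((y - X @ beta) ** 2).sum()

    rss_full = rss(one, x_a, x_b, x_a * x_b)
    df_err = len(y) - 4
    mse = rss_full / df_err
    # Type II: each main effect adjusted for the other main effect only
    f_a = (rss(one, x_b) - rss(one, x_a, x_b)) / mse
    f_b = (rss(one, x_a) - rss(one, x_a, x_b)) / mse
    f_ab = (rss(one, x_a, x_b) - rss_full) / mse
    res = two_way_anova(values, fa, fb)
    assert res.main_a.statistic == pytest.approx(f_a)
    assert res.main_b.statistic == pytest.approx(f_b)
    assert res.interaction.statistic == pytest.approx(f_ab)
    assert len(res.pairwise) == 6
    assert all(t.adjustment == "holm" for t in res.pairwise)
    with pytest.raises(ContractError):
        two_way_anova([1, 2, 3], ["NR", "NR", "R"], ["pre", "pre", "pre"])


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_formula_2x2():
    # direct 2x2 formula n(ad - bc)^2 / (row and column margins)
    a, b, c, d = 24, 12, 6, 23
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    res = chi_square_test([[a, b], [c, d]])
    assert res.statistic == pytest.approx(expected)
    assert res.statistic == pytest.approx(13.66, abs=0.005)
    assert res.p_value < 0.001


def test_chi_square_independence_and_symmetry():
    res = chi_square_test([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.p_value == 1.0
    t = [[24, 12], [6, 23]]
    assert chi_square_test(t).statistic == pytest.approx(
        chi_square_test(np.transpose(t)).statistic
    )
    with pytest.raises(ContractError):
        chi_square_test([[0, 0], [5, 5]])
    with pytest.raises(ValidationError):
        chi_square_test([[1, -2], [3, 4]])


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_monotone():
    x = [1.0, 2.0, 5.0, 9.0]
    assert spearman(x, [2.0, 4.0, 6.0, 8.0]).statistic == pytest.approx(1.0)
    assert spearman(x, [8.0, 6.0, 4.0, 2.0]).statistic == pytest.approx(-1.0)
    with pytest.raises(ContractError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_exact_matches_permutation_oracle(rng):
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    rho_obs = spearman(x, y).statistic
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        hits += abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_obs) - 1e-12
    assert spearman(x, y).p_value == pytest.approx(hits / total, abs=1e-12)


# ---------------------------------------------------------------------------
# survival


def test_kaplan_meier_all_events():
    curve = kaplan_meier([1.0, 2.0, 3.0], [True, True, True])
    assert curve.times == [1.0, 2.0, 3.0]
    assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
    assert curve.at_risk == [3, 2, 1]


def test_kaplan_meier_all_censored_and_negative():
    curve = kaplan_meier([1.0, 2.0], [False, False])
    assert curve.times == [] and curve.survival == []
    with pytest.raises(ValidationError):
        kaplan_meier([-1.0], [True])


def test_kaplan_meier_hand_computation():
    # events at 2 (1 of 5 at risk) and 4 (1 of 3 at risk); censor at 3
    times = [2.0, 3.0, 4.0, 5.0, 6.0]
    events = [True, False, True, False, False]
    curve = kaplan_meier(times, events)
    assert curve.times == [2.0, 4.0]
    assert curve.survival == pytest.approx([4 / 5, 4 / 5 * 2 / 3])


def test_km_no_censoring_equals_empirical(rng):
    times = np.round(rng.exponential(10, 40), 1) + 0.1
    curve = kaplan_meier(times, np.ones(40, dtype=bool))
    for t, s in zip(curve.times, curve.survival):
        assert s == pytest.approx((times > t).mean(), abs=1e-12)


def test_logrank_identical_groups():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [True, True, False, True]
    res = logrank(t, e, t, e)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.extra["hazard_ratio"] == pytest.approx(1.0)


def test_logrank_swap_inverts_hr(rng):
    t1 = rng.exponential(5, 30)
    t2 = rng.exponential(15, 30)
    e = np.ones(30, dtype=bool)
    a = logrank(t1, e, t2, e)
    b = logrank(t2, e, t1, e)
    assert a.extra["hazard_ratio"] == pytest.approx(1 / b.extra["hazard_ratio"])
    assert a.p_value == pytest.approx(b.p_value)
    with pytest.raises(UndefinedResultError):
        logrank([1.0], [False], [2.0], [False])


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test

    t1 = rng.exponential(5, 25)
    t2 = rng.exponential(9, 35)
    e1 = rng.random(25) < 0.8
    e2 = rng.random(35) < 0.8
    ours = logrank(t1, e1, t2, e2)
    ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
    assert ours.p_value == pytest.approx(ref.p_value, rel=1e-6)


def test_optimal_cutoff_matches_brute_force(rng):
    n = 60
    values = rng.normal(size=n)
    times = rng.exponential(10 * np.exp(-(values > 0.3).astype(float)), n)
    events = rng.random(n) < 0.8
    res = optimal_cutoff_split(values, times, events, minprop=0.1)

    # independent exhaustive scan using lifelines' log-rank
    from lifelines.statistics import logrank_test

    best_c, best_z = None, -1.0
    for c in np.unique(values)[:-1]:
        low = values <= c
        if low.sum() < 0.1 * n or (n - low.sum()) < 0.1 * n:
            continue
        lr = logrank_test(times[low], times[~low], events[low], events[~low])
        z = math.sqrt(lr.test_statistic)
        if z > best_z + 1e-12:
            best_c, best_z = float(c), z
    assert res.cutoff == pytest.approx(best_c)
    assert res.statistic == pytest.approx(best_z, rel=1e-9)
    assert min(res.n_low, res.n_high) >= 0.1 * n


def test_optimal_cutoff_degenerate_inputs():
    times = list(np.arange(1.0, 13.0))
    events = [True] * 12
    with pytest.raises(ContractError):
        optimal_cutoff_split([5.0] * 12, times, events)
    with pytest.raises(ContractError):
        optimal_cutoff_split([1, 2, 3], [1, 2, 3], [True] * 3)


def test_median_split_rules():
    high = median_split([1, 2, 3, 4])
    assert high.tolist() == [False, False, True, True]
    high = median_split([1, 2, 2, 3])  # median 2: ties go high
    assert high.tolist() == [False, True, True, True]
    assert median_split([5, 5, 5]).all()  # all equal: everyone high
    with pytest.raises(ContractError):
        median_split([])
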