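"""Cohort-level statistics: rank tests, ANOVA, contingency, survival.

All p-values are two-sided, tested at alpha = 0.05. The small-sample rank
tests (Mann-Whitney, Wilcoxon signed-rank, Spearman) switch to full
permutation/sign enumeration below a size threshold so that tied data are
handled exactly; above the threshold they use tie-corrected normal (or t)
approximations. Survival analysis uses the Kaplan-Meier product-limit
estimator and the Mantel-Haenszel log-rank test, with the hazard ratio
estimated as (O1/E1)/(O2/E2) and a log-scale confidence interval.

Dichotomisation utilities mirror the two conventions used in translational
cohort studies: a median split (ties assigned to the high group) and the
maximally selected rank statistic, which scans admissible cutpoints of a
continuous variable and picks the one maximising the standardised log-rank
statistic. The maximally-selected p-value is deliberately NOT corrected for
the cutpoint search here; the returned log-rank p at the chosen cutpoint is
descriptive and subject to selection bias (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, UndefinedResultError, ValidationError

ALPHA = 0.05

#: Pooled-size threshold below which Mann-Whitney enumerates all labelings.
MW_EXACT_MAX_N = 16
#: Nonzero-pair threshold below which Wilcoxon enumerates all sign patterns.
WILCOXON_EXACT_MAX_N = 15
#: Sample-size threshold below which Spearman enumerates all permutations.
SPEARMAN_EXACT_MAX_N = 7


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    adjustment: str = "none"
    extra: dict = dc_field(default_factory=dict)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate: step values at the distinct event times."""

    times: list[float]
    survival: list[float]
    at_risk: list[int]


@dataclass
class CutoffResult:
    """Maximally selected cutpoint of a continuous variable."""

    variable: str
    cutoff: float
    n_low: int
    n_high: int
    statistic: float  # |standardised log-rank| at the cutpoint
    p_value: float  # plain log-rank p at the cutpoint; selection-biased


# ---------------------------------------------------------------------------
# rank tests


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = MW_EXACT_MAX_N
) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    For pooled sizes up to ``exact_max_n`` the two-sided p is computed by
    full enumeration of all C(n, nx) group labelings (exact even under
    ties); larger samples use the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ContractError("mann_whitney: empty sample")
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mu = nx * ny / 2.0
    if n <= exact_max_n:
        dev = abs(u - mu)
        rank_min = nx * (nx + 1) / 2
        hits = total = 0
        for idx in itertools.combinations(range(n), nx):
            u_perm = ranks[list(idx)].sum() - rank_min
            total += 1
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        _, t = np.unique(pooled, return_counts=True)
        var = nx * ny / 12.0 * ((n + 1) - (t**3 - t).sum() / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)
            p = 2.0 * stats.norm.sf(z)
    return TestResult("mann_whitney", u, min(p, 1.0), (nx, ny))


def wilcoxon_signed_rank(
    pre: Sequence[float], post: Sequence[float], exact_max_n: int = WILCOXON_EXACT_MAX_N
) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; ties in |difference| get midranks. Up to
    ``exact_max_n`` nonzero pairs the p-value enumerates all 2^m sign
    patterns; beyond that the tie-corrected normal approximation with
    continuity correction is used.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ContractError("wilcoxon: unequal lengths")
    d = post - pre
    d = d[d != 0]
    m = len(d)
    if m == 0:
        raise UndefinedResultError("wilcoxon: all differences are zero")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = m * (m + 1) / 4.0
    if m <= exact_max_n:
        dev = abs(w_plus - mu)
        signs = (
            np.arange(2**m)[:, None] >> np.arange(m)[None, :]
        ) & 1  # all sign patterns
        sums = signs @ ranks
        p = float(np.mean(np.abs(sums - mu) >= dev - 1e-12))
    else:
        _, t = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - ((t**3 - t).sum()) / 48.0
        z = max(abs(w_plus - mu) - 0.5, 0.0) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(z)
    return TestResult("wilcoxon_signed_rank", w_plus, min(p, 1.0), (m,))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p with k-1 df)."""
    if len(groups) < 2:
        raise ContractError("kruskal_wallis: need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ContractError("kruskal_wallis: empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # scipy rejects all-identical data
        return TestResult("kruskal_wallis", 0.0, 1.0, tuple(len(a) for a in arrays))
    h, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(p), tuple(len(a) for a in arrays))


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = SPEARMAN_EXACT_MAX_N
) -> TestResult:
    """Spearman rank correlation (midranks) with two-sided p.

    For n <= ``exact_max_n`` the p-value enumerates all n! permutations of
    one margin; larger n uses the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ContractError("spearman: need equal lengths n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ContractError("spearman: constant input vector")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        dev = abs(rho)
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(r) >= dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return TestResult("spearman", rho, min(p, 1.0), (n,))


# ---------------------------------------------------------------------------
# contingency and ANOVA


def chi_square_test(table: Sequence[Sequence[int]], correction: bool = False) -> TestResult:
    """Pearson chi-square on a contingency table (no continuity correction
    by default, matching the usual 2x2 group comparison)."""
    arr = np.asarray(table)
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError("chi_square: counts must be non-negative integers")
        if np.any(arr < 0):
            raise ValidationError("chi_square: negative count")
        arr = arr.astype(int)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ContractError("chi_square: zero margin")
    res = stats.chi2_contingency(arr, correction=correction)
    return TestResult(
        "chi_square",
        float(res.statistic),
        float(res.pvalue),
        tuple(int(v) for v in arr.sum(axis=1)),
        extra={"df": int(res.dof)},
    )


@dataclass
class TwoWayAnovaResult:
    main_a: TestResult
    main_b: TestResult
    interaction: TestResult
    pairwise: list[TestResult]  # Holm-adjusted cell contrasts


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
) -> TwoWayAnovaResult:
    """2x2 two-way ANOVA (Type II sums of squares) with Holm pairwise contrasts.

    Both factors must be two-level with every design cell occupied; the
    design may be unbalanced. Pairwise cell contrasts are t tests pooled on
    the full-model residual mean square, Holm-adjusted across the six
    comparisons. With a zero residual mean square the convention F = 0,
    p = 1 is used for effects whose sum of squares is zero.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multitest import multipletests

    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": list(factor_a), "b": list(factor_b)}
    )
    levels_a, levels_b = sorted(df["a"].unique()), sorted(df["b"].unique())
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ContractError("two_way_anova: both factors must have exactly 2 levels")
    cells = {}
    for la in levels_a:
        for lb in levels_b:
            sub = df[(df["a"] == la) & (df["b"] == lb)]["y"].to_numpy()
            if len(sub) == 0:
                raise ContractError(f"two_way_anova: empty design cell ({la}, {lb})")
            cells[(la, lb)] = sub
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    mse = float(table.loc["Residual", "sum_sq"]) / max(
        float(table.loc["Residual", "df"]), 1.0
    )
    df_resid = float(table.loc["Residual", "df"])

    def _effect(row_name: str, display: str) -> TestResult:
        ss = float(table.loc[row_name, "sum_sq"])
        dfe = float(table.loc[row_name, "df"])
        if ss <= 1e-12:  # zero effect: F defined as 0 even with zero MSE
            return TestResult(display, 0.0, 1.0, (len(df),))
        if mse <= 0 or df_resid <= 0:
            return TestResult(display, math.inf, 0.0, (len(df),))
        f = (ss / dfe) / mse
        p = float(stats.f.sf(f, dfe, df_resid))
        return TestResult(display, float(f), p, (len(df),))

    main_a = _effect("C(a)", "anova_main_a")
    main_b = _effect("C(b)", "anova_main_b")
    interaction = _effect("C(a):C(b)", "anova_interaction")

    keys = [(la, lb) for la in levels_a for lb in levels_b]
    contrasts, raw_p = [], []
    for (k1, k2) in itertools.combinations(keys, 2):
        g1, g2 = cells[k1], cells[k2]
        diff = g1.mean() - g2.mean()
        if mse > 0 and df_resid > 0:
            se = math.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
            t = diff / se
            p = 2.0 * stats.t.sf(abs(t), df_resid)
        else:
            t = math.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        contrasts.append((k1, k2, t))
        raw_p.append(p)
    adj = multipletests(raw_p, method="holm")[1] if raw_p else []
    pairwise = [
        TestResult(
            f"cell {k1} vs {k2}",
            float(t),
            float(p_adj),
            (len(cells[k1]), len(cells[k2])),
            adjustment="holm",
        )
        for (k1, k2, t), p_adj in zip(contrasts, adj)
    ]
    return TwoWayAnovaResult(main_a, main_b, interaction, pairwise)


# ---------------------------------------------------------------------------
# survival


def _check_survival(times: np.ndarray, events: np.ndarray) -> None:
    if np.any(times < 0):
        raise ValidationError("negative survival time")
    if times.shape != events.shape:
        raise ContractError("times and events must align")


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimate.

    Subjects censored at t are still at risk at t (right-continuous
    convention), matching the standard Kaplan-Meier definition.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    _check_survival(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = sorted(np.unique(times[events]))
    surv = [float(kmf.predict(t)) for t in event_times]
    at_risk = [int((times >= t).sum()) for t in event_times]
    return SurvivalCurve(times=[float(t) for t in event_times], survival=surv, at_risk=at_risk)


def _logrank_oev(
    times: np.ndarray, events: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Observed/expected events per group and hypergeometric variance.

    Returns (O1, E1, O2, E2, V) summed over distinct event times.
    """
    o1 = float(events[in_group1].sum())
    o2 = float(events[~in_group1].sum())
    e1 = v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_t = float(at_risk.sum())
        n1_t = float((at_risk & in_group1).sum())
        d_t = float((events & (times == t)).sum())
        e1 += d_t * n1_t / n_t
        if n_t > 1:
            v += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    e2 = (o1 + o2) - e1
    return o1, e1, o2, e2, v


def logrank(
    times1: Sequence[float],
    events1: Sequence[bool],
    times2: Sequence[float],
    events2: Sequence[bool],
) -> TestResult:
    """Mantel-Haenszel log-rank test with an O/E hazard ratio.

    HR = (O1/E1)/(O2/E2) with CI exp(log HR +/- 1.96 sqrt(1/E1 + 1/E2));
    appropriate for the univariate group comparisons drawn here (no
    covariate adjustment).
    """
    t1 = np.asarray(times1, dtype=float)
    e1 = np.asarray(events1, dtype=bool)
    t2 = np.asarray(times2, dtype=float)
    e2 = np.asarray(events2, dtype=bool)
    _check_survival(t1, e1)
    _check_survival(t2, e2)
    if e1.sum() + e2.sum() == 0:
        raise UndefinedResultError("logrank: no events in either group")
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    mask1 = np.zeros(len(times), dtype=bool)
    mask1[: len(t1)] = True
    o1, exp1, o2, exp2, v = _logrank_oev(times, events, mask1)
    chi2 = (o1 - exp1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, 1)) if v > 0 else 1.0
    if o1 > 0 and o2 > 0 and exp1 > 0 and exp2 > 0:
        hr = (o1 / exp1) / (o2 / exp2)
        se = math.sqrt(1 / exp1 + 1 / exp2)
        ci = (hr * math.exp(-1.96 * se), hr * math.exp(1.96 * se))
    elif o1 == o2 == 0:
        hr, ci = 1.0, (math.nan, math.nan)
    else:
        hr = 0.0 if o1 == 0 else math.inf
        ci = (math.nan, math.nan)
    return TestResult(
        "logrank",
        float(chi2),
        p,
        (len(t1), len(t2)),
        extra={
            "hazard_ratio": hr,
            "hr_ci_low": ci[0],
            "hr_ci_high": ci[1],
            "o1": o1,
            "e1": exp1,
            "o2": o2,
            "e2": exp2,
        },
    )


def optimal_cutoff_split(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    minprop: float = 0.1,
    variable: str = "value",
) -> CutoffResult:
    """Maximally selected rank statistic: best high/low survival cutpoint.

    Scans every observed value as a candidate cutpoint (low: value <= c,
    high: value > c), keeps candidates where both groups have at least
    ``minprop * n`` members, and returns the cutpoint maximising the
    standardised log-rank statistic |O1 - E1| / sqrt(V); ties break toward
    the lower cutpoint. The reported p-value is the plain log-rank p at the
    selected cutpoint and is NOT adjusted for the search.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = len(values)
    if n < 10:
        raise ContractError("optimal_cutoff_split: need n >= 10")
    if not (0.0 < minprop < 0.5):
        raise ContractError("minprop must be in (0, 0.5)")
    _check_survival(times, events)
    min_size = minprop * n
    candidates = []
    for c in np.unique(values)[:-1]:  # top value leaves high group empty
        low = values <= c
        if low.sum() >= min_size and (n - low.sum()) >= min_size:
            candidates.append(float(c))
    if len(candidates) < 2:
        raise ContractError(
            "optimal_cutoff_split: fewer than 2 admissible cutpoints"
        )
    best = None
    for c in candidates:
        low = values <= c
        o1, e1, _, _, v = _logrank_oev(times, events, low)
        z = abs(o1 - e1) / math.sqrt(v) if v > 0 else 0.0
        if best is None or z > best[1] + 1e-12:  # strict: ties keep lower c
            best = (c, z)
    c, z = best
    low = values <= c
    p = float(stats.chi2.sf(z**2, 1))
    return CutoffResult(
        variable=variable,
        cutoff=c,
        n_low=int(low.sum()),
        n_high=int(n - low.sum()),
        statistic=z,
        p_value=p,
    )


def median_split(values: Sequence[float]) -> np.ndarray:
    """High/low dichotomisation at the median; ties go to the high group.

    Returns a boolean array, True for high (value >= median).
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ContractError("median_split: empty input")
    return values >= np.median(values)
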