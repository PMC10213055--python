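"""Survival analysis of a simulated cohort: KM, log-rank, dichotomisation.

Simulates clinical outcomes for a two-arm cohort in which higher
post-treatment CD8 infiltration lowers the DFS hazard, then (1) compares
the arms by log-rank with an O/E hazard ratio, and (2) dichotomises the
CD8 level by the maximally selected rank statistic and by the median.
"""

import numpy as np

from tilspatial import (
    kaplan_meier,
    logrank,
    median_split,
    optimal_cutoff_split,
)
from tilspatial.synthetic_data import CohortSimConfig, simulate_cohort

cohort = simulate_cohort(CohortSimConfig(seed=1), timepoints=())  # labels only
truth = cohort.truth["patients"]
arm = {r.patient_id: r.arm for r in cohort.clinical}
t = np.array([r.dfs_time for r in cohort.clinical])
e = np.array([r.dfs_event for r in cohort.clinical])
is_napc = np.array([arm[r.patient_id] == "NAPC" for r in cohort.clinical])

res = logrank(t[is_napc], e[is_napc], t[~is_napc], e[~is_napc])
print(f"NAPC vs NAC DFS: log-rank chi2 = {res.statistic:.2f}, "
      f"p = {res.p_value:.3f}, HR = {res.extra['hazard_ratio']:.2f} "
      f"[{res.extra['hr_ci_low']:.2f}, {res.extra['hr_ci_high']:.2f}]")

cd8 = np.array([truth[r.patient_id]["lambda_post"]["CD8_T"] for r in cohort.clinical])
cut = optimal_cutoff_split(cd8, t, e, minprop=0.1, variable="CD8_T_post")
print(f"optimal CD8 cutpoint {cut.cutoff:.6f} cells/um^2 "
      f"(low n={cut.n_low}, high n={cut.n_high}), |z| = {cut.statistic:.2f}")
high = cd8 > cut.cutoff
res2 = logrank(t[high], e[high], t[~high], e[~high])
print(f"high vs low CD8 DFS: HR = {res2.extra['hazard_ratio']:.2f}, "
      f"p = {res2.p_value:.4f} (p is selection-biased by the cutpoint scan)")

med_high = median_split(cd8)
km_hi = kaplan_meier(t[med_high], e[med_high])
km_lo = kaplan_meier(t[~med_high], e[~med_high])
last = min(len(km_hi.times), len(km_lo.times)) - 1
print(f"median split: S(t) reaches {km_hi.survival[-1]:.2f} (high) vs "
      f"{km_lo.survival[-1]:.2f} (low) at the last event time")
print("HR < 1 for high-CD8 groups reflects the configured protective effect "
      "of post-treatment CD8 infiltration.")
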