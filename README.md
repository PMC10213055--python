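# tilspatial

Quantification and spatial-proximity analysis of tumor-infiltrating
lymphocytes (TILs) in multiplex fluorescent immunohistochemistry (mIHC)
fields, together with the cohort statistics used in neoadjuvant treatment
studies of resectable NSCLC (chemotherapy alone, NAC, versus chemotherapy
plus PD-1 blockade, NAPC).

It is a library for analysts working with per-cell exports from segmented
mIHC images: tables of nuclear coordinates and binary marker calls (DAPI,
CD4, CD8, CD20, CD127, KLRG1, FoxP3), per-patient viable-tumor percentages,
TLS annotations and survival follow-up. A synthetic-data module generates
point-pattern fields and full two-arm cohorts with known ground truth, so
every pipeline stage is testable without access to patient data.

## What it computes

**Phenotyping and infiltration.** Cells are gated exclusively on lineage
markers (CD20 → B cell, else CD4 → CD4 T, else CD8 → CD8 T) with
CD127/KLRG1/FoxP3 subsets nested inside their lineage; infiltration level
is the ratio of phenotype-positive cells to DAPI-segmented cells per field,
averaged over a specimen's fields.

**Cross-type K function.** For reference cells *i* and target cells *j* in
a field of area α,

    K̂(r) = (α / D) · Σᵢ Σ_{j≠i} 1(d_ij ≤ r) · e_ij

with D = n_ref·n_target (`cross`, default) or n(n−1) (`as_printed`,
same-set only), and edge weight e_ij either 1 (`none`) or the translation
correction WH/((W−|Δx|)(H−|Δy|)) for a W×H rectangle, which makes
E[K̂(r)] = πr² under complete spatial randomness. The standard radius sweep
is r ∈ {10, 20, 30, 40, 60, 80} μm.

**Proximity density.** The mean number of target-phenotype cells within
30 μm of each reference-phenotype cell (raw counts, self excluded) — the
neighbourhood measure behind the finding that CD8⁺, CD8⁺CD127⁺ and
CD8⁺KLRG1⁺ T cells sit closer to CD4⁺ T and CD20⁺ B cells after combined
therapy.

**Response and TLS.** Per-slide viable-tumor percentages are averaged per
patient; 0% → pCR, ≤10% → MPR, otherwise non-MPR (pCR counts toward MPR
rates). TLS density is structures per mm² of evaluated tissue.

**Cohort statistics.** Mann-Whitney, Wilcoxon signed-rank, Kruskal-Wallis,
Spearman (each with exact small-sample enumeration under ties), Pearson
chi-square, 2×2 two-way ANOVA (Type II) with Holm-adjusted contrasts,
Kaplan-Meier, Mantel-Haenszel log-rank with an O/E hazard ratio, and
high/low dichotomisation by median (ties high) or by the maximally
selected rank statistic with a minimum group fraction.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_spatial_k_and_proximity.py` simulates a random (CSR)
and a clustered field at equal abundances and prints

```
  r (um)     pi r^2      K_csr  K_clustered
      10        314        272          746
      20       1257       1197         2586
      30       2827       2979         4640
      40       5027       5061         7143
      60      11310      11047        13333
      80      20106      20248        21431

proximity density at 30 um: CSR 1.22, clustered 1.66 CD8 cells per CD4 reference cell
```

K̂(r) tracks πr² when CD8 cells are placed independently of CD4 cells and
exceeds it when they are clustered around them, with the excess
concentrated below ~40 μm (the 15-μm dispersion of the clustering).
`python examples/03_response_and_tls.py` rebuilds the two-arm response
table and prints

```
 arm  n  n_mpr  n_pcr  mpr_rate_percent  pcr_rate_percent
 NAC 30      6      0              20.0               0.0
NAPC 35     23     16              65.7              45.7

MPR vs arm chi-square = 13.662, p = 2.19e-04
```

— the MPR rate roughly triples when PD-1 blockade is added to
chemotherapy, and the difference is far beyond chance at these arm sizes.

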