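# Methods

## Data model and conventions

A *field* is one 20× multispectral image region, modelled as an
axis-aligned rectangle (default 669 × 500 μm, configurable) with continuous
μm coordinates originating at the lower-left corner. Cells are
nuclear-segmented points with binary marker calls for DAPI, CD4, CD8, CD20,
CD127, KLRG1 and FoxP3; intensity thresholding happens upstream and is out
of scope. A *specimen* is one patient × timepoint (biopsy before therapy,
resection after) holding nominally ten fields. Inputs are comma-separated
UTF-8 with headers; outputs are tab-separated with floats serialised via
`repr` and re-read with round-trip parsing, so read(write(X)) is bit-exact.
Validation is total: malformed inputs raise typed errors
(schema/parse/validation), never silent coercion.

## Phenotype gating

Lineage is assigned by exclusive gating: CD20⁺ → B cell, else CD4⁺ → CD4 T,
else CD8⁺ → CD8 T, else *other*. A cell positive for two or more lineage
markers is flagged ambiguous and assigned *other* with a logged warning —
never dropped, and never given a fabricated lineage. Subsets (CD127/FoxP3
on CD4; CD127/KLRG1 on CD8) nest inside their lineage, so
density(CD8⁺CD127⁺) ≤ density(CD8⁺) holds in every field. Infiltration is
the ratio of phenotype count to DAPI count per field; specimen-level values
are the unweighted mean of per-field ratios (the fields are a random sample
of the slide; a pooled-count aggregation is available as an option, since
the original convention — per-field average versus pooled counts — is not
documented).

## Spatial statistics

The cross-type K function is estimated as

K̂(r) = (α / D) · Σᵢ∈ref Σⱼ∈target, j≠i 1(d_ij ≤ r) e_ij

with the distance threshold inclusive (d ≤ r), duplicate coordinates
allowed, boundary cells included, and a cell never counted as its own
neighbour (same-cell pairs arise when nested phenotypes are compared).
Two normalisations are provided: `cross` (D = n_ref n_target), the standard
bivariate form and the default; and `as_printed` (D = n(n−1)), the
univariate form, restricted to identical reference/target sets because it
is not defined for distinct phenotypes — requesting it for them is a
contract error rather than a silent reinterpretation. Two edge treatments:
`none` (e = 1, the literal double sum, negatively biased near the boundary)
and `translation` (default), e_ij = WH/((W−|Δx|)(H−|Δy|)) for a W×H
rectangle, which is unbiased under complete spatial randomness
(E K̂(r) = πr²) — a property the tests verify by Monte Carlo at every sweep
radius. Radius sweeps compute all pairwise distances once at the largest
radius and threshold per radius, so sweep values equal independent
single-radius calls exactly.

Proximity density is the arithmetic mean over reference cells of the number
of target cells within r = 30 μm, reported as raw, uncorrected counts
(its definition carries no edge correction; the edge deficit is
characterised in tests instead of corrected). Fields with no reference cell
are excluded from specimen aggregation with a log entry. Neighbour search
uses a k-d tree and is tested to agree exactly with exhaustive O(n²)
enumeration; a periodic (toroidal) metric is available for edge-effect-free
calibration work.

Default cohort pairs: references CD4 T and CD20 B against targets CD8,
CD8⁺CD127⁺, CD8⁺KLRG1⁺, plus B-cell references against CD4 and CD4⁺CD127⁺.

## Response and TLS

The patient's final viable percentage is the arithmetic mean of 1–5
per-slide values in [0, 100]. Classification: 0 → pCR, (0, 10] → MPR
(the boundary 10.0 is MPR), > 10 → non-MPR. pCR satisfies the MPR
definition and is included in MPR counts, which is required for the two
rates to be consistent in a cohort where nearly half the combined-therapy
arm reaches pCR. Display rounding is one decimal, half away from zero.
TLS density is count / evaluated area (mm²).

## Statistical layer

All p-values are two-sided at α = 0.05. Rank tests switch to full
enumeration below a size threshold so ties are handled exactly:
Mann-Whitney enumerates all C(n, n₁) group labelings for pooled n ≤ 16
(the tie-corrected, continuity-corrected normal approximation above; the
threshold is set at 16 because the approximation's error against
enumeration can reach ~0.01 at n = 8+8, and enumeration there costs
milliseconds); Wilcoxon signed-rank enumerates all 2^m sign patterns for
m ≤ 15 nonzero differences (zeros dropped, midranks on |d|); Spearman
enumerates all n! permutations for n ≤ 7 and uses the t approximation
above. Kruskal-Wallis (tie-corrected) and the Pearson chi-square (no
continuity correction by default) are delegated to scipy. The two-way
ANOVA fits the 2×2 crossed model by least squares with Type II sums of
squares (statsmodels), allowing unbalanced cells; pairwise cell contrasts
are t tests on the pooled residual mean square with Holm adjustment. With
a zero residual mean square, effects with zero sum of squares report
F = 0, p = 1.

Kaplan-Meier uses the product-limit estimator (lifelines) with the
right-continuous convention (subjects censored at t are at risk at t). The
log-rank test is Mantel-Haenszel with hypergeometric variance; the hazard
ratio is (O₁/E₁)/(O₂/E₂) with CI exp(log HR ± 1.96·√(1/E₁+1/E₂)) —
appropriate for the univariate, covariate-free group comparisons made
here, and cross-checked against lifelines in the tests. Under the null,
each test's type-I error is verified to sit in 5% ± 2% over 2000
replicates.

Dichotomisation: `median_split` assigns values ≥ median to the high group
(ties high). `optimal_cutoff_split` scans every observed value as a
cutpoint (low ≤ c < high), keeps candidates where both groups hold at
least `minprop·n` patients (default 0.1), and returns the cutpoint
maximising |O₁−E₁|/√V, ties breaking toward the lower cutpoint. The
returned log-rank p at that cutpoint is **not** corrected for the search
and is therefore optimistic; it is reported for curve-drawing, not
inference — the maximally-selected-statistic p-value adjustment is
deliberately not implemented.

## Synthetic-data generator

The generator emulates the *structure* of the study — it is not fit to any
real cohort. Defaults: arms NAC n = 30 and NAPC n = 35, paired pre/post
specimens, ten 669 × 500 μm fields each. Baseline intensities give ~1150
DAPI cells per field with TIL fractions of a few percent (B 3%, CD4 12%
including subsets, CD8 12% including subsets). Per-patient lognormal noise
(σ = 0.35) scales baselines; post/pre fold-changes are arm-specific with
lognormal noise (σ = 0.25): NAC raises only B cells (×1.8); NAPC raises B
(×2.0), CD4 (×1.6), CD4⁺CD127⁺ (×1.8), CD8 (×1.7) and the CD8 subsets
(×2.0), leaving Tregs flat — the direction and rough magnitude of the
reported treatment effects.

Spatial attraction is a Neyman-Scott (Thomas-type) process: in
post-treatment NAPC fields, CD8-phenotype cells are placed as offspring of
the field's CD4/CD20 cells with isotropic Gaussian dispersion σ = 15 μm
(chosen so the effect concentrates inside the 30-μm analysis radius) and a
30% uniformly placed background fraction. The expected offspring total
always equals intensity × area, so attraction changes geometry, never
abundance. Boundary handling is "clipped with redraw" by default (exact
intensities); a toroidal option exists for edge-free oracle tests.

MPR labels are drawn from a logistic model on the patient's standardised
CD8 fold-change noise, with per-arm intercepts calibrated by Gauss-Hermite
quadrature so the marginal rates equal the study's observed 20.0% (NAC)
and 65.7% (NAPC); pCR is drawn among MPR patients at 16/23 in NAPC and 0
in NAC. Per-slide viable percentages are witnesses of the label (pCR: all
0; MPR: U(0,10]; non-MPR: U(10,90]; 1–5 slides), not biology. DFS/OS are
exponential with log-hazard linear (slope −0.8) in the standardised log
post-treatment CD8 density relative to baseline, so the NAPC fold-change
induces an arm-level survival benefit (implied HR ≈ 0.4, attenuated toward
the null by the O/E estimator and censoring); censoring is exponential
with rate tuned to ≈30%. All randomness flows from one integer seed;
labels and ground truth are drawn from a stream separate from the point
patterns, so they are invariant to which timepoints are materialised.

What the generator does **not** emulate: tissue architecture (tumor nests,
stroma, necrosis), inhomogeneous cell intensity across a field, marker
intensity distributions and gating error, segmentation artefacts, and
correlations between phenotype abundances beyond the shared patient noise.
Passing tests therefore demonstrate correctness of the estimators and the
pipeline under known ground truth — not that real tissue satisfies CSR or
Thomas-process assumptions.

## Problem sizes used in validation

CSR calibration uses 500 simulated fields (3 Monte-Carlo SE bands);
oracle-equivalence checks use 100 random fields of up to 500 cells; the
directional cohort check uses 100 replicate cohorts at the study arm sizes
(post-treatment fields only, via the generator's `timepoints` argument)
and pools the null rejection rate across the six CD8 pairs, since a
per-pair rate at 100 replicates has a binomial SE (≈2.2%) wider than the
±2% band being checked; type-I calibration uses 2000 replicates per test;
hazard-ratio recovery uses 200 cohorts of 200 patients per arm at a true
HR of 0.3. `scripts/acceptance.py` reports the same quantities at somewhat
smaller replicate counts.

## Known limitations

- The `as_printed` K normalisation is retained only for same-set analyses;
  the package takes the position that n(n−1) with distinct phenotypes is a
  notational slip and refuses it rather than guessing.
- Proximity density is uncorrected for edge effects; near-boundary
  reference cells undercount neighbours (quantified under CSR in tests as
  the gap between `none`-corrected K and πr²).
- The optimal-cutpoint p-value is selection-biased (see above).
- The O/E hazard ratio is mildly conservative (biased toward 1) relative
  to a proportional-hazards fit, especially with heavy censoring.
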