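# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions taken where the underlying
analysis convention was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Polarisation scoring and classification

Raw staining intensities of the four polarisation markers (CD86, HLADR,
CD163, MRC1) are converted to percentile scores across the pooled
macrophage population with the symmetric convention

    s_i = (rank_i − 0.5) / n × 100,

using average ranks for ties. This keeps scores strictly inside (0, 100),
makes the mean score exactly 50, and renders every downstream quantity
invariant to strictly monotone transforms of any single marker's raw
intensities. The per-cell polarisation index is
`(s_CD86 + s_HLADR) − (s_CD163 + s_MRC1)`, bounded in [−200, 200].

Quartile cutoffs (25th/50th/75th empirical percentiles, linear
interpolation) are computed **once** on the pooled population (primary
tumours and metastases together) and then applied to subgroups. Quartile
bins are half-open: (−∞, q1], (q1, q2], (q2, q3], (q3, ∞). Under the
default orientation (`index_high_is_M1`) the top quartile — where the
declared M1 markers dominate — is labelled M1-like and the bottom quartile
M2-like; a `paper_literal` flag reverses the assignment for compatibility
with pipelines that label the lowest quartile M1. The middle two quartiles
are "mixed" and excluded from all density work. Degenerate input in which
q1 = q3 (no extreme quartile exists) labels every cell mixed with a logged
warning.

Two conventions are deliberately asymmetric and documented rather than
hidden: a cell exactly at q3 falls in Q3 (mixed side), while a cell exactly
at q1 falls in Q1 (extreme side); both follow directly from the half-open
bin definition. Percentiles are computed within CD68⁺ macrophages by
default (`population="macrophage"`), switchable to all cells.

## Densities, ratios and heterogeneity

A compartment density is count/area (cells/mm²) per core. Per-case
region×compartment densities use the unweighted mean over usable cores by
default ("average density per case"); area-weighted pooling
(Σcounts/Σareas) is available as `method="pooled"`. Mixed-type macrophages
count towards `all_macrophages` densities but never towards M1/M2 densities
or ratios.

The M1:M2 ratio is d_M1/d_M2 with an explicit +inf sentinel when d_M2 = 0 <
d_M1 and a missing value when both are zero. The sentinel, rather than an
epsilon-regularised ratio, keeps the low/high ordering needed for ROC
dichotomisation well defined without inventing a scale; ROC cutoff
selection treats +inf as ranking above all finite values. The integrative
polarisation score pools counts and areas over all four region×compartment
cells of a sample, which reduces to Σcounts_M1/Σcounts_M2.

Intratumoural heterogeneity is the sample SD (n−1 divisor) of per-core
densities over **all** usable cores of a sample — tumour-centre and
invasive-margin cores pooled, computed separately per compartment and
class — and is missing for samples with fewer than two usable cores.
Pooling the two regions (rather than per-region SDs) follows the reading
that heterogeneity is a property of the whole tumour's cores; per-region
SDs can be had by filtering cores before the call.

## Spatial analysis

NNDs are Euclidean distances from each macrophage to the nearest tumour
cell **within the same core**; a TMA core is a tissue island, so cross-core
distances are not meaningful. The implementation uses a k-d tree but is
required (and tested) to agree exactly with an O(n·m) brute-force scan.
Cohort summaries concatenate per-core records; class medians use the
midpoint convention for even counts. The "percent closer" contrast is
(1 − median_M1/median_M2) × 100, computed from unrounded medians.

Marker-versus-distance curves use a penalized cubic B-spline (P-spline): 40
basis functions on uniformly extended knots, second-difference coefficient
penalty, penalty weight chosen by generalized cross-validation over a
log-spaced grid (10⁻⁴…10⁸) unless fixed. Uniform knot extension puts all
linear functions in the penalty null space, so constants and straight lines
are reproduced exactly at any penalty weight — a useful correctness anchor.
"Scaled" intensities are z-scores per marker across pooled macrophages.
Fits with fewer than 20 points are refused (a raw scatter is the honest
display at that size).

## Survival analysis

Exclusions precede everything: R1-resected patients, and patients who died
within 30 post-operative days (an event with time ≤ 30 days; early
censoring is retained). The outcome is 5-year overall survival
(administrative censoring at 1826 days).

Continuous exposures are dichotomised at the ROC cutpoint maximising
Youden's J against the binary label "died within 5 years"; patients
censored before the horizon count as survivors for the label — a
simplification that slightly favours specificity and is stated here rather
than hidden. Candidate cutoffs are midpoints between adjacent sorted unique
values; the rule is value ≥ cutoff ⇒ high, ties broken toward the smallest
cutoff, and the reversed rule is reported as `direction="low"` when it
dominates. The criterion is pluggable; Youden's J is the default
operationalisation of "picked from the ROC curve".

Kaplan–Meier estimation, the two-group log-rank test, and Cox
proportional-hazards regression are delegated to lifelines (Efron tie
handling, Wald 95% CIs, Newton precision 1e-9); the hand-computable cases
(product-limit arithmetic, O−E log-rank, a closed-form two-event partial
likelihood) are verified in the test suite against independent manual
oracles. Adjusted models use the covariates sex, age (continuous),
comorbidity (RCSCS 1 vs ≥2), neoadjuvant therapy, number of pulmonary
metastases at diagnosis (1 vs ≥2), former liver metastases, and
synchronicity (disease-free interval ≤ 183 days defines synchronous). All
tests are two-sided at α = 0.05 with no multiple-testing correction,
matching standard practice for this kind of exploratory tissue analysis.

## The synthetic cohort generator

The generator's defaults define the simulated study conditions; they are
plausibility choices for a pulmonary-metastasectomy cohort, not fits to any
dataset.

- **Cohort structure**: 74 patients, each contributing a primary tumour and
  a first-metastasis sample; 2 cores per region (tumour centre, invasive
  margin) per sample; 5% of cores fail QC with a random reason.
- **Geometry**: 1-mm disc cores; the epithelial compartment is a union of
  random discs clipped to the core, grown and then bisected on the last
  disc's radius until the polygonal area matches the target fraction
  (tumour centre 0.45, invasive margin 0.30) within 0.5%. Areas are exact
  polygon measures and sum to the disc area.
- **Cells**: homogeneous Poisson per phenotype×compartment. Macrophages:
  700/900 per mm² in tumour-centre/invasive-margin stroma and 250/350 in
  epithelium (primaries ×0.85), which puts overall core densities in the
  several-hundred-per-mm² regime with invasive margin > tumour centre and
  metastases > primaries. Tumour cells 1400 (epithelium) / 80 (stroma);
  other cells 400/600.
- **Planted classes**: macrophages draw M1/mixed/M2 from per-sample-kind
  mixtures — primaries (0.30, 0.45, 0.25), metastases (0.20, 0.45, 0.35) —
  so metastases are M2-shifted by construction. A Bernoulli(0.5) patient
  flag `m2_rich` shifts that patient's metastasis mixture a further 0.10
  from M1 to M2 and carries the survival effect.
- **Markers**: lognormal, log-sd 0.5; planted M1 cells have log-mean 4.0 on
  CD86/HLADR and 2.0 on CD163/MRC1, M2 mirrored, mixed 3.0 everywhere;
  CD68 (4.5, 0.4) in macrophages, KRT (5.0, 0.4) in tumour cells,
  background (1.0, 0.6) elsewhere. This separation lets the quartile
  classifier recover planted non-mixed labels with high concordance while
  leaving realistic overlap near the quartile boundaries.
- **Attraction**: after placement, each macrophage moves toward its nearest
  tumour cell by an exponential step (scale 25 µm for M1, 12 µm mixed, 5 µm
  M2), truncated at 95% of the current distance; compartment labels are
  re-derived afterwards. This produces the qualitative spatial signature of
  interest — M1-like macrophages closer to tumour cells — without asserting
  a mechanistic model.
- **Survival**: exponential proportional hazards, baseline 4.5×10⁻⁴/day
  (≈40% 5-year survival at zero linear predictor), log-HR ln 2 on
  `m2_rich`, uniform administrative censoring over 365–2920 days. Clinical
  covariates are drawn independently of outcome with realistic marginals
  (median DFI ≈ 350 days, ~30% synchronous, 5.7% R1).
- **Reproducibility**: one integer seed; sub-streams keyed as
  (seed, 1, patient) for clinical draws and (seed, 2, patient, sample,
  region, core) for cores, so enlarging the cohort never perturbs
  already-generated patients.

What the generator does **not** emulate: segmentation error and phenotype
misclassification, intensity batch effects and spatial gradients within
cores, cellular exclusion volumes (points are ideal), re-metastasectomies,
correlated covariates, and non-proportional hazards. Passing tests
therefore demonstrate correctness of the analysis code and recoverability
of planted effects under the stated model — not robustness to the
imperfections of real multiplex-IHC data.

## Problem sizes in the tests and acceptance script

The acceptance script simulates the default 74-patient cohort (~590 cores,
~7×10⁵ cells) — comfortably desk-scale. The heavier calibration tests use
200 replicates of n = 500 patients for Cox recovery, 1000 replicates of
n = 60 for log-rank type-I error, 100 random 200×200 instances for NND
oracle equivalence, and a 50-patient paired cohort for the end-to-end
effect-direction check; these sizes give tight Monte-Carlo error on each
property while keeping the full suite in the minutes range.

## Known limitations

- ROC labels treat patients censored before 5 years as survivors; with
  heavy early censoring the cutoff will drift.
- The Youden criterion is one of several reasonable cutpoint rules; results
  for borderline exposures depend on it.
- The +inf ratio sentinel is ordinal, not metric: it supports cutoffs and
  ranks but cannot enter means or signed-rank differences (such records are
  dropped from paired comparisons, with the pair count reported).
- Density "averaging" across cores is unweighted by default; cores with
  small compartment areas get full weight, which inflates variance for
  sparse compartments (the pooled method avoids this at the cost of
  changing the estimand).
- The Cox models assume proportional hazards; no diagnostic is run
  automatically.
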