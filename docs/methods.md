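# Methods

`tipca` analyzes cross-sectional multiplex mediator panels measured in
plasma and solid organs after an acute inflammatory challenge (the motivating
setting is LPS endotoxemia in wild-type versus TLR4-null mice: 20 mediators,
plasma + six organs, sacrifice times 0, 1, 4, 6, 12, 24, 48 h, a handful of
animals per genotype per time point). This note records the models, the
numerical conventions, and the design decisions, in the order the pipeline
runs them.

## Data model

A `TimecourseDataset` is a long table with one row per (mouse, genotype,
time, compartment, mediator). The design is cross-sectional: each animal is
sacrificed at exactly one time point, so "time courses" are population
summaries and all correlation structure is *across animals*. Concentrations
are pg/ml (plasma) or pg/mg total protein (tissue); units are implied by the
compartment and never mixed within one. Zero concentrations are treated as
true zeros (below-detection), with no imputation; unparseable cells become
missing and are counted in the log. Time values must sit exactly on the
declared sampling grid.

### Standardization

`zscore` standardizes each (mediator, compartment) variable with the
**population (denominator n) SD**, so each column satisfies Σz² = n and a
correlation-scale PCA trace equals the number of variables. Constant columns
become all-zero and are flagged rather than dropped silently.
`log_transform` (log10(x+1) before centering) is off in `zscore` itself but
**on by default in the analysis estimators**: cytokine panels span several
decades and are approximately log-normal across animals, and on the raw
scale one severe animal dominates every variance, correlation, and loading.
The raw-scale behaviour remains available via `log_transform=False`.

## Time-interval PCA

The window 0–48 h is partitioned into six consecutive intervals
(0–1, 1–4, 4–6, 6–12, 12–24, 24–48 h). Intervals are **closed on both
ends**, so a boundary time point belongs to both adjacent intervals —
matching the shared endpoints of the interval labels. Within each interval
a PCA is run over the observations × (mediator × compartment) matrix
(20 × 7 = 140 variables by default), via SVD of the centered matrix, with
eigenvalues on the same denominator-n scale as the z-scoring. Loading sign
indeterminacy is resolved by forcing the largest-magnitude entry of each
column positive (downstream only absolute values are used).

Two normalization scopes are provided:

* `zscore_scope="interval"` — mean/SD recomputed inside the interval. This
  is the correlation-scale variant: Σλ equals the number of retained
  variables exactly, which the tests use as a conservation law. Its
  limitation is that every variable is forced to unit variance in every
  interval, so per-interval results carry no information about *when* a
  variable is active.
* `zscore_scope="global"` (estimator default) — each variable is scaled by
  its whole-course mean/SD, then centered **per time point** within the
  interval. Scaling globally preserves between-interval variance
  differences; centering per time point removes the deterministic time
  trend, leaving inter-animal covariance at the interval's times. This is
  the scope that lets the per-compartment profile track each compartment's
  activation window; sharp post-peak decays otherwise masquerade as late
  activity.

### Contribution scores and the top-25% selection

With retained leading components K (smallest set reaching a cumulative
explained-variance fraction `f_pc`), the raw weight of variable j is
`w_j = Σ_{k∈K} (λ_k/Σλ)·|v_jk|`, normalized to Σw̃ = 1; a squared-loading
variant (`scheme="sq_loading"`, for which f_pc = 1 reduces w̃ exactly to the
variable's variance share) is available. Ranks break ties by panel order,
then compartment order. The **top-25% selection** is the minimal rank prefix
whose cumulative score reaches 0.25 — so the cumulative score is ≥ 0.25 and
dropping the last member falls below it.

`contribution_scores` defaults to `f_pc = 0.95`. The `TimeIntervalPCA`
estimator uses `f_pc = 0.5`: with n ≪ J all sample variance lives in at most
n−1 components and the trailing ones are sampling noise, so attributing
contributions only to the leading axes that explain half the variance keeps
the ranking driven by real covariance structure. Recovery performance is
flat for f_pc between about 0.4 and 0.6, so the choice is not delicate.

### Compartment profile and peak-variance ordering

Per compartment per interval the profile records (i) the number of
top-25%-selected variables and (ii) the summed normalized contribution over
*all* of the compartment's variables — its share of the interval's variance.
Shares, not absolute variances, are compared across intervals because all
compartments measured in one interval come from the same sacrifice cohorts:
per-interval normalization cancels cohort-level severity fluctuations that
would otherwise dominate any absolute measure. Each compartment's
`peak_interval` is the share argmax (ties to the earlier interval), and the
compartment ordering sorts by peak-interval midpoint, reporting compartments
that share a peak interval as a tie group.

`whole_course_pca_top_k` runs the same scoring on a single PCA over all
time points and reports the top-k variables and how many sit in plasma — a
summary of whether the systemic compartment dominates the overall response.

## Correlation networks and spillover onset

At each (genotype, compartment, time point) the 20×20 pairwise-complete
Pearson matrix across mice is computed (log10 scale by default, raw
optional), with two-sided p-values from t = r·√((n−2)/(1−r²)), df = n−2;
cells with n < 3 get undefined p and are logged. The significance filter
zeroes entries with p ≥ α (strict `p < α`, default α = 0.05, **no
multiple-testing correction** — a deliberate, conventional choice for this
analysis style, and a documented caveat: at α = 0.05 about 10 of 190 pairs
are expected significant by chance per matrix).

Matrix resemblance is the Pearson correlation between the vectorized strict
upper triangles (190 entries) of two filtered matrices — a Mantel-type
statistic without permutation, undefined (flagged) when a triangle is
constant, symmetric by construction. Spillover onset is the earliest
sampling time t > 0 at which the plasma–organ similarity is ≥ θ for at least
m organs (defaults θ = 0.5, m = 2). Because the onset rule quantifies what
is inherently a qualitative visual comparison, the full similarity
trajectory is always reported next to the call, and the call should be read
as a flagged inference, not a measurement.

## Per-mediator statistics

`two_way_anova` fits a fixed-effects genotype × time model per (compartment,
mediator) with **Type-III sums of squares** (sum-to-zero contrasts), chosen
because group sizes differ between genotypes (n = 8 vs 4 by default); on
balanced data it coincides with the Type-I decomposition (tested). It runs
on raw concentrations by default, mirroring how such panels are usually
reported (means ± SEM), with a log option for the heavy tails. Zero residual
variance is flagged as degenerate with undefined p. Per-time-point genotype
contrasts use the model's pooled residual MS and are adjusted with the
step-down **Holm–Šidák** rule over the m = 7 time points:
sort ascending, adjusted p_(i) = max_{j≤i} 1 − (1 − p_(j))^(m−j+1), clipped
at 1. `auc_trapezoid` integrates the per-time mean concentration over
0–48 h and offers a per-mouse resampling bootstrap SE.

## Synthetic endotoxemia generator

The generator is an *emulator* of the study's statistical structure with
planted ground truth, not a mechanistic model of TLR4 signaling. Its
defaults are the package's standard study conditions, used by the test suite
and the acceptance script.

Each compartment mounts a gamma-shaped pulse in log10 space,
`pulse(t; τ, α) = (t/τ)^α·e^{α(1−t/τ)}` (unit peak at τ, baseline at 0 and
∞; α = 2 gives a realistically asymmetric wave). The log10 concentration of
mediator m in organ c for mouse i at time t is

    x = b_m + s_i · g · a_m β_{m,c} · pulse(t; τ_c + δ·[KO], α) + ε,

with per-mediator baseline b_m ~ U(0.5, 1.5) and amplitude
a_m ~ U(1.8, 2.8) log10 units (10–100 pg/ml baselines, peak inductions of
two to three decades, as LPS panels show), measurement noise
ε ~ N(0, 0.15²), genotype factor g = ρ = 0.2 with peak delay δ = 6 h for the
receptor-null strain ("lower and later"), and a per-mouse severity
multiplier s_i = e^{u_i}, u_i ~ N(0, 0.6²), shared across all mediators and
compartments of that mouse. The severity factor multiplies the *pulse*, not
the baseline, so mediators co-vary across animals exactly where and when
they are induced — the only mechanism by which a cross-sectional design can
generate correlation structure, and one that makes correlation matrices
time- and compartment-dependent (an additive animal effect would instead
give one constant correlation everywhere, making onset undetectable by
construction).

Responsiveness masks give compartments distinct signatures: the six organs
share a 12-mediator **parenchymal core** program plus 2 organ-specific
mediators each; plasma's locally produced program is the 8-mediator
non-core complement (blood-cell-derived mediators distinct from the
parenchymal core). Plasma mixes local production with lagged spillover:

    plasma pulse term = φ·A_plasma·pulse(t; τ_p)
                      + (1−φ)·Σ_c w_c·A_c·pulse(max(t−L, 0); τ_c),

with local fraction φ = 0.7, lag L = 4 h (clamped at 0 so baselines stay
flat), and mixing weights concentrated on the large filtering organs
(liver 0.40, heart 0.40, kidney 0.12, gut 0.08). Consequently the plasma
correlation matrix resembles the organ matrices only once the lagged organ
programs actually reach the blood — the planted signal the onset detector
must recover — while the no-spillover variant (φ = 1) and the receptor-null
genotype plant clean negatives.

Default peak times (τ: spleen 1, plasma 2, heart 5, liver 9, kidney 14,
gut 18, lung 18 h) plant a spleen → plasma → heart → liver → kidney →
gut/lung cascade. `GroundTruth` records the *effective* plasma peak — the
argmax of the mixed mean curve on a fine grid — rather than the nominal
τ_plasma, so ordering-recovery comparisons stay self-consistent for any φ.
Default group sizes are 8 wild-type and 4 null mice per time point (the
study range is 4–8; pairwise correlation at n below ~6 is too noisy to carry
a network analysis, so the wild-type arm sits at the upper end).
`null_dataset` (all amplitudes zero, ρ = 1) provides i.i.d. log-normal
baselines for type-I-error calibration.

### What the generator does and does not emulate

It reproduces the study's dimensions, the lower-and-later genotype
contrast, organ-specific activation windows, animal-to-animal severity
spread, and a lagged systemic spillover with distinct local plasma
production. It does **not** emulate assay floor/ceiling censoring,
mediator-specific kinetic shapes, negative feedback (e.g. IL-10-driven
suppression), inter-organ signalling other than organ → plasma, or any
mechanistic TLR4 biology. Passing recovery tests therefore shows the
pipeline can extract planted structure of this kind at the study's sample
sizes and noise levels — not that real endotoxemia data satisfy these
assumptions.

## Numerical conventions and degenerate inputs

Population (n) denominators throughout (z-scores, PCA eigenvalues);
contribution tie-breaks by panel then compartment order; intervals closed on
both ends; observations with any missing variable dropped from PCA (logged),
pairwise-complete handling in correlations; constant variables flagged and
excluded from PCA; similarity of a constant (e.g. fully filtered) matrix is
NaN and never counts toward onset; strict p < α; Holm–Šidák clipped at 1.
All randomness flows from explicit integer seeds; identical config + seed
reproduces byte-identical pipeline outputs, and the pipeline manifest
records a hash of the analysis-relevant configuration plus library versions.

## Problem sizes

The default dataset is 2 genotypes × 7 time points × (8 + 4) mice × 7
compartments × 20 mediators = 11,760 measurements and simulates in well
under a second. Recovery statistics in the tests and the acceptance script
use 50 replicates for ordering (at n = 6 per time point, σ = 0.15) and 50
for spillover plus 50 no-spillover nulls; ANOVA calibration uses 8 null
datasets × 140 mediator–compartment pairs = 1,120 tests. The full test
suite runs in about two minutes on one CPU; the acceptance script in about
one and a half.

## Known limitations

The compartment ordering is resolved only to the interval grid (late
intervals are wide, so compartments peaking at 14 h and 18 h often tie);
the onset detector's θ and m defaults are calibrated to the Mantel-type
similarity's realistic range at these sample sizes and should be
re-examined for other panels; no multiplicity correction is applied in the
correlation filter by design; and the ANOVA's raw-concentration default has
low power under log-normal severity spread — use `log_scale=True` when
power matters more than convention.
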