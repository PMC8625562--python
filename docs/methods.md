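# Methods

This note documents the statistical procedures implemented in `cordbmi`,
the choices made where the design was genuinely open, and what the
synthetic cohort does and does not establish.

## Growth reference and percentiles

BMI-for-age percentiles use the LMS transformation: for reference
parameters (L, M, S) at the child's sex and age, `z = ((X/M)^L − 1)/(L·S)`
for L ≠ 0 and `z = ln(X/M)/S` at L = 0 (the implementation switches to the
log form below |L| = 1e-6, where the two agree to well under 1e-8), and
`BMIPCT = 100·Φ(z)`.  Parameters are linearly interpolated in age between
the two bracketing reference rows for the child's sex; ages outside the
reference range clamp to the boundary row by default (configurable to
error).  Percentiles are defined only from 24 months, the earliest age in
the reference; younger visits are silently dropped from percentile output
but retained for raw-BMI analyses.  The reference is a pluggable headered
table (`sex, age_months, L, M, S`); the shipped synthetic reference has
smooth monotone-in-age M, widening S and mildly negative L — the
qualitative shape of pediatric BMI references — so no external download is
needed.  `percentile_to_bmi` inverts the map exactly (round-trip error
below 1e-8 percentile points), which is what lets the cohort generator
simulate on the percentile scale and emit BMI.

The exact-month-versus-completed-months question for aligning visit ages
to reference rows is resolved by interpolation; a reference built on a
different convention would shift percentiles by at most the within-interval
parameter change.

## Metabolite preparation

The order is fixed: CV filter → non-detect imputation → inverse normal
transformation.

* **CV filter.**  CV = 100·sd/mean over *observed raw* intensities, sample
  (n−1) standard deviation, computed over all samples (a pooled-QC-sample
  variant would be a caller-side substitution of the input panel).
  Exclusion is strict (`CV > threshold`, default 20%), so a metabolite
  exactly at the threshold is retained.  Metabolites with fewer than two
  observed values get their own exclusion status rather than a fake CV.
* **Non-detects** become half of the metabolite's minimum observed
  intensity; a fully non-detected metabolite is an error (no minimum
  exists).
* **Inverse normal transformation** maps ranks to normal quantiles,
  `Φ⁻¹((r − c)/(n − 2c + 1))` with Blom offset c = 3/8 (configurable);
  ties take average ranks and therefore remain tied after transformation.
  For untied columns the sorted scores are antisymmetric about zero, so
  downstream effect sizes are per (approximate) SD of the metabolite.

## Time-windows and trajectory groups

**Window construction** is greedy left-to-right over the pooled visit
ages: the current window is extended until it contains visits from at
least `min_n = 30` distinct children *and* has reached a target width
(the age span divided by a window-count hint), closing at the next visit
age; a window is force-closed at `max_width = 12` months, spans with no
visits are skipped rather than emitted empty, and an under-populated
terminal window merges into its predecessor.  A boundary is forced at 24
months so the percentile analysis uses exactly the windows at or above
age 2.  The hint (8 below 24 months, 28 above) is a target, not a
guarantee: on the default synthetic schedule, annual visit clustering
yields ~25 windows, every one satisfying both constraints.  Only the
constraints — not the count — are treated as binding.

**Window values** are per-child means of visits falling in the window
(half-open intervals; the final window is closed on the right).  Missing
cells are filled with the mean of the last and next observed window values
regardless of gap length; leading/trailing gaps carry the first/last
observed value outward.  The edge rule is a package decision (the
last-next average is undefined at series edges); every cell's provenance
(`observed` / `interpolated` / `edge_filled`) is recorded so downstream
code can restrict to observed cells — the per-window regressions do
exactly that.

**Classification** runs k-means (k = 2, Euclidean, 25 restarts, fixed
seed) on the complete percentile matrix, then one PCA of the
column-centered matrix over all children jointly (the per-cluster variant
was considered; the joint PCA matches the reported variance decomposition
of this family of analyses and keeps the PC2 axis common to both
clusters).  Deterministic orientation removes all label ambiguity:

* cluster 1 is the cluster with the higher grand-mean percentile;
* PC1 is oriented to correlate positively with per-child means;
* PC2 is oriented so its mean loading over the earliest third of windows
  exceeds that over the latest third.  Under this sign convention children
  whose percentiles rise sharply *within* the observed span score
  negative (late onset) and children already high throughout score
  positive (early onset), so the four groups are
  early-OWO = cluster 1 ∧ PC2 ≥ 0, late-OWO = cluster 1 ∧ PC2 < 0,
  NW-A / NW-B = cluster 2 split the same way.

NW-A ∪ NW-B → NW is the deterministic 3-level collapse; the empirical
justification (no metabolite separates NW-B from NW-A after FDR) is
recomputed by `association.explore_four_groups`, which emits the
per-contrast significance counts and a collapse recommendation.

Group curves are LOWESS (tricube local linear, default frac 0.3, via
statsmodels) over pooled (window-midpoint, percentile) points.

## Co-abundance modules

Unsigned weighted network on the transformed panel: `a_ij = |r_ij|^β`
(Pearson).  β is the smallest candidate in 1..20 whose scale-free fit
index reaches the target (default 0.80) on a plateau (improvement over
β−1 below 0.02); when no candidate qualifies, the fallback is the argmax
of the fit index **restricted to powers with mean connectivity ≥ 1** — an
essentially empty network (mean k ≪ 1) can show a spuriously high fit
index, and selecting it would dissolve all structure.  The fit index is
the signed R² of log₁₀ frequency on log₁₀ mean connectivity over ten
equal-width connectivity bins (negative when the slope is positive);
fewer than three non-empty bins → undefined.  β is overridable by config.

Topological overlap `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij)`, `TOM_ii = 1`, verified against a brute-force double-loop oracle to
1e-10.  Modules are branches of the average-linkage dendrogram of
1 − TOM, cut at 0.99 × the maximum merge height (the "tree"-style static
variant of dynamic tree cut; the hybrid variant's PAM stage is not
implemented).  Clusters smaller than 15 members stay grey.  Colors follow
the conventional size-ordered sequence (turquoise, blue, brown, ...), with
size ties broken by first-member position for determinism.  Optional
eigen-correlation merging exists behind a flag and is off by default.

Eigen-metabolites are the first principal component of the standardized
member columns, rescaled to unit variance and sign-oriented to correlate
positively with the members' mean profile, so "higher eigen-score" always
means "higher typical member abundance" and odds ratios are per SD.

## Association models

Baseline-category multinomial logit (statsmodels MNLogit, Newton with an
L-BFGS fallback when the observed information is singular or a Newton step
diverges — both flagged), reference group NW (NW-A for the exploratory
4-group models).  Covariates: sex, race (Black reference), preterm birth,
maternal smoking (Never reference), maternal overweight/obesity (binary by
default; a continuous maternal-BMI column is used as-is if supplied),
maternal education.  Explicit "Unknown" categories are kept as their own
dummy level so covariate missingness does not shrink n; complete-case
behavior falls out of simply dropping those rows upstream.  Wald CIs
`exp(β ± 1.96·SE)`; estimates with |β| > 20 are flagged as separation,
never silently dropped.  A zero-variance exposure short-circuits to the
covariates-only fit with β = 0.

FDR is Benjamini–Hochberg per contrast within the declared family: all
modules for the module table (ordered by the early-onset contrast's q),
all tested metabolites for metabolite tables, the union of members of
modules with p ≤ 0.05 on either contrast for the follow-up table.

Sex sensitivity: the full model adds exposure and exposure × sex; the null
drops both; LRT on 2 × (levels − 1) df, with per-contrast Wald p for the
interaction term alone also reported.

## Time-window regressions

Per window, OLS of the window-averaged BMI on exposure + sex +
exposure×sex + mean visit age + covariates (+ the sensitivity adjuster).
Only children *observed* in the window enter — regressing on imputed
outcomes would manufacture information.  A 2-df LRT (χ² reference) screens
the exposure's overall effect; sex-specific slopes are
β_F = β_exposure and β_M = β_exposure + β_interaction (female reference,
both reported, so the coding is immaterial), each standardized by the
within-sex SD of observed window BMI.  Models with fewer than 20 complete
cases are skipped; single-sex windows drop the interaction and are
flagged.  FDR families are per window.  Birthweight adjustment is skipped
for the first window by construction (at birth the outcome and the
adjuster coincide).  Null simulations for the LRT use n = 250 per
replicate; at much smaller n the χ²₂ reference is visibly
anticonservative, which is a property of the asymptotic approximation,
not of the implementation.

## Cohort descriptives

Group-stratified summaries: mean ± SD with one-way ANOVA for roughly
normal continuous variables, median (IQR) with Kruskal–Wallis for the
config-listed skewed ones (last-visit anthropometrics by default), count
(%) with Pearson chi-squared (no continuity correction, matching the
base-R default for tables beyond 2×2; Yates available for 2×2).
"Unknown" rows are displayed but excluded from the chi-squared test by
default — testing structurally missing categories answers no
epidemiological question — with a flag to include them.
`owo_percentages` reproduces, by pure arithmetic, the
overweight/obesity-at-last-visit shares per trajectory group and per
k-means cluster from either data flags or a published count table.

## Synthetic cohort

The generator emulates a high-risk urban US birth cohort followed from
birth to 18 years, with ground truth recorded for every planted feature.

* **Classes:** early-OWO / late-OWO / NW with probabilities
  0.41/0.27/0.32 at n = 900 (defaults).
* **Percentile curves:** NW flat at 40; early-OWO `40 + 50·expit((age −
  28)/8)` (≈85 by age 4, plateau ≈90); late-OWO `50 + 38·expit((age −
  110)/14)` (≈50 until age 6, ≈85 by age 12).  Child-level intercept
  SD 5, per-visit noise SD 4, mapped to BMI through the synthetic LMS
  reference; below 24 months an infant BMI curve with a small class boost
  is used directly.
* **Visit schedule:** dense nominal ages below 2 years, annual after,
  ±1 month jitter, 10% per-visit missingness; 12% of children have full
  follow-up and the rest drop out uniformly between 120 and 217 months.
  The dropout floor sits past the late-onset inflection deliberately: a
  late-onset child unobserved beyond age 4 is *informationally*
  indistinguishable from NW, and the generator's purpose is to define
  conditions under which the planted truth is recoverable.  Consequently
  the generator does not emulate the severe late-adolescent attrition of
  real cohorts, and recovery rates here say nothing about trajectory
  classification under such attrition.
* **Metabolome:** seven correlated blocks (sizes 60/50/43/25/23/20/20)
  plus 135 independent metabolites; block members are
  `√ρ·f_block + √(1−ρ)·ε` with ρ = 0.5; block factors shift by class —
  TAG/TAG/DAG blocks −0.25 SD and the CE block +0.25 SD in early-OWO,
  half that in late-OWO, 0 in NW.  Intensities are `scale·exp(0.1·x)`
  (≈10% CV), 19 junk metabolites get heavy log-noise (≈50% CV) to
  exercise the filter, and values below each metabolite's 2% quantile
  become non-detects.  The first 194 panel columns are tagged C8-pos,
  the rest HILIC-pos.
* **Covariates:** marginals typical of the target population (≈45%
  female, ≈60% Black, ≈18% preterm, ≈50% maternal OWO, ≈33% cesarean).
  Birthweight = 3000 g + 150·(early-OWO) − 120·f_TAG + N(0, 600²), and
  BMI before 48 months carries a fading birthweight effect — this is what
  makes birthweight behave as a partial mediator of the cord-metabolome
  signal, so that adjusting for it attenuates early-window effects
  (observed: mean |standardized β| 0.069 → 0.047 on the default cohort)
  while cesarean/breastfeeding adjustment moves them by < 1%.

Everything is deterministic given (config, seed).  What passing tests on
this cohort demonstrate: the pipeline recovers planted trajectory classes,
correlation blocks, effect directions and mediation structure at realistic
signal-to-noise, with calibrated error rates under the null.  What they do
not demonstrate: robustness to batch effects, drift, heteroscedastic
assay noise, informative missingness, or real-world attrition — none of
which the generator simulates.

## Numerical notes and limitations

* The planted ±0.25 SD module shifts put per-module detection power with
  FDR control almost exactly at 80% (z ≈ 3.0 against a BH-adjusted
  threshold z ≈ 2.1), so simulated recovery rates near that value
  fluctuate by a few points across seed sets; the reported rates should be
  read with their binomial error.
* Module counts on weakly-correlated panels are sensitive to the
  soft-threshold power and the cut height; the defaults recover planted
  blocks exactly at ρ ≥ 0.5 with the connectivity-floored power selection,
  but real panels with heterogeneous correlations may warrant the explicit
  β override.
* k-means with 25 restarts at a fixed seed is deterministic; classify
  results are invariant to child order and PCA basis sign by construction.
* The pipeline treats module eigen-scores as the time-window exposures by
  default; per-metabolite window analyses (376 × windows OLS fits) run in
  a few minutes through the same `run_window_analysis` API.
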