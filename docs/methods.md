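# Methods

## Scope and design

`sigfall` is an analysis pipeline for binary faller / non-faller
classification from 27 subject-level spatiotemporal gait characteristics.
It has four scientific layers — a synthetic cohort generator, descriptive
group statistics, three pre-processing transforms, and a classification
harness — presented around a model/results pair
(`FallClassificationExperiment` → `ExperimentResults`) in the style of
statistical modelling packages, with the generator and transforms as
plain functions/transformers.

## Synthetic cohort generator

The generator emulates the structure of a neurological inpatient cohort
assessed on a 20 m walk; it is the package's study condition, not a
tuning knob.

* **Group sizes** default to 190 non-fallers and 159 fallers.
* **Marginals.** Each characteristic has a configurable non-faller mean
  and SD; defaults are physiologically plausible values for slow clinical
  gait (e.g. stride velocity 0.90 ± 0.25 m/s, stride duration
  1.25 ± 0.15 s, 62 ± 3 % stance phase). These set the scale
  heterogeneity that standardisation must handle; their absolute values
  are otherwise immaterial.
* **Effects.** Faller feature j is shifted by `effect · base_sd[j]`.
  Defaults carry sign information only — fallers slower, shorter strides,
  reduced heel-strike angle, swing phase, swing-phase symmetry and
  circumduction; increased durations, timing variability, toe-off angle,
  step count and stance-phase symmetry — with |z| = 0.3 per signed
  feature, a modest separation that keeps classifier ranking
  non-degenerate. The ten unsigned characteristics have zero effect.
* **Correlation.** A Gaussian copula with a block-exchangeable
  correlation matrix: three blocks (pace, phase/timing, variability) with
  r = 0.7 within and r = 0.2 between blocks, reflecting the high
  collinearity of gait characteristics. Any block layout or explicit PSD
  matrix can be supplied.
* **Skewness.** The two gait-cycle variability measures are lognormal by
  default (moment-matched to the configured mean/SD through the copula),
  so the normality-gated test choice is exercised under default
  conditions. Note the lognormal marginal transform attenuates Pearson
  correlations slightly (≈ 4% at these coefficients of variation);
  correlation-recovery guarantees are stated for the normal marginals.
* **Demographics.** Age, height and mass are truncated normals per group
  (non-fallers 61.6 ± 12.2 y, 1.73 ± 0.10 m, 81.89 ± 16.35 kg; fallers
  65.0 ± 12.7 y, 1.70 ± 0.10 m, 76.31 ± 14.87 kg; bounds 18–100 y,
  1.30–2.20 m, 35–160 kg). BMI is derived as mass/height², so its group
  means match printed cohort values only approximately (a mean of ratios
  is not a ratio of means). Sex is Bernoulli with male fractions 115/190
  and 88/159.

What the generator does **not** emulate: physical coupling between
characteristics (velocity is not constrained to length/duration),
disease-subgroup mixture structure, measurement error of the sensor
system, or missing data. Passing tests therefore demonstrate the
pipeline's statistical behaviour under a known truth, not clinical
performance on real cohorts.

## Group statistics

Per feature, Shapiro–Wilk at α = 0.05 on each group gates between the
pooled-variance Student t-test (both groups consistent with normality)
and the two-sided Mann–Whitney U test; Welch's correction is available by
flag. The effect size is z = (faller mean − non-faller mean) / non-faller
sample SD (ddof = 1), treating non-fallers as the reference group — a
convention, documented rather than asserted as universal. No multiplicity
correction is applied by default; Bonferroni and Benjamini–Hochberg are
optional. Under the null generator the pooled per-feature rejection rate
is calibrated at α (verified over 200 cohorts), though within-cohort
feature correlation inflates the cohort-to-cohort variance of the
rejection count relative to an independence assumption.

## Standardisation

z = (x − x̄)/σ with population (1/N) SD, fitted on training rows only and
frozen for test rows. The formulation with separate per-group statistics
is retained as mode `per_group_literal` for reproduction studies only: it
needs the subject's label at transform time, and because it recentres
both groups to mean 0 / SD 1 it *erases* mean separation rather than
encoding it — it is unusable, and misleading, for prediction.

## PCA

Eigendecomposition of the population covariance of standardised training
data (equivalently the correlation matrix), eigenpairs sorted by
descending eigenvalue. Determinism conventions: each eigenvector's
largest-magnitude loading is made positive (first index on ties), and
exactly tied eigenvalues are ordered by that loading index. The Kaiser
rule retains eigenvalues strictly greater than 1 — meaningful only on the
unit-variance scale, which the 1/N convention guarantees exactly. The
achieved explained-variance fraction is reported, not asserted, since it
is cohort-specific. PCA is fitted per training fold by default; fitting
on the full data set is possible through the standalone `transform` CLI
but is flagged as exploratory.

## Path signatures

A subject's 27 characteristics are embedded as the 2-D piecewise-linear
path with points (j/27, zⱼ), j = 1…27 — an index–value embedding, the
simplest construction for turning an ordered scalar stream into a path.
The index coordinate is normalised to (0, 1] so the two coordinates have
comparable ranges. Because signatures are not scale-invariant and the
characteristics have heterogeneous units, values are z-scored with
training-partition statistics before embedding (`scaling="none"` exists
for algebra tests).

Computation is exact: closed-form per-segment signatures
(S(i₁,…,i_m) = (1/m!) ∏ Δ^{iⱼ}) folded with Chen's identity. The default
truncation order is k = 2 (6 non-constant terms); k is configurable to 7
with a warning above 5 (2^m growth per level). An independent brute-force
oracle (`signature_oracle`) computes every term by trapezoidal iterated
integration on a fine sampling of the path and is used only for testing.
Feature columns follow a fixed level-major, lexicographic word order
(S_1, S_2, S_1_1, S_1_2, S_2_1, S_2_2, …); the constant term is stored on
the signature object but dropped from feature matrices (zero variance).

**Information content at k = 2.** For this construction the index
increments are fixed, so S(1) and S(1,1) are constants of the embedding,
and the shuffle identities determine S(2,1) and S(2,2) from the rest; the
degree-2 signature carries exactly two informative coordinates,
S(2) = z₂₇ − z₁ and S(1,2) = ∫ x dz. This is a severe compression of a
27-dimensional profile: under the generator's default effect signs scaled
to |z| = 1.0 the Bayes-optimal accuracy in that 2-D feature space is
≈ 0.69, and measured random-forest accuracy plateaus near 0.77 even at
k = 7. The signature route is therefore expected to trail well-separated
linear baselines on z-scored features whenever the discriminative signal
is a mean shift spread across many characteristics; its advantage, if
any, lies in nonlinear shape structure that a mean-shift generator does
not produce. This bound is a property of the 2-D index–value embedding at
low truncation order, not of signatures in general.

## Classification harness

Six scikit-learn families with pinned hyperparameters (LDA svd solver;
logistic regression C = 1, lbfgs, 1000 iterations; Gaussian NB; SVC
linear kernel C = 1; KNN k = 5 uniform weights — odd k precludes binary
vote ties, residual distance ties resolve to the first-listed class;
random forest 100 trees seeded per repeat). The protocol is five
stratified 70/30 train/test splits with distinct seeds (default
1,2,3,4,5); stratification preserves the 190:159 imbalance in every
partition. A stratified 5-fold CV reading is available
(`protocol="kfold"`). AUC uses predicted probabilities where available
and signed decision values for SVM and LDA. If a split produces a
single-class training partition it is re-drawn with a shifted seed (at
most 10 attempts). All transforms are fitted inside the training
partition; grid evaluation shares one fitted transform per
(split × method) across the six models.

Metrics are computed from integer confusion counts, so the identities
accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)
hold exactly; F1 is the harmonic mean of precision and sensitivity and is
reported as 0 when both are 0 (no positive predictions and no recalled
positives); AUC is undefined (NaN) for single-class test truth.

## Numerical choices

* Algebraic signature identities are tested at 1e−12; the numeric oracle
  at 1e−3 (10⁴ sampling steps; trapezoidal error is far smaller, the
  band is deliberately loose).
* Constant-feature detection uses exact peak-to-peak equality, since the
  floating-point SD of a constant column can round to ~1e−16.
* CSV round-trips are byte-stable: floats serialise via repr and parse
  with round-trip precision.
* All randomness flows from explicit integer seeds (generator seed,
  per-repeat split seeds, per-repeat forest seeds); identical configs
  reproduce byte-identical outputs.

## Problem sizes used in the shipped checks

Cohort-level checks run at the default n = 349 (20 seeds for null
calibration of the full grid, 200 cohorts for test-size calibration, 100
for sign recovery); moment/correlation recovery uses 10⁴ subjects and
demographic recovery 10⁵; signature correctness uses 200 random paths of
2–10 segments at orders ≤ 4 against the 10⁴-step oracle. These sizes make
the statistical assertions sharp at conventional 3–3.5σ slack.

## Known limitations

* The degree-2 signature information bound above: with this embedding the
  signature route cannot represent arbitrary linear contrasts of the
  characteristics, so mean-shift-dominated cohorts favour the z-score
  route by construction.
* The Kaiser rule on block-exchangeable correlation counts the block-mean
  eigenvalues; it recovers the planted factor count for well-separated
  blocks (r_within = 0.7 vs r_between = 0.2) but is not a consistent
  factor-number estimator in general.
* The generator's effects act on means only; covariance differences
  between groups are not simulated.
* `per_group_literal` standardisation exists for methodological
  comparison only; see above.
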