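# sigfall

Gait-based fall-risk classification with three competing pre-processing
pipelines: z-score standardisation, PCA with Kaiser component selection,
and truncated path-signature features.

## The problem

Falls are a leading cause of morbidity in people with neurological
disorders. A 20 m instrumented walk with wearable inertial sensors yields
27 spatiotemporal gait characteristics per patient (means and
stride-to-stride SDs of stride duration/length/velocity, stance/swing
timing, foot angles, circumduction, plus step count, phase-symmetry ratios
and gait-cycle variability). Classifiers trained on such characteristics
can separate patients with a fall history ("fallers") from non-fallers,
but the characteristics are strongly correlated, heterogeneous in scale,
and high-dimensional relative to typical cohort sizes (a few hundred
inpatients), so the choice of pre-processing transform materially changes
classifier performance. `sigfall` implements and compares the three
transforms within a leakage-free repeated-holdout harness, and ships a
synthetic cohort generator that emulates the relevant clinical data
structure (group sizes 190 non-fallers / 159 fallers, block-correlated
features, signed group effects, demographics) so the full pipeline is
testable without access to patient data.

## The methods in brief

**Path signature.** A subject's characteristics (x₁, …, x₂₇) are embedded
as a 2-D piecewise-linear path γ with points (j/27, zⱼ), where zⱼ is the
z-scored value of characteristic j. The signature of γ is the sequence of
iterated integrals S(i₁,…,i_m) = ∫…∫_{t₁<…<t_m} dγ^{i₁}…dγ^{i_m},
indexed by words over {1, 2}. For one straight segment the closed form is
S(i₁,…,i_m) = (1/m!) ∏ⱼ Δ^{iⱼ}, and piece signatures combine by Chen's
identity S_{s,u}(w) = Σ_{w=u·v} S_{s,t}(u)·S_{t,u}(v), so no quadrature is
needed. Truncated at order k the feature vector has Σ_{m≤k} 2^m
non-constant terms — 6 at k = 2 (the default), 62 at k = 5, 254 at k = 7.

**PCA.** Eigendecomposition of the population covariance of standardised
training data (Eq. y = Wᵀ(x − x̄)); components with eigenvalue > 1 are
retained (Kaiser rule).

**Harness.** Six scikit-learn classifier families (LDA, logistic
regression, Gaussian naive Bayes, linear SVM, 5-NN, random forest with 100
trees) × the three transforms, evaluated over five stratified 70/30
train/test splits with distinct seeds. Every transform is fitted on the
training partition only. Metrics: accuracy, sensitivity (faller recall),
specificity, precision, F1, AUC.

## Worked example

```python
import sigfall as sf
from sigfall.cohort import CohortConfig

table = sf.generate_cohort(CohortConfig(seed=1))   # 349 subjects, 27 features
results = sf.FallClassificationExperiment(table).fit()
print(results.summary())
```

prints (cells are mean accuracy % with mean sensitivity/specificity %):

```
Model           zscore                  pca                     signature
----------------------------------------------------------------------------------------
LDA             81.71 (82, 82)          51.43 (8, 88)           61.14 (34, 84)
LR              82.48 (82, 83)          51.43 (8, 88)           60.19 (29, 87)
NB              63.81 (66, 62)          53.14 (22, 79)          56.38 (24, 84)
SVM-linear      80.95 (79, 82)          54.29 (0, 100)          59.05 (22, 90)
KNN             68.57 (64, 72)          49.52 (42, 56)          51.43 (37, 64)
RF              72.57 (62, 81)          53.14 (48, 57)          52.76 (40, 63)
```

Under the generator's default conditions (modest |z| = 0.3 group effects
on 17 characteristics) the linear models on z-scored features perform
best, PCA discards most of the discriminative signal (the Kaiser
components track the correlation blocks, not the group difference), and
the degree-2 signature sits in between — it compresses each subject to six
geometric terms of the feature path. `results.per_repeat` carries the
split-level metrics; `results.grid` the per-cell means.

Group-level description:

```python
comparison = sf.compare_groups(table)   # Shapiro-gated t / Mann-Whitney per feature
corr = sf.correlation_matrix(table)     # 27 x 27 Pearson matrix
```

The same pipeline is scriptable from the shell:

```bash
sigfall simulate --seed 1 --out cohort.csv
sigfall describe --in cohort.csv --out-dir results/
sigfall evaluate --in cohort.csv --methods zscore,pca,signature --out results/
```

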