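import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA

from sigfall import (
    PCAModel,
    apply_pca,
    apply_standardizer,
    fit_pca,
    fit_standardizer,
    select_components,
)
from sigfall.cohort import CohortConfig, build_correlation_matrix, default_effect_profile
from sigfall import default_schema, generate_cohort


# ------------------------------------------------------------- z-scoring

def test_pooled_standardisation_is_idempotent_on_training_data(default_cohort):
    params = fit_standardizer(default_cohort, mode="pooled_train")
    Z = apply_standardizer(params, default_cohort)
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)


def test_z_score_arithmetic():
    # a 65.0 observation against mean 61.6, SD 12.2
    assert (65.0 - 61.6) / 12.2 == pytest.approx(0.2787, abs=5e-5)


def test_round_trip_recovers_input(default_cohort):
    params = fit_standardizer(default_cohort)
    Z = apply_standardizer(params, default_cohort)
    np.testing.assert_allclose(Z * params.sd + params.mean, default_cohort.features, atol=1e-10)


def test_identity_params_are_identity_transform(default_cohort, make_table):
    params = fit_standardizer(default_cohort)
    params.mean = np.zeros(27)
    params.sd = np.ones(27)
    np.testing.assert_array_equal(apply_standardizer(params, default_cohort), default_cohort.features)


def test_constant_feature_rejected_by_name(make_table):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 27))
    X[:, default_schema().index("swing_time_mean")] = 4.2
    table = make_table(X, [0, 1] * 10)
    with pytest.raises(ValueError, match="swing_time_mean"):
        fit_standardizer(table)


def test_per_group_literal_differs_from_pooled_on_shifted_groups(make_table):
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 27))
    y = np.r_[np.zeros(100, dtype=int), np.ones(100, dtype=int)]
    X[y == 1, 0] += 3.0  # group shift on one feature
    table = make_table(X, y)
    pooled = apply_standardizer(fit_standardizer(table, "pooled_train"), table)
    literal = apply_standardizer(fit_standardizer(table, "per_group_literal"), table)
    assert not np.allclose(pooled[:, 0], literal[:, 0])
    # per-group mode recentres each group: the shift is erased
    assert abs(literal[y == 1, 0].mean()) < 1e-10 and abs(literal[y == 0, 0].mean()) < 1e-10
    # on unshifted features the two modes agree up to sampling noise
    r = np.corrcoef(pooled[:, 1], literal[:, 1])[0, 1]
    assert r > 0.99


def test_unknown_mode_rejected(default_cohort):
    with pytest.raises(ValueError, match="mode"):
        fit_standardizer(default_cohort, mode="median")


# ------------------------------------------------------------------ PCA

def test_eigenvalues_recover_diagonal_covariance():
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(100_000, 3)) * np.sqrt([3.0, 2.0, 1.0])
    model = fit_pca(Z)
    np.testing.assert_allclose(model.eigenvalues, [3.0, 2.0, 1.0], atol=0.05)


def test_perfect_correlation_collapses_to_one_component():
    rng = np.random.default_rng(3)
    x = rng.normal(size=500)
    model = fit_pca(np.column_stack([x, x]))
    assert model.eigenvalues[1] <= 1e-8
    assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-8)


def test_eigenvalue_sum_equals_total_variance(default_cohort):
    Z = apply_standardizer(fit_standardizer(default_cohort), default_cohort)
    model = fit_pca(Z)
    trace = np.trace((Z - Z.mean(0)).T @ (Z - Z.mean(0)) / Z.shape[0])
    assert model.eigenvalues.sum() == pytest.approx(trace, rel=1e-8)
    assert model.explained_variance_ratio.sum() == pytest.approx(1.0, rel=1e-12)


def test_components_orthonormal_and_eigenvalues_sorted(default_cohort):
    Z = apply_standardizer(fit_standardizer(default_cohort), default_cohort)
    model = fit_pca(Z)
    W = model.components
    np.testing.assert_allclose(W.T @ W, np.eye(W.shape[1]), atol=1e-10)
    assert (np.diff(model.eigenvalues) <= 1e-12).all()
    assert model.eigenvalues.min() >= -1e-10


def test_agrees_with_sklearn_pca(default_cohort):
    Z = apply_standardizer(fit_standardizer(default_cohort), default_cohort)
    model = fit_pca(Z)
    sk = SkPCA().fit(Z)
    # sklearn uses 1/(N-1); rescale to the population convention
    np.testing.assert_allclose(
        model.eigenvalues, sk.explained_variance_ * (len(Z) - 1) / len(Z), rtol=1e-8
    )
    np.testing.assert_allclose(np.abs(model.components.T), np.abs(sk.components_), atol=1e-8)


def test_kaiser_rule_strictly_above_one():
    model = PCAModel(np.zeros(4), np.eye(4), np.array([2.1, 1.5, 1.0, 0.4]))
    assert select_components(model, "kaiser") == 2
    assert select_components(model, "fixed:3") == 3
    with pytest.raises(ValueError):
        select_components(model, "fixed:5")
    with pytest.raises(ValueError):
        select_components(model, "scree")


def test_kaiser_finds_planted_five_block_structure():
    schema = default_schema()
    names = list(schema.names)
    blocks = {f"b{i}": names[sum([6, 6, 5, 5, 5][:i]):sum([6, 6, 5, 5, 5][: i + 1])] for i in range(5)}
    cfg = CohortConfig(
        correlation_blocks=blocks,
        effect_profile=default_effect_profile(magnitude=0.0),
        skew_features=(),
        seed=4,
        with_demographics=False,
    )
    table = generate_cohort(cfg)
    Z = apply_standardizer(fit_standardizer(table), table)
    assert select_components(fit_pca(Z), "kaiser") == 5


def test_projection_properties(default_cohort):
    Z = apply_standardizer(fit_standardizer(default_cohort), default_cohort)
    model = fit_pca(Z)
    Y = apply_pca(model, Z)
    # full projection is an isometry
    i, j = 5, 80
    orig = np.linalg.norm(Z[i] - Z[j])
    assert np.linalg.norm(Y[i] - Y[j]) == pytest.approx(orig, rel=1e-8)
    # components decorrelated on training data, variances equal eigenvalues
    C = np.cov(Y, rowvar=False, ddof=0)
    np.testing.assert_allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-8)
    np.testing.assert_allclose(np.diag(C), model.eigenvalues, rtol=1e-8, atol=1e-10)


def test_apply_pca_validates_shapes(default_cohort):
    Z = apply_standardizer(fit_standardizer(default_cohort), default_cohort)
    model = fit_pca(Z)
    with pytest.raises(ValueError):
        apply_pca(model, Z[:, :5])
    with pytest.raises(ValueError):
        apply_pca(model, Z, d=28)
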