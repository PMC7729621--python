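import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigfall import (
    PiecewisePath,
    build_path,
    chen_concatenate,
    default_schema,
    fit_standardizer,
    path_signature,
    segment_signature,
    signature_dimension,
    signature_features,
    signature_oracle,
    signature_words,
)
from sigfall.signature import SignatureTransform, word_label


def random_path(rng, n_points, d=2):
    return PiecewisePath(rng.standard_normal((n_points, d)))


# ---------------------------------------------------------------- dimension

@pytest.mark.parametrize("d,k,expected", [(2, 2, 6), (2, 5, 62), (2, 7, 254), (1, 4, 4), (3, 2, 12)])
def test_signature_dimension_level_sum(d, k, expected):
    assert signature_dimension(d, k) == expected
    assert len(signature_words(d, k)) == expected


def test_signature_dimension_rejects_nonpositive():
    with pytest.raises(ValueError):
        signature_dimension(0, 2)
    with pytest.raises(ValueError):
        signature_dimension(2, 0)


def test_word_order_is_level_major_lexicographic():
    words = signature_words(2, 2)
    assert words == [(1,), (2,), (1, 1), (1, 2), (2, 1), (2, 2)]
    assert word_label((1, 2)) == "S_1_2"


# ------------------------------------------------------------ one segment

def test_degenerate_segment_has_zero_signature():
    sig = segment_signature([1.0, 2.0], [1.0, 2.0], k=3)
    assert all(sig[w] == 0.0 for w in signature_words(2, 3))
    assert sig[()] == 1.0


def test_unit_diagonal_segment_closed_form():
    sig = segment_signature([0.0, 0.0], [1.0, 1.0], k=2)
    assert sig[(1,)] == sig[(2,)] == 1.0
    for w in [(1, 1), (1, 2), (2, 1), (2, 2)]:
        assert sig[w] == 0.5


def test_segment_cross_term_value():
    # displacement (2, 3): S(1,2) = (1/2!) * 2 * 3
    sig = segment_signature([0.0, 0.0], [2.0, 3.0], k=2)
    assert sig[(1, 2)] == 3.0


def test_segment_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        segment_signature([0.0], [1.0, 1.0], k=2)


# ------------------------------------------------------------------- Chen

def test_concatenation_with_trivial_signature_is_identity():
    rng = np.random.default_rng(0)
    a = segment_signature(rng.normal(size=2), rng.normal(size=2), k=3)
    trivial = segment_signature([0.0, 0.0], [0.0, 0.0], k=3)
    for combined in (chen_concatenate(a, trivial), chen_concatenate(trivial, a)):
        for w in signature_words(2, 3):
            assert combined[w] == pytest.approx(a[w], abs=1e-15)


def test_l_path_hand_computed_values():
    a = segment_signature([0.0, 0.0], [1.0, 0.0], k=2)
    b = segment_signature([1.0, 0.0], [1.0, 1.0], k=2)
    sig = chen_concatenate(a, b)
    expected = {(1,): 1.0, (2,): 1.0, (1, 1): 0.5, (2, 2): 0.5, (1, 2): 1.0, (2, 1): 0.0}
    for w, v in expected.items():
        assert sig[w] == pytest.approx(v, abs=1e-15)
    # fold over the same two segments gives the same result
    path = PiecewisePath([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
    full = path_signature(path, k=2)
    for w in signature_words(2, 2):
        assert full[w] == pytest.approx(sig[w], abs=1e-15)


def test_chen_concatenation_is_associative():
    rng = np.random.default_rng(1)
    pts = rng.standard_normal((4, 2))
    segs = [segment_signature(pts[i], pts[i + 1], k=3) for i in range(3)]
    left = chen_concatenate(chen_concatenate(segs[0], segs[1]), segs[2])
    right = chen_concatenate(segs[0], chen_concatenate(segs[1], segs[2]))
    for w in signature_words(2, 3):
        assert left[w] == pytest.approx(right[w], abs=1e-12)


def test_chen_rejects_mismatched_order():
    a = segment_signature([0.0, 0.0], [1.0, 1.0], k=2)
    b = segment_signature([0.0, 0.0], [1.0, 1.0], k=3)
    with pytest.raises(ValueError):
        chen_concatenate(a, b)


# ---------------------------------------------------------- full path

def test_reparametrisation_invariance_collinear_points():
    start, end = np.array([0.2, -1.0]), np.array([1.4, 2.0])
    single = path_signature(PiecewisePath([start, end]), k=3)
    ts = np.linspace(0, 1, 7)[:, None]  # 5 interior collinear points
    refined = path_signature(PiecewisePath(start + ts * (end - start)), k=3)
    for w in signature_words(2, 3):
        assert refined[w] == pytest.approx(single[w], abs=1e-10)


def test_truncation_warning_beyond_order_five():
    path = PiecewisePath([[0.0, 0.0], [1.0, 1.0]])
    with pytest.warns(UserWarning, match="d\\^k"):
        path_signature(path, k=6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(3, 8))
def test_shuffle_and_displacement_identities(seed, n_points):
    """Level-2 shuffle identities and the level-1 displacement identity."""
    path = random_path(np.random.default_rng(seed), n_points)
    sig = path_signature(path, k=2)
    assert sig[(1, 2)] + sig[(2, 1)] == pytest.approx(sig[(1,)] * sig[(2,)], abs=1e-12)
    for i in (1, 2):
        assert sig[(i, i)] == pytest.approx(sig[(i,)] ** 2 / 2, abs=1e-12)
        disp = path.points[-1, i - 1] - path.points[0, i - 1]
        assert sig[(i,)] == pytest.approx(disp, abs=1e-12)


# ----------------------------------------------------------------- oracle

def test_oracle_matches_closed_forms():
    l_path = PiecewisePath([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
    assert signature_oracle(l_path, k=2, steps=10_000)[(1, 2)] == pytest.approx(1.0, abs=1e-3)
    seg = PiecewisePath([[0.0, 0.0], [1.0, 1.0]])
    oracle = signature_oracle(seg, k=2, steps=10_000)
    for w in [(1, 1), (1, 2), (2, 1), (2, 2)]:
        assert oracle[w] == pytest.approx(0.5, abs=1e-3)


def test_oracle_converges_to_chen_computation():
    rng = np.random.default_rng(2)
    path = random_path(rng, 6)
    exact = path_signature(path, k=3).vector()
    errs = [
        np.abs(signature_oracle(path, k=3, steps=s).vector() - exact).max()
        for s in (500, 1000, 2000)
    ]
    assert errs[2] < errs[0]
    assert errs[2] < 1e-4


def test_oracle_rejects_too_few_steps():
    with pytest.raises(ValueError):
        signature_oracle(PiecewisePath([[0.0, 0.0], [1.0, 1.0]]), k=2, steps=5)


# ------------------------------------------------------------- build_path

def test_build_path_structure():
    rng = np.random.default_rng(3)
    path = build_path(rng.normal(size=27))
    assert path.points.shape == (27, 2)
    assert (np.diff(path.points[:, 0]) > 0).all()
    assert path.points[-1, 0] == pytest.approx(1.0)


def test_constant_feature_vector_gives_horizontal_line():
    path = build_path(np.full(27, 3.7))
    sig = path_signature(path, k=3)
    for w in signature_words(2, 3):
        if 2 in w:
            assert sig[w] == pytest.approx(0.0, abs=1e-12)


def test_scaling_modes_change_level2_terms(default_cohort):
    scaler = fit_standardizer(default_cohort)
    x = default_cohort.features[0]
    raw = path_signature(build_path(x, scaling="none"), k=2)
    scaled = path_signature(build_path(x, scaling="train_zscore", scaler=scaler), k=2)
    assert raw[(1, 2)] != pytest.approx(scaled[(1, 2)])


def test_build_path_input_validation():
    with pytest.raises(ValueError, match="length"):
        build_path(np.zeros(20))
    bad = np.zeros(27)
    bad[3] = np.nan
    with pytest.raises(ValueError, match="finite"):
        build_path(bad)
    with pytest.raises(ValueError, match="fitted"):
        build_path(np.zeros(27), scaling="train_zscore")


# ---------------------------------------------------- feature matrices

def test_signature_feature_matrix_shapes(default_cohort):
    scaler = fit_standardizer(default_cohort)
    F2 = signature_features(default_cohort, k=2, scaler=scaler)
    assert F2.shape == (349, 6)
    F5 = signature_features(default_cohort, k=5, scaler=scaler)
    assert F5.shape == (349, 62)


@pytest.mark.parametrize("k", range(1, 8))
def test_dimension_law_matches_column_count(k, make_table):
    rng = np.random.default_rng(4)
    table = make_table(rng.normal(size=(3, 27)), [0, 1, 1])
    F = signature_features(table, k=k, scaling="none")
    assert F.shape[1] == signature_dimension(2, k)


def test_identical_subjects_get_identical_rows(make_table):
    rng = np.random.default_rng(5)
    row = rng.normal(size=27)
    table = make_table(np.vstack([row, rng.normal(size=27), row]), [1, 0, 1])
    F = signature_features(table, k=3, scaling="none")
    np.testing.assert_array_equal(F[0], F[2])
    assert not np.array_equal(F[0], F[1])


def test_unfitted_transform_rejected(default_cohort):
    t = SignatureTransform(k=2, scaling="train_zscore")
    with pytest.raises(ValueError, match="fit"):
        t.transform(default_cohort)
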