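"""Truncated path signatures of piecewise-linear paths.

The signature of a path is the sequence of its iterated integrals, indexed
by words over the coordinate alphabet {1, …, d}; truncated at order k it is
a finite, reparametrisation-invariant feature vector that encodes the
path's shape, including nonlinear (area-type) interactions between
coordinates.  For a single straight segment the level-m term for word
(i₁, …, i_m) has the closed form (1/m!) ∏_j Δ^{i_j}, and the signature of a
concatenation is the truncated tensor product of the piece signatures
(Chen's identity), so signatures of piecewise-linear paths need no
quadrature.

A subject's 27 gait characteristics are embedded as a 2-D piecewise-linear
path: point j = (j/27, scaled value of characteristic j).  The level-2
signature set is {1, S(1), S(2), S(1,1), S(1,2), S(2,1), S(2,2)}; for a
2-D path the number of non-constant terms is Σ_{m=1..k} 2^m (62 at k = 5,
254 at k = 7).

Feature vectors are ordered level-major, lexicographically within a level:
S(1), S(2), S(1,1), S(1,2), S(2,1), S(2,2), S(1,1,1), …  The constant term
(empty word, always 1) is stored on ``SignatureFeature`` but excluded from
feature matrices.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .schema import FeatureSchema, default_schema
from .table import GaitFeatureTable

__all__ = [
    "PiecewisePath",
    "SignatureFeature",
    "signature_words",
    "signature_dimension",
    "word_label",
    "build_path",
    "segment_signature",
    "chen_concatenate",
    "path_signature",
    "signature_oracle",
    "SignatureTransform",
    "signature_features",
]

Word = tuple[int, ...]


def signature_dimension(d: int, k: int) -> int:
    """Number of non-constant signature terms: Σ_{m=1..k} d^m."""
    if d < 1 or k < 1:
        raise ValueError("path dimension and truncation order must be >= 1")
    if d == 1:
        return k
    return (d ** (k + 1) - d) // (d - 1)


def signature_words(d: int, k: int) -> list[Word]:
    """All non-empty words over {1..d} up to length k, level-major then lexicographic."""
    if d < 1 or k < 1:
        raise ValueError("path dimension and truncation order must be >= 1")
    out: list[Word] = []
    for m in range(1, k + 1):
        out.extend(itertools.product(range(1, d + 1), repeat=m))
    return out


def word_label(word: Word) -> str:
    """Column name for a word, e.g. (1, 2) -> 'S_1_2'."""
    return "S_" + "_".join(str(i) for i in word)


@dataclass(frozen=True)
class PiecewisePath:
    """Ordered points joined by straight segments in R^d."""

    points: np.ndarray  # (n_points, d)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] < 1:
            raise ValueError("a path needs >= 2 points of common dimension >= 1")
        if not np.isfinite(pts).all():
            raise ValueError("path points must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    @property
    def n_segments(self) -> int:
        return self.points.shape[0] - 1


@dataclass
class SignatureFeature:
    """Truncated signature: word -> iterated-integral value (empty word = 1)."""

    dimension: int
    order: int
    terms: dict[Word, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms.setdefault((), 1.0)

    def __getitem__(self, word: Word) -> float:
        return self.terms.get(tuple(word), 0.0)

    def vector(self, include_constant: bool = False) -> np.ndarray:
        """Terms in canonical word order (level-major, lexicographic)."""
        words = signature_words(self.dimension, self.order)
        vals = [self[w] for w in words]
        if include_constant:
            vals = [self[()]] + vals
        return np.array(vals)


def build_path(
    features: np.ndarray,
    schema: FeatureSchema | None = None,
    scaling: str = "none",
    scaler=None,
) -> PiecewisePath:
    """Embed a 27-vector of gait characteristics as a 2-D piecewise-linear path.

    Point j = (j/p, v_j), j = 1..p, where v_j is the (optionally z-scored)
    value of characteristic j; the index coordinate is normalised to (0, 1]
    so neither coordinate dominates by range alone.

    ``scaling='train_zscore'`` requires a fitted ``StandardizationParams``
    via ``scaler``; signatures are not scale-invariant and the
    characteristics carry heterogeneous units.
    """
    schema = schema or default_schema()
    values = np.asarray(features, dtype=float).ravel()
    if values.shape[0] != len(schema):
        raise ValueError(
            f"feature vector length {values.shape[0]} does not match schema length {len(schema)}"
        )
    if not np.isfinite(values).all():
        raise ValueError("feature values must be finite")
    if scaling == "train_zscore":
        if scaler is None:
            raise ValueError("scaling='train_zscore' requires fitted standardisation parameters")
        values = (values - scaler.mean) / scaler.sd
    elif scaling != "none":
        raise ValueError(f"unknown scaling mode: {scaling!r}")
    p = len(schema)
    index = np.arange(1, p + 1) / p
    return PiecewisePath(np.column_stack([index, values]))


def segment_signature(start: np.ndarray, end: np.ndarray, k: int) -> SignatureFeature:
    """Exact truncated signature of one straight segment.

    Term for word (i₁,…,i_m): (1/m!) ∏_j (end^{i_j} − start^{i_j}).
    """
    start = np.asarray(start, dtype=float).ravel()
    end = np.asarray(end, dtype=float).ravel()
    if start.shape != end.shape:
        raise ValueError("segment endpoints must have the same dimension")
    if k < 1:
        raise ValueError("truncation order must be >= 1")
    delta = end - start
    d = delta.shape[0]
    terms: dict[Word, float] = {(): 1.0}
    for word in signature_words(d, k):
        prod = 1.0
        for i in word:
            prod *= delta[i - 1]
        terms[word] = prod / math.factorial(len(word))
    return SignatureFeature(d, k, terms)


def chen_concatenate(a: SignatureFeature, b: SignatureFeature) -> SignatureFeature:
    """Signature of the concatenated path: truncated tensor product.

    Term for word w is Σ over splits w = u·v of a(u)·b(v), empty factors
    included (Chen's identity).
    """
    if a.dimension != b.dimension or a.order != b.order:
        raise ValueError("signatures must share dimension and truncation order")
    terms: dict[Word, float] = {(): 1.0}
    for word in signature_words(a.dimension, a.order):
        total = 0.0
        for cut in range(len(word) + 1):
            total += a[word[:cut]] * b[word[cut:]]
        terms[word] = total
    return SignatureFeature(a.dimension, a.order, terms)


def path_signature(path: PiecewisePath, k: int = 2) -> SignatureFeature:
    """Truncated signature of a piecewise-linear path.

    Left-fold of Chen concatenation over the exact per-segment signatures;
    default truncation order 2.
    """
    if k < 1:
        raise ValueError("truncation order must be >= 1")
    if k > 5 and path.dimension >= 2:
        warnings.warn(
            f"signature dimension grows as d^k: d={path.dimension}, k={k} gives "
            f"{signature_dimension(path.dimension, k)} terms",
            stacklevel=2,
        )
    sig = SignatureFeature(path.dimension, k, {(): 1.0})
    for j in range(path.n_segments):
        sig = chen_concatenate(sig, segment_signature(path.points[j], path.points[j + 1], k))
    return sig


def signature_oracle(path: PiecewisePath, k: int, steps: int = 10_000) -> SignatureFeature:
    """Brute-force signature by numeric iterated integration.

    Independent of the Chen/closed-form route: the path is finely sampled
    (segment vertices always included), and each term S^{w·i} = ∫ S^w dγ^i
    is accumulated bottom-up with the trapezoidal rule.  Converges to
    ``path_signature`` as steps grows; intended for testing only.
    """
    if steps < 10:
        raise ValueError("steps must be >= 10")
    per_seg = max(2, int(np.ceil(steps / path.n_segments)))
    chunks = []
    for j in range(path.n_segments):
        t = np.linspace(0.0, 1.0, per_seg + 1)[:-1, None]
        chunks.append(path.points[j] * (1 - t) + path.points[j + 1] * t)
    gamma = np.vstack(chunks + [path.points[-1:]])  # (n_samples, d)
    dg = np.diff(gamma, axis=0)

    d = path.dimension
    n = gamma.shape[0]
    level: dict[Word, np.ndarray] = {(): np.ones(n)}
    terms: dict[Word, float] = {(): 1.0}
    for m in range(1, k + 1):
        nxt: dict[Word, np.ndarray] = {}
        for word, f in level.items():
            mid = 0.5 * (f[:-1] + f[1:])
            for i in range(1, d + 1):
                g = np.empty(n)
                g[0] = 0.0
                g[1:] = np.cumsum(mid * dg[:, i - 1])
                nxt[word + (i,)] = g
        for word, g in nxt.items():
            terms[word] = float(g[-1])
        level = nxt
    return SignatureFeature(d, k, terms)


class SignatureTransform:
    """Per-subject signature feature extraction with train-only scaling.

    fit() estimates pooled per-feature z-score statistics on the training
    rows (when ``scaling='train_zscore'``); transform() embeds each
    subject's scaled characteristics as a 2-D path and returns the
    truncated signature terms (constant term excluded) in canonical word
    order.
    """

    def __init__(self, k: int = 2, scaling: str = "train_zscore"):
        if scaling not in ("none", "train_zscore"):
            raise ValueError(f"unknown scaling mode: {scaling!r}")
        self.k = k
        self.scaling = scaling
        self.scaler_ = None

    def fit(self, table: GaitFeatureTable) -> "SignatureTransform":
        if self.scaling == "train_zscore":
            from .preprocessing import fit_standardizer

            self.scaler_ = fit_standardizer(table, mode="pooled_train")
        return self

    @property
    def column_names(self) -> list[str]:
        return [word_label(w) for w in signature_words(2, self.k)]

    def transform(self, table: GaitFeatureTable) -> np.ndarray:
        if self.scaling == "train_zscore" and self.scaler_ is None:
            raise ValueError("transform called before fit in train_zscore mode")
        X = table.features
        out = np.empty((X.shape[0], signature_dimension(2, self.k)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(X.shape[0]):
                path = build_path(X[i], table.schema, scaling=self.scaling, scaler=self.scaler_)
                out[i] = path_signature(path, self.k).vector()
        return out


def signature_features(
    table: GaitFeatureTable,
    k: int = 2,
    scaling: str = "train_zscore",
    scaler=None,
) -> np.ndarray:
    """Signature feature matrix (one row per subject, constant term dropped).

    In ``train_zscore`` mode a fitted scaler must be supplied (or fit on
    this table first via :class:`SignatureTransform` for exploratory use).
    """
    t = SignatureTransform(k=k, scaling=scaling)
    if scaling == "train_zscore":
        if scaler is None:
            raise ValueError("signature_features requires a fitted scaler in train_zscore mode")
        t.scaler_ = scaler
    return t.transform(table)
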