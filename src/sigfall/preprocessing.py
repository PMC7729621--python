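"""Z-score standardisation and PCA with Kaiser component selection.

Both transforms are estimated on training rows only and frozen for test
rows.  Population (1/N) normalisation is used for the SD and the
covariance, so standardised training data has exactly unit variance and
the covariance of standardised data is the correlation matrix — the scale
on which the Kaiser "eigenvalue > 1" rule is meaningful.

A per-group standardisation mode ("per_group_literal": separate mean/SD
per label group) is retained purely for method-comparison studies; it
needs the label at transform time and must not be used for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import FALLER, NON_FALLER, GaitFeatureTable

__all__ = [
    "StandardizationParams",
    "fit_standardizer",
    "apply_standardizer",
    "PCAModel",
    "fit_pca",
    "select_components",
    "apply_pca",
]


@dataclass
class StandardizationParams:
    """Fitted per-feature location/scale; mode 'pooled_train' or 'per_group_literal'."""

    mean: np.ndarray
    sd: np.ndarray
    mode: str = "pooled_train"
    feature_names: tuple[str, ...] = ()
    group_stats: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def _moments(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return X.mean(axis=0), X.std(axis=0)  # population SD (ddof=0)


def fit_standardizer(table: GaitFeatureTable, mode: str = "pooled_train") -> StandardizationParams:
    """Estimate z-score statistics z = (x − x̄)/σ on a training table.

    'pooled_train' uses all training rows; 'per_group_literal' keeps
    separate statistics per label group (reproduction mode).  Constant
    (zero-variance) features are rejected by name.
    """
    if mode not in ("pooled_train", "per_group_literal"):
        raise ValueError(f"unknown standardisation mode: {mode!r}")
    X = table.features
    names = table.schema.names
    # exact constancy check; a constant column's SD may round to ~1e-16
    constant = np.ptp(X, axis=0) == 0

    def check(sd: np.ndarray, context: str) -> None:
        bad = [names[i] for i in np.flatnonzero(constant | (sd <= 0))]
        if bad:
            raise ValueError(f"zero-variance feature(s) {context}: {bad}")

    if mode == "pooled_train":
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        mean, sd = _moments(X)
        check(sd, "in training data")
        return StandardizationParams(mean, sd, mode, tuple(names))

    group_stats = {}
    for label in (NON_FALLER, FALLER):
        G = table.group(label)
        if G.shape[0] < 2:
            raise ValueError(f"need at least 2 training rows in group {label!r}")
        gm, gs = _moments(G)
        check(gs, f"in group {label!r}")
        group_stats[label] = (gm, gs)
    mean, sd = _moments(X)
    check(sd, "in training data")
    return StandardizationParams(mean, sd, mode, tuple(names), group_stats)


def apply_standardizer(params: StandardizationParams, table: GaitFeatureTable) -> np.ndarray:
    """Transform a table's features to z-scores with frozen parameters."""
    if params.feature_names and params.feature_names != table.schema.names:
        raise ValueError("table schema does not match the fitted standardiser")
    X = table.features
    if params.mode == "pooled_train":
        return (X - params.mean) / params.sd
    # reproduction mode: each row scaled by its own group's statistics
    Z = np.empty_like(X)
    labels = table.data["label"].to_numpy()
    for label, (gm, gs) in params.group_stats.items():
        mask = labels == label
        Z[mask] = (X[mask] - gm) / gs
    return Z


@dataclass
class PCAModel:
    """Eigendecomposition of the population covariance of standardised data.

    Columns of ``components`` are eigenvectors (descending eigenvalue);
    sign convention: the largest-magnitude loading of each component is
    positive; exact eigenvalue ties are ordered by the index of that
    loading.
    """

    center: np.ndarray
    components: np.ndarray  # (D, D), columns = eigenvectors
    eigenvalues: np.ndarray  # descending
    feature_names: tuple[str, ...] = ()

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def fit_pca(Z: np.ndarray, feature_names: tuple[str, ...] = ()) -> PCAModel:
    """Fit PCA on an already-standardised training matrix.

    Covariance uses the population (1/N) normalisation; eigenpairs are
    sorted by descending eigenvalue with deterministic tie-breaking and a
    fixed sign convention.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    center = Z.mean(axis=0)
    C = (Z - center).T @ (Z - center) / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(C)
    eigval = eigval[::-1].copy()
    eigvec = eigvec[:, ::-1].copy()
    # sign convention: largest-|loading| entry positive (first index on ties)
    lead = np.abs(eigvec).argmax(axis=0)
    signs = np.sign(eigvec[lead, np.arange(eigvec.shape[1])])
    signs[signs == 0] = 1.0
    eigvec = eigvec * signs
    # deterministic secondary sort for exactly-tied eigenvalues
    order = np.lexsort((lead, -eigval))
    return PCAModel(center, eigvec[:, order], eigval[order], tuple(feature_names))


def select_components(model: PCAModel, rule: str = "kaiser") -> int:
    """Number of components to retain.

    'kaiser': eigenvalues strictly greater than 1 (valid on standardised,
    unit-variance input); 'fixed:d': exactly d components.
    """
    if rule == "kaiser":
        return int((model.eigenvalues > 1.0).sum())
    if rule.startswith("fixed:"):
        d = int(rule.split(":", 1)[1])
        if not 1 <= d <= model.eigenvalues.shape[0]:
            raise ValueError(f"fixed component count {d} out of range 1..{model.eigenvalues.shape[0]}")
        return d
    raise ValueError(f"unknown selection rule: {rule!r}")


def apply_pca(model: PCAModel, Z: np.ndarray, d: int | None = None) -> np.ndarray:
    """Project standardised rows onto the first d components: y = Wᵀ(x − x̄)."""
    Z = np.asarray(Z, dtype=float)
    D = model.components.shape[0]
    if Z.ndim != 2 or Z.shape[1] != D:
        raise ValueError(f"expected {D} feature columns, got {Z.shape}")
    d = D if d is None else d
    if not 1 <= d <= D:
        raise ValueError(f"component count {d} out of range 1..{D}")
    return (Z - model.center) @ model.components[:, :d]
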