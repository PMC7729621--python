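"""Six-classifier evaluation harness with repeated stratified 70/30 splits.

The experiment object is built from a :class:`GaitFeatureTable`; ``fit()``
runs the full grid — six classifier families (LDA, logistic regression,
Gaussian naive Bayes, linear-kernel SVM, k-nearest neighbour, random
forest) × three pre-processing methods (z-score standardisation, PCA with
Kaiser selection, degree-2 path-signature features) — under the repeated
holdout protocol: for each repeat, a stratified 70/30 train/test split
drawn with that repeat's seed; every transform is fitted on the training
partition only and frozen for the test rows; metrics (accuracy,
sensitivity, specificity, precision, F1, AUC) are computed on the held-out
30%.  A 5-fold stratified CV reading of the protocol is available via
``protocol='kfold'``.

The faller group is the positive class: sensitivity is the fraction of
true fallers identified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .preprocessing import apply_pca, apply_standardizer, fit_pca, fit_standardizer, select_components
from .signature import SignatureTransform
from .table import GaitFeatureTable

__all__ = [
    "ModelSpec",
    "make_models",
    "confusion_metrics",
    "EvaluationConfig",
    "evaluate",
    "run_experiment",
    "FallClassificationExperiment",
    "ExperimentResults",
]

METHODS = ("zscore", "pca", "signature")
METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with an explicit, serialisable hyperparameter set."""

    name: str
    estimator: type
    hyperparameters: dict = field(default_factory=dict)
    seeded: bool = False  # whether the estimator takes random_state

    def build(self, random_state: int | None = None):
        params = dict(self.hyperparameters)
        if self.seeded:
            params["random_state"] = random_state
        return self.estimator(**params)


def make_models() -> list[ModelSpec]:
    """The six classifier families with pinned default hyperparameters."""
    return [
        ModelSpec("LDA", LinearDiscriminantAnalysis, {"solver": "svd"}),
        ModelSpec("LR", LogisticRegression, {"C": 1.0, "solver": "lbfgs", "max_iter": 1000}),
        ModelSpec("NB", GaussianNB, {}),
        ModelSpec("SVM-linear", SVC, {"kernel": "linear", "C": 1.0}),
        # vote/distance ties in KNN resolve to the class listed first
        # (non-faller) per scikit-learn's argmax convention; k=5 (odd)
        # precludes vote ties in the binary problem
        ModelSpec("KNN", KNeighborsClassifier, {"n_neighbors": 5, "weights": "uniform"}),
        ModelSpec("RF", RandomForestClassifier, {"n_estimators": 100}, seeded=True),
    ]


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """Binary metrics from a confusion matrix (positive class = 1 = faller).

    AUC is rank-based on ``scores`` (ties averaged) and reported as NaN
    when the truth contains a single class.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("truth and prediction lengths differ")
    if y_true.sum() == 0:
        raise ValueError("positive class absent from truth")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    prec = tp / (tp + fp) if (tp + fp) else math.nan
    f1 = (2 * prec * sens / (prec + sens)) if (tp + fp) and (prec + sens) > 0 else 0.0
    if scores is not None and len(set(y_true.tolist())) == 2:
        auc = float(roc_auc_score(y_true, scores))
    else:
        auc = math.nan
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "auc": auc,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


@dataclass(frozen=True)
class EvaluationConfig:
    """Repeated-split protocol configuration (defaults: 5 × stratified 70/30)."""

    n_repeats: int = 5
    test_fraction: float = 0.30
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    stratified: bool = True
    protocol: str = "repeated_holdout"  # or "kfold"
    signature_order: int = 2
    pca_rule: str = "kaiser"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need one seed per repeat")
        if len(set(self.seeds)) != self.n_repeats:
            raise ValueError("repeat seeds must be distinct")
        if self.protocol not in ("repeated_holdout", "kfold"):
            raise ValueError(f"unknown protocol: {self.protocol!r}")


def _splits(table: GaitFeatureTable, config: EvaluationConfig):
    """Yield (repeat_index, seed, train_idx, test_idx) pairs."""
    y = table.labels
    idx = np.arange(len(y))
    if config.protocol == "kfold":
        seed = config.seeds[0]
        cv = StratifiedKFold(n_splits=config.n_repeats, shuffle=True, random_state=seed)
        for r, (tr, te) in enumerate(cv.split(idx, y)):
            yield r, seed, tr, te
        return
    for r, seed in enumerate(config.seeds):
        for attempt in range(10):
            tr, te = train_test_split(
                idx,
                test_size=config.test_fraction,
                stratify=y if config.stratified else None,
                random_state=seed + attempt,
                shuffle=True,
            )
            if len(set(y[tr])) == 2:
                break
        else:
            raise RuntimeError(f"repeat {r}: could not draw a two-class training partition")
        yield r, seed, tr, te


def _subset(table: GaitFeatureTable, idx: np.ndarray) -> GaitFeatureTable:
    return GaitFeatureTable(table.data.iloc[idx].reset_index(drop=True), table.schema)


def _preprocess(
    method: str, train: GaitFeatureTable, test: GaitFeatureTable, config: EvaluationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the transform on the training partition only; apply to both."""
    if method == "zscore":
        params = fit_standardizer(train, mode="pooled_train")
        return apply_standardizer(params, train), apply_standardizer(params, test)
    if method == "pca":
        params = fit_standardizer(train, mode="pooled_train")
        z_train = apply_standardizer(params, train)
        z_test = apply_standardizer(params, test)
        model = fit_pca(z_train, train.schema.names)
        d = max(1, select_components(model, config.pca_rule))
        return apply_pca(model, z_train, d), apply_pca(model, z_test, d)
    if method == "signature":
        t = SignatureTransform(k=config.signature_order, scaling="train_zscore").fit(train)
        return t.transform(train), t.transform(test)
    raise ValueError(f"unknown pre-processing method: {method!r}")


def _model_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def evaluate(
    table: GaitFeatureTable,
    method: str,
    spec: ModelSpec,
    config: EvaluationConfig | None = None,
) -> pd.DataFrame:
    """Per-repeat metrics for one (pre-processing × model) cell."""
    config = config or EvaluationConfig()
    rows = []
    for r, seed, tr, te in _splits(table, config):
        X_tr, X_te = _preprocess(method, _subset(table, tr), _subset(table, te), config)
        y = table.labels
        model = spec.build(random_state=seed)
        model.fit(X_tr, y[tr])
        m = confusion_metrics(y[te], model.predict(X_te), _model_scores(model, X_te))
        rows.append({"method": method, "model": spec.name, "repeat": r, "seed": seed, **m})
    return pd.DataFrame(rows)


class FallClassificationExperiment:
    """Grid experiment: classifier families × pre-processing methods.

    Parameters
    ----------
    table
        Subject-level gait feature table with faller labels.
    methods
        Pre-processing methods to compare (subset of zscore, pca, signature).
    models
        Classifier specifications; defaults to the six standard families.
    config
        Split protocol; defaults to 5 stratified 70/30 repeats.
    """

    def __init__(
        self,
        table: GaitFeatureTable,
        methods: tuple[str, ...] = METHODS,
        models: list[ModelSpec] | None = None,
        config: EvaluationConfig | None = None,
    ):
        unknown = set(methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if len(set(table.labels)) < 2:
            raise ValueError("both classes must be present")
        self.table = table
        self.methods = tuple(methods)
        self.models = models if models is not None else make_models()
        self.config = config or EvaluationConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, schema=None, **kwargs) -> "FallClassificationExperiment":
        from .schema import default_schema

        return cls(GaitFeatureTable(frame, schema or default_schema()), **kwargs)

    def fit(self) -> "ExperimentResults":
        """Run the full grid; transforms are shared across models per split."""
        y = self.table.labels
        rows = []
        for r, seed, tr, te in _splits(self.table, self.config):
            train, test = _subset(self.table, tr), _subset(self.table, te)
            for method in self.methods:
                X_tr, X_te = _preprocess(method, train, test, self.config)
                for spec in self.models:
                    model = spec.build(random_state=seed)
                    model.fit(X_tr, y[tr])
                    m = confusion_metrics(y[te], model.predict(X_te), _model_scores(model, X_te))
                    rows.append(
                        {"method": method, "model": spec.name, "repeat": r, "seed": seed, **m}
                    )
        return ExperimentResults(pd.DataFrame(rows), self)


@dataclass
class ExperimentResults:
    """Per-repeat metrics plus grid aggregation and a formatted summary."""

    per_repeat: pd.DataFrame
    experiment: FallClassificationExperiment

    @property
    def grid(self) -> pd.DataFrame:
        """Mean metrics per (model × method) cell over repeats."""
        agg = (
            self.per_repeat.groupby(["model", "method"], sort=False)[list(METRICS)]
            .mean()
            .reset_index()
        )
        return agg

    def cell(self, model: str, method: str) -> pd.Series:
        g = self.grid
        row = g[(g["model"] == model) & (g["method"] == method)]
        if row.empty:
            raise KeyError(f"no cell ({model!r}, {method!r})")
        return row.iloc[0]

    def summary(self) -> str:
        """Text grid in 'accuracy (sensitivity, specificity) %' layout."""
        g = self.grid
        methods = list(self.experiment.methods)
        model_names = [s.name for s in self.experiment.models]
        header = ["Model".ljust(14)] + [m.ljust(22) for m in methods]
        lines = ["  ".join(header).rstrip(), "-" * (16 + 24 * len(methods))]
        for name in model_names:
            cells = []
            for method in methods:
                row = g[(g["model"] == name) & (g["method"] == method)]
                if row.empty:
                    cells.append("-".ljust(22))
                    continue
                r = row.iloc[0]
                cells.append(
                    f"{100 * r['accuracy']:5.2f} ({100 * r['sensitivity']:.0f}, {100 * r['specificity']:.0f})".ljust(22)
                )
            lines.append("  ".join([name.ljust(14)] + cells).rstrip())
        cfg = self.experiment.config
        lines.append("")
        lines.append(
            f"Protocol: {cfg.protocol}, {cfg.n_repeats} repeats, "
            f"test fraction {cfg.test_fraction:.2f}, seeds {list(cfg.seeds)}; "
            "positive class = faller; cells are mean accuracy % "
            "(mean sensitivity %, mean specificity %) over repeats."
        )
        return "\n".join(lines)


def run_experiment(
    table: GaitFeatureTable,
    config: EvaluationConfig | None = None,
    methods: tuple[str, ...] = METHODS,
    models: list[ModelSpec] | None = None,
) -> ExperimentResults:
    """Functional wrapper over :class:`FallClassificationExperiment`."""
    return FallClassificationExperiment(table, methods=methods, models=models, config=config).fit()
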