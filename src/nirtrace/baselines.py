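"""The classical machine-learning baselines: PLS-DA, PCA+LDA, SVM, RF, BPNN.

Each is tuned the way chemometric studies tune them: PLS-DA and LDA pick
their component count by stratified 10-fold CV accuracy; SVM and RF run an
exhaustive grid search; the BPNN is a modest single-hidden-layer perceptron
trained by backpropagation.  Everything behind :func:`fit_baseline` is a
scikit-learn estimator except PLS-DA, which is this package's own NIPALS
implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import SpectraError
from .plsda import PLSDA

BASELINE_KINDS = ("plsda", "lda", "svm", "rf", "bpnn")

#: Default hyperparameter grids.  The tuned knobs follow standard practice
#: for each model family; candidate values are config-overridable.
DEFAULT_GRIDS = {
    "plsda": {"n_components": list(range(1, 21))},
    "lda": {"n_pcs": [5, 10, 15, 20, 30, 40]},
    "svm": {
        "kernel": ["linear", "rbf"],
        "C": [0.1, 1, 10, 100],
        "gamma": ["scale", 0.001, 0.01, 0.1],
    },
    "rf": {
        "n_estimators": [100, 300, 500],
        "max_depth": [None, 10, 30],
        "min_samples_split": [2, 5],
        "min_samples_leaf": [1, 2],
        "max_features": ["sqrt", None],
    },
    "bpnn": {"hidden_sizes": [(64,)], "learning_rate": [0.001], "epochs": [500]},
}

#: Compact grids for desk-scale comparison runs: the same tuned knobs,
#: fewer candidates, so a full model comparison finishes in minutes.
COMPACT_GRIDS = {
    "plsda": {"n_components": list(range(1, 21))},
    "lda": {"n_pcs": [5, 10, 15, 20, 30]},
    "svm": {"kernel": ["linear", "rbf"], "C": [1, 10, 100], "gamma": ["scale", 0.01]},
    "rf": {
        "n_estimators": [200], "max_depth": [None, 20], "min_samples_split": [2],
        "min_samples_leaf": [1], "max_features": ["sqrt"],
    },
    "bpnn": {"hidden_sizes": [(64,)], "learning_rate": [0.001], "epochs": [500]},
}

_GRID_KEYS = {k: set(v) for k, v in DEFAULT_GRIDS.items()}


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to fit and how to tune it."""

    kind: str
    grid: dict | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.kind not in BASELINE_KINDS:
            raise SpectraError(f"unknown baseline kind {self.kind!r}")
        if self.grid is not None:
            if not self.grid:
                raise SpectraError("empty hyperparameter grid")
            extra = set(self.grid) - _GRID_KEYS[self.kind]
            if extra:
                raise SpectraError(
                    f"grid keys {sorted(extra)} are not valid for {self.kind!r}"
                )

    @property
    def resolved_grid(self) -> dict:
        return dict(self.grid) if self.grid is not None else dict(DEFAULT_GRIDS[self.kind])

    @property
    def n_combinations(self) -> int:
        g = self.resolved_grid
        out = 1
        for values in g.values():
            out *= len(values)
        return out


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    estimator: object              # anything with .predict(X)
    best_params: dict
    cv_accuracy: float

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))


class _PLSDAEstimator:
    """Thin sklearn-style adaptor around the package's PLS-DA."""

    def __init__(self, n_components=None, max_components=20, cv_folds=10, seed=0):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, y):
        self.results_ = PLSDA(X, y).fit(
            n_components=self.n_components,
            max_components=self.max_components,
            cv_folds=self.cv_folds,
            seed=self.seed,
        )
        return self

    def predict(self, X):
        return self.results_.predict(X)

    def get_params(self, deep=True):
        return {
            "n_components": self.n_components,
            "max_components": self.max_components,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def _fit_plsda(spec: BaselineSpec, X, y) -> FittedBaseline:
    grid = spec.resolved_grid
    max_comp = max(grid["n_components"])
    est = _PLSDAEstimator(
        n_components=None, max_components=max_comp,
        cv_folds=spec.cv_folds, seed=spec.seed,
    ).fit(X, y)
    res = est.results_
    return FittedBaseline(
        spec=spec,
        estimator=est,
        best_params={"n_components": res.n_components},
        cv_accuracy=float(res.cv_accuracy),
    )


def _fit_lda(spec: BaselineSpec, X, y) -> FittedBaseline:
    grid = spec.resolved_grid
    cap = min(X.shape[0] - 2, X.shape[1])
    candidates = [p for p in grid["n_pcs"] if p <= cap] or [min(5, cap)]
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    best = None
    for n_pcs in candidates:
        pipe = Pipeline(
            [("pca", PCA(n_components=n_pcs, svd_solver="full")),
             ("lda", LinearDiscriminantAnalysis())]
        )
        acc = cross_val_score(pipe, X, y, cv=skf).mean()
        if best is None or acc > best[1] + 1e-12:
            best = (n_pcs, acc)
    n_pcs, cv_acc = best
    pipe = Pipeline(
        [("pca", PCA(n_components=n_pcs, svd_solver="full")),
         ("lda", LinearDiscriminantAnalysis())]
    ).fit(X, y)
    return FittedBaseline(spec, pipe, {"n_pcs": n_pcs}, float(cv_acc))


def _fit_grid_search(spec: BaselineSpec, X, y, estimator, param_grid) -> FittedBaseline:
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(estimator, param_grid, cv=skf, scoring="accuracy", n_jobs=1)
    search.fit(X, y)
    # keep the whole search: predict() delegates to the refit best estimator
    # and cv_results_ documents the exhaustive exploration
    return FittedBaseline(
        spec, search, dict(search.best_params_), float(search.best_score_)
    )


def _fit_bpnn(spec: BaselineSpec, X, y) -> FittedBaseline:
    grid = spec.resolved_grid
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    best = None
    for hidden, lr, epochs in itertools.product(
        grid["hidden_sizes"], grid["learning_rate"], grid["epochs"]
    ):
        pipe = Pipeline(
            [("scale", StandardScaler()),
             ("mlp", MLPClassifier(
                 hidden_layer_sizes=tuple(hidden), learning_rate_init=lr,
                 max_iter=epochs, random_state=spec.seed))]
        )
        acc = cross_val_score(pipe, X, y, cv=skf).mean()
        params = {"hidden_sizes": tuple(hidden), "learning_rate": lr, "epochs": epochs}
        if best is None or acc > best[1] + 1e-12:
            best = (params, acc)
    params, cv_acc = best
    pipe = Pipeline(
        [("scale", StandardScaler()),
         ("mlp", MLPClassifier(
             hidden_layer_sizes=params["hidden_sizes"],
             learning_rate_init=params["learning_rate"],
             max_iter=params["epochs"], random_state=spec.seed))]
    ).fit(X, y)
    return FittedBaseline(spec, pipe, params, float(cv_acc))


def fit_baseline(spec: BaselineSpec, X, y) -> FittedBaseline:
    """Fit one tuned baseline; returns the model, chosen hyperparameters,
    and its cross-validation accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if spec.kind == "plsda":
        return _fit_plsda(spec, X, y)
    if spec.kind == "lda":
        return _fit_lda(spec, X, y)
    if spec.kind == "svm":
        return _fit_grid_search(
            spec, X, y, SVC(random_state=spec.seed), spec.resolved_grid
        )
    if spec.kind == "rf":
        return _fit_grid_search(
            spec, X, y, RandomForestClassifier(random_state=spec.seed),
            spec.resolved_grid,
        )
    return _fit_bpnn(spec, X, y)
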