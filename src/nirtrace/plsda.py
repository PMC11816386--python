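"""Partial least squares discriminant analysis (PLS-DA).

PLS-DA regresses a one-hot class indicator matrix Y on the spectra X by
NIPALS PLS2: successive latent variables t_a = X w_a are extracted to
maximize covariance with Y, X and Y are deflated, and the accumulated
regression coefficients B = W (P'W)^-1 Q' map centered spectra to K
continuous class scores.  Classification is argmax over the K scores (ties
break toward the lower class index).

The number of latent variables is the model's one real hyperparameter; it
is chosen as the smallest count attaining the maximal stratified k-fold
cross-validation accuracy, as is standard in chemometric model selection.

The public surface is both functional (``fit_pls`` / ``plsda_predict`` /
``select_components_cv``) and object-based (``PLSDA(X, y).fit()`` returning
a :class:`PLSDAResults` with a ``summary()`` table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataset import SpectraError


def one_hot(y: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    K = int(y.max()) + 1 if n_classes is None else n_classes
    Y = np.zeros((y.size, K))
    Y[np.arange(y.size), y] = 1.0
    return Y


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS2 state mapping spectra to K class scores."""

    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray       # W, p x a
    x_loadings: np.ndarray    # P, p x a
    y_loadings: np.ndarray    # Q, K x a
    scores: np.ndarray        # T, n x a (training latent variables)
    coefficients: np.ndarray  # B = W (P'W)^-1 Q', p x K
    n_classes: int


def _nipals_pls2(X0: np.ndarray, Y0: np.ndarray, n_components: int,
                 tol: float = 1e-10, max_iter: int = 500):
    """Classical NIPALS PLS2 on pre-centered X0, Y0."""
    n, p = X0.shape
    K = Y0.shape[1]
    X, Y = X0.copy(), Y0.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((K, n_components))
    T = np.zeros((n, n_components))
    for a in range(n_components):
        u = Y[:, np.argmax(Y.var(axis=0))]
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm < 1e-300:
                raise SpectraError("PLS weight collapsed: zero-variance X block")
            w /= norm
            t = X @ w
            q = Y.T @ t / (t @ t)
            qn = np.linalg.norm(q)
            u = Y @ q / (q @ q) if qn > 0 else t
            if np.linalg.norm(t - t_old) < tol * max(1.0, np.linalg.norm(t)):
                break
            t_old = t
        tt = t @ t
        if tt < 1e-300:
            raise SpectraError("degenerate PLS score; reduce n_components")
        p_load = X.T @ t / tt
        q_load = Y.T @ t / tt
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, q_load)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q_load, t
    return W, P, Q, T


def _coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, Q.T)


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSDAModel:
    """Fit PLS2 of one-hot Y on spectra X with the given component count."""
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        raise SpectraError("X and Y row counts differ")
    if n_components < 1 or n_components > min(X.shape[0] - 1, X.shape[1]):
        raise SpectraError(
            f"n_components must lie in [1, {min(X.shape[0] - 1, X.shape[1])}]"
        )
    if np.allclose(X.var(axis=0), 0):
        raise SpectraError("X has zero variance everywhere")
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    W, P, Q, T = _nipals_pls2(X - x_mean, Y - y_mean, n_components)
    return PLSDAModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coefficients=_coefficients(W, P, Q),
        n_classes=Y.shape[1],
    )


def plsda_predict(model: PLSDAModel, X: np.ndarray):
    """Predict (labels, continuous K-column score matrix)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise SpectraError(
            f"expected {model.x_mean.size} wavenumbers, got {X.shape[1]}"
        )
    scores = (X - model.x_mean) @ model.coefficients + model.y_mean
    return scores.argmax(axis=1), scores


def select_components_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    folds: int = 10,
    seed: int = 0,
):
    """Choose the PLS component count by stratified k-fold CV accuracy.

    Returns ``(chosen, curve)`` where ``curve[a-1]`` is the CV accuracy with
    ``a`` components and ``chosen`` is the smallest count attaining the
    maximum.  One NIPALS fit per fold at ``max_components`` supplies every
    truncated model (the factors are nested).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    max_components = min(max_components, X.shape[0] - 2, X.shape[1])
    if max_components < 1:
        raise SpectraError("too few samples for component selection")
    K = int(y.max()) + 1
    hits = np.zeros(max_components)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        x_mean = X[tr].mean(axis=0)
        Y = one_hot(y[tr], K)
        y_mean = Y.mean(axis=0)
        W, P, Q, _ = _nipals_pls2(X[tr] - x_mean, Y - y_mean, max_components)
        Xc = X[te] - x_mean
        for a in range(1, max_components + 1):
            B = _coefficients(W[:, :a], P[:, :a], Q[:, :a])
            pred = (Xc @ B + y_mean).argmax(axis=1)
            hits[a - 1] += (pred == y[te]).sum()
    curve = hits / y.size
    chosen = int(np.argmax(curve)) + 1  # argmax -> smallest maximizer
    return chosen, curve


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class PLSDA:
    """PLS-DA classifier over spectra, statsmodels-style.

    Parameters
    ----------
    X : ndarray (n, p)
        Preprocessed absorbance matrix.
    y : ndarray (n,)
        Integer class labels in {0..K-1}.
    """

    def __init__(self, X, y, n_classes: int | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.n_classes = int(self.y.max()) + 1 if n_classes is None else n_classes

    def fit(self, n_components: int | None = None, max_components: int = 20,
            cv_folds: int = 10, seed: int = 0) -> "PLSDAResults":
        """Fit; when ``n_components`` is None it is chosen by k-fold CV."""
        curve = None
        if n_components is None:
            n_components, curve = select_components_cv(
                self.X, self.y, max_components=max_components,
                folds=cv_folds, seed=seed,
            )
        model = fit_pls(self.X, one_hot(self.y, self.n_classes), n_components)
        return PLSDAResults(self, model, cv_curve=curve)


@dataclass
class PLSDAResults:
    model_input: PLSDA
    model: PLSDAModel
    cv_curve: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.model.n_components

    @property
    def cv_accuracy(self) -> float | None:
        if self.cv_curve is None:
            return None
        return float(self.cv_curve[self.n_components - 1])

    def predict(self, X) -> np.ndarray:
        return plsda_predict(self.model, X)[0]

    def decision_scores(self, X) -> np.ndarray:
        return plsda_predict(self.model, X)[1]

    @property
    def training_accuracy(self) -> float:
        pred = self.predict(self.model_input.X)
        return float((pred == self.model_input.y).mean())

    def summary(self) -> str:
        lines = [
            "PLS-DA (NIPALS PLS2 on one-hot classes)",
            "=" * 44,
            f"n samples            {self.model_input.X.shape[0]:>10}",
            f"n wavenumbers        {self.model_input.X.shape[1]:>10}",
            f"n classes            {self.model.n_classes:>10}",
            f"latent variables     {self.n_components:>10}",
            f"training accuracy    {100 * self.training_accuracy:>9.2f}%",
        ]
        if self.cv_accuracy is not None:
            lines.append(f"CV accuracy          {100 * self.cv_accuracy:>9.2f}%")
        return "\n".join(lines)
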