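"""Wavelength (variable) selection for spectral classification.

Five selectors, each a pure function of (X, y, config, seed) returning a
:class:`WavelengthSubset`:

- LAR   — least angle regression entry order against the one-hot classes,
          prefix length chosen by PLS-DA cross-validation accuracy;
- CARS  — competitive adaptive reweighted sampling: Monte-Carlo PLS runs
          with an exponentially decreasing retained-variable schedule,
          winner = minimal RMSECV;
- UVE   — uninformative variable elimination: keep variables whose PLS
          coefficient stability beats the best appended noise column;
- SPA   — successive projections: greedy maximal orthogonal component,
          chains scored by the RMSECV of a multiple linear fit;
- GA    — genetic algorithm over binary chromosomes, fitness = CV accuracy
          of PLS-DA minus a sparsity penalty.

Regression-based selectors code the classes as a one-hot matrix and average
RMSECV over its columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lars_path
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import SpectraSet, SpectraError
from .plsda import fit_pls, one_hot, plsda_predict

METHODS = ("LAR", "CARS", "UVE", "SPA", "GA", "None")


@dataclass
class WavelengthSubset:
    indices: np.ndarray          # ordered, distinct column indices
    method: str
    trace: dict = field(default_factory=dict)
    selection_seed: int = 0

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.method not in METHODS:
            raise SpectraError(f"unknown selection method {self.method!r}")
        if np.unique(self.indices).size != self.indices.size:
            raise SpectraError("subset indices must be distinct")

    @property
    def n_selected(self) -> int:
        return self.indices.size


def full_subset(p: int) -> WavelengthSubset:
    """The no-selection subset: all columns."""
    return WavelengthSubset(np.arange(p), "None")


def apply_subset(spectra: SpectraSet, subset: WavelengthSubset) -> SpectraSet:
    if subset.method == "None":
        return spectra
    return spectra.select_columns(subset.indices)


# ---------------------------------------------------------------------------
# Shared scoring helpers
# ---------------------------------------------------------------------------

def _pls_components(n: int, p: int, cap: int = 10) -> int:
    return max(1, min(cap, n - 2, p))

def _rmsecv(X, Y, folds=5, seed=0, max_components=10):
    """K-fold RMSE of the PLS2 fit of one-hot Y, averaged over columns."""
    n, p = X.shape
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse, count = 0.0, 0
    for tr, te in kf.split(X):
        a = _pls_components(tr.size, p, max_components)
        model = fit_pls(X[tr], Y[tr], a)
        _, pred = plsda_predict(model, X[te])
        sse += ((pred - Y[te]) ** 2).sum()
        count += Y[te].size
    return float(np.sqrt(sse / count))


def _cv_accuracy(X, y, folds=5, seed=0, max_components=10):
    """Stratified K-fold classification accuracy of a PLS-DA fit."""
    n, p = X.shape
    K = int(y.max()) + 1
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    hits = 0
    for tr, te in skf.split(X, y):
        a = _pls_components(tr.size, p, max_components)
        model = fit_pls(X[tr], one_hot(y[tr], K), a)
        pred, _ = plsda_predict(model, X[te])
        hits += int((pred == y[te]).sum())
    return hits / y.size


def _coefficient_weights(X, Y, max_components=10):
    """Per-variable importance: L2 norm of PLS coefficients over classes."""
    a = _pls_components(X.shape[0], X.shape[1], max_components)
    model = fit_pls(X, Y, a)
    return np.linalg.norm(model.coefficients, axis=1)


def _prefix_ladder(p: int, max_vars: int) -> list[int]:
    sizes = np.unique(np.geomspace(2, min(max_vars, p), num=12).round().astype(int))
    return [int(s) for s in sizes]


# ---------------------------------------------------------------------------
# LAR
# ---------------------------------------------------------------------------

def select_lar(X, y, max_vars: int | None = None, folds: int = 5,
               seed: int = 0) -> WavelengthSubset:
    """Rank variables by least-angle entry order; keep the best CV prefix.

    The least-angle path is run against each one-hot class column; a
    variable's rank is its earliest entry position across columns (ties:
    lower column, then lower index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if np.allclose(np.asarray(y, float).var(), 0):
        raise SpectraError("constant response: nothing to regress on")
    max_vars = p if max_vars is None else min(max_vars, p)
    Y = one_hot(y)
    entry_step = np.full(p, np.inf)
    for k in range(Y.shape[1]):
        _, active, _ = lars_path(X, Y[:, k], method="lar", max_iter=max_vars)
        for pos, j in enumerate(active):
            entry_step[j] = min(entry_step[j], pos + k / (Y.shape[1] + 1.0))
    order = np.argsort(entry_step, kind="stable")
    entered = order[np.isfinite(entry_step[order])][:max_vars]
    if entered.size == 0:
        raise SpectraError("least-angle path selected no variables")

    ladder = [s for s in _prefix_ladder(p, entered.size)]
    accs = [_cv_accuracy(X[:, entered[:s]], y, folds=folds, seed=seed) for s in ladder]
    best = ladder[int(np.argmax(accs))]
    return WavelengthSubset(
        entered[:best], "LAR",
        trace={"entry_order": entered, "prefix_sizes": ladder, "prefix_cv_accuracy": accs},
        selection_seed=seed,
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def select_cars(X, y, n_runs: int = 50, folds: int = 5, seed: int = 0,
                subsample: float = 0.8, max_components: int = 10) -> WavelengthSubset:
    """Competitive adaptive reweighted sampling.

    Run i keeps the top fraction r_i = a*exp(-k*i) of variables by PLS
    coefficient magnitude (exponentially decreasing from all of them to
    2/p), then resamples within them with probability proportional to the
    magnitudes; the run with minimal RMSECV wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if n_runs < 2:
        raise SpectraError("CARS needs at least 2 runs")
    Y = one_hot(y)
    rng = np.random.default_rng(seed)
    # exponentially decreasing fraction: r_1 = 1, r_{n_runs} = 2/p
    k = np.log(p / 2.0) / (n_runs - 1)
    a = np.exp(k)
    retained = np.arange(p)
    best = (np.inf, retained, -1)
    trace_rows = []
    for i in range(1, n_runs + 1):
        rows = rng.choice(n, size=max(2, int(round(subsample * n))), replace=False)
        weights = np.zeros(p)
        weights[retained] = _coefficient_weights(
            X[np.ix_(rows, retained)], Y[rows], max_components
        )
        n_keep = min(retained.size, max(2, int(round(a * np.exp(-k * i) * p))))
        top = retained[np.argsort(-weights[retained], kind="stable")[:n_keep]]
        # adaptive reweighted sampling within the EDF survivors: heavily
        # weighted variables almost surely survive, low-weight ones may
        # drop out; 5x draws keep the survivor count near the schedule
        w = weights[top]
        probs = w / w.sum() if w.sum() > 0 else np.full(top.size, 1.0 / top.size)
        retained = np.unique(rng.choice(top, size=5 * n_keep, replace=True, p=probs))
        rmsecv = _rmsecv(X[:, retained], Y, folds=folds, seed=seed,
                         max_components=max_components)
        trace_rows.append({"run": i, "n_retained": retained.size, "rmsecv": rmsecv})
        if rmsecv < best[0]:
            best = (rmsecv, retained.copy(), i)
    return WavelengthSubset(
        np.sort(best[1]), "CARS",
        trace={"runs": trace_rows, "best_run": best[2], "best_rmsecv": best[0]},
        selection_seed=seed,
    )


# ---------------------------------------------------------------------------
# UVE
# ---------------------------------------------------------------------------

def select_uve(X, y, n_noise: int | None = None, folds: int = 10,
               seed: int = 0, max_components: int = 10) -> WavelengthSubset:
    """Uninformative variable elimination with appended noise columns.

    Stability c_j = mean(b_j)/sd(b_j) of the per-fold PLS coefficients
    (maximum magnitude over the class columns); the cutoff is the largest
    |c| among the appended noise columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    n_noise = p if n_noise is None else n_noise
    rng = np.random.default_rng(seed)
    Xa = np.hstack([X, rng.uniform(0.0, 1.0, size=(n, n_noise))])
    Y = one_hot(y)
    K = Y.shape[1]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    coefs = np.zeros((folds, p + n_noise, K))
    for f, (tr, _) in enumerate(kf.split(Xa)):
        a = _pls_components(tr.size, p + n_noise, max_components)
        coefs[f] = fit_pls(Xa[tr], Y[tr], a).coefficients
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stab = np.where(sd > 0, np.abs(mean) / sd, 0.0)
    if np.any(sd == 0):
        warnings.warn("zero coefficient spread for some variables; stability set to 0")
    c = stab.max(axis=1)  # per-variable stability over class columns
    cutoff = float(c[p:].max())
    keep = np.where(c[:p] > cutoff)[0]
    return WavelengthSubset(
        keep, "UVE",
        trace={"stability": c[:p], "noise_stability": c[p:], "cutoff": cutoff},
        selection_seed=seed,
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def _spa_chain(Xn, start: int, max_vars: int) -> list[int]:
    """Greedy orthogonal-projection chain from one start column."""
    n, p = Xn.shape
    proj = Xn.copy()
    chain = [start]
    for _ in range(max_vars - 1):
        v = proj[:, chain[-1]].copy()
        nv = v @ v
        if nv < 1e-12:
            break
        proj = proj - np.outer(v, v @ proj) / nv
        norms = np.einsum("ij,ij->j", proj, proj)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < 1e-10:
            warnings.warn("SPA stopped early: remaining columns are rank-deficient")
            break
        chain.append(j)
    return chain


def _mlr_rmsecv(X, Y, folds=5, seed=0):
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse, count = 0.0, 0
    for tr, te in kf.split(X):
        A = np.hstack([np.ones((tr.size, 1)), X[tr]])
        B, *_ = np.linalg.lstsq(A, Y[tr], rcond=None)
        pred = np.hstack([np.ones((te.size, 1)), X[te]]) @ B
        sse += ((pred - Y[te]) ** 2).sum()
        count += Y[te].size
    return float(np.sqrt(sse / count))


def select_spa(X, y, max_vars: int = 25, folds: int = 5, seed: int = 0,
               starts=None) -> WavelengthSubset:
    """Successive projections algorithm.

    From each candidate start column, grow a chain by repeatedly adding the
    column with the largest component orthogonal to the span of the chain;
    chains are scored by the RMSECV of an intercepted multiple linear fit
    of the one-hot classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if max_vars > min(n - 1, p):
        raise SpectraError("max_vars exceeds min(n-1, p)")
    Y = one_hot(y)
    Xc = X - X.mean(axis=0)
    starts = range(p) if starts is None else starts
    best = (np.inf, None, None)
    scores = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficiency warnings per chain
        for s in starts:
            chain = _spa_chain(Xc, s, max_vars)
            score = _mlr_rmsecv(X[:, chain], Y, folds=folds, seed=seed)
            scores[s] = score
            if score < best[0]:
                best = (score, chain, s)
    return WavelengthSubset(
        np.asarray(best[1]), "SPA",
        trace={"chain_scores": scores, "best_start": best[2], "best_rmsecv": best[0]},
        selection_seed=seed,
    )


# ---------------------------------------------------------------------------
# GA
# ---------------------------------------------------------------------------

def select_ga(X, y, pop_size: int = 64, n_generations: int = 30,
              crossover_rate: float = 0.8, mutation_rate: float | None = None,
              folds: int = 5, seed: int = 0, sparsity_penalty: float = 0.1,
              init_fraction: float = 0.1, tournament: int = 3,
              max_components: int = 5) -> WavelengthSubset:
    """Genetic algorithm over binary wavelength masks.

    Fitness = stratified CV accuracy of a PLS-DA fit on the active columns
    minus ``sparsity_penalty * active_fraction``; tournament selection,
    one-point crossover, bit-flip mutation (default rate 1/p), elitism of 1.
    An all-zero chromosome gets fitness -inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if pop_size % 2:
        raise SpectraError("pop_size must be even")
    mutation_rate = 1.0 / p if mutation_rate is None else mutation_rate
    if not (0 < crossover_rate < 1 and 0 < mutation_rate < 1):
        raise SpectraError("crossover and mutation rates must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    pop = rng.random((pop_size, p)) < init_fraction
    for chrom in pop:  # guarantee a live gene per chromosome
        if not chrom.any():
            chrom[rng.integers(p)] = True

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        if not chrom.any():
            return -np.inf
        key = chrom.tobytes()
        if key not in cache:
            active = np.where(chrom)[0]
            acc = _cv_accuracy(X[:, active], y, folds=folds, seed=seed,
                               max_components=max_components)
            cache[key] = acc - sparsity_penalty * active.size / p
        return cache[key]

    fits = np.array([fitness(c) for c in pop])
    best_per_gen = [float(fits.max())]
    for _ in range(n_generations):
        elite = pop[int(np.argmax(fits))].copy()
        children = [elite]
        while len(children) < pop_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(pop_size, size=tournament)
                parents.append(pop[contenders[np.argmax(fits[contenders])]].copy())
            if rng.random() < crossover_rate:
                cut = rng.integers(1, p)
                parents[0][cut:], parents[1][cut:] = (
                    parents[1][cut:].copy(), parents[0][cut:].copy(),
                )
            for child in parents:
                flip = rng.random(p) < mutation_rate
                child ^= flip
                if len(children) < pop_size:
                    children.append(child)
        pop = np.array(children)
        fits = np.array([fitness(c) for c in pop])
        best_per_gen.append(float(fits.max()))
    winner = pop[int(np.argmax(fits))]
    return WavelengthSubset(
        np.where(winner)[0], "GA",
        trace={"best_fitness_per_generation": best_per_gen},
        selection_seed=seed,
    )


SELECTORS = {
    "lar": select_lar,
    "cars": select_cars,
    "uve": select_uve,
    "spa": select_spa,
    "ga": select_ga,
}
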