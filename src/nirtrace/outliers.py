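"""Abnormal-sample screening by Mahalanobis distance in PCA score space.

Raw spectra are ~1500-dimensional while a study has only a few hundred
samples, so the sample covariance of the full spectra is singular.  The
screen therefore projects onto the leading principal components (enough to
cover 99% of variance, capped at 10) and computes each sample's Mahalanobis
distance from the multivariate mean of the scores; samples beyond
``mean + k * sd`` of the distance distribution are removed in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .dataset import SpectraSet, SpectraError


@dataclass
class OutlierReport:
    distances: np.ndarray
    threshold: float
    removed_ids: list
    kept_ids: list
    n_components: int
    variance_explained: float


def pca_scores(absorbance: np.ndarray, n_components: int):
    """Mean-centered PCA: returns (scores, loadings, variance fractions)."""
    X = np.asarray(absorbance, dtype=float)
    cap = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= cap:
        raise SpectraError(
            f"n_components must lie in [1, {cap}] for a {X.shape} matrix"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.components_, pca.explained_variance_ratio_


def mahalanobis_distances(scores: np.ndarray) -> np.ndarray:
    """d_i = sqrt((s_i - mu)^T Sigma^-1 (s_i - mu)) over the score rows."""
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    n, k = S.shape
    if n <= k:
        raise SpectraError("need more samples than score dimensions")
    centered = S - S.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    try:
        solved = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError as exc:
        raise SpectraError(
            "singular score covariance; reduce the number of PCA components"
        ) from exc
    return np.sqrt(np.einsum("ij,ji->i", centered, solved))


def remove_outliers(
    spectra: SpectraSet,
    threshold_sds: float = 3.0,
    variance_target: float = 0.99,
    max_components: int = 10,
) -> tuple[SpectraSet, OutlierReport]:
    """One-pass removal of samples whose distance exceeds mean + k*sd.

    Components are the smallest count covering ``variance_target`` of the
    variance, capped at ``max_components``.
    """
    if spectra.n_samples < 10:
        raise SpectraError("outlier screening needs at least 10 samples")
    cap = min(max_components, spectra.n_samples - 1, spectra.n_wavenumbers)
    scores, _, var_frac = pca_scores(spectra.absorbance, cap)
    cum = np.cumsum(var_frac)
    n_comp = int(np.searchsorted(cum, variance_target) + 1)
    n_comp = min(n_comp, cap)
    d = mahalanobis_distances(scores[:, :n_comp])
    threshold = float(d.mean() + threshold_sds * d.std())
    keep = d <= threshold
    if not keep.any():
        raise SpectraError("degenerate threshold: every sample flagged")
    report = OutlierReport(
        distances=d,
        threshold=threshold,
        removed_ids=list(spectra.sample_ids[~keep]),
        kept_ids=list(spectra.sample_ids[keep]),
        n_components=n_comp,
        variance_explained=float(cum[n_comp - 1]),
    )
    return spectra.take(np.where(keep)[0]), report
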