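"""Spectral preprocessing: Savitzky-Golay smoothing, multiplicative scatter
correction, first derivative, and the eight-strategy catalog built from
their combinations (none, SG, MSC, FD, SG+MSC, SG+FD, MSC+FD, SG+MSC+FD).

Operators compose in the canonical order SG -> MSC -> FD.  MSC carries
train-derived state (the reference spectrum is the training-set mean), so a
strategy is *fitted* on the training partition and then applied unchanged
to test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectraSet, SpectraError

#: The eight-strategy catalog, in presentation order.
STRATEGY_NAMES = ("none", "SG", "MSC", "FD", "SG+MSC", "SG+FD", "MSC+FD", "SG+MSC+FD")


@dataclass(frozen=True)
class PreprocessStrategy:
    """One named combination of the three base operators.

    sg_window / sg_polyorder apply to both smoothing and the SG derivative
    kernel; fd_method selects between the SG first-derivative kernel
    (default chemometrics practice) and plain central differences.
    """

    name: str
    sg_window: int = 11
    sg_polyorder: int = 2
    fd_method: str = "sg_derivative"

    def __post_init__(self):
        if self.name not in STRATEGY_NAMES:
            raise SpectraError(
                f"unknown strategy {self.name!r}; expected one of {STRATEGY_NAMES}"
            )
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise SpectraError("sg_window must be an odd integer >= 3")
        if self.sg_polyorder >= self.sg_window:
            raise SpectraError("sg_polyorder must be < sg_window")
        if self.fd_method not in ("sg_derivative", "finite_difference"):
            raise SpectraError(f"unknown fd_method {self.fd_method!r}")

    @property
    def uses_sg(self) -> bool:
        return "SG" in self.name.split("+")

    @property
    def uses_msc(self) -> bool:
        return "MSC" in self.name.split("+")

    @property
    def uses_fd(self) -> bool:
        return "FD" in self.name.split("+")


def catalog(**kwargs) -> list[PreprocessStrategy]:
    """All eight strategies with shared operator settings."""
    return [PreprocessStrategy(name, **kwargs) for name in STRATEGY_NAMES]


@dataclass
class FittedPreprocessor:
    strategy: PreprocessStrategy
    msc_reference: np.ndarray | None
    wavenumbers: np.ndarray

    def __post_init__(self):
        if self.strategy.uses_msc != (self.msc_reference is not None):
            raise SpectraError("msc_reference must be present iff the strategy uses MSC")

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        """Apply the frozen strategy to new spectra (no refitting)."""
        X = spectra.absorbance
        s = self.strategy
        if s.uses_sg:
            X = sg_smooth(X, s.sg_window, s.sg_polyorder)
        if s.uses_msc:
            X = msc_apply(X, self.msc_reference)
        if s.uses_fd:
            X = first_derivative(X, spectra.wavenumbers, s.fd_method,
                                 window=s.sg_window, polyorder=s.sg_polyorder)
        return spectra.with_absorbance(X)


# ---------------------------------------------------------------------------
# Base operators
# ---------------------------------------------------------------------------

def sg_smooth(absorbance: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing, row-wise."""
    X = np.atleast_2d(np.asarray(absorbance, dtype=float))
    if window % 2 == 0:
        raise SpectraError("SG window must be odd")
    if window < polyorder + 1:
        raise SpectraError("SG window must be >= polyorder + 1")
    if window > X.shape[1]:
        raise SpectraError("SG window exceeds the number of wavenumbers")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1)


def msc_fit(train_absorbance: np.ndarray) -> np.ndarray:
    """MSC reference spectrum = column-wise mean of the training rows."""
    X = np.atleast_2d(np.asarray(train_absorbance, dtype=float))
    if X.shape[0] < 2:
        raise SpectraError("MSC reference needs at least 2 training spectra")
    return X.mean(axis=0)


def msc_apply(absorbance: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Regress each row on the reference (x ~ b + a*ref); return (x - b)/a."""
    X = np.atleast_2d(np.asarray(absorbance, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise SpectraError("MSC reference length does not match spectra")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    slopes = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.where(np.abs(slopes) < 1e-12)[0]
    if bad.size:
        raise SpectraError(f"MSC slope vanishes for row {bad[0]}")
    intercepts = X.mean(axis=1) - slopes * ref.mean()
    return (X - intercepts[:, None]) / slopes[:, None]


def first_derivative(
    absorbance: np.ndarray,
    wavenumbers: np.ndarray,
    method: str = "sg_derivative",
    window: int = 11,
    polyorder: int = 2,
) -> np.ndarray:
    """d(absorbance)/d(wavenumber), row-wise.

    The derivative is taken with respect to the axis *values*, so a
    descending (instrument-order) grid yields the same signs as an
    ascending one.
    """
    X = np.atleast_2d(np.asarray(absorbance, dtype=float))
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.size != X.shape[1]:
        raise SpectraError("wavenumber axis does not match spectra")
    if method == "finite_difference":
        return np.gradient(X, wn, axis=1)
    if method != "sg_derivative":
        raise SpectraError(f"unknown derivative method {method!r}")
    step = np.diff(wn)
    if not np.allclose(step, step[0], rtol=1e-6):
        # SG kernels assume uniform spacing; fall back to exact gradient
        return np.gradient(X, wn, axis=1)
    out = savgol_filter(
        X, window_length=window, polyorder=max(polyorder, 1), deriv=1,
        delta=abs(step[0]), axis=1,
    )
    return out if step[0] > 0 else -out


def fit_apply_strategy(
    train: SpectraSet, test: SpectraSet, strategy: PreprocessStrategy
) -> tuple[SpectraSet, SpectraSet, FittedPreprocessor]:
    """Fit a strategy on the training set and apply it to both partitions.

    The MSC reference (the only train-derived state) is computed on the
    training rows *after* any SG smoothing, then reused verbatim on test.
    """
    reference = None
    if strategy.uses_msc:
        X_train = train.absorbance
        if strategy.uses_sg:
            X_train = sg_smooth(X_train, strategy.sg_window, strategy.sg_polyorder)
        reference = msc_fit(X_train)
    fitted = FittedPreprocessor(
        strategy=strategy, msc_reference=reference, wavenumbers=train.wavenumbers
    )
    return fitted.apply(train), fitted.apply(test), fitted
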