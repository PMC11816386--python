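"""Core containers and I/O for labeled NIR spectra.

A :class:`SpectraSet` is the currency of the whole pipeline: an absorbance
matrix (samples x wavenumbers), its wavenumber axis in reciprocal
centimetres, per-sample string identifiers, and optional integer origin
labels.  Spectra travel on disk as plain CSV with the header
``sample_id,label,<wavenumber>,...``; an optional YAML sidecar maps integer
labels to origin names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml


class SpectraError(ValueError):
    """Raised for malformed or inconsistent spectral data."""


@dataclass
class SpectraSet:
    """Labeled absorbance spectra on a common wavenumber grid.

    Parameters
    ----------
    wavenumbers : ndarray, shape (p,)
        Strictly monotone axis in cm^-1 (ascending or descending; FT-NIR
        exports are typically descending, 10,000 -> 4000).
    absorbance : ndarray, shape (n, p)
        Unitless absorbance, one row per sample; must be finite.
    sample_ids : ndarray of str, shape (n,)
    labels : ndarray of int, shape (n,), optional
        Class codes in ``{0..K-1}``; ``None`` for unlabeled data.
    label_names : dict, optional
        Map from integer label to origin name, e.g. ``{0: "XG"}``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray | None = None
    label_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        self._validate()

    def _validate(self) -> None:
        n, p = self.absorbance.shape
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size != p:
            raise SpectraError(
                f"wavenumber axis length {self.wavenumbers.size} does not match "
                f"{p} absorbance columns"
            )
        d = np.diff(self.wavenumbers)
        if p > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraError("wavenumber axis must be strictly monotone")
        if self.sample_ids.size != n:
            raise SpectraError(
                f"{self.sample_ids.size} sample ids for {n} absorbance rows"
            )
        if self.labels is not None and self.labels.size != n:
            raise SpectraError(f"{self.labels.size} labels for {n} absorbance rows")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraError("absorbance contains non-finite values")

    # -- basic queries -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            raise SpectraError("unlabeled SpectraSet has no class count")
        return int(self.labels.max()) + 1

    # -- derivation ----------------------------------------------------
    def take(self, rows: np.ndarray) -> "SpectraSet":
        """Row subset (or reordering) by integer index."""
        rows = np.asarray(rows, dtype=int)
        return replace(
            self,
            absorbance=self.absorbance[rows],
            sample_ids=self.sample_ids[rows],
            labels=None if self.labels is None else self.labels[rows],
        )

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraSet":
        """Same samples/axis, new absorbance values (e.g. after preprocessing)."""
        return replace(self, absorbance=np.asarray(matrix, dtype=float))

    def select_columns(self, indices: np.ndarray) -> "SpectraSet":
        """Column subset in the given order (wavelength selection)."""
        indices = np.asarray(indices, dtype=int)
        if indices.size and (indices.min() < 0 or indices.max() >= self.n_wavenumbers):
            raise SpectraError("column index out of range")
        return replace(
            self,
            wavenumbers=self.wavenumbers[indices],
            absorbance=self.absorbance[:, indices],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"sample_id": self.sample_ids}
        if self.labels is not None:
            cols["label"] = self.labels
        frame = pd.DataFrame(cols)
        spec = pd.DataFrame(
            self.absorbance, columns=[_format_wavenumber(w) for w in self.wavenumbers]
        )
        return pd.concat([frame, spec.set_index(frame.index)], axis=1)


@dataclass
class SplitResult:
    """A train/test partition of a :class:`SpectraSet`."""

    train: SpectraSet
    test: SpectraSet
    seed: int
    ratio: float

    def __post_init__(self) -> None:
        overlap = set(self.train.sample_ids) & set(self.test.sample_ids)
        if overlap:
            raise SpectraError(f"train/test ids overlap: {sorted(overlap)[:5]}")


def _format_wavenumber(w: float) -> str:
    return f"{w:.6f}".rstrip("0").rstrip(".")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectra(spectra: SpectraSet, path, sidecar: bool = False) -> None:
    """Write a SpectraSet as CSV (header ``sample_id,label,<wn>,...``).

    With ``sidecar=True`` and named labels, a YAML file ``<path>.meta.yaml``
    mapping integer labels to origin names is written alongside.
    """
    spectra.to_frame().to_csv(path, index=False, float_format="%.12g")
    if sidecar and spectra.label_names:
        with open(f"{path}.meta.yaml", "w") as fh:
            yaml.safe_dump({"label_names": {int(k): v for k, v in spectra.label_names.items()}}, fh)


def read_spectra(path, has_labels: bool = True) -> SpectraSet:
    """Read the CSV dialect written by :func:`write_spectra`.

    The header row carries the wavenumber grid; the first column is the
    sample id and, when ``has_labels``, the second column is the integer
    label.  Ragged rows and non-numeric absorbance raise :class:`SpectraError`
    naming the offending row.
    """
    try:
        frame = pd.read_csv(path, dtype={0: str})
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise SpectraError(f"ragged CSV in {path}: {exc}") from exc
    meta_cols = 2 if has_labels else 1
    if frame.shape[1] <= meta_cols:
        raise SpectraError(f"{path}: no wavenumber columns found")
    wn_cols = frame.columns[meta_cols:]
    try:
        wavenumbers = np.asarray([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraError(f"{path}: non-numeric wavenumber header: {exc}") from exc
    spec = frame[wn_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.where(~np.isfinite(spec).all(axis=1))[0]
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise SpectraError(
            f"{path}: non-numeric or missing absorbance in row {bad[0] + 2}"
        )
    labels = frame.iloc[:, 1].to_numpy(dtype=int) if has_labels else None
    label_names = None
    meta_path = f"{path}.meta.yaml"
    try:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
        label_names = {int(k): v for k, v in meta.get("label_names", {}).items()}
    except FileNotFoundError:
        pass
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=spec,
        sample_ids=frame.iloc[:, 0].to_numpy(dtype=object),
        labels=labels,
        label_names=label_names,
    )


# ---------------------------------------------------------------------------
# Replicate averaging and the train/test split
# ---------------------------------------------------------------------------

def average_replicates(spectra: SpectraSet, replicate_key) -> SpectraSet:
    """Average replicate scans of each physical sample.

    ``replicate_key`` maps each sample id to its group key: a callable, a
    dict, or a sequence aligned with the rows.  Output has one row per group
    (arithmetic mean of that group's rows), groups in order of first
    appearance, labels carried over.  Mixed labels within a group are an
    error.
    """
    ids = spectra.sample_ids
    if callable(replicate_key):
        keys = [replicate_key(s) for s in ids]
    elif isinstance(replicate_key, dict):
        keys = [replicate_key[s] for s in ids]
    else:
        keys = list(replicate_key)
        if len(keys) != len(ids):
            raise SpectraError("replicate_key length does not match sample count")

    order: dict = {}
    for i, k in enumerate(keys):
        order.setdefault(k, []).append(i)

    rows, out_ids, out_labels = [], [], []
    for key, members in order.items():
        rows.append(spectra.absorbance[members].mean(axis=0))
        out_ids.append(str(key))
        if spectra.labels is not None:
            group_labels = set(spectra.labels[members].tolist())
            if len(group_labels) > 1:
                raise SpectraError(
                    f"replicate group {key!r} mixes labels {sorted(group_labels)}"
                )
            out_labels.append(group_labels.pop())
    return SpectraSet(
        wavenumbers=spectra.wavenumbers,
        absorbance=np.vstack(rows),
        sample_ids=np.asarray(out_ids, dtype=object),
        labels=np.asarray(out_labels) if out_labels else None,
        label_names=spectra.label_names,
    )


def _stratified_train_indices(labels: np.ndarray, n_train: int, rng: np.random.Generator) -> np.ndarray:
    """Per-class floor allocation, remainder to the largest fractional parts."""
    classes, counts = np.unique(labels, return_counts=True)
    ratio = n_train / labels.size
    floors = np.floor(counts * ratio).astype(int)
    frac = counts * ratio - floors
    short = n_train - floors.sum()
    for c in np.argsort(-frac)[:short]:
        floors[c] += 1
    picks = []
    for cls, k in zip(classes, floors):
        members = np.where(labels == cls)[0]
        picks.append(rng.permutation(members)[:k])
    return np.sort(np.concatenate(picks))


def split_train_test(
    spectra: SpectraSet,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> SplitResult:
    """Random train/test split with ``floor(ratio * n)`` training samples.

    Stratified by default so every origin class is represented in the test
    set; per-class train fractions are then within one sample of ``ratio``.
    Deterministic given ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise SpectraError(f"split ratio must lie in (0, 1), got {ratio}")
    n = spectra.n_samples
    n_train = math.floor(ratio * n)
    rng = np.random.default_rng(seed)
    if stratified:
        if spectra.labels is None:
            raise SpectraError("stratified split requires labels")
        counts = np.bincount(spectra.labels)
        if counts[counts > 0].min() < 2:
            raise SpectraError("stratified split needs >= 2 samples per class")
        train_idx = _stratified_train_indices(spectra.labels, n_train, rng)
    else:
        train_idx = np.sort(rng.permutation(n)[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return SplitResult(
        train=spectra.take(np.where(mask)[0]),
        test=spectra.take(np.where(~mask)[0]),
        seed=seed,
        ratio=ratio,
    )
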