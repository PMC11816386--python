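import dataclasses

import numpy as np
import pytest

import nirtrace as nt
from nirtrace.simulate import _default_bands


@pytest.fixture(scope="session")
def tiny_spectra():
    """A 3-sample, 4-wavenumber set small enough to reason about by hand."""
    return nt.SpectraSet(
        wavenumbers=[8000.0, 7000.0, 6000.0, 5000.0],
        absorbance=[[0.1, 0.2, 0.3, 0.4],
                    [0.5, 0.6, 0.7, 0.8],
                    [0.9, 1.0, 1.1, 1.2]],
        sample_ids=["a", "b", "c"],
        labels=[0, 1, 0],
    )


def small_config(**overrides):
    """A scaled-down synthetic configuration for fast unit tests."""
    base = nt.default_config(seed=5)
    params = dict(
        n_per_class=(12, 12, 12, 12, 12),
        wavenumber_grid=(10_000.0, 4_000.0, 256),
        outlier_fraction=0.0,
    )
    params.update(overrides)
    return dataclasses.replace(base, **params)


@pytest.fixture(scope="session")
def small_dataset():
    """Averaged sample-level spectra from the scaled-down generator."""
    cfg = small_config()
    replicate_level, truth = nt.generate(cfg)
    avg = nt.average_replicates(replicate_level, nt.replicate_group)
    return avg, truth


@pytest.fixture(scope="session")
def separable_toy():
    """Two widely separated 1-D classes: any sane classifier is perfect."""
    rng = np.random.default_rng(3)
    n = 40
    X = np.hstack([
        np.concatenate([rng.normal(-5, 0.2, n), rng.normal(5, 0.2, n)])[:, None],
        rng.normal(0, 0.2, (2 * n, 4)),
    ])
    y = np.repeat([0, 1], n)
    return X, y
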