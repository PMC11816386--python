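"""The spectral CNN: shape algebra, gradients, training contracts, sweeps."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirtrace as nt
from nirtrace.dataset import SpectraError
from nirtrace.cnn import (
    CNNConfig, SWEEP_GRIDS, build_cnn, train_cnn, cnn_predict,
    hyperparameter_sweep, softmax, _Network,
)
from .conftest import small_config


def _toy_data(n=40, p=64, K=3, seed=0, effect=3.0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % K
    X = rng.normal(0, 0.3, size=(n, p))
    for k in range(K):
        X[y == k, 8 + 12 * k : 14 + 12 * k] += effect
    return X, y


class TestBuildCnn:
    def test_shape_algebra_on_input_16(self):
        cfg = CNNConfig(input_length=16, n_classes=5, n_conv_layers=3, pool_size=2)
        assert cfg.conv_lengths() == [8, 4, 2]
        layers = {l.name: l for l in build_cnn(cfg)}
        assert layers["maxpool1"].output_shape == (32, 8)
        assert layers["maxpool2"].output_shape == (32, 4)
        assert layers["maxpool3"].output_shape == (32, 2)
        assert layers["flatten"].output_shape == (64,)

    def test_parameter_counts_match_hand_arithmetic(self):
        cfg = CNNConfig(input_length=1556, n_classes=5)
        layers = {l.name: l for l in build_cnn(cfg)}
        assert layers["conv1"].n_params == (1 * 3 + 1) * 32
        assert layers["conv2"].n_params == (32 * 3 + 1) * 32
        assert layers["conv3"].n_params == (32 * 3 + 1) * 32
        assert layers["batchnorm1"].n_params == 64
        flat = 32 * (1556 // 2 // 2 // 2)
        assert layers["dense"].n_params == (flat + 1) * 5

    def test_too_short_input_names_minimal_length(self):
        with pytest.raises(SpectraError, match="at least 8"):
            CNNConfig(input_length=7, n_classes=3, n_conv_layers=3, pool_size=2)

    def test_even_kernel_rejected(self):
        with pytest.raises(SpectraError, match="odd"):
            CNNConfig(input_length=64, kernel_size=4)

    @settings(max_examples=30, deadline=None)
    @given(length=st.integers(8, 2000), layers=st.integers(1, 4),
           pool=st.integers(2, 3))
    def test_shape_algebra_matches_recursive_formula(self, length, layers, pool):
        def recurse(L, k):
            return L if k == 0 else recurse(L // pool, k - 1)
        if recurse(length, layers) < 1:
            with pytest.raises(SpectraError):
                CNNConfig(input_length=length, n_conv_layers=layers, pool_size=pool)
        else:
            cfg = CNNConfig(input_length=length, n_conv_layers=layers, pool_size=pool)
            assert cfg.conv_lengths()[-1] == recurse(length, layers)


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 24))
        y = rng.integers(0, 3, size=6)
        cfg = CNNConfig(input_length=24, n_classes=3, n_conv_layers=2,
                        kernels_per_layer=4, batch_size=6)
        net = _Network(cfg, np.random.default_rng(0), dtype=np.float64)
        onehot = np.zeros((6, 3))
        onehot[np.arange(6), y] = 1.0

        def loss():
            p = softmax(net.forward(X, training=True))
            return -np.log(p[np.arange(6), y]).mean()

        p = softmax(net.forward(X, training=True))
        net.backward((p - onehot) / 6)
        for layer, name, value, gattr in net.all_params():
            g = getattr(layer, gattr)
            probe = np.unravel_index(np.argmax(np.abs(g)), g.shape)
            if abs(g[probe]) < 1e-10:  # conv bias is a no-op under batch-norm
                continue
            eps = 1e-6
            old = value[probe]
            value[probe] = old + eps
            lp = loss()
            value[probe] = old - eps
            lm = loss()
            value[probe] = old
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[probe], rel=1e-5), (type(layer), name)


class TestTraining:
    def test_small_subset_reaches_perfect_training_accuracy(self):
        X, y = _toy_data(n=21, p=64)
        cfg = CNNConfig(input_length=64, n_classes=3, epochs=200, seed=0)
        _, history = train_cnn(cfg, X, y)
        assert history.accuracy[-1] == 1.0

    def test_loss_decreases_from_first_epoch(self):
        X, y = _toy_data(n=60, p=64)
        cfg = CNNConfig(input_length=64, n_classes=3, epochs=15, seed=0)
        _, history = train_cnn(cfg, X, y)
        assert history.loss[-1] < history.loss[0]
        assert len(history.loss) == len(history.accuracy) == 15

    def test_same_seed_reruns_are_bit_identical(self):
        X, y = _toy_data(n=36, p=32)
        cfg = CNNConfig(input_length=32, n_classes=3, epochs=8, seed=5)
        m1, h1 = train_cnn(cfg, X, y)
        m2, h2 = train_cnn(cfg, X, y)
        assert h1.loss == h2.loss and h1.accuracy == h2.accuracy
        _, p1 = cnn_predict(m1, X)
        _, p2 = cnn_predict(m2, X)
        np.testing.assert_array_equal(p1, p2)

    def test_exploding_learning_rate_aborts_with_diagnostic(self):
        X, y = _toy_data(n=30, p=32)
        cfg = CNNConfig(input_length=32, n_classes=3, epochs=50, seed=0,
                        learning_rate=1e30)
        with pytest.raises(SpectraError, match="non-finite"):
            train_cnn(cfg, X, y)

    def test_noisier_spectra_never_classify_better(self):
        accs = []
        for noise in (0.005, 0.02, 0.08):
            per_seed = []
            for seed in range(3):
                cfg = small_config(noise_sd=noise, seed=20 + seed,
                                   n_per_class=(25,) * 5)
                spec, _ = nt.generate(cfg)
                avg = nt.average_replicates(spec, nt.replicate_group)
                split = nt.split_train_test(avg, ratio=0.8, seed=seed)
                c = CNNConfig(input_length=avg.n_wavenumbers, n_classes=5,
                              epochs=15, seed=seed)
                model, _ = train_cnn(c, split.train.absorbance, split.train.labels)
                pred, _ = cnn_predict(model, split.test.absorbance)
                per_seed.append((pred == split.test.labels).mean())
            accs.append(np.mean(per_seed))
        sd = np.std(accs) if np.std(accs) > 0 else 0.05
        assert accs[1] <= accs[0] + max(0.06, sd)
        assert accs[2] <= accs[1] + max(0.06, sd)


class TestPredict:
    def test_probabilities_are_a_distribution(self):
        X, y = _toy_data(n=30, p=32)
        cfg = CNNConfig(input_length=32, n_classes=3, epochs=5, seed=0)
        model, _ = train_cnn(cfg, X, y)
        labels, probs = cnn_predict(model, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))

    def test_length_mismatch_rejected(self):
        X, y = _toy_data(n=30, p=32)
        cfg = CNNConfig(input_length=32, n_classes=3, epochs=2, seed=0)
        model, _ = train_cnn(cfg, X, y)
        with pytest.raises(SpectraError, match="wavenumbers"):
            cnn_predict(model, np.ones((2, 64)))

    def test_noiseless_separable_set_is_perfect(self):
        X, y = _toy_data(n=60, p=64, effect=5.0)
        cfg = CNNConfig(input_length=64, n_classes=3, epochs=60, seed=1)
        model, _ = train_cnn(cfg, X, y)
        X2, y2 = _toy_data(n=60, p=64, seed=99, effect=5.0)
        pred, _ = cnn_predict(model, X2)
        assert (pred == y2).mean() == 1.0


class TestSweep:
    def test_standard_grids_match_study_candidates(self):
        assert set(SWEEP_GRIDS["layers"]) == {2, 3, 4}
        assert set(SWEEP_GRIDS["kernel_size"]) == {3, 5, 7}
        assert set(SWEEP_GRIDS["batch_size"]) == {8, 16, 32}
        assert set(SWEEP_GRIDS["learning_rate"]) == {5e-5, 1e-4, 5e-4}

    def test_single_value_sweep_equals_plain_run(self):
        X, y = _toy_data(n=30, p=32)
        base = CNNConfig(input_length=32, n_classes=3, epochs=6, seed=2)
        rows, histories = hyperparameter_sweep(base, "kernel_size", [3], X, y)
        _, plain = train_cnn(base, X, y)
        assert len(rows) == 1
        assert rows[0]["final_train_loss"] == plain.loss[-1]
        assert histories[3].accuracy == plain.accuracy

    def test_row_per_candidate_value(self):
        X, y = _toy_data(n=24, p=32)
        base = CNNConfig(input_length=32, n_classes=3, epochs=3, seed=0)
        rows, _ = hyperparameter_sweep(base, "batch_size", [8, 16, 32], X, y,
                                       X_test=X, y_test=y)
        assert [r["value"] for r in rows] == [8, 16, 32]
        assert all("test_accuracy" in r for r in rows)

    def test_unknown_axis_rejected(self):
        base = CNNConfig(input_length=32, n_classes=3)
        with pytest.raises(SpectraError, match="axis"):
            hyperparameter_sweep(base, "dropout", [0.1], np.ones((4, 32)),
                                 np.zeros(4, dtype=int))
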