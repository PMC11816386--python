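"""Savitzky-Golay, MSC, first derivative, and the eight-strategy catalog."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirtrace as nt
from nirtrace.dataset import SpectraError
from nirtrace.preprocess import (
    PreprocessStrategy, STRATEGY_NAMES, catalog, sg_smooth, msc_fit, msc_apply,
    first_derivative, fit_apply_strategy,
)


class TestSavitzkyGolay:
    def test_constant_row_unchanged(self):
        row = np.full((1, 50), 0.7)
        np.testing.assert_allclose(sg_smooth(row, 11, 2), row, atol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        x = np.arange(60.0)
        row = (0.02 * x**2 - 0.3 * x + 1.0)[None, :]
        out = sg_smooth(row, 11, 2)
        # oracle: direct local least-squares quadratic fit at each point
        for i in (10, 25, 49):
            lo = i - 5
            idx = np.arange(lo, lo + 11)
            coef = np.polyfit(idx - i, row[0, idx], 2)
            assert out[0, i] == pytest.approx(coef[-1], abs=1e-9)
        np.testing.assert_allclose(out[0, 5:-5], row[0, 5:-5], atol=1e-9)

    def test_white_noise_variance_contracts(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=(1, 500))
        assert sg_smooth(row, 11, 2).var() < row.var()

    def test_even_window_rejected(self):
        with pytest.raises(SpectraError, match="odd"):
            sg_smooth(np.ones((1, 20)), 10, 2)


class TestMsc:
    def test_reference_is_training_mean(self):
        r = np.linspace(1.0, 2.0, 8)
        np.testing.assert_allclose(msc_fit(np.vstack([r, r])), r, atol=1e-15)
        np.testing.assert_allclose(msc_fit(np.vstack([r, 3 * r])), 2 * r, atol=1e-14)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 20))
        np.testing.assert_allclose(msc_fit(X), X.mean(axis=0), atol=1e-12)

    def test_reference_row_unchanged(self):
        ref = np.linspace(0.5, 1.5, 30) + np.sin(np.arange(30) / 3)
        out = msc_apply(ref[None, :], ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_known_affine_row_restored(self):
        ref = np.linspace(0.5, 1.5, 30)
        out = msc_apply((2.0 * ref + 0.5)[None, :], ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(a=st.floats(0.2, 5.0), b=st.floats(-2.0, 2.0))
    def test_affine_family_collapses_onto_reference(self, a, b):
        ref = np.linspace(0.4, 1.6, 25) + np.cos(np.arange(25.0) / 4)
        out = msc_apply(np.vstack([a * ref + b, ref]), ref)
        np.testing.assert_allclose(out[0], out[1], atol=1e-10)

    def test_idempotent_with_fixed_reference(self):
        rng = np.random.default_rng(2)
        ref = np.linspace(0.4, 1.4, 40)
        X = 0.8 * ref + 0.2 + rng.normal(0, 0.05, size=(6, 40))
        once = msc_apply(X, ref)
        np.testing.assert_allclose(msc_apply(once, ref), once, atol=1e-10)

    def test_zero_slope_row_identified(self):
        ref = np.linspace(0.4, 1.4, 20)
        X = np.vstack([ref, np.full(20, 0.3)])
        with pytest.raises(SpectraError, match="row 1"):
            msc_apply(X, ref)


class TestFirstDerivative:
    wn_down = np.linspace(10_000.0, 4_000.0, 400)

    @pytest.mark.parametrize("method", ["sg_derivative", "finite_difference"])
    def test_constant_row_maps_to_zero(self, method):
        out = first_derivative(np.full((1, 400), 1.3), self.wn_down, method)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("method", ["sg_derivative", "finite_difference"])
    def test_linear_row_gives_constant_slope(self, method):
        m = 2.5e-4
        row = (m * self.wn_down + 0.1)[None, :]
        out = first_derivative(row, self.wn_down, method)
        np.testing.assert_allclose(out[0, 10:-10], m, atol=1e-8)

    def test_sinusoid_matches_analytic_derivative(self):
        wn = np.linspace(4_000.0, 10_000.0, 4000)  # fine ascending grid
        omega = 2 * np.pi / 800.0
        row = np.sin(omega * wn)[None, :]
        out = first_derivative(row, wn, "sg_derivative", window=7, polyorder=3)
        expected = omega * np.cos(omega * wn)
        np.testing.assert_allclose(out[0, 20:-20], expected[20:-20],
                                   atol=2e-3 * omega)

    def test_axis_direction_does_not_flip_sign(self):
        wn_up = self.wn_down[::-1].copy()
        row_down = (1e-4 * self.wn_down)[None, :]
        row_up = (1e-4 * wn_up)[None, :]
        d_down = first_derivative(row_down, self.wn_down)
        d_up = first_derivative(row_up, wn_up)
        np.testing.assert_allclose(d_down.mean(), d_up.mean(), atol=1e-10)
        assert d_down.mean() > 0

    @settings(max_examples=15, deadline=None)
    @given(c=st.floats(-3.0, 3.0))
    def test_invariant_to_constant_baseline(self, c):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, 400))
        a = first_derivative(X, self.wn_down)
        b = first_derivative(X + c, self.wn_down)
        np.testing.assert_allclose(a, b, atol=1e-10)


def _two_sets(n_train=10, n_test=4, p=120, seed=0):
    rng = np.random.default_rng(seed)
    wn = np.linspace(9000.0, 5000.0, p)
    mk = lambda n, tag: nt.SpectraSet(
        wn, 1.0 + 0.3 * np.sin(wn / 500)[None, :] + rng.normal(0, 0.05, (n, p)),
        [f"{tag}{i}" for i in range(n)], rng.integers(0, 2, n))
    return mk(n_train, "tr"), mk(n_test, "te")


class TestStrategies:
    def test_catalog_enumerates_eight(self):
        assert len(catalog()) == 8
        assert tuple(s.name for s in catalog()) == STRATEGY_NAMES

    def test_unknown_name_and_bad_params_rejected(self):
        with pytest.raises(SpectraError):
            PreprocessStrategy("SNV")
        with pytest.raises(SpectraError):
            PreprocessStrategy("SG", sg_window=8)
        with pytest.raises(SpectraError):
            PreprocessStrategy("SG", sg_window=5, sg_polyorder=5)

    def test_none_strategy_is_identity(self):
        train, test = _two_sets()
        tr, te, fitted = fit_apply_strategy(train, test, PreprocessStrategy("none"))
        np.testing.assert_allclose(tr.absorbance, train.absorbance, atol=1e-15)
        np.testing.assert_allclose(te.absorbance, test.absorbance, atol=1e-15)
        assert fitted.msc_reference is None

    def test_sg_fd_equals_stepwise_composition(self):
        train, test = _two_sets()
        strat = PreprocessStrategy("SG+FD")
        tr, _, _ = fit_apply_strategy(train, test, strat)
        stepwise = first_derivative(
            sg_smooth(train.absorbance, strat.sg_window, strat.sg_polyorder),
            train.wavenumbers, strat.fd_method,
            window=strat.sg_window, polyorder=strat.sg_polyorder,
        )
        np.testing.assert_allclose(tr.absorbance, stepwise, atol=1e-12)

    def test_msc_reference_fitted_on_train_only(self):
        train, test = _two_sets()
        _, _, fitted = fit_apply_strategy(train, test, PreprocessStrategy("MSC"))
        np.testing.assert_allclose(
            fitted.msc_reference, train.absorbance.mean(axis=0), atol=1e-12
        )
        # applying to a different test set reuses the same frozen reference
        _, test2 = _two_sets(seed=9)
        out = fitted.apply(test2)
        np.testing.assert_allclose(
            out.absorbance, msc_apply(test2.absorbance, fitted.msc_reference),
            atol=1e-12,
        )

    @pytest.mark.parametrize("name", STRATEGY_NAMES)
    def test_shape_preserved_and_rows_independent(self, name):
        train, test = _two_sets()
        strat = PreprocessStrategy(name)
        tr, _, fitted = fit_apply_strategy(train, test, strat)
        assert tr.absorbance.shape == train.absorbance.shape
        perm = np.array([3, 1, 4, 0, 2, 5, 9, 7, 8, 6])
        out_perm = fitted.apply(train.take(perm))
        np.testing.assert_allclose(
            out_perm.absorbance, tr.absorbance[perm], atol=1e-10
        )
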