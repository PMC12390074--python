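"""Cross-basis construction: spline properties, lag-knot placement, the
brute-force double-loop oracle, and effect-contrast identities."""

import numpy as np
import pytest

from etepm.basis import (BasisSpec, ModelDesign, cross_basis,
                         cumulative_effect, eval_basis, lag_knots_log,
                         lag_specific_effect, ncs_basis)
from etepm.clogit import FitResult


def brute_force_cross_basis(lagged, f, g):
    n, L1 = lagged.shape
    J = f(lagged[0, 0]).size
    K = g(0.0).size
    out = np.zeros((n, J * K))
    for t in range(n):
        for j in range(J):
            for k in range(K):
                s = 0.0
                for l in range(L1):
                    s += f(lagged[t, l])[j] * g(float(l))[k]
                out[t, j * K + k] = s
    return out


class TestNcsBasis:
    def test_contains_linear_functions(self):
        x = np.linspace(0.0, 10.0, 200)
        B = ncs_basis(x, [3.0, 6.0], (0.0, 10.0), intercept=True)
        target = 2.5 * x - 1.0
        coef, res, *_ = np.linalg.lstsq(B, target, rcond=None)
        assert np.max(np.abs(B @ coef - target)) < 1e-10

    def test_zero_knots_no_intercept_is_linear_map(self):
        x = np.linspace(-2.0, 5.0, 50)
        B = ncs_basis(x, [], (-2.0, 5.0))
        assert B.shape == (50, 1)
        np.testing.assert_allclose(B[:, 0], x)

    def test_second_derivative_vanishes_beyond_boundaries(self):
        # outward one-sided differences: the spline is linear at and beyond
        # the boundary knots, so the second difference is exactly zero
        h = 1e-3
        import warnings
        for x0, sgn in ((-0.0, -1.0), (10.0, 1.0), (-0.5, -1.0), (11.0, 1.0)):
            xs = np.array([x0, x0 + sgn * h, x0 + 2 * sgn * h])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                B = ncs_basis(xs, [3.0, 6.0], (0.0, 10.0), intercept=False)
            second = (B[0] - 2 * B[1] + B[2]) / h ** 2
            assert np.max(np.abs(second)) < 1e-6

    def test_column_count(self):
        x = np.linspace(0, 6, 10)
        assert ncs_basis(x, [2.0, 4.0], (0.0, 6.0)).shape[1] == 3
        assert ncs_basis(x, [2.0, 4.0], (0.0, 6.0), intercept=True).shape[1] == 4


class TestLagKnots:
    def test_closed_form_for_max_lag_six(self):
        np.testing.assert_allclose(lag_knots_log(6, 2),
                                   [6 ** (1 / 3), 6 ** (2 / 3)], rtol=1e-12)

    def test_single_knot_is_log_midpoint(self):
        np.testing.assert_allclose(lag_knots_log(6, 1), [np.sqrt(6)], rtol=1e-12)

    def test_knots_strictly_inside_range(self):
        k = lag_knots_log(6, 2)
        assert np.all((k > 1.0) & (k < 6.0))

    def test_plus_one_variant(self):
        k = lag_knots_log(6, 2, plus_one=True)
        np.testing.assert_allclose(k, np.exp(np.log(7.0) * np.array([1, 2]) / 3) - 1)


class TestCrossBasis:
    def test_reference_exposure_gives_zero_row(self):
        lagged = np.zeros((3, 7), dtype=int)
        cb = cross_basis(lagged, BasisSpec("strata", levels=(0, 1, 2), reference=0),
                         BasisSpec("ncs", interior_knots=(1.8, 3.3),
                                   boundary_knots=(0.0, 6.0), intercept=True))
        np.testing.assert_array_equal(cb.matrix, 0.0)

    def test_linear_basis_intercept_lag_reduces_to_moving_sum(self):
        rng = np.random.default_rng(0)
        lagged = rng.normal(size=(10, 7))
        cb = cross_basis(lagged, BasisSpec("linear", scale=1.0),
                         BasisSpec("poly", degree=1, scale=1.0, intercept=True))
        # column (j=0, k=intercept) = sum over lags
        np.testing.assert_allclose(cb.matrix[:, 0], lagged.sum(axis=1))

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        var_spec = BasisSpec("ncs", interior_knots=(0.3, 0.6),
                             boundary_knots=(-2.0, 2.0))
        lag_spec = BasisSpec("ncs", interior_knots=tuple(lag_knots_log(6, 2)),
                             boundary_knots=(0.0, 6.0), intercept=True)
        for _ in range(50):
            lagged = rng.normal(size=(5, 7)).clip(-2, 2)
            cb = cross_basis(lagged, var_spec, lag_spec)
            f = lambda v: eval_basis(var_spec, np.array([v]))[0]
            g = lambda l: eval_basis(lag_spec, np.array([l]))[0]
            np.testing.assert_allclose(cb.matrix,
                                       brute_force_cross_basis(lagged, f, g),
                                       atol=1e-12)

    def test_strata_value_outside_levels_rejected(self):
        with pytest.raises(ValueError):
            cross_basis(np.full((2, 7), 9),
                        BasisSpec("strata", levels=(0, 1), reference=0),
                        BasisSpec("poly", degree=1, intercept=True))


def _toy_fit(design, beta, vcov=None):
    p = design.ncols
    return FitResult(beta=np.asarray(beta, float),
                     vcov=np.zeros((p, p)) if vcov is None else vcov,
                     loglik=-1.0, n_sets=10, converged=True, iterations=3)


class TestEffects:
    def _design(self):
        rng = np.random.default_rng(2)
        lagged = rng.integers(0, 3, size=(20, 7))
        cb = cross_basis(lagged, BasisSpec("strata", levels=(0, 1, 2), reference=0),
                         BasisSpec("ncs", interior_knots=tuple(lag_knots_log(6, 2)),
                                   boundary_knots=(0.0, 6.0), intercept=True))
        return ModelDesign().add("ete", cb)

    def test_zero_beta_gives_unit_or_and_degenerate_ci(self):
        design = self._design()
        fit = _toy_fit(design, np.zeros(design.ncols))
        e = cumulative_effect(fit, design, "ete", 1)
        assert e.or_ == 1.0 and e.ci_low == 1.0 and e.ci_high == 1.0

    def test_single_column_log2_gives_or_two(self):
        lagged = np.ones((5, 7))
        cb = cross_basis(lagged, BasisSpec("linear", scale=1.0),
                         BasisSpec("poly", degree=1, scale=1.0, intercept=True))
        design = ModelDesign().add("x", cb)
        # keep only the intercept-lag column active: contrast of +1 exposure
        fit = _toy_fit(design, [np.log(2.0) / 7.0, 0.0])
        e = cumulative_effect(fit, design, "x", 1.0)
        assert e.or_ == pytest.approx(2.0, rel=1e-12)

    def test_lag_specific_log_ors_sum_to_cumulative(self):
        design = self._design()
        rng = np.random.default_rng(3)
        fit = _toy_fit(design, rng.normal(size=design.ncols))
        for level in (1, 2):
            cum = cumulative_effect(fit, design, "ete", level).log_or
            parts = [lag_specific_effect(fit, design, "ete", level, l).log_or
                     for l in range(7)]
            assert np.sum(parts) == pytest.approx(cum, abs=1e-10)

    def test_contrast_matches_constant_exposure_row_prediction(self):
        # a person-day held at one level over all lags has a cross-basis row
        # identical to the cumulative contrast vector
        design = self._design()
        cb = design.blocks["ete"]
        rng = np.random.default_rng(4)
        fit = _toy_fit(design, rng.normal(size=design.ncols))
        for level in (1, 2):
            row = cross_basis(np.full((1, 7), level), cb.var_spec,
                              cb.lag_spec).matrix[0]
            assert row @ fit.beta == pytest.approx(
                cumulative_effect(fit, design, "ete", level).log_or, abs=1e-10)

    def test_contrast_at_reference_rejected(self):
        design = self._design()
        fit = _toy_fit(design, np.zeros(design.ncols))
        with pytest.raises(ValueError):
            cumulative_effect(fit, design, "ete", 0)
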