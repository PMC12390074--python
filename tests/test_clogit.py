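"""Conditional logistic likelihood: closed forms, a grid-search oracle, an
independent statsmodels cross-check, invariances, and the LR test."""

import numpy as np
import pytest
from scipy import stats

from etepm import clogit


def _pair_design(n_case_exposed, n_control_exposed):
    """1:1 sets with a binary covariate: n10 sets with exposed case /
    unexposed control and n01 reversed."""
    X, sets, case = [], [], []
    sid = 0
    for _ in range(n_case_exposed):
        X += [[1.0], [0.0]]
        case += [1, 0]
        sets += [sid, sid]
        sid += 1
    for _ in range(n_control_exposed):
        X += [[0.0], [1.0]]
        case += [1, 0]
        sets += [sid, sid]
        sid += 1
    return np.array(X), np.array(sets), np.array(case)


def grid_search_beta(X, sets, case, lo=-3.0, hi=3.0, n=24001):
    """Dense 1-D likelihood scan: the independent oracle."""
    grid = np.linspace(lo, hi, n)
    x = X[:, 0]
    ll = np.zeros(n)
    for s in np.unique(sets):
        m = sets == s
        eta = np.outer(x[m], grid)                      # (set size, n)
        mx = eta.max(axis=0)
        ll += eta[case[m].astype(bool)][0] - (
            np.log(np.exp(eta - mx).sum(axis=0)) + mx)
    return grid[np.argmax(ll)]


class TestFit:
    def test_null_loglik_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        sets = np.repeat(np.arange(3), 4)
        case = np.tile([1, 0, 0, 0], 3)
        res = clogit.fit(np.zeros_like(X), sets, case, max_iter=1)
        assert res.loglik == pytest.approx(-3 * np.log(4))
        assert clogit.null_loglik([4, 4, 4]) == pytest.approx(-3 * np.log(4))

    def test_discordant_pair_closed_form(self):
        X, sets, case = _pair_design(20, 10)
        res = clogit.fit(X, sets, case)
        assert res.converged
        assert res.beta[0] == pytest.approx(np.log(2.0), abs=1e-6)
        # McNemar-type variance: 1/n10 + 1/n01
        assert res.vcov[0, 0] == pytest.approx(1 / 20 + 1 / 10, rel=1e-4)

    def test_symmetric_design_gives_zero(self):
        rng = np.random.default_rng(1)
        X, sets, case = [], [], []
        for s in range(15):
            v = rng.normal(size=2)
            X += [[v[0]], [v[1]], [v[1]], [v[0]]]
            case += [1, 0, 1, 0]
            sets += [2 * s, 2 * s, 2 * s + 1, 2 * s + 1]
        res = clogit.fit(np.array(X), np.array(sets), np.array(case))
        assert abs(res.beta[0]) < 1e-7

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        for rep in range(25):
            n_sets = int(rng.integers(4, 11))
            sizes = rng.integers(2, 5, size=n_sets)
            X, sets, case = [], [], []
            for s, m in enumerate(sizes):
                x = rng.normal(size=m)
                c = np.zeros(m, int)
                c[rng.integers(0, m)] = 1
                X += list(x[:, None])
                case += list(c)
                sets += [s] * m
            X, sets, case = np.array(X), np.array(sets), np.array(case)
            res = clogit.fit(X, sets, case)
            if not res.converged or abs(res.beta[0]) > 2.5:
                continue  # likelihood too flat/separated for the bounded scan
            oracle = grid_search_beta(X, sets, case)
            assert res.beta[0] == pytest.approx(oracle, abs=1e-3)

    def test_matches_statsmodels_conditional_logit(self):
        sm = pytest.importorskip("statsmodels.discrete.conditional_models")
        rng = np.random.default_rng(3)
        n_sets = 150
        sets = np.repeat(np.arange(n_sets), 4)
        X = rng.normal(size=(4 * n_sets, 2))
        eta = X @ np.array([0.8, -0.4])
        case = np.zeros(4 * n_sets, int)
        for s in range(n_sets):
            m = slice(4 * s, 4 * s + 4)
            p = np.exp(eta[m] - eta[m].max())
            case[4 * s + rng.choice(4, p=p / p.sum())] = 1
        ours = clogit.fit(X, sets, case)
        theirs = sm.ConditionalLogit(case, X, groups=sets).fit(disp=False)
        # statsmodels stops at a looser gradient tolerance than our solver
        np.testing.assert_allclose(ours.beta, theirs.params, atol=1e-3)
        np.testing.assert_allclose(ours.loglik, theirs.llf, rtol=1e-6)
        np.testing.assert_allclose(ours.vcov, theirs.cov_params(), rtol=1e-2)

    def test_gradient_small_at_optimum(self, effect_matched):
        from etepm.models import fit_single_exposure_model
        df, eff, _ = effect_matched
        res, design, _ = fit_single_exposure_model(df)
        assert res.converged
        X = design.matrix()
        codes, _ = clogit.pd_factorize(df["subject_id"].to_numpy())
        order = np.argsort(codes, kind="stable")
        starts = np.concatenate(([0], np.flatnonzero(np.diff(codes[order])) + 1))
        sizes = np.diff(np.concatenate((starts, [len(codes)])))
        _, grad, _ = clogit._ll_grad_info(
            X[order], df["is_case"].to_numpy().astype(bool)[order], starts,
            np.repeat(np.arange(len(starts)), sizes), res.beta)
        assert np.max(np.abs(grad)) < 1e-6

    def test_invariant_to_per_set_covariate_shift(self):
        rng = np.random.default_rng(4)
        n_sets = 40
        sets = np.repeat(np.arange(n_sets), 4)
        X = rng.normal(size=(4 * n_sets, 2))
        case = np.tile([1, 0, 0, 0], n_sets)
        base = clogit.fit(X, sets, case)
        shifts = rng.normal(size=(n_sets, 2)) * 5
        shifted = clogit.fit(X + shifts[sets], sets, case)
        np.testing.assert_allclose(base.beta, shifted.beta, atol=1e-8)

    def test_set_without_case_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError):
            clogit.fit(X, [0, 0, 1, 1], [1, 0, 0, 0])

    def test_separation_flagged(self):
        # perfectly separated: exposed day always the case
        X, sets, case = _pair_design(25, 0)
        res = clogit.fit(X, sets, case)
        assert not res.converged


class TestLrTest:
    def test_identical_models(self):
        X, sets, case = _pair_design(10, 10)
        res = clogit.fit(X, sets, case)
        chi2, df, p = clogit.lr_test(res, res)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_chi2_quantile(self):
        f = clogit.FitResult(np.zeros(3), np.eye(3), -10.0, 5, True, 1)
        r = clogit.FitResult(np.zeros(1), np.eye(1), -10.0 - 5.991 / 2, 5, True, 1)
        chi2, df, p = clogit.lr_test(f, r)
        assert df == 2
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_null_extra_column_p_uniform(self):
        # a pure-noise extra column should give U(0,1) LR p-values
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            n_sets = 60
            sets = np.repeat(np.arange(n_sets), 3)
            x1 = rng.normal(size=(3 * n_sets, 1))
            noise = rng.normal(size=(3 * n_sets, 1))
            case = np.tile([1, 0, 0], n_sets)
            full = clogit.fit(np.hstack([x1, noise]), sets, case)
            red = clogit.fit(x1, sets, case)
            pvals.append(clogit.lr_test(full, red)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestLinearityGate:
    def test_linear_truth_prefers_linear(self, effect_matched):
        from etepm.models import lagged
        df, eff, _ = effect_matched
        gate = clogit.linearity_gate(lagged(df, "pm25"),
                                     df["subject_id"].to_numpy(),
                                     df["is_case"].to_numpy())
        assert gate["choice"] == "linear-dlm"
        assert gate["df"] == 8

    def test_threshold_effect_detected_as_nonlinear(self):
        # strong step effect in exposure: the spline model must win
        rng = np.random.default_rng(6)
        n_sets = 3000
        sets = np.repeat(np.arange(n_sets), 4)
        pm = rng.lognormal(3.7, 0.5, size=(4 * n_sets, 7))
        eta = 1.5 * (pm[:, 0] > 55.0)
        case = np.zeros(4 * n_sets, int)
        for s in range(n_sets):
            m = slice(4 * s, 4 * s + 4)
            w = np.exp(eta[m] - eta[m].max())
            case[4 * s + rng.choice(4, p=w / w.sum())] = 1
        gate = clogit.linearity_gate(pm, sets, case)
        assert gate["choice"] == "ncs-dlnm"
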