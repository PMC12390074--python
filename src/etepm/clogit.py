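"""Conditional logistic regression for 1:M matched sets.

With exactly one case per matched set the exact conditional likelihood is

    L(beta) = prod_sets  exp(x_case' beta) / sum_{j in set} exp(x_j' beta)

(the softmax probability that the case, among set members, is the one with
the event), so no tie approximation is needed.  The solver is Newton-Raphson
with analytic gradient and observed information, log-sum-exp stabilised
set-level denominators, and step-halving when a step would decrease the
log-likelihood.  The covariance of the estimate is the inverse observed
information at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .basis import BasisSpec, ModelDesign, cross_basis, lag_knots_log

__all__ = ["FitResult", "fit", "lr_test", "linearity_gate", "null_loglik"]

_MAX_ITER = 100
_GRAD_TOL = 1e-8
_STEP_TOL = 1e-10
_SEPARATION_BETA = 15.0


@dataclass
class FitResult:
    """Maximum conditional-likelihood estimate for one model."""

    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_sets: int
    converged: bool
    iterations: int

    def to_json(self) -> str:
        return json.dumps({
            "beta": self.beta.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "n_sets": self.n_sets,
            "converged": self.converged,
            "iterations": self.iterations,
        })

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        d = json.loads(s)
        return cls(beta=np.asarray(d["beta"]), vcov=np.asarray(d["vcov"]),
                   loglik=d["loglik"], n_sets=d["n_sets"],
                   converged=d["converged"], iterations=d["iterations"])


def _group_rows(set_id):
    """Stable sort order plus reduceat boundaries for the matched sets."""
    codes, _ = pd_factorize(set_id)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(sorted_codes)) + 1))
    return order, starts


def pd_factorize(values):
    """Integer codes for arbitrary set labels (hashable or array-like)."""
    arr = np.asarray(values)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes, uniq


def null_loglik(set_sizes) -> float:
    """Log-likelihood at beta = 0: minus the sum of log set sizes."""
    return float(-np.sum(np.log(np.asarray(set_sizes, dtype=float))))


def _ll_grad_info(X, is_case, starts, set_of_row, beta, want_derivs=True):
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - m[set_of_row])
    denom = np.add.reduceat(w, starts)
    ll = float(eta[is_case].sum() - np.sum(np.log(denom) + m))
    if not want_derivs:
        return ll, None, None
    p = w / denom[set_of_row]
    grad = X[is_case].sum(axis=0) - X.T @ p
    pX = p[:, None] * X
    M = np.add.reduceat(pX, starts, axis=0)
    info = X.T @ pX - M.T @ M
    return ll, grad, info


def fit(X, set_id, is_case, max_iter: int = _MAX_ITER, start=None) -> FitResult:
    """Fit the conditional logistic model.

    Parameters
    ----------
    X : (n_rows, p) design matrix of person-day covariates.
    set_id : per-row matched-set label (one case per set required).
    is_case : per-row 0/1 indicator of the case day.

    Raises
    ------
    ValueError if a set lacks exactly one case or has no controls.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    is_case = np.asarray(is_case).astype(bool)
    order, starts = _group_rows(set_id)
    Xs, cs = X[order], is_case[order]
    n_sets = starts.size
    sizes = np.diff(np.concatenate((starts, [Xs.shape[0]])))
    if np.any(sizes < 2):
        raise ValueError("every matched set needs at least one control")
    cases_per_set = np.add.reduceat(cs.astype(int), starts)
    if np.any(cases_per_set != 1):
        raise ValueError("every matched set must contain exactly one case")
    set_of_row = np.repeat(np.arange(n_sets), sizes)

    p = Xs.shape[1]
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    ll, grad, info = _ll_grad_info(Xs, cs, starts, set_of_row, beta)
    converged = False
    it = 0

    def gtol(ll_val):
        # the gradient is a sum over all person-days, so its float64 noise
        # floor grows with the log-likelihood magnitude; keep the strict
        # absolute tolerance for small problems and scale it up with |ll|
        return max(_GRAD_TOL, 4e-12 * (1.0 + abs(ll_val)))

    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < gtol(ll):
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving: never accept a decrease in log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = _ll_grad_info(Xs, cs, starts, set_of_row, cand,
                                   want_derivs=False)[0]
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        if np.max(np.abs(scale * step)) < _STEP_TOL:
            beta = cand
            ll, grad, info = _ll_grad_info(Xs, cs, starts, set_of_row, beta)
            converged = bool(np.max(np.abs(grad)) < max(1e-6, gtol(ll)))
            break
        beta = beta + scale * step
        ll, grad, info = _ll_grad_info(Xs, cs, starts, set_of_row, beta)
        if np.max(np.abs(beta)) > _SEPARATION_BETA \
                and np.max(np.abs(grad)) > max(1e-6, gtol(ll)):
            converged = False  # separation: likelihood unbounded
            break
    else:
        converged = bool(np.max(np.abs(grad)) < max(1e-6, gtol(ll)))

    if np.max(np.abs(grad)) < gtol(ll):
        converged = True
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    return FitResult(beta=beta, vcov=vcov, loglik=ll, n_sets=int(n_sets),
                     converged=converged, iterations=it)


def lr_test(fit_full: FitResult, fit_reduced: FitResult):
    """Likelihood-ratio test of nested conditional logistic models.

    Returns (chi2, df, p); chi2 is clipped at zero.
    """
    if fit_full.n_sets != fit_reduced.n_sets:
        raise ValueError("models were fit on different matched sets")
    df = fit_full.beta.size - fit_reduced.beta.size
    if df < 0:
        raise ValueError("reduced model has more columns than the full model")
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def linearity_gate(lagged_pm, set_id, is_case, adjust=None, alpha: float = 0.05,
                   n_exposure_knots: int = 2, lag_spec: BasisSpec = None):
    """Choose between a linear DLM and a spline DLNM for the PM2.5 exposure.

    Fits the natural-cubic-spline exposure model (3 df: 2 interior knots
    placed at equal intervals on the log-exposure scale) and the nested
    linear-exposure model over the same lag basis, then applies the
    likelihood-ratio test: if p >= alpha the association is taken as linear.

    Parameters
    ----------
    lagged_pm : (n_rows, max_lag+1) lagged PM2.5 values, µg/m³.
    adjust : optional extra design columns (ndarray) included in both models.

    Returns
    -------
    dict with keys 'choice' ('linear-dlm' | 'ncs-dlnm'), 'p', 'chi2', 'df',
    'fit_linear', 'fit_ncs'.
    """
    lagged_pm = np.asarray(lagged_pm, dtype=float)
    max_lag = lagged_pm.shape[1] - 1
    if lag_spec is None:
        lag_spec = BasisSpec("ncs", interior_knots=tuple(lag_knots_log(max_lag, 2)),
                             boundary_knots=(0.0, float(max_lag)), intercept=True)
    lo, hi = float(lagged_pm.min()), float(lagged_pm.max())
    if lo <= 0:
        raise ValueError("PM2.5 values must be positive for log-scale knots")
    kn = np.exp(np.linspace(np.log(lo), np.log(hi), n_exposure_knots + 2))[1:-1]
    spec_ncs = BasisSpec("ncs", interior_knots=tuple(kn), boundary_knots=(lo, hi))
    spec_lin = BasisSpec("linear", scale=10.0)

    cb_ncs = cross_basis(lagged_pm, spec_ncs, lag_spec)
    cb_lin = cross_basis(lagged_pm, spec_lin, lag_spec)

    def with_adjust(M):
        return M if adjust is None else np.hstack([M, np.asarray(adjust, dtype=float)])

    fit_ncs = fit(with_adjust(cb_ncs.matrix), set_id, is_case)
    fit_lin = fit(with_adjust(cb_lin.matrix), set_id, is_case)
    chi2, df, p = lr_test(fit_ncs, fit_lin)
    choice = "linear-dlm" if p >= alpha else "ncs-dlnm"
    return {"choice": choice, "p": p, "chi2": chi2, "df": df,
            "fit_linear": fit_lin, "fit_ncs": fit_ncs}
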