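"""Exposure-lag cross-basis construction and effect summaries.

A distributed-lag (non)linear model represents the coefficient of an
exposure as a smooth surface over exposure level and lag.  The cross-basis
row for person-day ``t`` is

    M[t, (j, k)] = sum_{l=0..L} f_j(x_{t-l}) * g_k(l)

where ``f`` is the exposure basis (strata indicators, linear, natural cubic
spline) and ``g`` the lag basis (natural cubic spline or polynomial)
evaluated at integer lags.  Cumulative and lag-specific odds ratios are
linear contrasts ``c' beta`` with delta-method standard errors
``sqrt(c' V c)``.

Conventions: the lag basis carries an intercept column; the exposure basis
does not (the reference level is absorbed).  Lag knots default to equal
spacing on the log-lag scale over [log 1, log L]; the alternative
``log(l + 1)`` placement is available via ``plus_one=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BasisSpec",
    "CrossBasisMatrix",
    "ModelDesign",
    "EffectEstimate",
    "ncs_basis",
    "lag_knots_log",
    "eval_basis",
    "cross_basis",
    "cumulative_effect",
    "lag_specific_effect",
]

_Z95 = 1.959963984540054


def ncs_basis(x, interior_knots, boundary_knots, intercept: bool = False) -> np.ndarray:
    """Natural (restricted) cubic spline basis, linear beyond the boundaries.

    Column count = len(interior_knots) + 1 (+1 with intercept).
    """
    x = np.asarray(x, dtype=float).ravel()
    interior = np.asarray(interior_knots, dtype=float)
    b0, b1 = map(float, boundary_knots)
    knots = np.concatenate(([b0], np.sort(interior), [b1]))
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing and inside boundaries")
    if x.size and (knots.min() < x.min() - 1e-9 or knots.max() > x.max() + 1e-9):
        warnings.warn("spline knots lie outside the data-supported range",
                      stacklevel=2)
    K = knots.size
    kK, kKm1 = knots[-1], knots[-2]

    def d(j):
        return (np.clip(x - knots[j], 0, None) ** 3
                - np.clip(x - kK, 0, None) ** 3) / (kK - knots[j])

    dKm1 = (np.clip(x - kKm1, 0, None) ** 3
            - np.clip(x - kK, 0, None) ** 3) / (kK - kKm1)
    cols = [x] + [d(j) - dKm1 for j in range(K - 2)]
    if intercept:
        cols = [np.ones_like(x)] + cols
    return np.column_stack(cols)


def lag_knots_log(max_lag: int = 6, n_knots: int = 2, plus_one: bool = False) -> np.ndarray:
    """Interior lag knots equally spaced on the log-lag scale.

    Default: ``exp`` of equally spaced interior points of [log 1, log L],
    i.e. {L^(1/3), L^(2/3)} for L=6, n=2.  With ``plus_one`` the spacing is
    on log(l + 1) instead.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if plus_one:
        pts = np.linspace(0.0, np.log(max_lag + 1.0), n_knots + 2)[1:-1]
        return np.exp(pts) - 1.0
    pts = np.linspace(0.0, np.log(float(max_lag)), n_knots + 2)[1:-1]
    return np.exp(pts)


@dataclass(frozen=True)
class BasisSpec:
    """One dimension (exposure or lag) of a cross-basis.

    kind: 'strata' (levels with a designated reference), 'linear'
    (x / scale), 'ncs' (natural cubic spline) or 'poly' (scaled polynomial).
    """

    kind: str
    levels: tuple = None
    reference: object = None
    interior_knots: tuple = None
    boundary_knots: tuple = None
    degree: int = None
    scale: float = 1.0
    intercept: bool = False

    def __post_init__(self):
        if self.kind not in ("strata", "linear", "ncs", "poly"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "strata" and (self.levels is None or self.reference is None):
            raise ValueError("strata basis requires levels and a reference")
        if self.kind == "poly" and (self.degree is None or self.degree < 1):
            raise ValueError("poly degree must be >= 1")
        if self.kind == "ncs" and self.boundary_knots is None:
            raise ValueError("ncs basis requires boundary knots")

    @property
    def ncols(self) -> int:
        if self.kind == "strata":
            return len(self.levels) - 1
        if self.kind == "linear":
            return 1 + int(self.intercept)
        if self.kind == "ncs":
            n_int = 0 if self.interior_knots is None else len(self.interior_knots)
            return n_int + 1 + int(self.intercept)
        return self.degree + int(self.intercept)

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def eval_basis(spec: BasisSpec, x) -> np.ndarray:
    """Evaluate the basis at values ``x``; shape (len(x), spec.ncols)."""
    x = np.asarray(x)
    if spec.kind == "strata":
        flat = x.ravel()
        levels = list(spec.levels)
        known = np.isin(flat, np.asarray(levels))
        if not np.all(known):
            raise ValueError(f"strata values outside declared levels {levels}")
        non_ref = [lv for lv in levels if lv != spec.reference]
        return np.column_stack([(flat == lv).astype(float) for lv in non_ref])
    xf = x.astype(float).ravel()
    if spec.kind == "linear":
        cols = [xf / spec.scale]
        if spec.intercept:
            cols = [np.ones_like(xf)] + cols
        return np.column_stack(cols)
    if spec.kind == "ncs":
        return ncs_basis(xf, spec.interior_knots or (), spec.boundary_knots,
                         spec.intercept)
    # poly, scaled to avoid ill-conditioning
    z = xf / spec.scale
    cols = [z ** d for d in range(1, spec.degree + 1)]
    if spec.intercept:
        cols = [np.ones_like(z)] + cols
    return np.column_stack(cols)


@dataclass
class CrossBasisMatrix:
    """Cross-basis expansion of a person-day x lag exposure history."""

    matrix: np.ndarray            # (n, J*K), column order (j outer, k inner)
    var_spec: BasisSpec
    lag_spec: BasisSpec
    max_lag: int

    @property
    def ncols(self) -> int:
        return self.matrix.shape[1]

    def lag_basis_values(self) -> np.ndarray:
        """g_k(l) for l = 0..max_lag; shape (max_lag+1, K)."""
        return eval_basis(self.lag_spec, np.arange(self.max_lag + 1.0))


def cross_basis(lagged_exposure, var_spec: BasisSpec, lag_spec: BasisSpec) -> CrossBasisMatrix:
    """Build the cross-basis matrix from an (n, max_lag+1) lagged-exposure array.

    Column (j, k) of row t equals ``sum_l f_j(x[t, l]) * g_k(l)``.
    """
    lagged = np.asarray(lagged_exposure)
    if lagged.ndim != 2:
        raise ValueError("lagged_exposure must be 2-D (person-days x lags)")
    n, L1 = lagged.shape
    F = eval_basis(var_spec, lagged.ravel()).reshape(n, L1, -1)
    G = eval_basis(lag_spec, np.arange(L1, dtype=float))
    M = np.einsum("nlj,lk->njk", F, G).reshape(n, -1)
    return CrossBasisMatrix(matrix=M, var_spec=var_spec, lag_spec=lag_spec,
                            max_lag=L1 - 1)


@dataclass
class ModelDesign:
    """Named cross-basis blocks concatenated into one design matrix."""

    blocks: dict = field(default_factory=dict)

    def add(self, name: str, cb: CrossBasisMatrix) -> "ModelDesign":
        self.blocks[name] = cb
        return self

    def matrix(self) -> np.ndarray:
        return np.hstack([cb.matrix for cb in self.blocks.values()])

    def col_slice(self, name: str) -> slice:
        start = 0
        for key, cb in self.blocks.items():
            if key == name:
                return slice(start, start + cb.ncols)
            start += cb.ncols
        raise KeyError(name)

    @property
    def ncols(self) -> int:
        return sum(cb.ncols for cb in self.blocks.values())


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio with 95% CI on both OR and log-OR scales."""

    or_: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float

    def as_dict(self) -> dict:
        return {"or": self.or_, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "log_or": self.log_or, "se": self.se}


def _exposure_contrast(cb: CrossBasisMatrix, contrast) -> np.ndarray:
    """f_j evaluated at the requested contrast (level vs reference or delta-x)."""
    spec = cb.var_spec
    if spec.kind == "strata":
        if contrast == spec.reference:
            raise ValueError("contrast level equals the reference")
        return eval_basis(spec, np.asarray([contrast]))[0]
    if spec.kind == "linear":
        return np.asarray([float(contrast) / spec.scale])
    if spec.kind in ("ncs", "poly"):
        x1, x0 = contrast  # value vs reference value
        f = eval_basis(spec, np.asarray([x1, x0], dtype=float))
        return f[0] - f[1]
    raise ValueError(spec.kind)


def _effect(fit, design: ModelDesign, block: str, contrast, lag=None) -> EffectEstimate:
    cb = design.blocks[block]
    f = _exposure_contrast(cb, contrast)
    G = cb.lag_basis_values()
    g = G[int(lag)] if lag is not None else G.sum(axis=0)
    c_block = np.outer(f, g).ravel()
    c = np.zeros(design.ncols)
    c[design.col_slice(block)] = c_block
    log_or = float(c @ fit.beta)
    var = float(c @ fit.vcov @ c)
    if var < 0 or not np.isfinite(var):
        raise ValueError("invalid contrast variance (singular covariance?)")
    se = np.sqrt(var)
    return EffectEstimate(
        or_=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        log_or=log_or, se=se,
    )


def cumulative_effect(fit, design: ModelDesign, block: str, contrast) -> EffectEstimate:
    """Cumulative (lag 0..L summed) odds ratio for the given contrast."""
    return _effect(fit, design, block, contrast, lag=None)


def lag_specific_effect(fit, design: ModelDesign, block: str, contrast, lag: int) -> EffectEstimate:
    """Single-lag odds ratio; the lag-specific log-ORs sum to the cumulative one."""
    cb = design.blocks[block]
    if not 0 <= int(lag) <= cb.max_lag:
        raise ValueError(f"lag must lie in [0, {cb.max_lag}]")
    return _effect(fit, design, block, contrast, lag=int(lag))
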