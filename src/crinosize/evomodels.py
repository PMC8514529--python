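"""Likelihood models of trait evolution on stage-binned time series.

The vector of bin means y is modelled as a single multivariate normal
observation (joint parametrization). Every model adds the per-bin
sampling-error variance eps_i = variance_i / n_i to the covariance
diagonal. Nine models are compared by small-sample corrected AIC:

* StrictStasis  -- mean theta, no evolutionary variance (K = 1)
* Stasis        -- mean theta, iid evolutionary variance omega (K = 2)
* URW           -- unbiased random walk: Cov_ij = vstep * min(t_i, t_j) (K = 2)
* GRW           -- general (directional) random walk: adds drift mstep (K = 3)
* Punc-1        -- two stasis regimes split at one shift point (K = 5)
* Stasis-URW, Stasis-GRW, URW-Stasis, GRW-Stasis
                -- one mode switching to another at a shift point

Maximization profiles the variance parameter on a log scale (coarse scan
plus bounded Brent refinement) with the mean parameters solved in closed
form by GLS at each step; nested models feed their optima into the
richer model's candidate set, which makes the log-likelihood nesting
orderings (StrictStasis <= Stasis <= Punc-1, URW <= GRW) hold by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .series import TraitSeries

__all__ = [
    "MODEL_NAMES",
    "ModelFit",
    "InsufficientDataError",
    "aicc",
    "akaike_weights",
    "fit_grw",
    "fit_urw",
    "fit_stasis",
    "fit_strict_stasis",
    "fit_punc1",
    "fit_mode_shift",
    "fit9",
]

MODEL_NAMES = (
    "StrictStasis",
    "Stasis",
    "URW",
    "GRW",
    "Punc-1",
    "Stasis-URW",
    "Stasis-GRW",
    "URW-Stasis",
    "GRW-Stasis",
)

#: absolute floor (log10 mm^3)^2 applied to sampling-error variances so the
#: joint covariance stays positive definite on noise-free synthetic series
EPS_FLOOR = 1e-10

_LOG2PI = math.log(2.0 * math.pi)


class InsufficientDataError(ValueError):
    """Too few bins for the requested model."""


@dataclass(frozen=True)
class ModelFit:
    """One fitted evolutionary-mode model."""

    model: str
    logL: float
    K: int
    n: int
    params: dict = field(default_factory=dict)
    aicc: float = math.nan
    weight: float | None = None
    shift_index: int | None = None
    shift_stage: str | None = None


# ---------------------------------------------------------------------------
# information criteria


def aicc(logL: float, K: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= K + 1:
        raise ValueError(
            f"AICc correction undefined for n={n} <= K+1={K + 1}"
        )
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1.0) / (n - K - 1.0)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights exp(-Delta_i/2) normalized over the compared set."""
    a = np.asarray(aicc_values, dtype=float)
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


# ---------------------------------------------------------------------------
# profile-likelihood machinery


def _gls_logl(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Maximize the MVN log-likelihood over mean coefficients by GLS.

    Returns (logL, beta) for y ~ N(X beta, V), or (-inf, None) when V is
    numerically indefinite.
    """
    try:
        c = cho_factor(V, lower=True)
    except LinAlgError:
        return -math.inf, None
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    A = X.T @ Vi_X
    b = X.T @ Vi_y
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return -math.inf, None
    resid = y - X @ beta
    q = float(resid @ cho_solve(c, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    n = len(y)
    return -0.5 * (n * _LOG2PI + logdet + q), beta


def _scan_and_refine(objective, u_grid: np.ndarray, u_extra: Sequence[float] = ()):
    """Maximize objective(u) over a coarse grid, Brent-refine, try extras.

    Returns (best_value, best_u, best_payload); objective returns
    (value, payload).
    """
    evals = {}

    def ev(u):
        if u not in evals:
            evals[u] = objective(u)
        return evals[u]

    candidates = list(u_grid) + [u for u in u_extra if np.isfinite(u)]
    best_u = max(candidates, key=lambda u: ev(u)[0])
    step = float(u_grid[1] - u_grid[0]) if len(u_grid) > 1 else 1.0
    lo, hi = best_u - step, best_u + step
    res = minimize_scalar(
        lambda u: -ev(u)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-9},
    )
    if np.isfinite(res.fun):
        ev(float(res.x))
    best_u = max(evals, key=lambda u: evals[u][0])
    return evals[best_u][0], best_u, evals[best_u][1]


def _floored_eps(eps: np.ndarray) -> np.ndarray:
    return np.maximum(np.asarray(eps, dtype=float), EPS_FLOOR)


# -- random walks -----------------------------------------------------------


def _fit_walk(
    y: np.ndarray,
    t: np.ndarray,
    eps: np.ndarray,
    directional: bool,
    u_extra: Sequence[float] = (),
):
    """ML fit of URW/GRW on raw arrays; returns (logL, params, best_u)."""
    n = len(y)
    eps = _floored_eps(eps)
    X = np.column_stack([np.ones(n), t]) if directional else np.ones((n, 1))
    minT = np.minimum.outer(t, t)
    diag_eps = np.diag(eps)

    def objective(u):
        V = math.exp(u) * minT + diag_eps
        return _gls_logl(y, X, V)

    # method-of-moments scale for the step variance
    d, dt = np.diff(y), np.diff(t)
    dt_mean = float(np.mean(dt)) if len(dt) else 1.0
    s2_mom = float(np.var(d)) / dt_mean if len(d) > 1 else float(np.var(y)) + 1.0
    s2_mom = max(s2_mom, 1e-12)
    u0 = math.log(s2_mom)
    grid = np.linspace(u0 - 22.0, u0 + 8.0, 31)
    logL, u_best, beta = _scan_and_refine(objective, grid, u_extra)
    params = {"anc": float(beta[0]), "vstep": math.exp(u_best)}
    if directional:
        params["mstep"] = float(beta[1])
    return logL, params, u_best


def fit_urw(series: TraitSeries) -> ModelFit:
    """Unbiased random walk: y_i = anc + Brownian(vstep * t_i) + noise."""
    n = len(series)
    if n < 3:
        raise InsufficientDataError(f"URW needs >= 3 bins, got {n}")
    logL, params, _ = _fit_walk(series.mean, series.elapsed_time, series.eps, False)
    return ModelFit("URW", logL, 2, n, params)


def fit_grw(series: TraitSeries) -> ModelFit:
    """General (directional) random walk with drift mstep per Myr."""
    n = len(series)
    if n < 3:
        raise InsufficientDataError(f"GRW needs >= 3 bins, got {n}")
    # seed with the URW optimum so the nested fit can never win
    _, _, u_urw = _fit_walk(series.mean, series.elapsed_time, series.eps, False)
    logL, params, _ = _fit_walk(
        series.mean, series.elapsed_time, series.eps, True, u_extra=[u_urw]
    )
    return ModelFit("GRW", logL, 3, n, params)


# -- stasis -----------------------------------------------------------------


def _stasis_logl_at(y: np.ndarray, eps: np.ndarray, omega: float):
    v = omega + eps
    theta = float(np.sum(y / v) / np.sum(1.0 / v))
    ll = -0.5 * float(np.sum(np.log(2.0 * math.pi * v) + (y - theta) ** 2 / v))
    return ll, theta


def _fit_stasis_arrays(y: np.ndarray, eps: np.ndarray, omega_extra: Sequence[float] = ()):
    """ML stasis fit on raw arrays; returns (logL, theta, omega)."""
    eps = _floored_eps(eps)
    scale = max(float(np.var(y)), float(np.mean(eps)), 1e-12)
    u0 = math.log(scale)
    grid = np.linspace(u0 - 22.0, u0 + 6.0, 29)

    def objective(u):
        ll, theta = _stasis_logl_at(y, eps, math.exp(u))
        return ll, theta

    u_extra = [math.log(w) for w in omega_extra if w and w > 0]
    logL, u_best, theta = _scan_and_refine(objective, grid, u_extra)
    omega = math.exp(u_best)
    # omega -> 0 boundary (strict-stasis limit) evaluated exactly
    ll0, theta0 = _stasis_logl_at(y, eps, 0.0)
    if ll0 >= logL:
        logL, theta, omega = ll0, theta0, 0.0
    return logL, theta, omega


def fit_stasis(series: TraitSeries) -> ModelFit:
    """Stasis: bin means fluctuate iid around an optimum theta with variance omega."""
    n = len(series)
    if n < 2:
        raise InsufficientDataError(f"Stasis needs >= 2 bins, got {n}")
    logL, theta, omega = _fit_stasis_arrays(series.mean, series.eps)
    return ModelFit("Stasis", logL, 2, n, {"theta": theta, "omega": omega})


def fit_strict_stasis(series: TraitSeries) -> ModelFit:
    """Strict stasis: omega = 0, only sampling error around theta."""
    n = len(series)
    if n < 2:
        raise InsufficientDataError(f"StrictStasis needs >= 2 bins, got {n}")
    logL, theta = _stasis_logl_at(series.mean, _floored_eps(series.eps), 0.0)
    return ModelFit("StrictStasis", logL, 1, n, {"theta": theta})


# -- shift models -----------------------------------------------------------

_SEGMENT_K = {"stasis": 2, "urw": 2, "grw": 3}


def _fit_segment(mode: str, y, t, eps, hints):
    """Fit one regime on a sub-series (time re-zeroed); returns (logL, params)."""
    if mode == "stasis":
        logL, theta, omega = _fit_stasis_arrays(y, eps, omega_extra=hints.get("omega", ()))
        return logL, {"theta": theta, "omega": omega}
    if mode in ("urw", "grw"):
        directional = mode == "grw"
        logL, params, _ = _fit_walk(y, t, eps, directional, u_extra=hints.get("u", ()))
        return logL, params
    raise ValueError(f"unknown segment mode {mode!r}; expected stasis/urw/grw")


def fit_mode_shift(
    series: TraitSeries,
    mode1: str,
    mode2: str,
    minb: int = 5,
    name: str | None = None,
    hints: dict | None = None,
) -> ModelFit:
    """One evolutionary mode switching to another at a single shift point.

    The shift index r (first bin of the second regime) is profiled over
    minb <= r <= n - minb; each segment is fitted independently with its
    own level (the second regime's level is a free parameter, not anchored
    to the first regime's endpoint) and its elapsed time restarted at the
    shift. K = K(mode1) + K(mode2) + 1 for the shift point itself.
    """
    n = len(series)
    if minb < 2:
        raise ValueError("minb must be >= 2")
    if n < 2 * minb:
        raise InsufficientDataError(
            f"shift model needs >= {2 * minb} bins (minb={minb}), got {n}"
        )
    hints = hints or {}
    y, t, eps = series.mean, series.elapsed_time, series.eps
    best = None
    for r in range(minb, n - minb + 1):
        l1, p1 = _fit_segment(mode1, y[:r], t[:r] - t[0], eps[:r], hints)
        l2, p2 = _fit_segment(mode2, y[r:], t[r:] - t[r], eps[r:], hints)
        total = l1 + l2
        if best is None or total > best[0]:
            best = (total, r, p1, p2)
    logL, r, p1, p2 = best
    params = {f"seg1_{k}": v for k, v in p1.items()}
    params.update({f"seg2_{k}": v for k, v in p2.items()})
    K = _SEGMENT_K[mode1] + _SEGMENT_K[mode2] + 1
    label = name or f"{mode1.upper() if mode1 != 'stasis' else 'Stasis'}-" \
        f"{mode2.upper() if mode2 != 'stasis' else 'Stasis'}"
    return ModelFit(
        label, logL, K, n, params, shift_index=r, shift_stage=series.stages[r]
    )


def fit_punc1(series: TraitSeries, minb: int = 5) -> ModelFit:
    """Single punctuation: two stasis regimes split at one shift point."""
    # feeding the whole-series stasis optimum into each segment guarantees
    # logL(Punc-1) >= logL(Stasis)
    hints = {}
    if len(series) >= 2:
        _, _, omega = _fit_stasis_arrays(series.mean, series.eps)
        hints["omega"] = (omega,)
    return fit_mode_shift(series, "stasis", "stasis", minb, name="Punc-1", hints=hints)


# ---------------------------------------------------------------------------
# the nine-model comparison


def fit9(series: TraitSeries, minb: int = 5) -> list[ModelFit]:
    """Fit all nine models, attach AICc and Akaike weights, sort by weight.

    Series shorter than 2*minb bins get only the four simple models
    (StrictStasis, Stasis, URW, GRW), with the weights renormalized over
    that reduced set. Ties in weight are broken toward fewer parameters,
    then canonical model order.
    """
    n = len(series)
    if n < 5:
        raise InsufficientDataError(
            f"model comparison needs >= 5 bins for the AICc correction, got {n}"
        )
    y, t, eps = series.mean, series.elapsed_time, series.eps

    strict = fit_strict_stasis(series)
    ll_st, theta, omega = _fit_stasis_arrays(y, eps)
    stasis = ModelFit("Stasis", ll_st, 2, n, {"theta": theta, "omega": omega})
    ll_urw, p_urw, u_urw = _fit_walk(y, t, eps, False)
    urw = ModelFit("URW", ll_urw, 2, n, p_urw)
    ll_grw, p_grw, u_grw = _fit_walk(y, t, eps, True, u_extra=[u_urw])
    grw = ModelFit("GRW", ll_grw, 3, n, p_grw)
    fits = [strict, stasis, urw, grw]

    if n >= 2 * minb and n > 6:  # complex models have K = 5
        hints = {"omega": (omega,), "u": (u_urw, u_grw)}
        fits.append(fit_mode_shift(series, "stasis", "stasis", minb, "Punc-1", hints))
        fits.append(fit_mode_shift(series, "stasis", "urw", minb, "Stasis-URW", hints))
        fits.append(fit_mode_shift(series, "stasis", "grw", minb, "Stasis-GRW", hints))
        fits.append(fit_mode_shift(series, "urw", "stasis", minb, "URW-Stasis", hints))
        fits.append(fit_mode_shift(series, "grw", "stasis", minb, "GRW-Stasis", hints))

    aiccs = [aicc(f.logL, f.K, f.n) for f in fits]
    weights = akaike_weights(aiccs)
    order = {name: i for i, name in enumerate(MODEL_NAMES)}
    fits = [
        replace(f, aicc=a, weight=float(w))
        for f, a, w in zip(fits, aiccs, weights)
    ]
    fits.sort(key=lambda f: (-f.weight, f.K, order[f.model]))
    return fits
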