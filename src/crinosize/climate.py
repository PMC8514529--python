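"""Temperature-body-size regression with AR(1) errors.

Fits y_t = beta0 + beta1 * x_t + e_t with e_t = phi * e_{t-1} + eta_t,
eta_t ~ N(0, sigma2), by exact maximum likelihood: for a candidate phi
the model is reduced to OLS by the Prais-Winsten transform, beta and
sigma2 drop out in closed form, and the resulting profile likelihood is
maximized over phi in (-1, 1). AR0 constrains phi = 0 (plain OLS).
Predictor and intercept-only null fits under the same error structure
are compared pairwise by AICc. delta-18-O series can be used as an
inverse temperature proxy via a sign flip at load time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .series import TraitSeries
from .timescale import GeologicTimescale

__all__ = [
    "GLSFit",
    "NullComparison",
    "align_series",
    "gls_fit",
    "compare_to_null",
    "detrend",
]

_LOG2PI = math.log(2.0 * math.pi)
_PHI_BOUND = 0.999
_PHI_WARN = 0.98


@dataclass(frozen=True)
class GLSFit:
    """ML fit of a (possibly AR(1)-correlated) linear regression."""

    beta0: float
    beta1: float | None
    phi: float
    sigma2: float
    logL: float
    K: int
    aicc: float
    n: int
    nonstationary: bool = False


def _prais_winsten(z: np.ndarray, phi: float) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    out[0] = math.sqrt(1.0 - phi * phi) * z[0]
    out[1:] = z[1:] - phi * z[:-1]
    return out


def _profile_logl(y: np.ndarray, X: np.ndarray, phi: float):
    """Profile logL over (beta, sigma2) at fixed phi."""
    ys = _prais_winsten(y, phi)
    Xs = np.column_stack([_prais_winsten(X[:, j], phi) for j in range(X.shape[1])])
    beta, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    if rank < X.shape[1]:
        return -math.inf, beta, math.nan
    rss = float(np.sum((ys - Xs @ beta) ** 2))
    n = len(y)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    logL = -0.5 * n * (_LOG2PI + 1.0 + math.log(sigma2)) + 0.5 * math.log(1.0 - phi * phi)
    return logL, beta, sigma2


def gls_fit(y, x=None, ar: str = "ar1") -> GLSFit:
    """Exact-ML GLS regression of y on x with AR0 or AR1 errors.

    ``x=None`` fits the intercept-only null. K counts beta0 (+beta1 if x
    given) + sigma2 (+phi for AR1); AICc therefore needs n >= K + 2.
    """
    ar = ar.lower()
    if ar not in ("ar0", "ar1"):
        raise ValueError(f"ar must be 'ar0' or 'ar1', got {ar!r}")
    y = np.asarray(y, dtype=float)
    if x is None:
        X = np.ones((len(y), 1))
    else:
        x = np.asarray(x, dtype=float)
        if len(x) != len(y):
            raise ValueError("y and x must have equal length")
        if np.ptp(x) == 0:
            raise ValueError("predictor x is constant; regression is degenerate")
        X = np.column_stack([np.ones(len(y)), x])
    K = X.shape[1] + 1 + (1 if ar == "ar1" else 0)
    n = len(y)
    if n < K + 2:
        raise ValueError(
            f"insufficient data: n={n} < K+2={K + 2} for {ar.upper()} "
            f"with {X.shape[1]} mean parameters"
        )

    if ar == "ar0":
        phi = 0.0
        logL, beta, sigma2 = _profile_logl(y, X, phi)
    else:
        res = minimize_scalar(
            lambda p: -_profile_logl(y, X, p)[0],
            bounds=(-_PHI_BOUND, _PHI_BOUND),
            method="bounded",
            options={"xatol": 1e-10},
        )
        phi = float(res.x)
        # phi = 0 evaluated explicitly so AR1 can never fall below AR0
        if _profile_logl(y, X, 0.0)[0] > -res.fun:
            phi = 0.0
        logL, beta, sigma2 = _profile_logl(y, X, phi)

    nonstat = abs(phi) > _PHI_WARN
    if nonstat:
        warnings.warn(
            f"AR(1) coefficient at boundary (phi={phi:.4f}); "
            "errors are close to nonstationary",
            stacklevel=2,
        )
    return GLSFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]) if X.shape[1] == 2 else None,
        phi=phi,
        sigma2=float(sigma2),
        logL=float(logL),
        K=K,
        aicc=-2.0 * logL + 2.0 * K + 2.0 * K * (K + 1.0) / (n - K - 1.0),
        n=n,
        nonstationary=nonstat,
    )


@dataclass(frozen=True)
class NullComparison:
    """Paired AICc comparison of predictor model vs intercept-only null."""

    predictor: GLSFit
    null: GLSFit
    delta_aicc: float  # AICc(null) - AICc(predictor); > 0 favours the predictor
    supported: str  # "predictor" or "null"


def compare_to_null(y, x, ar: str = "ar1") -> NullComparison:
    """Fit the temperature-predictor model and its null under the same AR order."""
    pred = gls_fit(y, x, ar=ar)
    null = gls_fit(y, None, ar=ar)
    delta = null.aicc - pred.aicc
    return NullComparison(
        predictor=pred,
        null=null,
        delta_aicc=float(delta),
        supported="predictor" if delta > 0 else "null",
    )


def detrend(values, mode: str = "diff") -> np.ndarray:
    """Remove a trend from a series.

    ``diff`` (default): first differences of successive values (length
    n-1). ``linear``: residuals from an OLS line against the index
    (length n).
    """
    v = np.asarray(values, dtype=float)
    if mode == "diff":
        return np.diff(v)
    if mode == "linear":
        idx = np.arange(len(v), dtype=float)
        coeffs = np.polyfit(idx, v, 1)
        return v - np.polyval(coeffs, idx)
    raise ValueError(f"unknown detrend mode {mode!r}; expected 'diff' or 'linear'")


def align_series(
    size_series: TraitSeries,
    climate: pd.DataFrame,
    timescale: GeologicTimescale,
    invert: bool = False,
) -> pd.DataFrame:
    """Pair stage-binned sizes with a proxy curve sampled at (age_ma, value).

    Each stage's climate value is the mean of all curve samples whose age
    falls inside the stage's [top_ma, base_ma] span. Stages lacking either
    variable are dropped with a warning; ``invert`` flips the sign for
    inverse proxies such as delta-18-O.
    """
    required = {"age_ma", "value"}
    if not required <= set(climate.columns):
        raise ValueError(f"climate table needs columns {sorted(required)}")
    ages = climate["age_ma"].to_numpy(float)
    vals = climate["value"].to_numpy(float)
    if invert:
        vals = -vals

    rows, dropped = [], []
    for i, stage in enumerate(size_series.stages):
        mask = (ages >= timescale.top_ma(stage)) & (ages <= timescale.base_ma(stage))
        if not mask.any():
            dropped.append(stage)
            continue
        rows.append(
            {
                "stage": stage,
                "midpoint_ma": timescale.midpoint_ma(stage),
                "elapsed_myr": float(size_series.elapsed_time[i]),
                "size_mean": float(size_series.mean[i]),
                "climate_value": float(vals[mask].mean()),
                "n_curve_samples": int(mask.sum()),
            }
        )
    if not rows:
        raise ValueError("climate curve and size series share no stage coverage")
    if dropped:
        warnings.warn(f"stages without climate samples dropped: {dropped}", stacklevel=2)
    return pd.DataFrame(rows)
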