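"""Statistical primitives shared by every screening stage.

The pipeline needs a small, fixed set of statistics: Welch's unequal-variance
t-test for replicate comparisons, Benjamini–Hochberg step-up adjustment for
screen-scale multiplicity, per-plate Z-normalization, trapezoidal area under
OD600 growth curves, and a logistic growth-model fit

    N(t) = K / (1 + ((K - N0) / N0) * exp(-r t))

with carrying capacity ``K`` (OD units), intrinsic growth rate ``r`` (per
hour) and inoculum ``N0`` (OD units).  All functions are pure: the same
inputs always give the same outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .errors import DegeneratePlateError, InvalidInputError

__all__ = [
    "WelchResult",
    "LogisticFit",
    "welch_t_test",
    "one_sample_t_test",
    "bh_adjust",
    "zscore",
    "trapezoid_auc",
    "logistic_od",
    "logistic_auc",
    "fit_logistic",
]


@dataclass(frozen=True)
class WelchResult:
    """Two-sided Welch t-test result.

    ``df`` is the Welch–Satterthwaite approximation, which never exceeds the
    pooled ``n1 + n2 - 2``.  Swapping the two samples negates ``t_statistic``
    and ``mean_diff`` and leaves ``p_value`` unchanged.
    """

    t_statistic: float
    df: float
    p_value: float
    mean_diff: float


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic growth parameters.

    ``converged`` is False when the curve carries no usable growth signal
    (flat well) or the optimizer failed; in that case ``growth_rate_r`` is
    NaN and only the empirical AUC of the raw curve is meaningful.
    """

    carrying_capacity_K: float
    growth_rate_r: float
    initial_N0: float
    rss: float
    converged: bool


def _as_sample(x: Sequence[float], name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise InvalidInputError(f"{name} needs at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch (unequal variance) t-test.

    Convention for the degenerate case where both samples have zero variance:
    equal means give ``t = 0, p = 1``; unequal means give an infinite ``t``
    and ``p = 0`` (the samples are then trivially separated).
    """
    a = _as_sample(sample_a, "sample_a")
    b = _as_sample(sample_b, "sample_b")
    n1, n2 = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    if va == 0.0 and vb == 0.0:
        df = float(n1 + n2 - 2)
        if diff == 0.0:
            return WelchResult(0.0, df, 1.0, 0.0)
        return WelchResult(float(np.sign(diff)) * np.inf, df, 0.0, float(diff))
    sa, sb = va / n1, vb / n2
    se = np.sqrt(sa + sb)
    t = diff / se
    # Welch–Satterthwaite degrees of freedom
    df = (sa + sb) ** 2 / (sa**2 / (n1 - 1) + sb**2 / (n2 - 1))
    p = 2.0 * float(special.stdtr(df, -abs(t)))
    return WelchResult(float(t), float(df), min(p, 1.0), float(diff))


def one_sample_t_test(sample: Sequence[float], popmean: float = 0.0) -> WelchResult:
    """One-sample two-sided t-test of ``mean(sample) == popmean``."""
    a = _as_sample(sample, "sample")
    n = a.size
    sd = a.std(ddof=1)
    diff = a.mean() - popmean
    df = float(n - 1)
    if sd == 0.0:
        if diff == 0.0:
            return WelchResult(0.0, df, 1.0, 0.0)
        return WelchResult(float(np.sign(diff)) * np.inf, df, 0.0, float(diff))
    t = diff / (sd / np.sqrt(n))
    p = 2.0 * float(special.stdtr(df, -abs(t)))
    return WelchResult(float(t), df, min(p, 1.0), float(diff))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Each adjusted value is >= its raw value and capped at 1; ranking order is
    preserved and the transform is idempotent on its own output.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise InvalidInputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


def zscore(values: Sequence[float], ddof: int = 1) -> np.ndarray:
    """Center to mean 0 and scale to standard deviation 1 (sample SD by default).

    Raises :class:`DegeneratePlateError` when the values have zero spread so a
    degenerate plate is flagged instead of silently zeroed.
    """
    x = _as_sample(values, "values")
    sd = x.std(ddof=ddof)
    # spread at rounding level counts as zero: flag it rather than amplify noise
    tol = 1e-12 * max(1.0, float(np.abs(x).max()))
    if not np.isfinite(sd) or sd <= tol:
        raise DegeneratePlateError("zero spread: cannot Z-normalize")
    return (x - x.mean()) / sd


def trapezoid_auc(times: Sequence[float], od: Sequence[float]) -> float:
    """Trapezoidal area under an OD-versus-time curve, in OD·hours."""
    t = np.asarray(times, dtype=float).ravel()
    y = np.asarray(od, dtype=float).ravel()
    if t.size != y.size:
        raise InvalidInputError("times and od must have equal length")
    if t.size < 2:
        raise InvalidInputError("need at least 2 time points")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
        raise InvalidInputError("times and od must be finite")
    if np.any(np.diff(t) <= 0.0):
        raise InvalidInputError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


def logistic_od(t, K: float, r: float, N0: float):
    """Logistic growth curve N(t) = K / (1 + ((K-N0)/N0) e^{-rt})."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def logistic_auc(K: float, r: float, N0: float, t_end: float, t_start: float = 0.0) -> float:
    """Closed-form integral of the logistic curve over [t_start, t_end].

    Antiderivative: (K/r) * ln( (N0 (e^{rt} - 1) + K) / K ).
    """

    def antider(t: float) -> float:
        return (K / r) * np.log((N0 * (np.exp(r * t) - 1.0) + K) / K)

    return float(antider(t_end) - antider(t_start))


def _init_growth_rate(t: np.ndarray, y: np.ndarray, K0: float, N0_0: float) -> float:
    # slope of log(OD) over the early quasi-exponential window
    mask = (y > 1.2 * N0_0) & (y < 0.7 * K0) & (y > 0.0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
        if np.isfinite(slope) and slope > 0.0:
            return float(np.clip(slope, 1e-3, 20.0))
    return 0.5


def fit_logistic(
    curve_times: Sequence[float],
    od: Sequence[float],
    min_signal: float = 0.05,
) -> LogisticFit:
    """Nonlinear least-squares fit of the logistic growth model.

    Deterministic initialization: ``K`` from the maximum OD, ``N0`` from the
    first positive OD reading and ``r`` from the slope of log(OD) over the
    early exponential window (fallback 0.5/h).  Curves whose total OD span is
    below ``min_signal`` are flagged non-converged without fitting; their
    empirical AUC remains available through :func:`trapezoid_auc`.
    """
    t = np.asarray(curve_times, dtype=float).ravel()
    y = np.asarray(od, dtype=float).ravel()
    if t.size != y.size:
        raise InvalidInputError("times and od must have equal length")
    if t.size < 8:
        raise InvalidInputError("need at least 8 time points to fit a growth model")
    if np.any(np.diff(t) <= 0.0):
        raise InvalidInputError("times must be strictly increasing")
    if np.any(y < 0.0) or not np.all(np.isfinite(y)):
        raise InvalidInputError("od must be finite and non-negative")

    positive = y[y > 0.0]
    N0_0 = float(positive[0]) if positive.size else 1e-6
    K0 = float(max(y.max(), N0_0 * 1.01, 1e-6))
    span = float(y.max() - y.min())
    if span < min_signal:
        rss = float(np.sum((y - y.mean()) ** 2))
        return LogisticFit(K0, float("nan"), N0_0, rss, False)

    r0 = _init_growth_rate(t, y, K0, N0_0)
    p0 = np.array([K0, r0, N0_0])
    try:
        popt, _ = optimize.curve_fit(
            logistic_od,
            t,
            y,
            p0=p0,
            bounds=(np.array([1e-9, 1e-9, 1e-12]), np.array([np.inf, np.inf, np.inf])),
            method="trf",
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        rss = float(np.sum((y - logistic_od(t, *p0)) ** 2))
        return LogisticFit(K0, float("nan"), N0_0, rss, False)

    K, r, N0 = (float(v) for v in popt)
    rss = float(np.sum((y - logistic_od(t, K, r, N0)) ** 2))
    converged = bool(np.isfinite(rss) and K > 0.0 and r > 0.0 and 0.0 < N0 <= K)
    if not converged:
        return LogisticFit(K, float("nan"), N0, rss, False)
    return LogisticFit(K, r, N0, rss, True)
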