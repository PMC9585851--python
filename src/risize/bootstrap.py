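"""Bootstrap layer: resample RI limits at one candidate n and summarize them.

For a candidate sample size n, B resamples of size n are drawn with
replacement from the reference population; each yields a (lower, upper)
pair of RI limits by the chosen estimator. The B lower limits and B upper
limits form the sampling distributions from which percentile confidence
intervals of each reference limit are taken, and the B interval widths are
condensed to a scalar (median by default) used as the denominator of the
convergence ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AnalytePopulation, normalize_method, quantile
from .errors import ConfigError, DegenerateDataError, InputError

__all__ = ["LimitDistribution", "CIPair", "resample_limits", "percentile_ci", "width_summary"]

WIDTH_SUMMARIES = ("median", "mean", "quintile1", "quintile2", "quintile3", "quintile4")

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class LimitDistribution:
    """The B bootstrap replicates of (lower, upper) RI limits at one n."""

    n: int
    method: str
    lowers: np.ndarray
    uppers: np.ndarray
    widths: np.ndarray
    redraws: int = 0

    def __post_init__(self):
        if not (self.lowers.size == self.uppers.size == self.widths.size):
            raise InputError("limit arrays must have equal length B")

    @property
    def B(self) -> int:
        return int(self.lowers.size)


@dataclass(frozen=True)
class CIPair:
    """90% (by default) percentile CIs of the lower and upper reference limits."""

    lower_ci: tuple[float, float]
    upper_ci: tuple[float, float]
    level: float = 0.90

    def __post_init__(self):
        for lo, hi in (self.lower_ci, self.upper_ci):
            if lo > hi:
                raise InputError("CI endpoints out of order")

    @property
    def lower_width(self) -> float:
        return self.lower_ci[1] - self.lower_ci[0]

    @property
    def upper_width(self) -> float:
        return self.upper_ci[1] - self.upper_ci[0]


def _batch_boxcox_llf(lam: np.ndarray, logx: np.ndarray, slog: np.ndarray) -> np.ndarray:
    """Profile log-likelihood for a per-row λ vector; rows of logx are replicates."""
    n = logx.shape[1]
    lamc = lam[:, None]
    small = np.abs(lamc) < 1e-9
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        y = np.where(small, logx, np.expm1(lamc * logx) / np.where(small, 1.0, lamc))
        var = y.var(axis=1)  # MLE variance, matching the scipy llf form
        llf = (lam - 1.0) * slog - 0.5 * n * np.log(var)
    return np.where(np.isfinite(llf), llf, -np.inf)


def _batch_boxcox_lambda(X: np.ndarray, lo: float = -5.0, hi: float = 5.0,
                         iters: int = 42) -> np.ndarray:
    """Golden-section maximization of the Box-Cox profile llf, one λ per row.

    42 iterations shrink the bracket below 1e-5 of its initial width.
    """
    logx = np.log(X)
    slog = logx.sum(axis=1)
    a = np.full(X.shape[0], lo)
    b = np.full(X.shape[0], hi)
    for _ in range(iters):
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = _batch_boxcox_llf(c, logx, slog)
        fd = _batch_boxcox_llf(d, logx, slog)
        keep_left = fc >= fd
        b = np.where(keep_left, d, b)
        a = np.where(keep_left, a, c)
    return 0.5 * (a + b)


def _batch_parametric_limits(X: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Transformed-parametric limits for each row of X (resamples as rows).

    Rows with non-positive values get a per-row shift 1 − min before the
    transform, mirroring the scalar estimator. Returns (lowers, uppers);
    rows whose fit degenerates come back non-finite for the caller to redraw.
    """
    B, n = X.shape
    mins = X.min(axis=1)
    shift = np.where(mins <= 0.0, 1.0 - mins, 0.0)
    Xs = X + shift[:, None]
    lam = _batch_boxcox_lambda(Xs)
    lamc = lam[:, None]
    small = np.abs(lamc) < 1e-9
    logx = np.log(Xs)
    with np.errstate(over="ignore", invalid="ignore"):
        Y = np.where(small, logx, np.expm1(lamc * logx) / np.where(small, 1.0, lamc))
    m = Y.mean(axis=1)
    s = Y.std(axis=1, ddof=1)
    z = float(stats.norm.ppf(0.5 * (1.0 + level)))
    lo_t, hi_t = m - z * s, m + z * s

    def invert(yv: np.ndarray, at_lower: bool) -> np.ndarray:
        smalll = np.abs(lam) < 1e-9
        arg = lam * yv + 1.0
        with np.errstate(over="ignore", invalid="ignore"):
            out = np.where(
                smalll,
                np.exp(yv),
                np.power(np.maximum(arg, 1e-300), 1.0 / np.where(smalll, 1.0, lam)),
            )
        # clip where outside the transform range: lower limit -> domain boundary 0
        bad = (~smalll) & (arg <= 0.0)
        if at_lower:
            out = np.where(bad & (lam > 0), 0.0, out)
            out = np.where(bad & (lam < 0), np.nan, out)
        else:
            out = np.where(bad & (lam < 0), np.inf, out)
            out = np.where(bad & (lam > 0), np.nan, out)
        return out - shift

    lowers = invert(lo_t, at_lower=True)
    uppers = invert(hi_t, at_lower=False)
    return lowers, uppers


def resample_limits(
    pop: AnalytePopulation,
    n: int,
    B: int,
    method: str,
    rng_seed,
    level: float = 0.95,
) -> LimitDistribution:
    """Draw B size-n resamples with replacement and compute RI limits for each.

    Deterministic for a fixed seed (``rng_seed`` may be an int,
    ``SeedSequence`` or ``Generator``). Degenerate replicates under the
    parametric estimator (constant resample, or a fit whose limits are not
    finite) are redrawn, up to a total budget of 10·B redraws; exhausting the
    budget raises. Constant resamples are valid for the non-parametric
    estimator (a zero-width interval).
    """
    method = normalize_method(method)
    if method == "analytic":
        raise ConfigError("'analytic' is a ground-truth tag, not a resampling method")
    if n < 20:
        raise InputError(f"candidate sample size must be >= 20, got {n}")
    if B < 2:
        raise InputError(f"bootstrap replicate count must be >= 2, got {B}")
    rng = np.random.default_rng(rng_seed)
    X = pop.values[rng.integers(0, pop.n, size=(B, n))]

    alpha = 0.5 * (1.0 - level)
    if method == "nonparametric":
        lowers, uppers = np.quantile(X, [alpha, 1.0 - alpha], axis=1, method="weibull")
        redraws = 0
    else:
        lowers, uppers = _batch_parametric_limits(X, level)
        redraws = 0
        budget = 10 * B
        bad = (np.ptp(X, axis=1) == 0.0) | ~np.isfinite(lowers) | (uppers <= lowers)
        # uppers may be +inf legitimately only for lambda<0 fits; treat as bad for redraw
        bad |= ~np.isfinite(uppers)
        while bad.any():
            k = int(bad.sum())
            if redraws + k > budget:
                raise DegenerateDataError(
                    f"redraw budget exhausted at n={n} for method '{method}': "
                    f"population too degenerate for the parametric fit"
                )
            redraws += k
            Xk = pop.values[rng.integers(0, pop.n, size=(k, n))]
            X[bad] = Xk
            lo_k, hi_k = _batch_parametric_limits(Xk, level)
            lowers[bad] = lo_k
            uppers[bad] = hi_k
            bad = (np.ptp(X, axis=1) == 0.0) | ~np.isfinite(lowers) | ~np.isfinite(uppers) | (uppers <= lowers)

    lowers = np.asarray(lowers, dtype=float)
    uppers = np.asarray(uppers, dtype=float)
    return LimitDistribution(
        n=n, method=method, lowers=lowers, uppers=uppers,
        widths=uppers - lowers, redraws=redraws,
    )


def percentile_ci(samples, level: float = 0.90) -> tuple[float, float]:
    """Percentile bootstrap CI: the ((1−level)/2, (1+level)/2) quantiles."""
    a = np.asarray(samples, dtype=float).ravel()
    if a.size < 2:
        raise InputError("percentile CI requires at least 2 samples")
    if not (0.0 < level < 1.0):
        raise ConfigError("CI level must be in (0, 1)")
    alpha = 0.5 * (1.0 - level)
    lo, hi = quantile(a, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def ci_pair(dist: LimitDistribution, level: float = 0.90) -> CIPair:
    """Percentile CIs of both reference limits from one limit distribution."""
    return CIPair(
        lower_ci=percentile_ci(dist.lowers, level),
        upper_ci=percentile_ci(dist.uppers, level),
        level=level,
    )


def width_summary(dist: LimitDistribution | np.ndarray, summary: str = "median") -> float:
    """Scalar summary of the B bootstrap RI widths.

    ``median`` (default) and ``mean``, plus ``quintile1``..``quintile4`` (the
    20/40/60/80th percentiles) for sensitivity analysis of the convergence
    ratio denominator.
    """
    widths = dist.widths if isinstance(dist, LimitDistribution) else np.asarray(dist, float)
    if widths.size == 0:
        raise InputError("width summary of an empty distribution")
    if summary == "median":
        return float(quantile(widths, 0.5))
    if summary == "mean":
        return float(widths.mean())
    if summary in WIDTH_SUMMARIES:  # quintile1..4
        k = int(summary[-1])
        return float(quantile(widths, 0.2 * k))
    raise ConfigError(
        f"unknown width summary {summary!r}; expected one of {WIDTH_SUMMARIES}"
    )
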