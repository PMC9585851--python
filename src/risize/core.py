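"""Reference-interval core: outlier filtering, normality, Box-Cox, RI estimators.

A 95% reference interval (RI) spans the central 95% of an analyte's
distribution in a healthy reference population, bounded by the 2.5th and
97.5th percentile reference limits. Two estimators are provided:

* **transformed parametric** — Box-Cox transform the data toward normality,
  take mean ± z·SD on the transformed scale, back-transform the limits;
* **non-parametric** — empirical 2.5th/97.5th percentiles.

All percentiles in the package use one quantile convention: linear
interpolation of order statistics at rank r = p(n+1) (Weibull plotting
position, the CLSI convention for non-parametric reference limits), with
ranks outside [1, n] clipped to the extreme order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import ConfigError, DomainError, InputError

__all__ = [
    "AnalytePopulation",
    "TukeyResult",
    "NormalityReport",
    "BoxCoxTransform",
    "ReferenceInterval",
    "quantile",
    "tukey_filter",
    "ks_normality",
    "boxcox_fit",
    "boxcox_apply",
    "boxcox_invert",
    "parametric_ri",
    "nonparametric_ri",
]

#: RI estimator tags. "analytic" marks ground-truth intervals from a known
#: generating distribution (synthetic module), not an estimator.
METHOD_TAGS = ("transformed_parametric", "nonparametric", "analytic")

_METHOD_ALIASES = {
    "parametric": "transformed_parametric",
    "transformed_parametric": "transformed_parametric",
    "nonparametric": "nonparametric",
    "non-parametric": "nonparametric",
    "analytic": "analytic",
}


def normalize_method(method: str) -> str:
    """Map user-facing method names onto canonical tags."""
    try:
        return _METHOD_ALIASES[method]
    except KeyError:
        raise ConfigError(
            f"unknown RI method {method!r}; expected one of "
            "'transformed_parametric' (alias 'parametric') or 'nonparametric'"
        ) from None


def quantile(values: Sequence[float] | np.ndarray, p, axis=None) -> np.ndarray | float:
    """Package-wide quantile: rank r = p(n+1), linear interpolation, clipped.

    This is numpy's ``method="weibull"``; it matches the CLSI rank convention
    for non-parametric reference limits and is used everywhere a percentile
    is taken (reference limits, bootstrap CIs, quartiles, width summaries).
    """
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise InputError("quantile of an empty sequence")
    return np.quantile(a, p, axis=axis, method="weibull")


def _as_1d_floats(values, what: str) -> np.ndarray:
    a = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise InputError(f"{what} must be finite (got NaN or inf)")
    return a


@dataclass(frozen=True)
class AnalytePopulation:
    """One analyte's cleaned measurements for a reference population.

    Immutable: the sample-size search resamples from it, never mutates it.
    """

    values: np.ndarray
    analyte_name: str = "analyte"
    unit: str = ""

    def __post_init__(self):
        a = _as_1d_floats(self.values, "population values")
        if a.size < 1:
            raise InputError("population must contain at least 1 value")
        a.setflags(write=False)
        object.__setattr__(self, "values", a)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TukeyResult:
    """Outcome of Tukey fence filtering (values kept in input order)."""

    kept: np.ndarray
    removed: np.ndarray
    lower_fence: float
    upper_fence: float

    @property
    def n_removed(self) -> int:
        return int(self.removed.size)


@dataclass(frozen=True)
class NormalityReport:
    """Kolmogorov-Smirnov (Lilliefors) normality assessment."""

    statistic: float
    p_value: float
    is_normal: bool
    note: str = ""


@dataclass(frozen=True)
class BoxCoxTransform:
    """A fitted Box-Cox power transform y = ((x+shift)^λ − 1)/λ (λ≠0), ln(x+shift) (λ=0).

    ``shift`` is the non-negative offset added before transforming so that
    all inputs are strictly positive; it is 0 when the data already are.
    """

    lmbda: float
    shift: float = 0.0

    def __post_init__(self):
        if self.shift < 0:
            raise ConfigError("Box-Cox shift must be non-negative")


@dataclass(frozen=True)
class ReferenceInterval:
    """A (lower, upper) reference interval with method and transform metadata."""

    lower: float
    upper: float
    level: float = 0.95
    method: str = "nonparametric"
    transform: BoxCoxTransform | None = None
    n_used: int = 0
    clipped: bool = False

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise ConfigError("RI level must be in (0, 1)")
        if self.lower > self.upper:
            raise InputError("reference interval has lower > upper")
        if self.method not in METHOD_TAGS:
            raise ConfigError(f"unknown method tag {self.method!r}")
        if (self.transform is not None) != (self.method == "transformed_parametric"):
            raise ConfigError(
                "transform metadata present iff method is 'transformed_parametric'"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def tukey_filter(values) -> TukeyResult:
    """Identify outliers by Tukey's fences Q1 − 1.5·IQR and Q3 + 1.5·IQR.

    Quartiles use the package quantile convention. Kept values preserve the
    input order. Requires at least 4 values so quartiles are defined.
    """
    a = _as_1d_floats(values, "values")
    if a.size < 4:
        raise InputError(
            f"Tukey filtering requires at least 4 values, got {a.size}"
        )
    q1, q3 = quantile(a, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (a >= lo) & (a <= hi)
    return TukeyResult(kept=a[mask], removed=a[~mask], lower_fence=float(lo), upper_fence=float(hi))


def ks_normality(values, alpha: float = 0.05) -> NormalityReport:
    """Kolmogorov-Smirnov normality check with parameters estimated from data.

    Uses the Lilliefors correction (plain KS against fitted parameters is
    anti-conservative). A constant input cannot be normal in any useful sense
    and is reported as non-normal with a note rather than raising.
    """
    a = _as_1d_floats(values, "values")
    if a.size < 5:
        raise InputError(f"normality test requires at least 5 values, got {a.size}")
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must be in (0, 1)")
    if np.ptp(a) == 0.0:
        return NormalityReport(
            statistic=1.0, p_value=0.0, is_normal=False,
            note="degenerate input: all values equal, normality undefined",
        )
    from statsmodels.stats.diagnostic import lilliefors

    stat, pval = lilliefors(a, dist="norm")
    return NormalityReport(
        statistic=float(stat), p_value=float(pval), is_normal=bool(pval >= alpha)
    )


def _profile_llf(lmbda: float, x: np.ndarray) -> float:
    # scipy's boxcox_llf: (λ−1)Σln x − n/2 · ln(var_MLE(y))
    return float(stats.boxcox_llf(lmbda, x))


def boxcox_fit(values, bounds: tuple[float, float] = (-5.0, 5.0)) -> BoxCoxTransform:
    """Fit λ by maximizing the Box-Cox profile log-likelihood over ``bounds``.

    Non-positive data are shifted by 1 − min(values) first. The bounded
    scalar optimizer runs at tolerance 1e-5; near-ties are broken toward the
    simpler transform (smaller \\|λ\\|, preferring λ=0 exactly when it is as good).
    """
    a = _as_1d_floats(values, "values")
    if a.size < 2 or np.ptp(a) == 0.0:
        raise InputError("Box-Cox likelihood undefined for constant input")
    mn = a.min()
    shift = 1.0 - mn if mn <= 0.0 else 0.0
    x = a + shift
    res = optimize.minimize_scalar(
        lambda l: -_profile_llf(l, x),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-5},
    )
    lam = float(res.x)
    best = _profile_llf(lam, x)
    # tie-break toward smaller |lambda|
    for cand in (0.0, -lam):
        if abs(cand) < abs(lam) and _profile_llf(cand, x) >= best - 1e-9:
            lam = cand
            break
    return BoxCoxTransform(lmbda=lam, shift=shift)


def boxcox_apply(values, t: BoxCoxTransform) -> np.ndarray:
    """Apply a fitted Box-Cox transform; shifted values must be positive."""
    a = _as_1d_floats(values, "values")
    x = a + t.shift
    if np.any(x <= 0.0):
        raise DomainError("Box-Cox requires strictly positive (shifted) values")
    return special.boxcox(x, t.lmbda)


def boxcox_invert(values, t: BoxCoxTransform) -> np.ndarray:
    """Exact inverse of :func:`boxcox_apply`, then subtract the shift."""
    y = np.asarray(values, dtype=float)
    if t.lmbda != 0.0 and np.any(t.lmbda * y + 1.0 <= 0.0):
        raise DomainError(
            f"value outside the range of the Box-Cox transform (lambda={t.lmbda:g})"
        )
    return special.inv_boxcox(y, t.lmbda) - t.shift


def parametric_ri(values, level: float = 0.95) -> ReferenceInterval:
    """Transformed parametric RI: Box-Cox, mean ± z·SD, back-transform.

    z is the exact standard-normal quantile at (1+level)/2. If the lower
    limit on the transformed scale falls outside the transform's range (a
    strongly right-skewed fit), it is clipped to the domain boundary and the
    interval flagged, rather than raising.
    """
    a = _as_1d_floats(values, "values")
    if a.size < 20:
        raise InputError(f"parametric RI requires at least 20 values, got {a.size}")
    if np.ptp(a) == 0.0:
        raise InputError("parametric RI undefined for constant input")
    t = boxcox_fit(a)
    y = boxcox_apply(a, t)
    m = float(y.mean())
    s = float(y.std(ddof=1))
    z = float(stats.norm.ppf(0.5 * (1.0 + level)))
    lo_t, hi_t = m - z * s, m + z * s
    clipped = False
    lam = t.lmbda
    if lam > 0 and lam * lo_t + 1.0 <= 0.0:
        lower = -t.shift  # boundary: x + shift -> 0
        clipped = True
    else:
        lower = float(boxcox_invert(np.array([lo_t]), t)[0])
    if lam < 0 and lam * hi_t + 1.0 <= 0.0:
        upper = float("inf")
        clipped = True
    else:
        upper = float(boxcox_invert(np.array([hi_t]), t)[0])
    return ReferenceInterval(
        lower=lower, upper=upper, level=level,
        method="transformed_parametric", transform=t, n_used=a.size, clipped=clipped,
    )


def nonparametric_ri(values, level: float = 0.95) -> ReferenceInterval:
    """Non-parametric RI: empirical percentiles at (1±level)/2."""
    a = _as_1d_floats(values, "values")
    if a.size < 20:
        raise InputError(f"non-parametric RI requires at least 20 values, got {a.size}")
    alpha = 0.5 * (1.0 - level)
    lo, hi = quantile(a, [alpha, 1.0 - alpha])
    return ReferenceInterval(
        lower=float(lo), upper=float(hi), level=level,
        method="nonparametric", n_used=a.size,
    )
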