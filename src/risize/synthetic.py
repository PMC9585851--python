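"""Synthetic reference populations with analytically known reference intervals.

The generator emulates the statistical structure of routine clinical-
chemistry reference data: analytes that are approximately normal with small
between-subject variation (thyroid hormones FT3/FT4/TT3/TT4-like, CV of
6–9.4%) and right-skewed analytes (TSH-like, between-subject CV 35%),
in populations of several thousand. Because each family has closed-form (or
numerically invertible) quantiles, the true 2.5th/97.5th percentiles are
available as ground truth for estimator-recovery tests.

Presets fix only the coefficient of variation; the location is arbitrary
(default mean 1.0 in analyte units) because the estimators are location/
scale-equivariant for the normal family and scale-equivariant for the
lognormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .core import AnalytePopulation, ReferenceInterval
from .errors import ConfigError

__all__ = ["SimulationSpec", "PRESETS", "preset_spec", "generate_population", "true_ri"]

FAMILIES = ("normal", "lognormal", "gamma", "mixture")

#: Between-subject CVs of the thyroid-panel presets; the TSH-like analyte is
#: right-skewed (lognormal), the others approximately normal.
PRESETS: Mapping[str, tuple[str, float]] = {
    "tsh_like": ("lognormal", 0.350),
    "ft3_like": ("normal", 0.060),
    "ft4_like": ("normal", 0.077),
    "tt3_like": ("normal", 0.094),
    "tt4_like": ("normal", 0.064),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic reference population."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    pop_size: int = 5000
    seed: int = 0
    preset: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.pop_size < 100:
            raise ConfigError("pop_size must be >= 100")
        _validate_params(self.family, dict(self.params))


def _validate_params(family: str, p: dict) -> dict:
    try:
        if family == "normal":
            out = {"mean": float(p["mean"]), "sd": float(p["sd"])}
            if out["sd"] <= 0:
                raise ConfigError("normal sd must be positive")
        elif family == "lognormal":
            out = {"mu": float(p["mu"]), "sigma": float(p["sigma"])}
            if out["sigma"] <= 0:
                raise ConfigError("lognormal sigma must be positive")
        elif family == "gamma":
            out = {"shape": float(p["shape"]), "scale": float(p["scale"])}
            if out["shape"] <= 0 or out["scale"] <= 0:
                raise ConfigError("gamma shape and scale must be positive")
        else:  # mixture of two normals
            out = {k: float(p[k]) for k in ("weight1", "mean1", "sd1", "mean2", "sd2")}
            if not (0.0 < out["weight1"] < 1.0):
                raise ConfigError("mixture weight1 must be in (0, 1)")
            if out["sd1"] <= 0 or out["sd2"] <= 0:
                raise ConfigError("mixture sds must be positive")
    except KeyError as e:
        raise ConfigError(f"family {family!r} missing parameter {e.args[0]!r}") from None
    return out


def preset_spec(name: str, pop_size: int = 5000, seed: int = 0,
                location: float = 1.0) -> SimulationSpec:
    """Build a SimulationSpec from a named analyte preset.

    ``location`` is the population mean in analyte units. For the lognormal
    preset the (mu, sigma) are solved so the distribution has exactly that
    mean and the preset CV: sigma² = ln(1 + CV²), mu = ln(location) − sigma²/2.
    """
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; expected one of {tuple(PRESETS)}")
    if location <= 0:
        raise ConfigError("preset location must be positive")
    family, cv = PRESETS[name]
    if family == "normal":
        params = {"mean": location, "sd": cv * location}
    else:
        sigma2 = math.log(1.0 + cv * cv)
        params = {"mu": math.log(location) - 0.5 * sigma2, "sigma": math.sqrt(sigma2)}
    return SimulationSpec(family=family, params=params, pop_size=pop_size,
                          seed=seed, preset=name)


def generate_population(spec: SimulationSpec) -> AnalytePopulation:
    """Draw the population; deterministic given ``spec.seed``."""
    p = _validate_params(spec.family, dict(spec.params))
    rng = np.random.default_rng(spec.seed)
    if spec.family == "normal":
        values = rng.normal(p["mean"], p["sd"], size=spec.pop_size)
    elif spec.family == "lognormal":
        values = rng.lognormal(p["mu"], p["sigma"], size=spec.pop_size)
    elif spec.family == "gamma":
        values = rng.gamma(p["shape"], p["scale"], size=spec.pop_size)
    else:
        comp = rng.random(spec.pop_size) < p["weight1"]
        values = np.where(
            comp,
            rng.normal(p["mean1"], p["sd1"], size=spec.pop_size),
            rng.normal(p["mean2"], p["sd2"], size=spec.pop_size),
        )
    name = spec.preset or spec.family
    return AnalytePopulation(values=values, analyte_name=name, unit="arbitrary")


def _mixture_ppf(q: float, p: dict, tol: float = 1e-10) -> float:
    w = p["weight1"]
    cdf = lambda x: (w * stats.norm.cdf(x, p["mean1"], p["sd1"])
                     + (1 - w) * stats.norm.cdf(x, p["mean2"], p["sd2"]))
    lo = min(p["mean1"] - 10 * p["sd1"], p["mean2"] - 10 * p["sd2"])
    hi = max(p["mean1"] + 10 * p["sd1"], p["mean2"] + 10 * p["sd2"])
    return float(optimize.brentq(lambda x: cdf(x) - q, lo, hi, xtol=tol))


def true_ri(spec: SimulationSpec, level: float = 0.95) -> ReferenceInterval:
    """Analytic (2.5th, 97.5th by default) quantiles of the generating law.

    The two-normal mixture has no closed form; its quantiles come from
    root-finding on the CDF (tolerance well below 1e-8).
    """
    p = _validate_params(spec.family, dict(spec.params))
    alpha = 0.5 * (1.0 - level)
    qs = (alpha, 1.0 - alpha)
    if spec.family == "normal":
        lo, hi = stats.norm.ppf(qs, loc=p["mean"], scale=p["sd"])
    elif spec.family == "lognormal":
        dist = stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        lo, hi = dist.ppf(qs)
    elif spec.family == "gamma":
        dist = stats.gamma(a=p["shape"], scale=p["scale"])
        lo, hi = dist.ppf(qs)
    else:
        lo, hi = (_mixture_ppf(q, p) for q in qs)
    return ReferenceInterval(lower=float(lo), upper=float(hi), level=level,
                             method="analytic", n_used=0)
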