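"""Minimum-sample-size search for reference-interval establishment.

The estimator sweeps candidate sample sizes n over a grid (outer loop). At
each n the bootstrap layer (inner loop) yields 90% CIs of both reference
limits and a scalar summary W of the B bootstrap RI widths. The ratios

    R1 = width(CI of lower limit) / W      R2 = width(CI of upper limit) / W

implement the rule that a reference limit is adequately estimated when its
CI is narrower than 0.2 times the RI width. A candidate n is flagged 1 when
both ratios pass. Because the ratios fluctuate, the flag sequence is
smoothed twice with window w (default 10): a moving sum, then a moving
median of the sums. The first index where the moving median equals w marks
the first *stably* passing sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bootstrap import WIDTH_SUMMARIES, ci_pair, resample_limits, width_summary
from .core import AnalytePopulation, normalize_method
from .errors import ConfigError, InputError

__all__ = [
    "EstimatorConfig",
    "SizeGridPoint",
    "SearchResult",
    "evaluate_n",
    "moving_sum",
    "moving_median",
    "first_stable_n",
    "estimate_sample_size",
    "validate_at_n",
]

_METHOD_CODE = {"transformed_parametric": 1, "nonparametric": 2}
_VALIDATION_KEY = 7919  # spawn-key tag separating the validation stream from the search


@dataclass(frozen=True)
class EstimatorConfig:
    """Configuration of the sample-size search.

    Defaults are the reference settings of the method: grid 40..2000 step 1,
    B = 1000 resamples, 95% RI, 90% CI, ratio threshold 0.2, window 10.
    """

    n_min: int = 40
    n_max: int = 2000
    step: int = 1
    B: int = 1000
    ri_level: float = 0.95
    ci_level: float = 0.90
    threshold: float = 0.2
    window: int = 10
    method: str = "transformed_parametric"
    width_summary: str = "median"
    seed: int = 0
    early_stop: bool = True
    report_position: str = "run_start"  # or "window_end"

    def __post_init__(self):
        if self.n_min < 20:
            raise ConfigError("n_min must be >= 20")
        if self.n_max < self.n_min:
            raise ConfigError("n_max must be >= n_min")
        if self.step < 1:
            raise ConfigError("step must be >= 1")
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigError("threshold must be in (0, 1)")
        if self.width_summary not in WIDTH_SUMMARIES:
            raise ConfigError(f"width_summary must be one of {WIDTH_SUMMARIES}")
        if self.report_position not in ("run_start", "window_end"):
            raise ConfigError("report_position must be 'run_start' or 'window_end'")
        object.__setattr__(self, "method", normalize_method(self.method))

    @property
    def n_grid(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1, self.step)


@dataclass(frozen=True)
class SizeGridPoint:
    """Per-candidate-n summary of the bootstrap layer."""

    n: int
    ci_lower_width: float
    ci_upper_width: float
    ri_width_summary: float
    R1: float
    R2: float
    flag: int
    degenerate: bool = False
    redraws: int = 0


@dataclass(frozen=True)
class SearchResult:
    """Outcome of the sweep: estimated minimum n (or None), trace, validation."""

    estimated_n: int | None
    method: str
    trace: tuple[SizeGridPoint, ...]
    moving_sums: np.ndarray | None
    moving_medians: np.ndarray | None
    config: EstimatorConfig
    validation: tuple[float, float] | None = None

    @property
    def converged(self) -> bool:
        return self.estimated_n is not None

    @property
    def flags(self) -> np.ndarray:
        return np.array([p.flag for p in self.trace], dtype=int)


def _point_seed(config: EstimatorConfig, n: int, validation: bool = False):
    """Independent child stream per (method, n): order- and stop-invariant."""
    key = (_METHOD_CODE[config.method], int(n))
    if validation:
        key = key + (_VALIDATION_KEY,)
    return np.random.SeedSequence(entropy=config.seed, spawn_key=key)


def evaluate_n(pop: AnalytePopulation, n: int, config: EstimatorConfig,
               seed=None) -> SizeGridPoint:
    """One outer-loop step: bootstrap at n, CIs, width summary, ratios, flag.

    A zero (or non-finite) width summary makes the ratios undefined; the
    point is marked degenerate with flag 0 — a population that cannot spread
    never counts as converged.
    """
    if seed is None:
        seed = _point_seed(config, n)
    dist = resample_limits(pop, n, config.B, config.method, seed, level=config.ri_level)
    cis = ci_pair(dist, config.ci_level)
    w = width_summary(dist, config.width_summary)
    if not np.isfinite(w) or w <= 0.0:
        return SizeGridPoint(
            n=n, ci_lower_width=cis.lower_width, ci_upper_width=cis.upper_width,
            ri_width_summary=w, R1=float("inf"), R2=float("inf"), flag=0,
            degenerate=True, redraws=dist.redraws,
        )
    r1 = cis.lower_width / w
    r2 = cis.upper_width / w
    flag = int(r1 < config.threshold and r2 < config.threshold)
    return SizeGridPoint(
        n=n, ci_lower_width=cis.lower_width, ci_upper_width=cis.upper_width,
        ri_width_summary=w, R1=r1, R2=r2, flag=flag, redraws=dist.redraws,
    )


def moving_sum(flags: Sequence[int], w: int) -> np.ndarray:
    """Sums over trailing contiguous windows; output length len − w + 1."""
    a = np.asarray(flags)
    if a.size < w:
        raise InputError(f"moving sum needs at least w={w} elements, got {a.size}")
    return sliding_window_view(a, w).sum(axis=1)


def moving_median(xs: Sequence[float], w: int) -> np.ndarray:
    """Medians over trailing contiguous windows (even windows: mean of the
    two central order statistics); output length len − w + 1."""
    a = np.asarray(xs, dtype=float)
    if a.size < w:
        raise InputError(f"moving median needs at least w={w} elements, got {a.size}")
    return np.median(sliding_window_view(a, w), axis=1)


def first_stable_n(flags: Sequence[int], n_grid: Sequence[int], *,
                   window: int = 10,
                   report_position: str = "run_start") -> int | None:
    """First stably-passing n after double smoothing; None if none exists.

    Computes s = moving_sum(flags, w), m = moving_median(s, w) and finds the
    first index j with m[j] = w. ``run_start`` (default) reports n_grid[j],
    the start of the earliest window contributing to the all-pass median;
    ``window_end`` reports n_grid[j + 2(w−1)], the grid point at which
    stability was confirmed. Returns None when the sequence is still too
    short to evaluate (fewer than 2w − 1 flags).
    """
    f = np.asarray(flags)
    grid = np.asarray(n_grid)
    if f.size != grid.size:
        raise InputError("flags and n_grid must have equal length")
    w = window
    if f.size < 2 * w - 1:
        return None
    m = moving_median(moving_sum(f, w), w)
    hits = np.flatnonzero(m == w)
    if hits.size == 0:
        return None
    j = int(hits[0])
    if report_position == "window_end":
        return int(grid[j + 2 * (w - 1)])
    return int(grid[j])


def estimate_sample_size(pop: AnalytePopulation, config: EstimatorConfig) -> SearchResult:
    """Run the full two-layer search for one estimation method.

    Ascending sweep over the grid; with ``early_stop`` the sweep halts as
    soon as the stability condition is decided (the double smoothing only
    looks backwards, so the first hit cannot change with further points).
    Non-convergence by n_max is a result (estimated_n None), not an error.
    The validation ratios at the estimate come from an independent seeded
    re-run, mirroring how a fresh cohort of that size would behave.
    """
    grid = config.n_grid
    trace: list[SizeGridPoint] = []
    flags: list[int] = []
    estimated: int | None = None
    for n in grid:
        trace.append(evaluate_n(pop, int(n), config))
        flags.append(trace[-1].flag)
        est = first_stable_n(
            flags, grid[: len(flags)],
            window=config.window, report_position=config.report_position,
        )
        if est is not None:
            estimated = est
            if config.early_stop:
                break
    f = np.asarray(flags)
    sums = moving_sum(f, config.window) if f.size >= config.window else None
    medians = (
        moving_median(sums, config.window)
        if sums is not None and sums.size >= config.window else None
    )
    validation = None
    if estimated is not None:
        validation = validate_at_n(
            pop, estimated, config, _point_seed(config, estimated, validation=True)
        )
    return SearchResult(
        estimated_n=estimated, method=config.method, trace=tuple(trace),
        moving_sums=sums, moving_medians=medians, config=config,
        validation=validation,
    )


def validate_at_n(pop: AnalytePopulation, n: int, config: EstimatorConfig,
                  seed) -> tuple[float, float]:
    """Fresh evaluation at one n with an independent seed; returns (R1, R2).

    These are the validation ratios reported next to an estimate — a
    stochastic re-run, so they are usually but not necessarily both below
    the threshold.
    """
    point = evaluate_n(pop, int(n), config, seed=seed)
    return (point.R1, point.R2)
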