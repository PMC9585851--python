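"""Independent brute-force oracles the implementation is checked against.

Everything here is written from the definitions (sort-and-interpolate
quantiles, explicit window loops, grid-search likelihood), deliberately
avoiding the package's own code paths.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
from scipy import stats


def quantile_oracle(values, p: float) -> float:
    """Rank r = p(n+1), linear interpolation, ranks clipped to [1, n]."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    r = p * (n + 1)
    r = min(max(r, 1.0), float(n))
    i = int(math.floor(r))
    frac = r - i
    if i >= n:
        return xs[-1]
    return xs[i - 1] + frac * (xs[i] - xs[i - 1])


def moving_sum_oracle(flags, w: int) -> list:
    return [sum(flags[i:i + w]) for i in range(len(flags) - w + 1)]


def moving_median_oracle(xs, w: int) -> list:
    return [statistics.median(xs[i:i + w]) for i in range(len(xs) - w + 1)]


def first_stable_oracle(flags, n_grid, w: int, position: str = "run_start"):
    """Direct evaluation of the smooth-twice-then-first-hit pipeline."""
    if len(flags) < 2 * w - 1:
        return None
    s = moving_sum_oracle(list(flags), w)
    m = moving_median_oracle(s, w)
    for j, v in enumerate(m):
        if v == w:
            if position == "window_end":
                return n_grid[j + 2 * (w - 1)]
            return n_grid[j]
    return None


def boxcox_lambda_grid(x, lo: float = -3.0, hi: float = 3.0,
                       step: float = 0.001) -> float:
    """Grid-search maximizer of the Box-Cox profile log-likelihood."""
    lams = np.arange(lo, hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, x) for l in lams])
    return float(lams[int(np.argmax(llf))])


def normal_quantile_se(p: float, n: int, sd: float = 1.0) -> float:
    """Asymptotic SE of the empirical p-quantile of a normal sample."""
    z = stats.norm.ppf(p)
    f = stats.norm.pdf(z) / sd
    return math.sqrt(p * (1 - p) / n) / f


def lognormal_quantile_se(p: float, n: int, mu: float, sigma: float) -> float:
    z = stats.norm.ppf(p)
    q = math.exp(mu + sigma * z)
    f = stats.norm.pdf(z) / (q * sigma)
    return math.sqrt(p * (1 - p) / n) / f
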