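"""Welch's unequal-variance t-test and small summary utilities."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["WelchResult", "welch_t", "summary_mean_sd"]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float  # Welch-Satterthwaite degrees of freedom (real-valued)
    p: float  # two-tailed
    degenerate: bool = False  # both variances zero


def welch_t(x, y) -> WelchResult:
    """Welch's two-sample t-test (two-tailed, unequal variances).

    t = (mean x - mean y) / sqrt(s2x/nx + s2y/ny); df by the
    Welch-Satterthwaite approximation.  When both samples have zero
    variance: equal means give t = 0, p = 1; unequal means give p = 0,
    both flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dm = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if dm == 0:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0, degenerate=True)
        return WelchResult(
            t=math.copysign(math.inf, dm), df=float(nx + ny - 2), p=0.0, degenerate=True
        )
    se2 = vx / nx + vy / ny
    t = dm / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return WelchResult(t=float(t), df=float(df), p=p)


def summary_mean_sd(values) -> tuple[float, float, float]:
    """(mean, sample sd, standard error); sd and se are NaN at n = 1."""
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("need n >= 1")
    if len(v) == 1:
        return float(v[0]), float("nan"), float("nan")
    sd = float(v.std(ddof=1))
    return float(v.mean()), sd, sd / math.sqrt(len(v))
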