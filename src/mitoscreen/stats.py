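"""Shared statistical primitives.

`welch_t_test` is a vectorised Welch (unequal-variance) two-sample t-test
written out explicitly — the group comparisons throughout the screen run
through this one function, and the suite cross-checks it against
scipy.stats.ttest_ind.  Fisher's one-sided exact test delegates to scipy.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["welch_t_test", "fisher_exact_greater", "bonferroni"]


def welch_t_test(x: np.ndarray, y: np.ndarray, axis: int = -1):
    """Two-sided Welch t-test along `axis`.

    Returns (t, df, p).  Where both samples have zero variance the statistic
    is undefined; t and p come back as NaN and the caller decides the policy
    (the signature filter maps that case to p = 1 and flags it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = x.shape[axis]
    ny = y.shape[axis]
    if nx < 2 or ny < 2:
        raise ValueError("Welch t-test needs at least 2 observations per group")
    mx = x.mean(axis=axis)
    my = y.mean(axis=axis)
    vx = x.var(axis=axis, ddof=1)
    vy = y.var(axis=axis, ddof=1)
    sx = vx / nx
    sy = vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sx + sy)
        t = (mx - my) / se
        df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact p for the 2x2 table
    [[a, b], [c, d]]: probability of observing >= a successes in the first
    row given the margins."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("2x2 table entries must be non-negative")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment with cap at 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("multiplier must be >= 1")
    return min(1.0, p * m)
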