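"""Replicate-number survey-design calculus.

Given a per-replicate detection probability p (from a fitted occupancy
model) and assuming water replicates are independent, the probability
that at least k of n replicates are positive is the binomial upper
tail.  Evaluating the same tail at the false-positive rate p10 gives
the probability that an unoccupied site is *declared* positive under a
"k of n positives" site-calling rule — raising k trades a little
detection power for a large reduction in site-level false positives.

Confidence intervals for the per-replicate probability push through the
tail by endpoint transform, which is exact because the binomial upper
tail is monotone increasing in p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "cumulative_detection",
    "rule_false_positive",
    "min_replicates",
    "design_curve",
    "DesignCurve",
    "NO_FINITE_N",
]

#: Sentinel from :func:`min_replicates` when no replicate count can work.
NO_FINITE_N = math.inf


def _check_nk(n: int, k: int) -> None:
    if k > n:
        raise ValueError(f"require k <= n, got k={k}, n={n}")
    if k < 1 or n < 1:
        raise ValueError(f"require n >= 1 and k >= 1, got n={n}, k={k}")


def cumulative_detection(p: float, n: int, k: int = 1) -> float:
    """P(at least k of n independent replicates detect), the binomial
    upper tail sum_{j=k}^{n} C(n,j) p^j (1-p)^(n-j)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    _check_nk(n, k)
    return float(binom.sf(k - 1, n, p))


def rule_false_positive(p10: float, n: int, k: int = 1) -> float:
    """Probability an *unoccupied* site is declared positive under a
    k-of-n rule: the same binomial tail evaluated at p10."""
    return cumulative_detection(p10, n, k)


def min_replicates(p: float, target: float = 0.95, k: int = 1, n_max: int = 10_000) -> float:
    """Smallest n >= k with cumulative_detection(p, n, k) >= target.

    Returns the ``NO_FINITE_N`` sentinel when p = 0 (or the target is
    unreachable within ``n_max`` replicates).  For k = 1 the closed form
    ceil(log(1-target) / log(1-p)) applies and is used.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p == 0.0 and target > 0.0:
        return NO_FINITE_N
    if k == 1:
        if p >= target or p == 1.0:
            return 1
        n = math.ceil(math.log1p(-target) / math.log1p(-p))
        # guard the float boundary either side of the closed form
        while n > 1 and cumulative_detection(p, n - 1, 1) >= target:
            n -= 1
        while cumulative_detection(p, n, 1) < target:
            n += 1
        return n
    for n in range(k, n_max + 1):
        if cumulative_detection(p, n, k) >= target:
            return n
    return NO_FINITE_N


@dataclass(frozen=True)
class DesignCurve:
    """Tidy replicate-design table: one row per replicate count n."""

    k: int
    p: float
    p_lo: float
    p_hi: float
    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table


def design_curve(
    p: float,
    ci: tuple[float, float] | None = None,
    n_max: int = 10,
    k: int = 1,
    p10: float | None = None,
) -> DesignCurve:
    """Cumulative detection (with CI) as a function of replicate count.

    ``ci`` is the per-replicate (lower, upper) confidence interval; its
    endpoints are pushed through the monotone binomial tail, so the
    cumulative interval always brackets the cumulative point estimate.
    When ``p10`` is given, a ``fp_rule`` column reports the k-of-n
    false-positive probability at each n.
    """
    lo, hi = ci if ci is not None else (p, p)
    if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
        raise ValueError(f"CI endpoints must lie in [0, 1], got {ci}")
    if not lo <= p <= hi:
        raise ValueError(f"per-replicate CI {ci} does not bracket p={p}")
    rows = []
    for n in range(k, n_max + 1):
        row = {
            "n": n,
            "k": k,
            "p": p,
            "cumulative": cumulative_detection(p, n, k),
            "lo": cumulative_detection(lo, n, k),
            "hi": cumulative_detection(hi, n, k),
        }
        if p10 is not None:
            row["fp_rule"] = rule_false_positive(p10, n, k)
        rows.append(row)
    return DesignCurve(k=k, p=p, p_lo=lo, p_hi=hi, table=pd.DataFrame(rows))
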