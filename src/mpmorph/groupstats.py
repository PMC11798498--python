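"""One-way ANOVA from first principles.

Fixed-effects one-way analysis of variance: with g groups of sizes n_i and
grand size N,

    SS_between = sum_i n_i (mean_i - grand_mean)^2,   df_b = g - 1
    SS_within  = sum_i sum_j (x_ij - mean_i)^2,       df_w = N - g
    F = (SS_between / df_b) / (SS_within / df_w)

and the p-value is the upper tail of the F(df_b, df_w) distribution,
evaluated through the regularized incomplete beta function

    P(F > x) = I_{d2 / (d2 + d1 x)}(d2/2, d1/2),

computed with the standard continued-fraction expansion (absolute error
below 1e-10). The whole chain is self-contained so the statistic and its
tail probability carry no dependence beyond basic array arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AnovaResult", "one_way_anova", "f_upper_tail", "betainc_regularized"]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_ns: tuple[int, ...]
    grand_mean: float


def one_way_anova(groups: Sequence[Sequence[float]], missing: str = "drop") -> AnovaResult:
    """One-way fixed-effects ANOVA across two or more groups.

    Parameters
    ----------
    groups : sequence of samples
        Each sample is a sequence of reals; NaNs are dropped when
        ``missing="drop"`` (default) and rejected when ``missing="fail"``.
        A value that summarises several fragments (a printed mean) counts
        as the single observation it is entered as.

    Notes
    -----
    All groups identical in value gives F = 0 and p = 1, which is a valid
    result, not an error. ``df_within = 0`` (no residual degrees of
    freedom) is an error.
    """
    if missing not in ("drop", "fail"):
        raise ValueError("missing must be 'drop' or 'fail'")
    cleaned: list[np.ndarray] = []
    for gi, g in enumerate(groups):
        arr = np.asarray(list(g), dtype=float)
        if np.isnan(arr).any():
            if missing == "fail":
                raise ValueError(f"group {gi} contains missing values")
            arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError(f"group {gi} is empty after dropping missing values")
        cleaned.append(arr)
    if len(cleaned) < 2:
        raise ValueError("need at least two groups")
    ns = tuple(int(a.size) for a in cleaned)
    N = sum(ns)
    g = len(cleaned)
    df_b, df_w = g - 1, N - g
    if df_w < 1:
        raise ValueError("no residual degrees of freedom (df_within = 0)")
    grand = float(sum(a.sum() for a in cleaned) / N)
    ss_b = float(sum(a.size * (a.mean() - grand) ** 2 for a in cleaned))
    ss_w = float(sum(((a - a.mean()) ** 2).sum() for a in cleaned))
    if ss_w == 0.0:
        if ss_b == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, ns, grand)
        return AnovaResult(math.inf, df_b, df_w, 0.0, ns, grand)
    F = (ss_b / df_b) / (ss_w / df_w)
    return AnovaResult(float(F), df_b, df_w, f_upper_tail(F, df_b, df_w), ns, grand)


def f_upper_tail(x: float, d1: int, d2: int) -> float:
    """Upper-tail probability P(F(d1, d2) > x)."""
    if d1 < 1 or d2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({d1}, {d2})")
    if not x >= 0:
        raise ValueError(f"x must be non-negative, got {x}")
    if x == 0:
        return 1.0
    if math.isinf(x):
        return 0.0
    return betainc_regularized(d2 / (d2 + d1 * x), d2 / 2.0, d1 / 2.0)


def betainc_regularized(x: float, a: float, b: float) -> float:
    """Regularized incomplete beta function I_x(a, b).

    Lentz-style continued-fraction evaluation; the symmetry
    I_x(a, b) = 1 - I_{1-x}(b, a) keeps the fraction in its rapidly
    converging region x < (a + 1) / (a + b + 2).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got {x}")
    if a <= 0 or b <= 0:
        raise ValueError("shape parameters must be positive")
    if x == 0.0:
        return 0.0
    if x == 1.0:
        return 1.0
    ln_front = (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + a * math.log(x)
        + b * math.log1p(-x)
    )
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _beta_cf(x, a, b) / a
    return 1.0 - front * _beta_cf(1.0 - x, b, a) / b


def _beta_cf(x: float, a: float, b: float, max_iter: int = 500, eps: float = 1e-15) -> float:
    """Continued fraction for the incomplete beta (modified Lentz)."""
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            return h
    raise RuntimeError("incomplete beta continued fraction failed to converge")
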