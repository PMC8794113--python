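"""Wilson score intervals and interval-overlap significance calls.

MCC lives on [-1, 1]; it is mapped to the proportion scale via
``(mcc + 1) / 2``, the Wilson interval is computed there, and the bounds are
mapped back — keeping them inside [-1, 1].  ECE, accuracy and F are treated
directly as proportions.  Significance between two reported values is called
iff their confidence intervals do not overlap (the only procedure the source
tables support; conservative relative to a formal two-sample test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .metrics import NA, is_na

_PROPORTION_METRICS = ("ece", "accuracy", "f", "f_score", "precision", "recall")


@dataclass(frozen=True)
class WilsonInterval:
    estimate: float
    lower: float
    upper: float
    n: int
    level: float = 0.95
    scale: str = "proportion"

    @property
    def width(self) -> float:
        return self.upper - self.lower


def wilson_interval(p_hat: float, n: int, level: float = 0.95) -> WilsonInterval:
    """Closed-form Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = norm.ppf(0.5 * (1.0 + level))
    z2n = z * z / n
    center = (p_hat + z2n / 2.0) / (1.0 + z2n)
    half = (z / (1.0 + z2n)) * math.sqrt(p_hat * (1.0 - p_hat) / n + z2n / (4.0 * n))
    # clamp to [0, 1] and absorb float rounding so the estimate is always contained
    lower = min(max(center - half, 0.0), p_hat)
    upper = max(min(center + half, 1.0), p_hat)
    return WilsonInterval(
        estimate=p_hat,
        lower=lower,
        upper=upper,
        n=n,
        level=level,
        scale="proportion",
    )


def metric_interval(value: float, metric: str, n: int, level: float = 0.95) -> WilsonInterval:
    """Wilson interval for a reported metric value.

    NA metric values propagate to an NA interval.
    """
    if metric not in _PROPORTION_METRICS and metric != "mcc":
        raise ValueError(f"unknown metric {metric!r}")
    scale = "mcc" if metric == "mcc" else "proportion"
    if is_na(value):
        return WilsonInterval(estimate=NA, lower=NA, upper=NA, n=n, level=level, scale=scale)
    if metric == "mcc":
        base = wilson_interval((value + 1.0) / 2.0, n, level)
        return WilsonInterval(
            estimate=value,
            lower=2.0 * base.lower - 1.0,
            upper=2.0 * base.upper - 1.0,
            n=n,
            level=level,
            scale="mcc",
        )
    return wilson_interval(value, n, level)


def significant_difference(a: WilsonInterval, b: WilsonInterval) -> tuple[bool, int]:
    """Non-overlap significance call between two same-level intervals.

    Returns ``(significant, direction)`` with direction the sign of
    ``a.estimate - b.estimate``.  NA intervals are never significant.
    """
    if a.level != b.level:
        raise ValueError(f"mismatched confidence levels: {a.level} vs {b.level}")
    if is_na(a.estimate) or is_na(b.estimate):
        return False, 0
    disjoint = a.lower > b.upper or b.lower > a.upper
    diff = a.estimate - b.estimate
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    return bool(disjoint), direction
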