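"""Wald (normal-approximation) confidence intervals for binomial proportions."""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["ProportionEstimate", "wald_proportion_ci"]


@dataclass(frozen=True)
class ProportionEstimate:
    k: int
    n: int
    p: float
    ci_low: float
    ci_high: float
    level: float

    @property
    def pct(self) -> float:
        return 100.0 * self.p


def wald_proportion_ci(k: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """p ± z·√(p(1−p)/n), no continuity correction, clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p = k / n
    z = float(stats.norm.ppf(0.5 + level / 2))
    half = z * math.sqrt(p * (1 - p) / n)
    return ProportionEstimate(
        k=k,
        n=n,
        p=p,
        ci_low=max(0.0, p - half),
        ci_high=min(1.0, p + half),
        level=level,
    )
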