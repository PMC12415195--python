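"""Small statistics used for committor comparisons.

Two-proportion z-tests (pooled variance) for comparing sampled commitment
probabilities between conditions, and binomial proportion confidence
intervals (Wilson score by default, Clopper-Pearson optionally) for error
bars on sampled committor estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = ["proportions_ztest", "binomial_ci", "proportions_agree"]


def proportions_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test.

    z = (p1 - p2) / sqrt(p*(1-p*)*(1/n1 + 1/n2)) with p* the pooled
    proportion; returns (z, two-sided p).  If the pooled proportion is 0 or 1
    the statistic is degenerate and (0.0, 1.0) is returned with a warning.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("require 0 <= k <= n and n > 0")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; z-test uninformative")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def binomial_ci(k: int, n: int, level: float = 0.95,
                method: str = "wilson") -> tuple[float, float]:
    """Binomial proportion confidence interval.

    ``method`` is ``"wilson"`` (score interval, default) or ``"beta"``
    (Clopper-Pearson exact).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    if method not in ("wilson", "beta"):
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=method)
    return float(lo), float(hi)


def proportions_agree(k1: int, n1: int, k2: int, n2: int,
                      alpha: float = 0.05) -> bool:
    """True if two sampled proportions are statistically compatible.

    Convenience wrapper used for ensemble-population comparisons: the pooled
    z-test does not reject equality at level ``alpha``.
    """
    _, p = proportions_ztest(k1, n1, k2, n2)
    return p >= alpha
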