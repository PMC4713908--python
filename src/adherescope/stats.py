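"""Shared correlation machinery.

A single Pearson implementation serves both the morning self-management
association and the lagged sleep-adherence analysis: product-moment r with
a two-sided p-value from the t distribution with n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-test p-value.

    Raises ``ValueError`` on fewer than 3 pairs or zero variance on either
    side (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
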