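"""Multiple-testing corrections shared by the correlation and enrichment stages.

Single source of truth for Benjamini–Hochberg and Holm adjustments so the
clinical-correlation family (fixed family size m = 16) and the
over-representation analysis (family = tested terms) cannot drift apart.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike


def _validate(p: ArrayLike, m: int | None) -> tuple[np.ndarray, int]:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size and (np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m_eff = p.size if m is None else int(m)
    if m_eff < p.size:
        raise ValueError(f"family size m={m_eff} smaller than number of tests {p.size}")
    return p, m_eff


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold α/m."""
    if m < 1:
        raise ValueError("m must be ≥ 1")
    return alpha / m


def holm_adjust(p: ArrayLike, m: int | None = None) -> np.ndarray:
    """Holm step-down adjusted p-values.

    ``m`` fixes the family size; it may exceed ``len(p)`` when some planned
    tests produced no p-value (not-testable cells still consume a slot).
    """
    p, m_eff = _validate(p, m)
    if p.size == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate(p[order] * (m_eff - np.arange(p.size)))
    adj = np.empty_like(p)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def bh_adjust(p: ArrayLike, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p, m_eff = _validate(p, m)
    if p.size == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    adj_sorted = np.minimum.accumulate((p[order] * m_eff / ranks)[::-1])[::-1]
    adj = np.empty_like(p)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj
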