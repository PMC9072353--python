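"""Multiple-testing corrections used across the package.

Two procedures appear throughout the analyses: Benjamini–Hochberg step-up
FDR adjustment (the per-shuffle tile family of the consensus DMR caller) and
the Holm–Šídák step-down family-wise correction (clonal KS comparisons,
ΔCt t-tests and CPM t-tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fdr_bh", "holm_sidak"]


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q(i) = min over j with rank >= rank(i) of m * p(j) / rank(j), capped at 1;
    returned in the input order.  Empty input yields an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def holm_sidak(p_values) -> np.ndarray:
    """Holm–Šídák step-down adjusted p-values.

    Sort ascending; adjusted(i) = 1 - (1 - p(i))^(m - i + 1); enforce
    monotone non-decreasing along the sorted order; cap at 1; return in the
    input order.  The step-down adjustment never exceeds the single-step
    Šídák value 1 - (1 - p)^m.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    exponents = m - np.arange(m)  # m, m-1, ..., 1 along the sorted order
    adj_sorted = 1.0 - np.power(1.0 - p[order], exponents)
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj
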