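"""Independent brute-force oracles used to validate the package's statistics.

Everything here is deliberately slow and definition-level: exhaustive
permutation enumeration for the KS test, bisection over the rejection level
for the step-down/step-up multiple-testing procedures, and the classical
pooled two-proportion z-test.  None of it shares code with the
implementations it checks.
"""

import itertools
import math

import numpy as np
from scipy import stats


def ks_d(a, b):
    """Max absolute ECDF difference, ties collapsed."""
    vals = np.unique(np.concatenate([a, b]))
    ca = np.searchsorted(np.sort(a), vals, side="right") / len(a)
    cb = np.searchsorted(np.sort(b), vals, side="right") / len(b)
    return float(np.max(np.abs(ca - cb)))


def brute_ks_p(a, b):
    """Exact permutation p-value of the two-sample KS D by full enumeration."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    d_obs = ks_d(a, b)
    hits = total = 0
    for comb in itertools.combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        if ks_d(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return d_obs, hits / total


def _holm_sidak_rejected(p, alpha):
    """Index set rejected by the step-down Sidak procedure at level alpha."""
    order = np.argsort(p, kind="mergesort")
    m = len(p)
    rejected = set()
    for rank, idx in enumerate(order):
        crit = 1.0 - (1.0 - alpha) ** (1.0 / (m - rank))
        if p[idx] <= crit:
            rejected.add(idx)
        else:
            break
    return rejected


def _bh_rejected(p, alpha):
    """Index set rejected by the BH step-up procedure at level alpha."""
    order = np.argsort(p, kind="mergesort")
    m = len(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    return set(order[:k_star])


def adjusted_by_bisection(p, rejected_at, iterations=60):
    """Adjusted p-values as inf{alpha : hypothesis rejected at level alpha}."""
    p = np.asarray(p, float)
    out = np.empty(len(p))
    for i in range(len(p)):
        lo, hi = 0.0, 1.0
        for _ in range(iterations):
            mid = 0.5 * (lo + hi)
            if i in rejected_at(p, mid):
                hi = mid
            else:
                lo = mid
        out[i] = hi
    return out


def brute_holm_sidak(p):
    return adjusted_by_bisection(p, _holm_sidak_rejected)


def brute_bh(p):
    return adjusted_by_bisection(p, _bh_rejected)


def ztest_two_proportion_p(ma, ta, mb, tb):
    """Classical pooled two-proportion z-test, two-sided."""
    pa, pb = ma / ta, mb / tb
    pool = (ma + mb) / (ta + tb)
    se = math.sqrt(pool * (1 - pool) * (1 / ta + 1 / tb))
    if se == 0:
        return 1.0
    return 2.0 * stats.norm.sf(abs(pb - pa) / se)
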