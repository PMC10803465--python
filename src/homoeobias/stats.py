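"""Shared statistical primitives: Fisher's exact test and BH adjustment.

Two-sided Fisher p-values follow the standard definition: the sum of the
probabilities of all tables (with the observed margins fixed) whose
hypergeometric probability does not exceed that of the observed table.
Near-equality is judged with the customary 1e-7 relative gate so that exact
ties (symmetric tables) are always included.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

_TIE_GATE = 1 + 1e-7


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for one 2x2 table of counts."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() == 0:
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def fisher_exact_rows(a, b, c, d) -> np.ndarray:
    """Vector of two-sided Fisher p-values for tables [[a,b],[c,d]] rowwise."""
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    out = np.empty(a.shape, dtype=float)
    for i in range(a.size):
        out.flat[i] = fisher_exact_2x2(
            [[a.flat[i], b.flat[i]], [c.flat[i], d.flat[i]]]
        )
    return out


def fisher_p_support(r1: int, r2: int, c1: int) -> np.ndarray:
    """Two-sided Fisher p for every table with row sums (r1, r2) and first
    column sum c1.

    Returns the p-value for each feasible top-left cell ``a`` in
    ``max(0, c1-r2) .. min(r1, c1)``, computed from the full hypergeometric
    pmf over the support.  This vectorized path is exactly the two-sided
    definition used by :func:`fisher_exact_2x2` and is convenient when many
    tables share margins (or when enumerating small-table spaces).
    """
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, r1 + r2, r1, c1)
    p = np.array([pmf[pmf <= pmf_a * _TIE_GATE].sum() for pmf_a in pmf])
    return np.minimum(p, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1).

    adj(p_(i)) = min_{j >= i} m * p_(j) / j over the ascending order
    statistics; ties receive identical adjusted values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
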