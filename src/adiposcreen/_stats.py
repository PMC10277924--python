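"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_p[i] = min over j with p[j] >= p[i] of (m * p[j] / rank[j]), capped at 1.
    NaNs are passed through and excluded from the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via t = r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # |r| == 1 gives t = inf -> p = 0
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def logsumexp(a: np.ndarray) -> float:
    from scipy.special import logsumexp as _lse

    return float(_lse(np.asarray(a, dtype=float)))


def logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; returns -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))
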