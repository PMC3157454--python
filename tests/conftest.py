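"""Shared fixtures and independent naive oracles.

The oracles here deliberately re-derive every quantity by direct
enumeration or textbook formulas, sharing no code with the package paths
they check.
"""

import numpy as np
import pytest
from scipy import stats


# ---------------------------------------------------------------------------
# brute-force exact-test oracles (full outcome-grid enumeration)
# ---------------------------------------------------------------------------

def brute_point_null(x1, n1, x2, n2, p10, p20, statistic="adjusted", tol=1e-12):
    """O(n1*n2) enumeration of the point-null exact test."""
    if n1 == 0 or n2 == 0:
        return 1.0
    i = np.arange(n1 + 1)
    j = np.arange(n2 + 1)
    if statistic == "adjusted":
        w = p20 / p10
        v1 = (w * i) / (w * i + (n1 - i))
        v2 = j / (j + w * (n2 - j))
    else:
        v1 = i / n1 - p10
        v2 = j / n2 - p20
    T = np.abs(v1[:, None] - v2[None, :])
    P = np.outer(stats.binom.pmf(i, n1, p10), stats.binom.pmf(j, n2, p20))
    return float(P[T >= T[x1, x2] - tol].sum())


def brute_pooled(x1, n1, x2, n2, tol=1e-12):
    """O(n1*n2) enumeration of the pooled-estimate (classic) exact test."""
    if n1 == 0 or n2 == 0:
        return 1.0
    phat = (x1 + x2) / (n1 + n2)
    i = np.arange(n1 + 1)
    j = np.arange(n2 + 1)
    T = np.abs(i[:, None] / n1 - j[None, :] / n2)
    P = np.outer(stats.binom.pmf(i, n1, phat), stats.binom.pmf(j, n2, phat))
    return float(P[T >= T[x1, x2] - tol].sum())


def brute_point_null_all_outcomes(n1, n2, p10, p20, statistic="adjusted", tol=1e-12):
    """p-values of the point-null test for every outcome (x1, x2) at once."""
    i = np.arange(n1 + 1)
    j = np.arange(n2 + 1)
    if statistic == "adjusted":
        w = p20 / p10
        v1 = (w * i) / (w * i + (n1 - i))
        v2 = j / (j + w * (n2 - j))
    else:
        v1 = i / n1 - p10
        v2 = j / n2 - p20
    T = np.abs(v1[:, None] - v2[None, :])
    P = np.outer(stats.binom.pmf(i, n1, p10), stats.binom.pmf(j, n2, p20))
    flat_T = T.ravel()
    flat_P = P.ravel()
    order = np.argsort(flat_T)
    # tail mass of outcomes with statistic >= t, then look up each outcome's t - tol
    sorted_T = flat_T[order]
    tail = np.concatenate([np.cumsum(flat_P[order][::-1])[::-1], [0.0]])
    idx = np.searchsorted(sorted_T, flat_T - tol, side="left")
    return np.minimum(1.0, tail[idx]).reshape(T.shape)


# ---------------------------------------------------------------------------
# other naive oracles
# ---------------------------------------------------------------------------

def naive_bh(p):
    """Direct formula q_i = min_{k: p(k) >= p(i)} (m * p(k) / rank(k))."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(1.0, q_sorted)
    return q


def naive_percentile_75(values):
    """Linear-interpolation 75th percentile from the sorted-index formula."""
    v = np.sort(np.asarray(values, dtype=float))
    h = 0.75 * (len(v) - 1)
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def naive_fisher_2x2(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric tables with
    probability <= observed."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = np.array([stats.hypergeom.pmf(k, n, row1, col1)
                      for k in range(lo, hi + 1)])
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def naive_interval_hits(genes, dmrs, flank):
    """O(n*m) scan: gene associated iff some DMR intersects the flanked span."""
    out = {}
    for g in genes:
        lo = max(0, g["start"] - flank)
        hi = g["end"] + flank
        out[g["gene_id"]] = any(
            d["chrom"] == g["chrom"] and d["start"] < hi and d["end"] > lo
            for d in dmrs)
    return out


def naive_clusters(genes, window):
    """Transitive closure of the pairwise within-window predicate."""
    genes = sorted(genes, key=lambda g: (g["chrom"], g["start"], g["end"]))
    n = len(genes)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            ga, gb = genes[a], genes[b]
            if ga["chrom"] != gb["chrom"]:
                continue
            gap = max(ga["start"], gb["start"]) - min(ga["end"], gb["end"])
            if gap <= window:
                parent[find(a)] = find(b)
    groups = {}
    for k, g in enumerate(genes):
        groups.setdefault(find(k), []).append(g["gene_id"])
    return sorted(sorted(v) for v in groups.values() if len(v) >= 2)


@pytest.fixture
def rng():
    return np.random.default_rng(20110823)
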