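"""Genomic context of imprinted genes: DMR association and mini-clusters.

Imprinted expression is often anchored by differential DNA methylation
between embryo and endosperm; a gene is associated with a DMR when some
DMR intersects the gene body extended by a flank (default 2 kb) on either
side.  Enrichment over chance is measured against random draws of
equally many genes from the informative universe, with Fisher's exact
test on the resulting association table.  Mini-clusters are runs of
imprinted genes within a genomic window (default 10 kb, boundary to
boundary), chained by single linkage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = ["read_bed_intervals", "associate_dmrs", "dmr_enrichment",
           "find_miniclusters"]


def read_bed_intervals(path) -> pd.DataFrame:
    """Plain BED3+ intervals (chrom, start, end; 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append({"chrom": f[0], "start": int(f[1]), "end": int(f[2])})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if ((df["end"] - df["start"]) <= 0).any():
        raise ValueError("BED intervals must have start < end")
    return df


def _as_interval_table(genes) -> pd.DataFrame:
    """Accept GeneModel lists or (gene_id, chrom, start, end) frames."""
    if isinstance(genes, pd.DataFrame):
        return genes[["gene_id", "chrom", "start", "end"]].copy()
    return pd.DataFrame([{"gene_id": g.gene_id, "chrom": g.chrom,
                          "start": g.start, "end": g.end} for g in genes])


def associate_dmrs(genes, dmrs: pd.DataFrame, flank_bp: int = 2000) -> pd.Series:
    """Per-gene boolean: any DMR within the gene or ``flank_bp`` either side.

    The test interval is [gene_start - flank, gene_end + flank), clipped
    at zero; half-open interval intersection on the gene's chromosome.
    """
    gt = _as_interval_table(genes)
    trees: dict[str, IntervalTree] = {}
    for _, d in dmrs.iterrows():
        trees.setdefault(d["chrom"], IntervalTree())[d["start"]:d["end"]] = True
    hits = []
    for _, g in gt.iterrows():
        tree = trees.get(g["chrom"])
        lo = max(0, g["start"] - flank_bp)
        hi = g["end"] + flank_bp
        hits.append(bool(tree is not None and tree.overlap(lo, hi)))
    return pd.Series(hits, index=gt["gene_id"].to_numpy(), name="dmr_associated")


def dmr_enrichment(imprinted_ids, informative_genes, dmrs: pd.DataFrame,
                   flank_bp: int = 2000, n_draws: int = 1000, seed: int = 0):
    """Fold enrichment of DMR association over random informative genes.

    Draws ``n_draws`` random sets of the same size from the informative
    universe, reports the mean associated count as the expectation, and
    runs a two-sided Fisher's exact test on
    [[assoc_imprinted, non_assoc_imprinted],
     [assoc_random(mean, rounded), non_assoc_random]].
    Returns ``(fold, p, observed, expected_mean)``.
    """
    assoc = associate_dmrs(informative_genes, dmrs, flank_bp=flank_bp)
    imprinted_ids = [g for g in imprinted_ids if g in assoc.index]
    k = len(imprinted_ids)
    if k == 0:
        raise ValueError("no imprinted genes found in the informative universe")
    obs = int(assoc.loc[imprinted_ids].sum())

    rng = np.random.default_rng(seed)
    universe = assoc.index.to_numpy()
    flags = assoc.to_numpy()
    draws = np.empty(n_draws)
    for t in range(n_draws):
        pick = rng.choice(len(universe), size=k, replace=False)
        draws[t] = flags[pick].sum()
    expected = float(draws.mean())

    exp_assoc = int(round(expected))
    table = [[obs, k - obs], [exp_assoc, k - exp_assoc]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    fold = obs / expected if expected > 0 else float("inf")
    return fold, p, obs, expected


def find_miniclusters(imprinted_genes, window_bp: int = 10000,
                      informative_genes=None) -> list:
    """Single-linkage chains of imprinted genes within ``window_bp``.

    Distance is boundary to boundary (gap between gene spans; overlapping
    genes have distance 0).  Clusters of two or more genes are reported,
    each as a dict with the member ids, span, and — when the informative
    universe is supplied — an ``adjacent`` flag, true when no other
    informative gene lies strictly between consecutive members.  Output
    is invariant to input ordering.
    """
    gt = _as_interval_table(imprinted_genes).sort_values(
        ["chrom", "start", "end", "gene_id"]).reset_index(drop=True)
    universe = (None if informative_genes is None
                else _as_interval_table(informative_genes))

    clusters = []
    current = []
    current_end = None
    current_chrom = None

    def flush():
        if len(current) >= 2:
            members = [g["gene_id"] for g in current]
            cl = {"chrom": current_chrom,
                  "start": current[0]["start"],
                  "end": max(g["end"] for g in current),
                  "genes": members, "size": len(members)}
            if universe is not None:
                cl["adjacent"] = _is_adjacent(current, universe)
            clusters.append(cl)

    for _, g in gt.iterrows():
        if (current and g["chrom"] == current_chrom
                and g["start"] - current_end <= window_bp):
            current.append(g)
            current_end = max(current_end, g["end"])
        else:
            flush()
            current = [g]
            current_end = g["end"]
            current_chrom = g["chrom"]
    flush()
    return clusters


def _is_adjacent(members, universe: pd.DataFrame) -> bool:
    ids = {g["gene_id"] for g in members}
    chrom = members[0]["chrom"]
    for a, b in zip(members, members[1:]):
        gap_lo, gap_hi = a["end"], b["start"]
        between = universe[(universe["chrom"] == chrom)
                           & (~universe["gene_id"].isin(ids))
                           & (universe["start"] >= gap_lo)
                           & (universe["end"] <= gap_hi)]
        if len(between):
            return False
    return True
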