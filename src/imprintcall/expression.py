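"""Expression-level support: RPKM, upper-quartile Fisher DE, DE factor.

Differential expression between two single-library experiments follows
the upper-quartile idea: a gene's read counts in the two libraries are
compared against the ratio of the libraries' 75th-percentile counts
(computed over loci expressed in at least one library) with Fisher's
exact test, instead of against total library size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rpkm", "upper_quartile", "fisher_de", "de_factor",
           "de_table", "library_correlation"]


def rpkm(count, gene_length_bp, total_mapped_reads):
    """Reads per kilobase of exon model per million uniquely mapped reads."""
    gene_length_bp = np.asarray(gene_length_bp, dtype=float)
    total = float(total_mapped_reads)
    if np.any(gene_length_bp <= 0):
        raise ValueError("gene length must be positive")
    if total <= 0:
        raise ValueError("total mapped reads must be positive")
    return 1e9 * np.asarray(count, dtype=float) / (gene_length_bp * total)


def upper_quartile(counts_lib1, counts_lib2):
    """75th percentile of each library over loci nonzero in either library.

    Linear interpolation between order statistics (the numpy default) is
    the documented percentile convention.
    """
    c1 = np.asarray(counts_lib1, dtype=float)
    c2 = np.asarray(counts_lib2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("count vectors must have equal length")
    expressed = (c1 > 0) | (c2 > 0)
    if not expressed.any():
        raise ValueError("all loci have zero counts in both libraries")
    return (float(np.percentile(c1[expressed], 75)),
            float(np.percentile(c2[expressed], 75)))


def fisher_de(c1, c2, q75_1, q75_2, reference_scale: float | None = None):
    """Two-sided Fisher's exact test of a gene's counts against the
    upper-quartile reference ratio.

    The 2x2 table is [[c1, c2], [round(q75_1*S), round(q75_2*S)]] with S
    chosen so the larger reference entry is ~1000 (configurable via
    ``reference_scale``; the reference-row magnitude is a sensitivity
    knob, pinned only by its null behaviour at equal normalized ratios).
    Returns ``(p, direction)`` with direction the sign of
    c1/q75_1 - c2/q75_2.
    """
    if q75_1 <= 0 or q75_2 <= 0:
        raise ValueError("upper quartiles must be positive")
    S = reference_scale if reference_scale is not None else 1000.0 / max(q75_1, q75_2)
    table = [[int(c1), int(c2)],
             [int(round(q75_1 * S)), int(round(q75_2 * S))]]
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return float(p), int(np.sign(c1 / q75_1 - c2 / q75_2))


def de_factor(c1, c2, q75_1, q75_2, z: float = 1.96, pseudocount: float = 0.5):
    """Confident lower bound on the upper-quartile-normalised fold change.

    exp(|log((c1+pc)/(c2+pc) * q75_2/q75_1)| - z*sqrt(1/(c1+pc)+1/(c2+pc)))
    """
    a = c1 + pseudocount
    b = c2 + pseudocount
    L = abs(np.log((a / b) * (q75_2 / q75_1)))
    se = np.sqrt(1.0 / a + 1.0 / b)
    return max(0.0, float(np.exp(L - z * se)))


def de_table(counts: pd.DataFrame, lib1: str, lib2: str) -> pd.DataFrame:
    """Per-gene DE p/q-values, factor and direction between two libraries.

    ``counts`` needs gene_id plus one count column per library.
    """
    from .imprinting_stats import bh_adjust

    q1, q2 = upper_quartile(counts[lib1], counts[lib2])
    rows = [fisher_de(c1, c2, q1, q2) for c1, c2 in zip(counts[lib1], counts[lib2])]
    out = pd.DataFrame({
        "gene_id": counts["gene_id"].to_numpy(),
        "p_de": [r[0] for r in rows],
        "direction": [r[1] for r in rows],
        "de_factor": [de_factor(c1, c2, q1, q2)
                      for c1, c2 in zip(counts[lib1], counts[lib2])],
    })
    out["q_de"] = bh_adjust(out["p_de"])
    return out[["gene_id", "p_de", "q_de", "de_factor", "direction"]]


def library_correlation(x, y, method: str = "pearson"):
    """QC correlation (Pearson or Spearman) between two expression vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if method == "pearson":
        return float(stats.pearsonr(x[ok], y[ok])[0])
    if method == "spearman":
        return float(stats.spearmanr(x[ok], y[ok])[0])
    raise ValueError(f"unknown method {method!r}")
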