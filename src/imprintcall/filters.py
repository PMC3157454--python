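"""Seed-coat contamination filter for candidate maternally expressed genes.

The seed coat is diploid maternal tissue; transcripts carried over from
it inflate apparent maternal expression, so genes far more expressed in
seed coat than in the assayed tissue can masquerade as MEGs.  Candidate
MEGs whose log2 seed-coat minus tissue reference expression exceeds a
threshold (canonically 1.04, about two-fold) are removed; PEG candidates
are never touched (maternal contamination cannot fake a PEG), and genes
with no reference data are retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["SEEDCOAT_THRESHOLD", "read_reference_expression",
           "seedcoat_difference", "derive_threshold", "filter_megs"]

#: canonical fixed threshold on the log2 seed-coat minus tissue difference
SEEDCOAT_THRESHOLD = 1.04

#: candidate-PEG pool size below which the data-driven threshold is unstable
MIN_PEGS_FOR_THRESHOLD = 20


def read_reference_expression(path) -> pd.DataFrame:
    """Reference TSV: gene_id, seed_coat, endosperm, embryo (log2, '.' missing)."""
    df = pd.read_csv(path, sep="\t", na_values=".")
    missing = {"gene_id", "seed_coat", "endosperm", "embryo"} - set(df.columns)
    if missing:
        raise ValueError(f"reference expression lacks columns: {sorted(missing)}")
    return df


def seedcoat_difference(ref: pd.DataFrame, tissue: str) -> pd.Series:
    """Per-gene log2(seed coat) - log2(tissue); NaN where data is missing."""
    if tissue not in ("embryo", "endosperm"):
        raise ValueError(f"unknown tissue {tissue!r}")
    diff = ref["seed_coat"] - ref[tissue]
    return pd.Series(diff.to_numpy(), index=ref["gene_id"].to_numpy(),
                     name="seedcoat_diff")


def derive_threshold(peg_differences) -> float:
    """Data-driven threshold: 95th percentile of candidate-PEG differences.

    Mirrors how the canonical 1.04 was obtained (PEGs cannot be created by
    maternal contamination, so their seed coat-tissue spread calibrates
    the innocuous range).  Requires a reasonably sized PEG pool.
    """
    d = np.asarray(peg_differences, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < MIN_PEGS_FOR_THRESHOLD:
        raise ValueError(
            f"need >= {MIN_PEGS_FOR_THRESHOLD} candidate-PEG differences for a "
            f"stable threshold; got {d.size} (use the fixed default instead)")
    return float(np.percentile(d, 95))


def filter_megs(results: pd.DataFrame, differences: pd.Series,
                threshold: float = SEEDCOAT_THRESHOLD,
                candidate_col: str = "call") -> pd.DataFrame:
    """Demote maternal candidates that look like seed-coat contamination.

    Rows whose call is MEG (or direction maternal among candidates) with a
    known difference strictly greater than ``threshold`` get their call
    replaced by ``not_imprinted`` and a ``filter_reason`` of
    ``seedcoat_contamination``.  Idempotent; never touches PEGs; missing
    reference data retains the gene.
    """
    out = results.copy()
    if "filter_reason" not in out.columns:
        out["filter_reason"] = "."
    diff = out["gene_id"].map(differences)
    is_meg = out[candidate_col] == "MEG"
    removed = is_meg & diff.notna() & (diff > threshold)
    out["seedcoat_diff"] = diff.to_numpy()
    out.loc[removed, "filter_reason"] = "seedcoat_contamination"
    out.loc[removed, candidate_col] = "not_imprinted"
    return out
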