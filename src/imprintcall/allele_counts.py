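"""Classify aligned reads as Col or Ler by SNP overlap and count per gene.

A read is informative when it overlaps at least one known Col/Ler SNP
within the exons of exactly one gene.  Classification follows the
all-SNPs-agree rule: a read is Col only if every overlapped SNP shows the
Col base (Ler symmetric); a mixture or a third allele is *conflicting*,
no SNP overlap is *ambiguous*.  Reads that are not uniquely mapped, or
whose aligned blocks touch exons of more than one gene, are excluded
before counting.

Coordinates are 0-based half-open internally; SNP tables are 1-based
(converted on read), GFF3 is 1-based inclusive, BED 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel", "read_snp_table", "read_snps_vcf", "filter_snps",
    "read_gene_models_gff3", "read_gene_models_bed", "classify_read",
    "count_alleles", "merge_reciprocal",
]

SNP_COLUMNS = ["chrom", "pos", "col_base", "ler_base", "consensus_fraction"]
CLASSES = ("col", "ler", "ambiguous", "conflicting")


@dataclass
class GeneModel:
    """A gene as a union of exon intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    exons: list = field(default_factory=list)

    def __post_init__(self):
        self.exons = _merge_intervals(self.exons)
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id} has no exonic length")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def _merge_intervals(intervals):
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# reference inputs
# ---------------------------------------------------------------------------

def read_snp_table(path) -> pd.DataFrame:
    """SNP TSV: chrom, pos (1-based), col_base, ler_base, consensus_fraction.

    '.' marks a missing consensus fraction (such SNPs survive filtering).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=".")
    missing = set(SNP_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"SNP table lacks columns: {sorted(missing)}")
    if "consensus_fraction" not in df.columns:
        df["consensus_fraction"] = np.nan
    bad = df["col_base"] == df["ler_base"]
    if bad.any():
        raise ValueError(f"{bad.sum()} SNPs have identical Col and Ler bases")
    return df[SNP_COLUMNS]


def read_snps_vcf(path, sample_is_ler: bool = True) -> pd.DataFrame:
    """Biallelic SNPs from a VCF; REF is Col, ALT is Ler by default."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        if not v.is_snp or len(v.ALT) != 1:
            continue
        col, ler = (v.REF, v.ALT[0]) if sample_is_ler else (v.ALT[0], v.REF)
        rows.append({"chrom": v.CHROM, "pos": v.POS, "col_base": col,
                     "ler_base": ler, "consensus_fraction": np.nan})
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def filter_snps(snps: pd.DataFrame, min_consensus: float = 0.95) -> pd.DataFrame:
    """Drop SNPs whose known consensus support is below ``min_consensus``.

    The boundary is inclusive (0.95 is retained); SNPs with no consensus
    information are kept.
    """
    cf = snps["consensus_fraction"]
    keep = cf.isna() | (cf >= min_consensus)
    return snps[keep].reset_index(drop=True)


def read_gene_models_gff3(path) -> list:
    """Gene models from GFF3 via gffutils (exons grouped under genes)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        exons = [(e.start - 1, e.end)                    # GFF3 1-based inclusive
                 for e in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        models.append(GeneModel(gene.id, gene.seqid, gene.strand, exons))
    return models


def read_gene_models_bed(path) -> list:
    """Gene models from BED6 (one exon) or BED12 (blocked) lines."""
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
            strand = f[5] if len(f) > 5 else "."
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            else:
                exons = [(start, end)]
            models.append(GeneModel(name, chrom, strand, exons))
    return models


# ---------------------------------------------------------------------------
# classification and counting
# ---------------------------------------------------------------------------

def classify_read(bases_at_snps) -> str:
    """All-SNPs-agree rule on (observed, col_base, ler_base) triples.

    Classification is strand-agnostic: callers must pass bases already on
    the reference orientation (as pysam reports them).  A base matching
    neither strain makes the read conflicting, not ignored.
    """
    if not bases_at_snps:
        return "ambiguous"
    votes = set()
    for obs, col, ler in bases_at_snps:
        obs = obs.upper()
        if obs == col.upper():
            votes.add("col")
        elif obs == ler.upper():
            votes.add("ler")
        else:
            return "conflicting"
    return votes.pop() if len(votes) == 1 else "conflicting"


class _GeneIndex:
    """Exon interval lookup per chromosome -> gene ids."""

    def __init__(self, gene_models):
        self.trees: dict[str, IntervalTree] = {}
        self.by_id = {}
        for g in gene_models:
            self.by_id[g.gene_id] = g
            tree = self.trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                tree[s:e] = g.gene_id

    def genes_for_blocks(self, chrom, blocks):
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        hits = set()
        for s, e in blocks:
            for iv in tree.overlap(s, e):
                hits.add(iv.data)
        return hits


def _snp_index(snps: pd.DataFrame):
    idx = {}
    for chrom, grp in snps.groupby("chrom"):
        order = np.argsort(grp["pos"].to_numpy())
        idx[chrom] = (grp["pos"].to_numpy()[order] - 1,          # 0-based
                      grp["col_base"].to_numpy()[order],
                      grp["ler_base"].to_numpy()[order])
    return idx


def count_alleles(sam_path, gene_models, snps: pd.DataFrame, cross_label: str,
                  mapq_floor: int = 0):
    """Tally Col/Ler/ambiguous/conflicting reads per gene for one library.

    Uniqueness: a read counts as uniquely mapped when its MAPQ exceeds
    ``mapq_floor`` or it carries an explicit NH=1 tag (the closest
    SAM-level proxy for discarding equal-score multi-mappers).  Reads
    touching exons of more than one gene are excluded.  Returns
    ``(counts, total_unique)`` — the per-gene table (with the cross label
    attached) and the library's uniquely-mapped read total for RPKM.
    """
    import pysam

    gene_idx = _GeneIndex(gene_models)
    snp_idx = _snp_index(snps)
    tallies = {g.gene_id: dict.fromkeys(CLASSES, 0) for g in gene_models}
    total_unique = 0
    unknown_chroms = set()

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec_no, read in enumerate(sam):
            try:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                unique = read.mapping_quality > mapq_floor or (
                    read.has_tag("NH") and read.get_tag("NH") == 1)
                if not unique:
                    continue
                chrom = read.reference_name
                if chrom not in gene_idx.trees:
                    if chrom not in unknown_chroms:
                        unknown_chroms.add(chrom)
                        logger.warning("SAM chromosome %r not in gene models; skipping", chrom)
                    continue
                total_unique += 1
                blocks = read.get_blocks()
                genes = gene_idx.genes_for_blocks(chrom, blocks)
                if len(genes) != 1:
                    continue                 # non-exonic, or overlapping genes
                gene = genes.pop()
                triples = []
                if chrom in snp_idx:
                    pos0, colb, lerb = snp_idx[chrom]
                    ref2q = {r: q for q, r in read.get_aligned_pairs(matches_only=True)}
                    for s, e in blocks:
                        lo, hi = np.searchsorted(pos0, [s, e])
                        for k in range(lo, hi):
                            q = ref2q.get(pos0[k])
                            if q is None:    # under a deletion: skipped
                                continue
                            triples.append((read.query_sequence[q], colb[k], lerb[k]))
                tallies[gene][classify_read(triples)] += 1
            except (ValueError, KeyError, AttributeError) as exc:
                raise ValueError(f"malformed SAM record #{rec_no}: {exc}") from exc

    counts = pd.DataFrame([
        {"gene_id": g, "cross": cross_label, "n_col": t["col"], "n_ler": t["ler"],
         "n_ambiguous": t["ambiguous"], "n_conflicting": t["conflicting"]}
        for g, t in tallies.items()])
    return counts, total_unique


def merge_reciprocal(counts_colxler: pd.DataFrame,
                     counts_lerxcol: pd.DataFrame) -> pd.DataFrame:
    """Outer-join the per-cross tallies into one reciprocal count table.

    Genes seen in only one cross get zeros on the other side.  The result
    carries the maternal orientation implicitly: Col is maternal in
    colxler columns, Ler in lerxcol columns.
    """
    for name, df in (("colxler", counts_colxler), ("lerxcol", counts_lerxcol)):
        if df["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene_id in {name} counts")
    left = counts_colxler.set_index("gene_id")[["n_col", "n_ler"]]
    left.columns = ["colxler_col", "colxler_ler"]
    right = counts_lerxcol.set_index("gene_id")[["n_col", "n_ler"]]
    right.columns = ["lerxcol_col", "lerxcol_ler"]
    merged = left.join(right, how="outer").fillna(0).astype(int)
    merged.index.name = "gene_id"
    return merged.reset_index()
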