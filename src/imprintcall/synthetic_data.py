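"""Synthetic reciprocal-cross data with known imprinting structure.

Emulates the data model of a seed allele-specific expression study: for
each gene, informative (SNP-overlapping) read counts in two reciprocal
crosses are drawn binomially around a true Col fraction determined by the
gene's class —

* biallelic: maternal fraction at the tissue expectation (1/2 embryo,
  2/3 endosperm);
* MEG / PEG: maternal fraction drawn per gene from a range, so partial
  imprinting is the default and complete imprinting the extreme;
* cis: a strain fold effect multiplying the Col allele's expression in
  both crosses, independent of parent of origin.

Maternal-tissue (seed coat) contamination is modelled causally: a
contaminated sample carries extra reads that are 100% maternal-strain,
allocated to genes in proportion to their seed-coat expression excess.
This reproduces the key asymmetry — contamination can fake MEGs but can
only hide PEGs.  A companion reference-expression table (log2 scale,
seed coat / endosperm / embryo) supports the contamination filter, and a
toy SAM + FASTA + GFF3 + SNP fixture supports end-to-end read counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .imprinting_stats import COUNT_COLUMNS

__all__ = ["SimConfig", "generate_counts", "generate_reference_expression",
           "make_toy_reference", "generate_reads"]


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions emulated here.

    Informative depth per gene per cross is negative-binomial (mean 50,
    dispersion 2) — overdispersed, so a realistic share of genes falls
    below the 15-read floor.  Class proportions give a minority of
    imprinted genes with MEGs outnumbering PEGs.  ``kappa`` is the mass
    fraction of contaminating maternal seed-coat RNA (0 = clean sample).
    """

    n_genes: int = 2000
    tissue: str = "endosperm"
    depth_mean: float = 50.0
    depth_dispersion: float = 2.0
    frac_meg: float = 0.05
    frac_peg: float = 0.02
    frac_cis: float = 0.02
    #: per-gene maternal-fraction ranges for imprinted classes
    meg_m: tuple = (0.85, 1.0)
    peg_m: tuple = (0.0, 0.40)
    #: |log2| strain fold range for cis genes (sign drawn at random)
    cis_log2_fold: tuple = (0.5, 2.0)
    kappa: float = 0.0
    #: fraction of genes strongly seed-coat enriched, and their log2 excess
    #: (8- to 256-fold: the storage/protective transcripts that dominate the
    #: seed-coat RNA pool and hence the contaminant mass)
    sc_high_frac: float = 0.10
    sc_high_excess: tuple = (3.0, 8.0)
    sc_background_sd: float = 0.5
    #: fraction of genes missing from the reference expression table
    missing_frac: float = 0.15
    seed: int = 0

    @property
    def m0(self) -> float:
        return 0.5 if self.tissue == "embryo" else 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.tissue not in ("embryo", "endosperm"):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if not (0 <= self.frac_meg and 0 <= self.frac_peg and 0 <= self.frac_cis):
            raise ValueError("class fractions must be non-negative")
        if self.frac_meg + self.frac_peg + self.frac_cis > 1:
            raise ValueError("class fractions must sum to at most 1")
        if not 0 <= self.kappa < 1:
            raise ValueError("kappa must lie in [0, 1)")
        for lo, hi in (self.meg_m, self.peg_m):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("maternal-fraction ranges must lie in [0, 1]")


def _col_fraction(m: np.ndarray, cis_fold: np.ndarray, maternal_is_col: bool):
    """Col read fraction given maternal fraction m and Col:Ler strain fold."""
    col_share = m if maternal_is_col else 1.0 - m
    return col_share * cis_fold / (col_share * cis_fold + (1.0 - col_share))


def generate_counts(config: SimConfig):
    """Draw a reciprocal count table and its ground truth.

    Returns ``(counts, truth)`` DataFrames.  ``counts`` has the canonical
    columns (gene_id, colxler_col, colxler_ler, lerxcol_col, lerxcol_ler);
    ``truth`` records the class, true per-cross maternal fractions, strain
    fold, log2 base expression, seed-coat log2 excess, and the drawn
    (pre-contamination) depths.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    m0 = config.m0

    n_meg = round(config.frac_meg * n)
    n_peg = round(config.frac_peg * n)
    n_cis = round(config.frac_cis * n)
    klass = np.array(["biallelic"] * n, dtype=object)
    order = rng.permutation(n)
    klass[order[:n_meg]] = "MEG"
    klass[order[n_meg:n_meg + n_peg]] = "PEG"
    klass[order[n_meg + n_peg:n_meg + n_peg + n_cis]] = "cis"

    m = np.full(n, m0)
    is_meg = klass == "MEG"
    is_peg = klass == "PEG"
    m[is_meg] = rng.uniform(*config.meg_m, is_meg.sum())
    m[is_peg] = rng.uniform(*config.peg_m, is_peg.sum())

    cis_fold = np.ones(n)
    is_cis = klass == "cis"
    log2f = rng.uniform(*config.cis_log2_fold, is_cis.sum())
    log2f *= rng.choice([-1.0, 1.0], is_cis.sum())
    cis_fold[is_cis] = 2.0 ** log2f

    base_expr = rng.normal(5.0, 2.0, n)
    sc_excess = rng.normal(0.0, config.sc_background_sd, n)
    sc_high = np.zeros(n, dtype=bool)
    n_high = round(config.sc_high_frac * n)
    sc_high[rng.choice(n, n_high, replace=False)] = True
    sc_excess[sc_high] = rng.uniform(*config.sc_high_excess, n_high)

    disp = config.depth_dispersion
    p_nb = disp / (disp + config.depth_mean)
    n1 = rng.negative_binomial(disp, p_nb, n)
    n2 = rng.negative_binomial(disp, p_nb, n)

    f1 = _col_fraction(m, cis_fold, maternal_is_col=True)
    f2 = _col_fraction(m, cis_fold, maternal_is_col=False)
    a1 = rng.binomial(n1, f1)
    b1 = n1 - a1
    a2 = rng.binomial(n2, f2)
    b2 = n2 - a2

    if config.kappa > 0:
        # contaminant reads ~ Poisson, proportional to seed-coat excess;
        # normalised so the transcriptome-wide contaminant mass is ~kappa
        w = 2.0 ** sc_excess
        lam = (config.kappa / (1.0 - config.kappa)) * config.depth_mean * w / w.mean()
        c1 = rng.poisson(lam)
        c2 = rng.poisson(lam)
        a1 = a1 + c1          # maternal strain is Col in cross 1
        b2 = b2 + c2          # and Ler in cross 2

    counts = pd.DataFrame({
        "gene_id": [f"G{k:05d}" for k in range(n)],
        "colxler_col": a1, "colxler_ler": b1,
        "lerxcol_col": a2, "lerxcol_ler": b2,
    })[COUNT_COLUMNS]
    truth = pd.DataFrame({
        "gene_id": counts["gene_id"],
        "klass": klass,
        "m1": m, "m2": m,
        "cis_fold": cis_fold,
        "base_expr": base_expr,
        "sc_excess": sc_excess,
        "depth1": n1, "depth2": n2,
    })
    return counts, truth


def generate_reference_expression(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Companion log2 reference expression table (seed coat/endosperm/embryo).

    Seed-coat expression is the gene's base expression plus its seed-coat
    excess; genes flagged as strongly seed-coat enriched are kept above
    the canonical 1.04 filter threshold by construction (a strongly
    enriched transcript is reliably detected as such on the array).
    Missingness (no array data) is concentrated on the weakest-expressed
    genes, as probe detection fails mainly for low-expression loci.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(truth)
    endosperm = truth["base_expr"].to_numpy() + rng.normal(0, 0.3, n)
    embryo = truth["base_expr"].to_numpy() + rng.normal(0, 0.5, n)
    diff = truth["sc_excess"].to_numpy() + rng.normal(0, 0.2, n)
    sc_high = truth["sc_excess"].to_numpy() >= min(config.sc_high_excess)
    diff[sc_high] = np.maximum(diff[sc_high], 1.1)
    seed_coat = endosperm + diff

    ref = pd.DataFrame({
        "gene_id": truth["gene_id"].to_numpy(),
        "seed_coat": seed_coat,
        "endosperm": endosperm,
        "embryo": embryo,
    })
    n_missing = round(config.missing_frac * n)
    if n_missing:
        detect = ref[["seed_coat", "endosperm", "embryo"]].max(axis=1)
        detect = detect + rng.normal(0, 0.5, n)      # noisy detection limit
        drop = detect.nsmallest(n_missing).index
        ref.loc[drop, ["seed_coat", "endosperm", "embryo"]] = np.nan
    return ref


# ---------------------------------------------------------------------------
# read-level fixture (toy genome, SAM)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def make_toy_reference(n_genes: int, seed: int = 0, gene_length: int = 300,
                       spacing: int = 200, snps_per_gene: int = 1,
                       chrom: str = "chr1"):
    """Toy single-chromosome genome for read-level round trips.

    Returns ``(ref_seq, gene_models, snps)``: the Col reference sequence,
    a gene-model table (one exon per gene, 0-based half-open), and a SNP
    table (1-based positions inside exons, col_base != ler_base).
    """
    rng = np.random.default_rng(seed)
    genes = []
    snp_rows = []
    pos = spacing
    seq = rng.choice(_BASES, spacing).tolist()
    for g in range(n_genes):
        start, end = pos, pos + gene_length
        genes.append({"gene_id": f"G{g:05d}", "chrom": chrom, "strand": "+",
                      "start": start, "end": end})
        seq.extend(rng.choice(_BASES, gene_length + spacing).tolist())
        step = gene_length // (snps_per_gene + 1)
        for s in range(snps_per_gene):
            p0 = start + (s + 1) * step              # 0-based
            col = seq[p0]
            ler = rng.choice(_BASES[_BASES != col])
            snp_rows.append({"chrom": chrom, "pos": p0 + 1, "col_base": col,
                             "ler_base": ler, "consensus_fraction": 1.0})
        pos = end + spacing
    ref_seq = "".join(seq)
    return ref_seq, pd.DataFrame(genes), pd.DataFrame(snp_rows)


def generate_reads(counts: pd.DataFrame, snps: pd.DataFrame,
                   gene_models: pd.DataFrame, config: SimConfig,
                   sam_prefix, fasta_path=None, ref_seq: str | None = None,
                   read_length: int = 36):
    """Write per-cross SAMs of strain-tagged reads realising a count table.

    For each gene, one read per informative count is placed so that it
    overlaps exactly one SNP of the gene, carrying the Col or Ler base at
    that position; counting the SAMs therefore recovers the generating
    table exactly.  SNPs outside every exon trigger a warning and are not
    used; genes without a usable SNP are skipped.  Writes
    ``<sam_prefix>.colxler.sam`` and ``<sam_prefix>.lerxcol.sam`` (and the
    Col reference FASTA if requested) and returns ``(sam_paths, subset)``
    where subset is the part of the count table actually realised.
    """
    import pysam

    rng = np.random.default_rng(config.seed + 2)
    gm = gene_models.set_index("gene_id")
    chrom_len: dict[str, int] = {}
    for _, g in gene_models.iterrows():
        chrom_len[g["chrom"]] = max(chrom_len.get(g["chrom"], 0), int(g["end"]) + 1000)

    usable: dict[str, list] = {}
    for _, s in snps.iterrows():
        p0 = int(s["pos"]) - 1
        hit = gene_models[(gene_models["chrom"] == s["chrom"])
                          & (gene_models["start"] <= p0)
                          & (p0 < gene_models["end"])]
        if len(hit) == 0:
            warnings.warn(f"SNP {s['chrom']}:{s['pos']} falls outside every exon; unused")
            continue
        usable.setdefault(hit.iloc[0]["gene_id"], []).append(s)

    if ref_seq is None:
        ref_seq = "".join(rng.choice(_BASES, max(chrom_len.values(), default=1000)))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for c in chrom_len:
                fh.write(f">{c}\n{ref_seq}\n")

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": len(ref_seq)} for c in chrom_len]}
    chrom_ids = {c: k for k, c in enumerate(chrom_len)}

    def place_read(gene_row, snp, strain, name):
        p0 = int(snp["pos"]) - 1
        lo = max(int(gene_row["start"]), p0 - read_length + 1)
        hi = min(p0, int(gene_row["end"]) - read_length)
        start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        seq = list(ref_seq[start:start + read_length])
        seq[p0 - start] = snp["col_base"] if strain == "col" else snp["ler_base"]
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = "".join(seq)
        a.flag = 0
        a.reference_id = chrom_ids[gene_row["chrom"]]
        a.reference_start = start
        a.mapping_quality = 50
        a.cigarstring = f"{read_length}M"
        return a

    sam_paths = {}
    written = set()
    for cross, col_key, ler_key in (("colxler", "colxler_col", "colxler_ler"),
                                    ("lerxcol", "lerxcol_col", "lerxcol_ler")):
        path = Path(f"{sam_prefix}.{cross}.sam")
        sam_paths[cross] = path
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            rid = 0
            for _, row in counts.iterrows():
                gene = row["gene_id"]
                if gene not in usable or gene not in gm.index:
                    continue
                g = gm.loc[gene]
                for strain, n_reads in (("col", row[col_key]), ("ler", row[ler_key])):
                    for _ in range(int(n_reads)):
                        snp = usable[gene][rng.integers(len(usable[gene]))]
                        out.write(place_read(g, snp, strain, f"r{rid}"))
                        rid += 1
                written.add(gene)
    subset = counts[counts["gene_id"].isin(written)].reset_index(drop=True)
    return sam_paths, subset
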