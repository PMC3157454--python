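"""Read classification, SNP filtering, and per-gene counting."""

import numpy as np
import pandas as pd
import pytest

from imprintcall import (
    GeneModel,
    SimConfig,
    classify_read,
    count_alleles,
    filter_snps,
    generate_reads,
    make_toy_reference,
    merge_reciprocal,
)
from imprintcall.allele_counts import read_gene_models_bed, read_snp_table


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "col_base", "ler_base",
                                       "consensus_fraction"])


class TestFilterSnps:
    def test_low_consensus_removed_boundary_inclusive(self):
        snps = snp_frame([("chr1", 10, "A", "G", 0.94),
                          ("chr1", 20, "C", "T", 0.95),
                          ("chr1", 30, "G", "A", np.nan)])
        kept = filter_snps(snps)
        assert list(kept["pos"]) == [20, 30]

    def test_empty_input(self):
        assert len(filter_snps(snp_frame([]))) == 0


class TestClassifyRead:
    def test_all_col_bases(self):
        assert classify_read([("A", "A", "G"), ("C", "C", "T")]) == "col"

    def test_all_ler_bases(self):
        assert classify_read([("G", "A", "G"), ("T", "C", "T")]) == "ler"

    def test_disagreeing_snps_conflict(self):
        assert classify_read([("A", "A", "G"), ("T", "C", "T")]) == "conflicting"

    def test_third_allele_conflicts(self):
        assert classify_read([("T", "A", "G")]) == "conflicting"

    def test_no_snp_overlap_is_ambiguous(self):
        assert classify_read([]) == "ambiguous"

    def test_case_insensitive(self):
        assert classify_read([("a", "A", "G")]) == "col"


def write_sam(path, reads, chrom="chr1", length=100000):
    lines = [f"@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for name, flag, rchrom, pos1, mapq, cigar, seq in reads:
        lines.append(f"{name}\t{flag}\t{rchrom}\t{pos1}\t{mapq}\t{cigar}\t"
                     f"*\t0\t0\t{seq}\t*")
    path.write_text("\n".join(lines) + "\n")


class TestCountAlleles:
    def test_round_trip_with_generated_reads(self, tmp_path):
        cfg = SimConfig(n_genes=8, depth_mean=12, frac_meg=0.25, frac_peg=0.25,
                        seed=5)
        ref_seq, gene_table, snps = make_toy_reference(8, seed=5)
        from imprintcall import generate_counts
        counts, _ = generate_counts(cfg)
        sam_paths, realised = generate_reads(counts, snps, gene_table, cfg,
                                             tmp_path / "toy", ref_seq=ref_seq)
        models = [GeneModel(r["gene_id"], r["chrom"], r["strand"],
                            [(r["start"], r["end"])])
                  for _, r in gene_table.iterrows()]
        c1, tot1 = count_alleles(sam_paths["colxler"], models, snps, "colxler")
        c2, tot2 = count_alleles(sam_paths["lerxcol"], models, snps, "lerxcol")
        merged = merge_reciprocal(c1, c2)
        got = merged.set_index("gene_id").loc[realised["gene_id"]]
        want = realised.set_index("gene_id")
        for col in ["colxler_col", "colxler_ler", "lerxcol_col", "lerxcol_ler"]:
            assert (got[col] == want[col]).all(), col
        assert tot1 == want[["colxler_col", "colxler_ler"]].to_numpy().sum()

    def test_read_spanning_two_overlapping_genes_excluded(self, tmp_path):
        models = [GeneModel("gA", "chr1", "+", [(100, 300)]),
                  GeneModel("gB", "chr1", "+", [(250, 500)])]
        snps = snp_frame([("chr1", 271, "A", "G", 1.0)])  # 1-based; 0-based 270
        sam = tmp_path / "overlap.sam"
        write_sam(sam, [("r1", 0, "chr1", 261, 50, "20M", "A" * 20)])
        counts, _ = count_alleles(sam, models, snps, "colxler")
        assert counts[["n_col", "n_ler", "n_ambiguous", "n_conflicting"]] \
            .to_numpy().sum() == 0

    def test_zero_read_sam_gives_zero_table(self, tmp_path):
        models = [GeneModel("gA", "chr1", "+", [(100, 300)])]
        sam = tmp_path / "empty.sam"
        write_sam(sam, [])
        counts, total = count_alleles(sam, models, snp_frame([]), "colxler")
        assert total == 0
        assert counts[["n_col", "n_ler", "n_ambiguous", "n_conflicting"]] \
            .to_numpy().sum() == 0

    def test_multimapper_discarded_by_mapq_floor(self, tmp_path):
        models = [GeneModel("gA", "chr1", "+", [(100, 300)])]
        snps = snp_frame([("chr1", 151, "A", "G", 1.0)])
        sam = tmp_path / "mapq.sam"
        write_sam(sam, [("good", 0, "chr1", 141, 50, "20M", "A" * 20),
                        ("multi", 0, "chr1", 141, 0, "20M", "A" * 20)])
        counts, total = count_alleles(sam, models, snps, "colxler")
        assert total == 1
        assert counts.loc[counts["gene_id"] == "gA", "n_col"].item() == 1

    def test_unknown_chromosome_skipped_with_warning(self, tmp_path, caplog):
        models = [GeneModel("gA", "chr1", "+", [(100, 300)])]
        sam = tmp_path / "chr.sam"
        write_sam(sam, [("r1", 0, "chr9", 141, 50, "20M", "A" * 20)],
                  chrom="chr9")
        with caplog.at_level("WARNING"):
            counts, total = count_alleles(sam, models, snp_frame([]), "colxler")
        assert total == 0
        assert "chr9" in caplog.text

    def test_tally_partition_invariant(self, tmp_path):
        # every counted read lands in exactly one of the four classes
        cfg = SimConfig(n_genes=5, depth_mean=10, seed=9)
        ref_seq, gene_table, snps = make_toy_reference(5, seed=9)
        from imprintcall import generate_counts
        counts, _ = generate_counts(cfg)
        sam_paths, realised = generate_reads(counts, snps, gene_table, cfg,
                                             tmp_path / "t", ref_seq=ref_seq)
        models = [GeneModel(r["gene_id"], r["chrom"], r["strand"],
                            [(r["start"], r["end"])])
                  for _, r in gene_table.iterrows()]
        c1, tot1 = count_alleles(sam_paths["colxler"], models, snps, "colxler")
        assert c1[["n_col", "n_ler", "n_ambiguous", "n_conflicting"]] \
            .to_numpy().sum() == tot1


class TestMergeReciprocal:
    def tally(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "cross", "n_col",
                                           "n_ler", "n_ambiguous",
                                           "n_conflicting"])

    def test_disjoint_gene_sets_zero_filled(self):
        c1 = self.tally([("gA", "colxler", 5, 3, 0, 0)])
        c2 = self.tally([("gB", "lerxcol", 2, 7, 0, 0)])
        m = merge_reciprocal(c1, c2).set_index("gene_id")
        assert m.loc["gA", "lerxcol_col"] == 0
        assert m.loc["gB", "colxler_ler"] == 0
        assert m.loc["gA", "colxler_col"] == 5

    def test_identity_merge(self):
        c = self.tally([("gA", "x", 5, 3, 1, 0), ("gB", "x", 2, 7, 0, 1)])
        m = merge_reciprocal(c, c).set_index("gene_id")
        assert m.loc["gA", "colxler_col"] == m.loc["gA", "lerxcol_col"] == 5

    def test_duplicate_gene_rejected(self):
        c = self.tally([("gA", "x", 5, 3, 0, 0), ("gA", "x", 1, 1, 0, 0)])
        with pytest.raises(ValueError):
            merge_reciprocal(c, self.tally([]))

    def test_maternal_total_identity(self, rng):
        rows1 = [(f"g{k}", "x", int(rng.integers(0, 50)),
                  int(rng.integers(0, 50)), 0, 0) for k in range(20)]
        rows2 = [(f"g{k}", "y", int(rng.integers(0, 50)),
                  int(rng.integers(0, 50)), 0, 0) for k in range(20)]
        m = merge_reciprocal(self.tally(rows1), self.tally(rows2))
        maternal = m["colxler_col"] + m["lerxcol_ler"]
        expect = np.array([r[2] for r in rows1]) + np.array([r[3] for r in rows2])
        got = m.set_index("gene_id").loc[[f"g{k}" for k in range(20)]]
        assert ((got["colxler_col"] + got["lerxcol_ler"]).to_numpy()
                == expect).all()


class TestFileReaders:
    def test_snp_table_round_trip(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("chrom\tpos\tcol_base\tler_base\tconsensus_fraction\n"
                     "chr1\t100\tA\tG\t0.99\nchr1\t200\tC\tT\t.\n")
        df = read_snp_table(p)
        assert len(df) == 2
        assert np.isnan(df["consensus_fraction"].iloc[1])

    def test_snp_table_rejects_identical_alleles(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("chrom\tpos\tcol_base\tler_base\tconsensus_fraction\n"
                     "chr1\t100\tA\tA\t0.99\n")
        with pytest.raises(ValueError):
            read_snp_table(p)

    def test_bed12_blocks_become_exons(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t500\tgA\t0\t+\t100\t500\t0\t2\t50,100\t0,300\n")
        (g,) = read_gene_models_bed(p)
        assert g.exons == [(100, 150), (400, 500)]
        assert g.length == 150

    def test_gene_model_rejects_empty(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "+", [])


class TestGff3Reader:
    def test_exons_grouped_under_genes(self, tmp_path):
        from imprintcall.allele_counts import read_gene_models_gff3
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t101\t500\t.\t+\t.\tID=gA\n"
            "chr1\t.\tmRNA\t101\t500\t.\t+\t.\tID=gA.1;Parent=gA\n"
            "chr1\t.\texon\t101\t200\t.\t+\t.\tParent=gA.1\n"
            "chr1\t.\texon\t401\t500\t.\t+\t.\tParent=gA.1\n")
        (g,) = read_gene_models_gff3(p)
        assert g.gene_id == "gA"
        assert g.exons == [(100, 200), (400, 500)]   # converted to 0-based
        assert g.length == 200


class TestGenerateReadsEdgeCases:
    def test_snp_outside_exons_warns_and_is_unused(self, tmp_path):
        import warnings as warnings_mod
        from imprintcall import SimConfig, generate_counts, generate_reads
        ref_seq, gene_table, snps = make_toy_reference(2, seed=1)
        stray = snp_frame([("chr1", 5, "A", "G", 1.0)])
        snps_all = pd.concat([snps, stray], ignore_index=True)
        cfg = SimConfig(n_genes=2, depth_mean=5, seed=1)
        counts, _ = generate_counts(cfg)
        with pytest.warns(UserWarning, match="outside every exon"):
            generate_reads(counts, snps_all, gene_table, cfg, tmp_path / "w",
                           ref_seq=ref_seq)
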