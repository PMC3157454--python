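"""End-to-end orchestration with a structured config and a run manifest.

Stage order follows the analysis narrative: count allelic reads (or load
a count table) -> informative-read floor -> exact test + BH -> seed-coat
contamination filter -> factor and cis filters (inside classification) ->
genomic context.  Every output is TSV ('.' for missing); a JSON manifest
records parameters, seed, package version, and input checksums so a run
is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .allele_counts import (count_alleles, filter_snps, merge_reciprocal,
                            read_gene_models_bed, read_gene_models_gff3,
                            read_snp_table)
from .filters import (SEEDCOAT_THRESHOLD, filter_megs,
                      read_reference_expression, seedcoat_difference)
from .genomic_context import (associate_dmrs, find_miniclusters,
                              read_bed_intervals)
from .imprinting_stats import COUNT_COLUMNS, CriteriaConfig, analyze_counts
from .synthetic_data import (SimConfig, generate_counts,
                             generate_reference_expression)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "load_counts", "write_tsv"]

MISSING = "."


@dataclass
class PipelineConfig:
    """Inputs, thresholds and bookkeeping for one pipeline run."""

    tissue: str = "endosperm"
    counts: str | None = None
    sam_colxler: str | None = None
    sam_lerxcol: str | None = None
    snps: str | None = None
    gene_models: str | None = None
    reference_expression: str | None = None
    dmrs: str | None = None
    out_dir: str = "imprintcall_out"
    seed: int = 0
    seedcoat_threshold: float = SEEDCOAT_THRESHOLD
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    simulate: SimConfig | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        crit = CriteriaConfig(**raw.pop("criteria", {}))
        sim = raw.pop("simulate", None)
        sim = SimConfig(**sim) if sim is not None else None
        cfg = cls(criteria=crit, simulate=sim, **raw)
        if cfg.tissue not in ("embryo", "endosperm"):
            raise ValueError(f"unknown tissue {cfg.tissue!r}")
        return cfg

    def input_paths(self):
        for name in ("counts", "sam_colxler", "sam_lerxcol", "snps",
                     "gene_models", "reference_expression", "dmrs"):
            p = getattr(self, name)
            if p is not None:
                yield name, Path(p)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=MISSING)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table lacks columns: {sorted(missing)}")
    return df


def _read_gene_models(path: str):
    p = Path(path)
    if p.suffix.lower() in (".gff", ".gff3"):
        return read_gene_models_gff3(p)
    return read_gene_models_bed(p)


def count_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """SAM + SNPs + gene models -> reciprocal count table."""
    snps = filter_snps(read_snp_table(cfg.snps))
    models = _read_gene_models(cfg.gene_models)
    c1, _ = count_alleles(cfg.sam_colxler, models, snps, "colxler")
    c2, _ = count_alleles(cfg.sam_lerxcol, models, snps, "lerxcol")
    return merge_reciprocal(c1, c2)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns a bundle of result frames.

    Fails fast with the offending path when a configured input does not
    exist.  Identical config + seed give identical outputs.
    """
    logging.basicConfig(level=cfg.log_level)
    for name, p in cfg.input_paths():
        if not p.exists():
            raise FileNotFoundError(f"configured input {name} not found: {p}")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if cfg.simulate is not None:
        counts, truth = generate_counts(cfg.simulate)
        ref = generate_reference_expression(cfg.simulate, truth)
        write_tsv(counts, out_dir / "simulated_counts.tsv")
        write_tsv(truth, out_dir / "simulated_truth.tsv")
        write_tsv(ref, out_dir / "simulated_reference_expression.tsv")
        bundle["truth"] = truth
        reference = ref
    elif cfg.counts is not None:
        counts = load_counts(cfg.counts)
        reference = (read_reference_expression(cfg.reference_expression)
                     if cfg.reference_expression else None)
    elif cfg.sam_colxler and cfg.sam_lerxcol and cfg.snps and cfg.gene_models:
        counts = count_stage(cfg)
        write_tsv(counts, out_dir / "allelic_counts.tsv")
        reference = (read_reference_expression(cfg.reference_expression)
                     if cfg.reference_expression else None)
    else:
        raise ValueError("config must provide counts, SAM inputs, or a "
                         "simulate block")
    bundle["counts"] = counts

    results = analyze_counts(counts, cfg.tissue, cfg.criteria)
    if reference is not None:
        diffs = seedcoat_difference(reference, cfg.tissue)
        results = filter_megs(results, diffs, threshold=cfg.seedcoat_threshold)
    write_tsv(results, out_dir / "imprinting_results.tsv")
    bundle["results"] = results

    if cfg.dmrs and cfg.gene_models:
        models = _read_gene_models(cfg.gene_models)
        dmrs = read_bed_intervals(cfg.dmrs)
        assoc = associate_dmrs(models, dmrs)
        imprinted = results.loc[results["call"].isin(["MEG", "PEG"]), "gene_id"]
        clusters = find_miniclusters(
            [m for m in models if m.gene_id in set(imprinted)],
            informative_genes=models)
        write_tsv(assoc.rename_axis("gene_id").reset_index(),
                  out_dir / "dmr_association.tsv")
        write_tsv(pd.DataFrame(clusters), out_dir / "miniclusters.tsv")
        bundle["dmr_association"] = assoc
        bundle["clusters"] = clusters

    manifest = {
        "package": "imprintcall",
        "version": __version__,
        "tissue": cfg.tissue,
        "seed": cfg.seed,
        "criteria": dataclasses.asdict(cfg.criteria),
        "simulate": dataclasses.asdict(cfg.simulate) if cfg.simulate else None,
        "seedcoat_threshold": cfg.seedcoat_threshold,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in cfg.input_paths()},
        "calls": results["call"].value_counts().to_dict(),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
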