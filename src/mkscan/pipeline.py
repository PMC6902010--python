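"""Stage orchestration: library entry points behind the command line.

Each ``run_*`` function corresponds to one pipeline stage, takes in-memory
inputs or file paths, and returns DataFrames plus bookkeeping counters so
that every dropped or NA gene is accounted for.  ``run_all`` chains the
stages on a dataset directory and writes deterministic TSV outputs and a
machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .group_comparison import (
    RANDOM_SET_SIZE_DEFAULT,
    compare_gene_sets,
    metabolite_count_comparison,
)
from .inter_divergence import (
    COVERAGE_MIN_DEFAULT,
    ESTIMATORS,
    EVALUE_MAX_DEFAULT,
    OrthologPair,
    reciprocal_best_hits,
)
from .intra_polymorphism import classify_gene_snps, per_accession_means, polymorphism_counts
from .codon_model import gene_site_totals
from .seqio import (
    GeneModel,
    SnpRecord,
    read_gene_models,
    read_similarity_hits,
    read_vcf,
    write_results_table,
)
from .selection_stats import classify_positive_selection, enrichment_test

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ContractViolation",
    "run_intra",
    "run_orthologs",
    "run_divergence",
    "run_selection",
    "run_compare",
    "run_all",
]


class ContractViolation(ValueError):
    """An input contract was violated (maps to CLI exit code 2)."""


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run.

    Threshold defaults mirror the emulated study: ortholog admission at
    E-value < 1e-3 and coverage > 90%, positive selection at FDR < 0.05,
    and a 10,000-gene random comparison set.
    """

    gff: str = ""
    genome_fasta: str = ""
    vcf: str = ""
    cds_a_fasta: str = ""
    cds_b_fasta: str = ""
    hits_ab: str = ""
    hits_ba: str = ""
    labels_tsv: str = ""
    metabolites_tsv: str = ""
    out_dir: str = "mkscan_out"
    evalue_max: float = EVALUE_MAX_DEFAULT
    coverage_min: float = COVERAGE_MIN_DEFAULT
    fdr_alpha: float = 0.05
    random_set_size: int = RANDOM_SET_SIZE_DEFAULT
    seed: int = 0
    estimator: str = "ng86_jc"
    fisher_fallback: bool = False

    def validate(self) -> None:
        if not (0 < self.fdr_alpha < 1):
            raise ContractViolation(f"fdr_alpha must lie in (0,1), got {self.fdr_alpha}")
        if self.evalue_max <= 0 or not (0 <= self.coverage_min <= 1):
            raise ContractViolation("thresholds out of range")
        if self.estimator not in ESTIMATORS:
            raise ContractViolation(
                f"unknown estimator {self.estimator!r}; available: {sorted(ESTIMATORS)}"
            )
        for name in ("gff", "genome_fasta", "vcf", "cds_a_fasta", "cds_b_fasta",
                     "hits_ab", "hits_ba", "labels_tsv"):
            path = getattr(self, name)
            if not path:
                raise ContractViolation(f"config field {name!r} is required")
            if not Path(path).exists():
                raise ContractViolation(f"{name}: no such file: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known - {"simulate"} - {k for k in raw if k.startswith("sim_")}
        if unknown:
            raise ContractViolation(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).parent
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        for name in ("gff", "genome_fasta", "vcf", "cds_a_fasta", "cds_b_fasta",
                     "hits_ab", "hits_ba", "labels_tsv", "metabolites_tsv", "out_dir"):
            value = getattr(cfg, name)
            if value and not Path(value).is_absolute():
                setattr(cfg, name, str(base / value))
        return cfg


# ---------------------------------------------------------------------------
# stage: intra-species polymorphism


def run_intra(
    genes: Sequence[GeneModel],
    snps: Sequence[SnpRecord],
    n_accessions: int,
) -> tuple[pd.DataFrame, Counter]:
    """Per-gene Pn/Ps and dN_SNP/dS_SNP over the whole gene set.

    SNPs are assigned to every gene whose CDS span covers them (a SNP in
    overlapping genes counts in each, flagged in the counters).
    """
    by_chrom: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        by_chrom.setdefault(snp.chrom, []).append(snp)
    positions: dict[str, list[int]] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda s: s.pos)
        positions[chrom] = [s.pos for s in by_chrom[chrom]]

    counters: Counter = Counter()
    assignments: Counter = Counter()
    rows = []
    for gene in genes:
        chrom_snps = by_chrom.get(gene.chrom, [])
        pos = positions.get(gene.chrom, [])
        start, end = gene.span
        lo = bisect_left(pos, start + 1)
        hi = bisect_right(pos, end)
        candidates = chrom_snps[lo:hi]
        classified, gene_counters = classify_gene_snps(gene, candidates)
        counters.update(gene_counters)
        for snp in classified:
            assignments[(gene.chrom, gene.cds_to_genomic(snp.cds_offset))] += 1
        sites = gene_site_totals(gene.cds_sequence, gene.gene_id)
        counts = polymorphism_counts(gene, classified, sites)
        mean_nonsyn, mean_syn = per_accession_means(classified, n_accessions)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "N": sites.N,
                "S": sites.S,
                "Pn": counts.Pn,
                "Ps": counts.Ps,
                "dn_snp": counts.dn_snp,
                "ds_snp": counts.ds_snp,
                "ratio": counts.ratio,
                "mean_nonsyn_per_accession": mean_nonsyn,
                "mean_syn_per_accession": mean_syn,
            }
        )
    counters["genes"] = len(genes)
    counters["snps_in_multiple_genes"] = sum(1 for v in assignments.values() if v > 1)
    counters["ratio_na_genes"] = int(sum(1 for r in rows if np.isnan(r["ratio"])))
    return pd.DataFrame(rows), counters


# ---------------------------------------------------------------------------
# stage: orthologs and divergence


def run_orthologs(
    hits_ab_path: str | Path,
    hits_ba_path: str | Path,
    query_lengths_a: Mapping[str, int] | None,
    query_lengths_b: Mapping[str, int] | None,
    evalue_max: float = EVALUE_MAX_DEFAULT,
    coverage_min: float = COVERAGE_MIN_DEFAULT,
) -> tuple[pd.DataFrame, Counter]:
    """Reciprocal-best-hit ortholog pairs from two hit tables."""
    hits_ab = read_similarity_hits(hits_ab_path, query_lengths_a)
    hits_ba = read_similarity_hits(hits_ba_path, query_lengths_b)
    pairs = reciprocal_best_hits(hits_ab, hits_ba, evalue_max, coverage_min)
    counters = Counter(
        hits_ab=len(hits_ab), hits_ba=len(hits_ba), pairs=len(pairs),
        unpaired_queries_a=len({h.query_id for h in hits_ab}) - len(pairs),
    )
    return pd.DataFrame([dataclasses.asdict(p) for p in pairs]), counters


def run_divergence(
    pairs: pd.DataFrame,
    cds_a: Mapping[str, str],
    cds_b: Mapping[str, str],
    estimator: str = "ng86_jc",
) -> tuple[pd.DataFrame, Counter]:
    """Per-pair Dn/Ds and KA/KS with the configured estimator backend."""
    estimate = ESTIMATORS[estimator]
    counters: Counter = Counter()
    rows = []
    for pair in pairs.itertuples(index=False):
        if pair.gene_a not in cds_a or pair.gene_b not in cds_b:
            counters["missing_cds"] += 1
            continue
        d = estimate(cds_a[pair.gene_a], cds_b[pair.gene_b], pair_id=pair.gene_a)
        counters["pairs_estimated"] += 1
        if d.na_reason:
            counters[f"na_{d.na_reason}"] += 1
        rows.append(
            {
                "gene_a": pair.gene_a,
                "gene_b": pair.gene_b,
                "Dn": d.Dn,
                "Ds": d.Ds,
                "N_avg": d.N_avg,
                "S_avg": d.S_avg,
                "KA": d.KA,
                "KS": d.KS,
                "ka_ks": d.ka_ks,
                "columns_counted": d.columns_counted,
            }
        )
    return pd.DataFrame(rows), counters


# ---------------------------------------------------------------------------
# stage: selection and comparison


def run_selection(
    intra: pd.DataFrame,
    divergence: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = 0.05,
    fisher: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, Counter]:
    """MK statistics, FDR-controlled flags and mQTG-with-CNV enrichment."""
    mk = intra[["gene_id", "Pn", "Ps"]].merge(
        divergence[["gene_a", "Dn", "Ds", "ka_ks"]].rename(columns={"gene_a": "gene_id"}),
        on="gene_id",
        how="inner",
    )
    counters = Counter(
        genes_intra=len(intra), genes_with_divergence=len(mk),
        genes_without_ortholog=len(intra) - len(mk),
    )
    results = classify_positive_selection(
        mk[["gene_id", "Pn", "Ps", "Dn", "Ds"]], alpha=alpha, fisher=fisher
    )
    results = results.merge(mk[["gene_id", "ka_ks"]], on="gene_id")
    counters["chi2_na_genes"] = int(results["chi2_p"].isna().sum())
    counters["pos_sel_NI"] = int(results["pos_sel_NI"].sum())
    counters["pos_sel_DoS"] = int(results["pos_sel_DoS"].sum())

    lab = labels.set_index("gene_id").reindex(results["gene_id"])
    member = (lab["is_mqtg"].astype(bool) & lab["has_cnv"].astype(bool)).to_numpy()
    enrich_rows = []
    for criterion, flag_col in (("NI", "pos_sel_NI"), ("DoS", "pos_sel_DoS")):
        res = enrichment_test(results[flag_col].to_numpy(), member)
        enrich_rows.append({"criterion": criterion, **res})
    return results, pd.DataFrame(enrich_rows), counters


def run_compare(
    results: pd.DataFrame,
    intra: pd.DataFrame,
    labels: pd.DataFrame,
    metabolites: pd.DataFrame | None = None,
    seed: int = 0,
    random_set_size: int = RANDOM_SET_SIZE_DEFAULT,
) -> pd.DataFrame:
    """Figure-style gene-set comparisons on dN_SNP/dS_SNP, KA/KS and NI."""
    metrics = (
        intra[["gene_id", "ratio"]]
        .rename(columns={"ratio": "dn_ds_snp"})
        .merge(results[["gene_id", "ka_ks", "NI"]], on="gene_id", how="left")
        .set_index("gene_id")
    )
    report = compare_gene_sets(metrics, labels, seed=seed, random_set_size=random_set_size)
    if metabolites is not None and len(metabolites):
        counts = metabolites.set_index("gene_id")["metabolite_count"]
        row = metabolite_count_comparison(counts, labels)
        report = pd.concat([report, pd.DataFrame([row])], ignore_index=True)
    return report


# ---------------------------------------------------------------------------
# end-to-end


def _fasta_dict(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run every stage on the configured inputs and write all outputs.

    Output TSVs are deterministic functions of (inputs, seed); the run
    manifest records input hashes, the package version and all stage
    counters so kept + dropped records reconcile at every stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes, rejections = read_gene_models(config.gff, config.genome_fasta)
    snps, vcf_skipped = read_vcf(config.vcf)
    n_accessions = _count_vcf_samples(config.vcf)
    intra, intra_counters = run_intra(genes, snps, n_accessions)

    proteins_a = {k: (len(v) - len(v) % 3) // 3 - 1 for k, v in _fasta_dict(config.cds_a_fasta).items()}
    proteins_b = {k: (len(v) - len(v) % 3) // 3 - 1 for k, v in _fasta_dict(config.cds_b_fasta).items()}
    pairs, rbh_counters = run_orthologs(
        config.hits_ab, config.hits_ba, proteins_a, proteins_b,
        config.evalue_max, config.coverage_min,
    )
    cds_a = _fasta_dict(config.cds_a_fasta)
    cds_b = _fasta_dict(config.cds_b_fasta)
    divergence, div_counters = run_divergence(pairs, cds_a, cds_b, config.estimator)

    labels = pd.read_csv(config.labels_tsv, sep="\t")
    if not {"gene_id", "is_mqtg", "has_cnv"} <= set(labels.columns):
        raise ContractViolation(
            f"labels file {config.labels_tsv} must have columns gene_id, is_mqtg, has_cnv"
        )
    results, enrichment, sel_counters = run_selection(
        intra, divergence, labels, alpha=config.fdr_alpha, fisher=config.fisher_fallback
    )
    metabolites = None
    if config.metabolites_tsv and Path(config.metabolites_tsv).exists():
        metabolites = pd.read_csv(config.metabolites_tsv, sep="\t")
    comparisons = run_compare(
        results, intra, labels, metabolites,
        seed=config.seed, random_set_size=config.random_set_size,
    )

    paths = {
        "intra": out / "intra_polymorphism.tsv",
        "orthologs": out / "orthologs.tsv",
        "divergence": out / "divergence.tsv",
        "selection": out / "selection.tsv",
        "enrichment": out / "enrichment.tsv",
        "comparisons": out / "comparisons.tsv",
        "manifest": out / "run_manifest.json",
    }
    write_results_table(intra, paths["intra"])
    write_results_table(pairs, paths["orthologs"])
    write_results_table(divergence, paths["divergence"])
    write_results_table(results, paths["selection"])
    enrichment.to_csv(paths["enrichment"], sep="\t", index=False, na_rep="NA")
    comparisons.to_csv(paths["comparisons"], sep="\t", index=False, na_rep="NA")

    manifest = {
        "mkscan_version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": {
            name: _sha256(getattr(config, name))
            for name in ("gff", "genome_fasta", "vcf", "cds_a_fasta", "cds_b_fasta",
                         "hits_ab", "hits_ba", "labels_tsv")
        },
        "counters": {
            "gene_models_rejected": len(rejections),
            "vcf_skipped": dict(vcf_skipped),
            "intra": {k: int(v) for k, v in intra_counters.items()},
            "orthologs": {k: int(v) for k, v in rbh_counters.items()},
            "divergence": {k: int(v) for k, v in div_counters.items()},
            "selection": {k: int(v) for k, v in sel_counters.items()},
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run_all complete: %d genes, %d pairs", len(genes), len(pairs))
    return paths


def _count_vcf_samples(vcf_path: str | Path) -> int:
    from cyvcf2 import VCF

    return len(VCF(str(vcf_path)).samples)
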