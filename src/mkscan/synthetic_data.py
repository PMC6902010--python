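"""Truth-tagged synthetic two-species dataset generator.

Emulates the study design end-to-end at desk scale: a set of
protein-coding genes on a small multi-chromosome genome (both strands,
some genes spliced), a sister species diverged under per-gene dN/dS
multipliers omega with a synonymous divergence target Ks, an accession
panel segregating SNPs with per-gene polymorphism omega, and gene labels
("mQTG", "CNV") with elevated omega in the mQTG-with-CNV class.  Every
file the real pipeline would consume is written: genome FASTA, GFF3, CDS
and protein FASTA for both species, VCF over the panel, a
BLAST-outfmt6-style similarity table in both directions, label and
metabolite tables, and a ground-truth table with the planted parameters.

Model assumptions (shared with the NG86 estimator so recovery tests
isolate implementation errors): mutations are uniform across bases (no
transition bias), sites evolve independently (no linkage or coalescent
structure), and proposals creating stop codons are rejected outright.
Because stop-creating changes are also excluded from the polymorphism
proposal pool, the divergence and polymorphism processes share the same
effective nonsynonymous target, so a fully neutral simulation (all
omega = 1) is neutral in the MK 2x2 sense.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .codon_model import (
    Effect,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    codon_single_base_changes,
    iter_codons,
    strip_terminal_stop,
)
from .seqio import GeneModel

__all__ = [
    "SimulationConfig",
    "GENE_CLASSES",
    "simulate_ancestral_genes",
    "evolve_divergence",
    "evolve_polymorphism",
    "emit_labels_and_truth",
    "simulate_dataset",
]

GENE_CLASSES = ("background", "mqtg_only", "cnv_only", "mqtg_cnv")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _neutral_omegas() -> dict[str, float]:
    return {c: 1.0 for c in GENE_CLASSES}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults mirror the emulated study: a 270-accession panel, synonymous
    divergence Ks ~ 0.15 between the two species, ~22 synonymous
    segregating sites per gene (theta_syn = 0.10 at 200-400 codons), and
    an elevated-omega mQTG-with-CNV class.  Class fractions are sized so
    each compared class holds enough genes for rank-based tests at
    desk scale rather than mirroring genome-wide label frequencies.
    """

    n_genes: int = 600
    codons_min: int = 200
    codons_max: int = 400
    n_accessions: int = 270
    divergence_ks_target: float = 0.15
    theta_syn: float = 0.10
    frac_mqtg_only: float = 0.30
    frac_mqtg_cnv: float = 0.35
    frac_cnv_only: float = 0.05
    omega_div: dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.20, "mqtg_only": 0.30, "cnv_only": 0.30, "mqtg_cnv": 0.55,
        }
    )
    omega_poly: dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.30, "mqtg_only": 0.40, "cnv_only": 0.40, "mqtg_cnv": 0.65,
        }
    )
    freq_model: str = "uniform"  # derived-allele frequency model: uniform | beta
    beta_params: tuple[float, float] = (0.5, 1.5)
    two_exon_fraction: float = 0.5
    n_chromosomes: int = 2
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_mqtg_only, self.frac_mqtg_cnv, self.frac_cnv_only)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must lie in [0,1] and sum to at most 1")
        for name, table in (("omega_div", self.omega_div), ("omega_poly", self.omega_poly)):
            for cls in GENE_CLASSES:
                if table.get(cls, -1) < 0:
                    raise ValueError(f"{name}[{cls!r}] must be defined and non-negative")
        if self.divergence_ks_target < 0 or self.theta_syn < 0:
            raise ValueError("rates must be non-negative")
        if self.n_genes < 1 or self.n_accessions < 1:
            raise ValueError("n_genes and n_accessions must be positive")
        if self.codons_min < 2 or self.codons_max < self.codons_min:
            raise ValueError("invalid codon length range")
        if self.freq_model not in ("uniform", "beta"):
            raise ValueError("freq_model must be 'uniform' or 'beta'")

    @classmethod
    def neutral(cls, **overrides) -> "SimulationConfig":
        """A fully neutral configuration (all omega = 1), for calibration."""
        cfg = cls(**overrides)
        cfg.omega_div = _neutral_omegas()
        cfg.omega_poly = _neutral_omegas()
        return cfg


def assign_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic per-gene class assignment under the configured seed."""
    n = config.n_genes
    n_mqtg_only = round(config.frac_mqtg_only * n)
    n_mqtg_cnv = round(config.frac_mqtg_cnv * n)
    n_cnv_only = round(config.frac_cnv_only * n)
    classes = (
        ["mqtg_only"] * n_mqtg_only
        + ["mqtg_cnv"] * n_mqtg_cnv
        + ["cnv_only"] * n_cnv_only
    )
    classes += ["background"] * (n - len(classes))
    return [classes[i] for i in rng.permutation(n)]


# ---------------------------------------------------------------------------
# ancestral genes and genome


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)]
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + "".join(body) + stop


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def simulate_ancestral_genes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], dict[str, str], list[str]]:
    """Random sense-codon genes placed on a synthetic genome.

    Genes start with ATG, contain no internal stops, end with a stop
    codon, sit on both strands across the configured chromosomes, and a
    configurable fraction is split into two exons.  Returns the gene
    models, the genome (chrom -> sequence), and the GFF3 lines describing
    them.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    chrom_cursor = {c: 0 for c in chrom_parts}
    genes: list[GeneModel] = []
    gff: list[str] = ["##gff-version 3"]

    for i in range(config.n_genes):
        gene_id = f"AT{i + 1:05d}"
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        n_codons = int(rng.integers(config.codons_min, config.codons_max + 1))
        cds = _random_cds(rng, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        spacer = _random_bases(rng, int(rng.integers(100, 301)))
        chrom_parts[chrom].append(spacer)
        chrom_cursor[chrom] += len(spacer)
        start = chrom_cursor[chrom]

        if rng.random() < config.two_exon_fraction and len(cds) >= 60:
            split = int(rng.integers(30, len(cds) - 29))
            exons_tx = [cds[:split], cds[split:]]  # transcription order
        else:
            exons_tx = [cds]
        intron = _random_bases(rng, int(rng.integers(60, 201))) if len(exons_tx) == 2 else ""

        if strand == "+":
            genomic_exons = exons_tx
        else:
            genomic_exons = [
                e.translate(_COMPLEMENT)[::-1] for e in reversed(exons_tx)
            ]
        intervals: list[tuple[int, int]] = []
        pos = start
        block = []
        for j, exon in enumerate(genomic_exons):
            if j > 0:
                block.append(intron)
                pos += len(intron)
            block.append(exon)
            intervals.append((pos, pos + len(exon)))
            pos += len(exon)
        chrom_parts[chrom].append("".join(block))
        chrom_cursor[chrom] = pos

        model = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand,
            cds_intervals=intervals, cds_sequence=cds,
        )
        model.validate()
        genes.append(model)

        tx_id = f"{gene_id}.1"
        g_start, g_end = intervals[0][0] + 1, intervals[-1][1]  # to GFF 1-based inclusive
        gff.append(f"{chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene_id}")
        gff.append(
            f"{chrom}\tsim\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={tx_id};Parent={gene_id}"
        )
        tx_order = intervals if strand == "+" else list(reversed(intervals))
        done = 0
        phased = []
        for s, e in tx_order:
            phase = (3 - done % 3) % 3
            phased.append(((s, e), phase))
            done += e - s
        for (s, e), phase in sorted(phased):
            gff.append(
                f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phase}\tID=cds-{tx_id};Parent={tx_id}"
            )

    genome = {c: "".join(parts) + _random_bases(rng, 150) for c, parts in chrom_parts.items()}
    return genes, genome, gff


# ---------------------------------------------------------------------------
# divergence


def evolve_divergence(
    genes: list[GeneModel],
    classes: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[dict]]:
    """Evolve a sister-species copy of each gene under its class omega.

    Each CDS position receives Poisson(divergence_ks_target) single-base
    proposals; synonymous proposals are accepted with probability 1,
    nonsynonymous with probability omega_div(class), and stop-creating
    proposals are rejected, so the realized synonymous rate per
    synonymous site matches the Ks target in expectation.  Returns the
    sister CDS set keyed by gene id and per-gene realized truth counts.
    """
    species_b: dict[str, str] = {}
    truth: list[dict] = []
    for gene, cls in zip(genes, classes):
        omega = config.omega_div[cls]
        codons = strip_terminal_stop(iter_codons(gene.cds_sequence))
        terminal = gene.cds_sequence[3 * len(codons):]
        n_positions = 3 * len(codons)
        n_events = rng.poisson(config.divergence_ks_target * n_positions)
        accepted_syn = accepted_nonsyn = 0
        for _ in range(n_events):
            pos = int(rng.integers(0, n_positions))
            ci, within = divmod(pos, 3)
            codon = codons[ci]
            ref = codon[within]
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            mutated = codon[:within] + alt + codon[within + 1:]
            if GENETIC_CODE[mutated] == "*":
                continue  # stop-creating proposals are never accepted
            if GENETIC_CODE[mutated] == GENETIC_CODE[codon]:
                codons[ci] = mutated
                accepted_syn += 1
            elif rng.random() < omega:
                codons[ci] = mutated
                accepted_nonsyn += 1
        species_b[gene.gene_id] = "".join(codons) + terminal
        truth.append(
            {"gene_id": gene.gene_id, "ds_true": accepted_syn, "dn_true": accepted_nonsyn}
        )
    return species_b, truth


# ---------------------------------------------------------------------------
# polymorphism


def _carrier_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    n = config.n_accessions
    if config.freq_model == "uniform":
        return int(rng.integers(1, n + 1))
    a, b = config.beta_params
    return max(1, int(round(rng.beta(a, b) * n)))


def evolve_polymorphism(
    genes: list[GeneModel],
    classes: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], list[dict]]:
    """Plant segregating sites on the reference (ancestral) gene set.

    Per gene, synonymous site numbers are Poisson(theta_syn * S) and
    nonsynonymous Poisson(theta_syn * omega_poly(class) * N'), where S and
    N' are the gene's synonymous and nonsynonymous-non-stop change counts
    divided by three, matching the acceptance rules of the divergence
    process.  Each site receives a derived-allele carrier subset of the
    accession panel drawn from the configured frequency model.  Returns
    VCF-ready records and per-gene realized truth counts.
    """
    records: list[dict] = []
    truth: list[dict] = []
    for gene, cls in zip(genes, classes):
        omega = config.omega_poly[cls]
        codons = strip_terminal_stop(iter_codons(gene.cds_sequence))
        syn_changes: list[tuple[int, str]] = []
        nonsyn_changes: list[tuple[int, str]] = []
        for ci, codon in enumerate(codons):
            for within, alt, effect in codon_single_base_changes(codon):
                offset = 3 * ci + within
                if effect is Effect.SYNONYMOUS:
                    syn_changes.append((offset, alt))
                elif effect is Effect.NONSYNONYMOUS:
                    nonsyn_changes.append((offset, alt))
                # nonsense changes are never proposed (stop-rejection rule)
        n_syn = min(rng.poisson(config.theta_syn * len(syn_changes) / 3.0), len(syn_changes))
        n_nonsyn = min(
            rng.poisson(config.theta_syn * omega * len(nonsyn_changes) / 3.0),
            len(nonsyn_changes),
        )
        chosen: list[tuple[int, str, str]] = []
        used: set[int] = set()
        for pool, count, label in (
            (syn_changes, n_syn, "syn"),
            (nonsyn_changes, n_nonsyn, "nonsyn"),
        ):
            picks = rng.choice(len(pool), size=count, replace=False) if count else []
            for idx in picks:
                offset, alt = pool[int(idx)]
                if offset in used:  # one biallelic record per position
                    continue
                used.add(offset)
                chosen.append((offset, alt, label))
        pn_true = sum(1 for _, _, label in chosen if label == "nonsyn")
        ps_true = len(chosen) - pn_true
        truth.append({"gene_id": gene.gene_id, "pn_true": pn_true, "ps_true": ps_true})
        for offset, alt, _ in chosen:
            pos0 = gene.cds_to_genomic(offset)
            ref_cds = gene.cds_sequence[offset]
            if gene.strand == "+":
                ref_g, alt_g = ref_cds, alt
            else:
                ref_g = ref_cds.translate(_COMPLEMENT)
                alt_g = alt.translate(_COMPLEMENT)
            k = _carrier_count(config, rng)
            carriers = rng.choice(config.n_accessions, size=k, replace=False)
            records.append(
                {
                    "chrom": gene.chrom,
                    "pos": pos0 + 1,
                    "ref": ref_g,
                    "alt": alt_g,
                    "carriers": np.sort(carriers),
                }
            )
    return records, truth


def _accession_names(n: int) -> list[str]:
    return [f"acc{i + 1:04d}" for i in range(n)]


def write_vcf(
    records: list[dict], genome: Mapping[str, str], n_accessions: int, path: Path
) -> None:
    """Write planted segregating sites as a VCF 4.2 with diploid genotypes.

    Accessions are inbred lines: carriers are written homozygous-alt.
    """
    samples = _accession_names(n_accessions)
    lines = ["##fileformat=VCFv4.2", "##source=mkscan-synthetic"]
    for chrom in sorted(genome):
        lines.append(f"##contig=<ID={chrom},length={len(genome[chrom])}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for rec in sorted(records, key=lambda r: (r["chrom"], r["pos"], r["alt"])):
        gts = ["0|0"] * n_accessions
        for i in rec["carriers"]:
            gts[int(i)] = "1|1"
        lines.append(
            f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t{rec['alt']}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# labels, truth, similarity hits, orchestration


def emit_labels_and_truth(
    classes: list[str],
    gene_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], list[dict]]:
    """Label rows (mQTG/CNV flags) and metabolite counts per gene.

    mQTGs are associated with 1 + Poisson counts of specialized
    metabolites, with a higher mean for the CNV-carrying class.
    """
    labels, metabolites = [], []
    for gene_id, cls in zip(gene_ids, classes):
        is_mqtg = cls in ("mqtg_only", "mqtg_cnv")
        has_cnv = cls in ("cnv_only", "mqtg_cnv")
        labels.append({"gene_id": gene_id, "is_mqtg": int(is_mqtg), "has_cnv": int(has_cnv)})
        if is_mqtg:
            lam = 2.5 if cls == "mqtg_cnv" else 1.0
            metabolites.append(
                {"gene_id": gene_id, "metabolite_count": 1 + int(rng.poisson(lam))}
            )
    return labels, metabolites


def _species_b_id(gene_id: str) -> str:
    return gene_id.replace("AT", "AL", 1)


def _write_fasta(seqs: Mapping[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _emit_hits(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    pairs: list[tuple[str, str]],
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """BLAST-outfmt6-style hit rows for true pairs plus low-scoring decoys."""

    def row(q: str, s: str, qseq: str, sseq: str, scale: float, cov: float) -> str:
        matches = sum(x == y for x, y in zip(qseq, sseq))
        length = max(1, int(round(cov * len(qseq))))
        pident = 100.0 * matches / max(len(qseq), 1)
        bitscore = round(scale * 2.0 * matches, 1)
        evalue = 10.0 ** (-min(180.0, scale * matches / 2.0))
        return (
            f"{q}\t{s}\t{pident:.2f}\t{length}\t{len(qseq) - matches}\t0\t1\t{length}"
            f"\t1\t{length}\t{evalue:.3g}\t{bitscore}"
        )

    ab, ba = [], []
    ids_b = [b for _, b in pairs]
    for a_id, b_id in pairs:
        pa, pb = proteins_a[a_id], proteins_b[b_id]
        ab.append(row(a_id, b_id, pa, pb, 1.0, 1.0))
        ba.append(row(b_id, a_id, pb, pa, 1.0, 1.0))
        if rng.random() < 0.10:  # paralog-like decoy, never the best hit
            decoy = ids_b[int(rng.integers(0, len(ids_b)))]
            if decoy != b_id:
                ab.append(row(a_id, decoy, pa, proteins_b[decoy], 0.3, 0.95))
    return ab, ba


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the complete dataset and write every pipeline input file.

    Returns a mapping of logical names to written paths; a manifest
    records the configuration and seed.  Output is byte-identical across
    reruns with the same configuration.
    """
    from .inter_divergence import translate_cds  # local import, avoids cycle at module load

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    classes = assign_classes(config, rng)
    genes, genome, gff_lines = simulate_ancestral_genes(config, rng)
    gene_ids = [g.gene_id for g in genes]
    species_b, div_truth = evolve_divergence(genes, classes, config, rng)
    vcf_records, poly_truth = evolve_polymorphism(genes, classes, config, rng)
    labels, metabolites = emit_labels_and_truth(classes, gene_ids, config, rng)

    cds_a = {g.gene_id: g.cds_sequence for g in genes}
    cds_b = {_species_b_id(gid): species_b[gid] for gid in gene_ids}
    proteins_a = {gid: translate_cds(seq) for gid, seq in cds_a.items()}
    proteins_b = {gid: translate_cds(seq) for gid, seq in cds_b.items()}
    pairs = [(gid, _species_b_id(gid)) for gid in gene_ids]
    hits_ab, hits_ba = _emit_hits(proteins_a, proteins_b, pairs, rng)

    paths = {name: outdir / fname for name, fname in {
        "genome": "genome.fa",
        "gff": "genes.gff3",
        "cds_a": "cds_a.fa",
        "cds_b": "cds_b.fa",
        "protein_a": "protein_a.fa",
        "protein_b": "protein_b.fa",
        "vcf": "snps.vcf",
        "hits_ab": "hits_ab.tsv",
        "hits_ba": "hits_ba.tsv",
        "labels": "labels.tsv",
        "metabolites": "metabolites.tsv",
        "truth": "truth.tsv",
        "manifest": "manifest.json",
    }.items()}

    _write_fasta(genome, paths["genome"])
    paths["gff"].write_text("\n".join(gff_lines) + "\n")
    _write_fasta(cds_a, paths["cds_a"])
    _write_fasta(cds_b, paths["cds_b"])
    _write_fasta(proteins_a, paths["protein_a"])
    _write_fasta(proteins_b, paths["protein_b"])
    write_vcf(vcf_records, genome, config.n_accessions, paths["vcf"])
    paths["hits_ab"].write_text("\n".join(hits_ab) + ("\n" if hits_ab else ""))
    paths["hits_ba"].write_text("\n".join(hits_ba) + ("\n" if hits_ba else ""))

    with open(paths["labels"], "w") as fh:
        fh.write("gene_id\tis_mqtg\thas_cnv\n")
        for row in labels:
            fh.write(f"{row['gene_id']}\t{row['is_mqtg']}\t{row['has_cnv']}\n")
    with open(paths["metabolites"], "w") as fh:
        fh.write("gene_id\tmetabolite_count\n")
        for row in metabolites:
            fh.write(f"{row['gene_id']}\t{row['metabolite_count']}\n")

    div_by_gene = {t["gene_id"]: t for t in div_truth}
    poly_by_gene = {t["gene_id"]: t for t in poly_truth}
    with open(paths["truth"], "w") as fh:
        fh.write(
            "gene_id\tgene_class\tomega_div_true\tomega_poly_true\t"
            "dn_true\tds_true\tpn_true\tps_true\tn_codons\n"
        )
        for gene, cls in zip(genes, classes):
            d, p = div_by_gene[gene.gene_id], poly_by_gene[gene.gene_id]
            fh.write(
                f"{gene.gene_id}\t{cls}\t{config.omega_div[cls]}\t{config.omega_poly[cls]}\t"
                f"{d['dn_true']}\t{d['ds_true']}\t{p['pn_true']}\t{p['ps_true']}\t"
                f"{gene.cds_length // 3 - 1}\n"
            )

    manifest = {
        "config": dataclasses.asdict(config),
        "files": {k: str(v.name) for k, v in paths.items() if k != "manifest"},
        "n_vcf_records": len(vcf_records),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
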