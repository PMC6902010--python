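"""Readers and writers for the external formats the pipeline touches.

Gene models come from GFF3 (1-based inclusive) or BED12 (0-based
half-open); coordinates are normalized at the boundary to a single internal
convention, 0-based half-open, which every other module assumes.  Genomes
are loaded fully in memory (desk-scale data); population SNPs are read from
VCF via cyvcf2; pairwise protein similarity hits use the 12-column
tab-delimited BLAST dialect with an optional 13th query-coverage column.

Heterozygous genotype calls count as alt-carrying: the target organisms are
near-homozygous inbred lines and the analysis is a per-accession
presence/absence model.  When a GFF3 annotates several mRNAs per gene, only
the longest total CDS is kept (deterministic tie-break on transcript id).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .codon_model import BASES, STOP_CODONS, FrameError, InternalStopError, AmbiguousBaseError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "SnpRecord",
    "SimilarityHit",
    "SeqIOError",
    "MissingChromosomeError",
    "VcfFormatError",
    "read_gene_models",
    "read_vcf",
    "read_similarity_hits",
    "write_results_table",
    "read_results_table",
]


class SeqIOError(ValueError):
    """Base class for file-boundary errors."""


class MissingChromosomeError(SeqIOError):
    """An annotation references a sequence absent from the genome FASTA."""


class VcfFormatError(SeqIOError):
    """The VCF could not be parsed."""


@dataclass
class GeneModel:
    """A gene's CDS geometry and spliced, strand-corrected sequence.

    ``cds_intervals`` are 0-based half-open genomic intervals in ascending
    genomic order; ``cds_sequence`` is the spliced coding sequence read
    5'->3' on the coding strand (reverse-complemented for minus-strand
    genes).  A terminal stop codon may be present and is ignored by all
    counting downstream.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    cds_sequence: str

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covering all CDS intervals, half-open."""
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a 0-based genomic position into the CDS (None if not in CDS)."""
        offset = 0
        for start, end in self.cds_intervals:
            if start <= pos0 < end:
                plus_offset = offset + (pos0 - start)
                break
            offset += end - start
        else:
            return None
        if self.strand == "+":
            return plus_offset
        return self.cds_length - 1 - plus_offset

    def cds_to_genomic(self, cds_offset: int) -> int:
        """Inverse of :meth:`genomic_to_cds` (0-based genomic position)."""
        if not 0 <= cds_offset < self.cds_length:
            raise IndexError(f"CDS offset {cds_offset} out of range for {self.gene_id}")
        plus_offset = (
            cds_offset if self.strand == "+" else self.cds_length - 1 - cds_offset
        )
        for start, end in self.cds_intervals:
            length = end - start
            if plus_offset < length:
                return start + plus_offset
            plus_offset -= length
        raise AssertionError("unreachable: interval lengths disagree with sequence")

    def validate(self) -> None:
        """Raise a named error if any GeneModel invariant is violated."""
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"{self.gene_id}: strand must be '+' or '-'")
        interval_len = sum(e - s for s, e in self.cds_intervals)
        if interval_len != self.cds_length:
            raise SeqIOError(
                f"{self.gene_id}: interval lengths ({interval_len}) != sequence length "
                f"({self.cds_length})"
            )
        if self.cds_length % 3 != 0:
            raise FrameError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")
        if any(b not in BASES for b in self.cds_sequence):
            raise AmbiguousBaseError(f"{self.gene_id}: CDS contains non-ACGT bases")
        codons = [self.cds_sequence[i : i + 3] for i in range(0, self.cds_length, 3)]
        internal = codons[:-1] if codons and codons[-1] in STOP_CODONS else codons
        for i, codon in enumerate(internal):
            if codon in STOP_CODONS:
                raise InternalStopError(
                    f"{self.gene_id}: internal stop codon at codon index {i}"
                )


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic single-nucleotide variant with its alt-carrying accessions."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    accession_presence: frozenset[str]


@dataclass(frozen=True)
class SimilarityHit:
    """Best-HSP-reduced pairwise protein similarity hit."""

    query_id: str
    subject_id: str
    evalue: float
    query_coverage: float
    bitscore: float


# ---------------------------------------------------------------------------
# gene models


def _load_genome(genome_fasta_path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta_path), "fasta")
    }


def _gff3_transcripts(path: str | Path):
    """Yield (gene_id, transcript_id, strand, chrom, [intervals]) from GFF3."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    tx_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            parents = tx.attributes.get("Parent", [tx.id])
            tx_gene[tx.id] = parents[0]
    per_tx: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or [cds.id]
        for parent in parents:
            info = per_tx.setdefault(
                parent,
                {"chrom": cds.seqid, "strand": cds.strand, "intervals": []},
            )
            info["intervals"].append((cds.start - 1, cds.end))  # to 0-based half-open
    for tx_id, info in per_tx.items():
        gene_id = tx_gene.get(tx_id, tx_id)
        info["intervals"].sort()
        yield gene_id, tx_id, info["strand"], info["chrom"], info["intervals"]


def _bed12_transcripts(path: str | Path):
    """Yield transcripts from BED12; blocks are taken as CDS intervals."""
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise SeqIOError(f"{path}:{line_no}: BED12 requires 12 columns")
            chrom, chrom_start, _, name, _, strand = fields[0], int(fields[1]), fields[2], fields[3], fields[4], fields[5]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            intervals = [
                (chrom_start + bs, chrom_start + bs + sz) for bs, sz in zip(starts, sizes)
            ]
            yield name, name, strand, chrom, sorted(intervals)


def read_gene_models(
    gff_or_bed_path: str | Path, genome_fasta_path: str | Path
) -> tuple[list[GeneModel], list[dict]]:
    """Read gene models and their spliced, strand-corrected CDS sequences.

    Returns ``(genes, rejections)`` where ``rejections`` lists genes that
    failed a GeneModel invariant as ``{"gene_id", "reason"}`` dicts.  A
    chromosome missing from the genome FASTA is a hard error
    (:class:`MissingChromosomeError`); per-gene invariant failures are
    reported, not raised.
    """
    genome = _load_genome(genome_fasta_path)
    path = Path(gff_or_bed_path)
    source = _bed12_transcripts(path) if path.suffix.lower() == ".bed" else _gff3_transcripts(path)

    candidates: dict[str, list] = defaultdict(list)
    for gene_id, tx_id, strand, chrom, intervals in source:
        candidates[gene_id].append((tx_id, strand, chrom, intervals))

    genes: list[GeneModel] = []
    rejections: list[dict] = []
    for gene_id in sorted(candidates):
        # longest total CDS wins; ties broken by lexicographic transcript id
        tx_id, strand, chrom, intervals = sorted(
            candidates[gene_id],
            key=lambda t: (-sum(e - s for s, e in t[3]), t[0]),
        )[0]
        if chrom not in genome:
            raise MissingChromosomeError(
                f"gene {gene_id}: chromosome {chrom!r} absent from genome FASTA"
            )
        chrom_seq = genome[chrom]
        spliced = "".join(chrom_seq[s:e] for s, e in intervals)
        if strand == "-":
            spliced = reverse_complement(spliced)
        model = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            cds_intervals=intervals,
            cds_sequence=spliced,
        )
        try:
            model.validate()
        except ValueError as exc:
            rejections.append({"gene_id": gene_id, "reason": f"{type(exc).__name__}: {exc}"})
            continue
        genes.append(model)
    if rejections:
        logger.info("read_gene_models: rejected %d gene(s)", len(rejections))
    return genes, rejections


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    vcf_path: str | Path, accession_ids: Sequence[str] | None = None
) -> tuple[list[SnpRecord], dict[str, int]]:
    """Read biallelic SNVs and their alt-carrying accessions from a VCF.

    Heterozygous and homozygous-alt genotypes both count as alt-carrying.
    Multiallelic records and indels are skipped and counted in the returned
    ``skipped`` dictionary.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # htslib reports parse failures opaquely
        raise VcfFormatError(f"cannot open VCF {vcf_path}: {exc}") from exc

    samples = list(vcf.samples)
    if accession_ids is None:
        indices = list(range(len(samples)))
    else:
        missing = [a for a in accession_ids if a not in samples]
        if missing:
            raise VcfFormatError(f"accessions absent from VCF header: {missing}")
        lookup = {s: i for i, s in enumerate(samples)}
        indices = [lookup[a] for a in accession_ids]

    records: list[SnpRecord] = []
    skipped = {"multiallelic": 0, "indel": 0, "non_snv": 0}
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                skipped["multiallelic"] += 1
                continue
            ref, alt = var.REF, var.ALT[0]
            if len(ref) != 1 or len(alt) != 1:
                skipped["indel"] += 1
                continue
            if ref not in BASES or alt not in BASES or ref == alt:
                skipped["non_snv"] += 1
                continue
            gt = var.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            carriers = frozenset(samples[i] for i in indices if gt[i] in (1, 2))
            records.append(
                SnpRecord(chrom=var.CHROM, pos=var.POS, ref=ref, alt=alt, accession_presence=carriers)
            )
    except VcfFormatError:
        raise
    except Exception as exc:
        raise VcfFormatError(
            f"malformed VCF record after {len(records)} parsed records in {vcf_path}: {exc}"
        ) from exc
    if any(skipped.values()):
        logger.info("read_vcf: skipped %s", skipped)
    return records, skipped


# ---------------------------------------------------------------------------
# similarity hits

_HIT_COLUMNS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_similarity_hits(
    path: str | Path, query_lengths: Mapping[str, int] | None = None
) -> list[SimilarityHit]:
    """Read 12/13-column tab-delimited similarity hits, best-HSP-reduced.

    Query coverage comes from the optional 13th column (a fraction, or a
    percentage if values exceed 1); otherwise it is computed as alignment
    length divided by the query length from ``query_lengths``.  Duplicate
    (query, subject) rows are reduced to the highest-bitscore HSP (ties
    broken by lower E-value).
    """
    try:
        df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] not in (12, 13):
        raise SeqIOError(f"{path}: expected 12 or 13 tab-delimited columns, got {df.shape[1]}")
    df.columns = _HIT_COLUMNS + (["query_coverage"] if df.shape[1] == 13 else [])

    if "query_coverage" in df.columns:
        cov = df["query_coverage"].astype(float)
        if (cov > 1.0).any():
            cov = cov / 100.0  # percentage dialect
    else:
        if query_lengths is None:
            raise SeqIOError(
                f"{path}: no coverage column; query_lengths required to compute coverage"
            )
        qlen = df["query_id"].map(query_lengths)
        if qlen.isna().any():
            missing = sorted(df.loc[qlen.isna(), "query_id"].unique())[:5]
            raise SeqIOError(f"{path}: query lengths missing for {missing}")
        cov = df["length"].astype(float) / qlen.astype(float)
    df = df.assign(query_coverage=cov)

    df = df.sort_values(
        ["query_id", "subject_id", "bitscore", "evalue"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates(["query_id", "subject_id"], keep="first")

    return [
        SimilarityHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            evalue=float(r.evalue),
            query_coverage=float(r.query_coverage),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# results tables


def write_results_table(records, path: str | Path) -> None:
    """Write a tab-delimited results table with 'NA' missing values.

    Accepts a DataFrame or an iterable of mappings/dataclasses.  Rows are
    ordered lexicographically by the first column (gene id by convention)
    so output is deterministic; floats keep full printed precision so a
    write/read round trip is lossless.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else dict(r) for r in records])
    df = records.sort_values(records.columns[0], kind="mergesort")
    # shortest round-trip float representation keeps the table lossless
    df.to_csv(
        str(path), sep="\t", index=False, na_rep="NA",
        float_format=lambda v: repr(float(v)),
    )


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(
        str(path), sep="\t", na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
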