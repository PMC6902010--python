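"""Intra-species polymorphism: SNP effect classification and per-gene Pn/Ps.

Population SNPs are mapped into each gene's CDS frame (strand-aware),
classified against the reference codon with the NG86 effect rules, and
summarized per gene as counts of distinct segregating nonsynonymous (Pn)
and synonymous (Ps) sites together with the rates dN_SNP = Pn/N and
dS_SNP = Ps/S and their ratio.

Conventions: each SNP is classified independently against the reference
codon (no haplotype codon reconstruction); nonsense changes pool into Pn;
a site segregating in several records counts once, as nonsynonymous if any
record at the site is amino-acid-changing; the ratio is NA when Ps = 0
(no pseudocount smoothing) and such genes are excluded downstream from
rank-based comparisons with logged counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .codon_model import Effect, SiteCounts, classify_point_mutation, is_stop
from .seqio import GeneModel, SnpRecord

__all__ = [
    "ClassifiedSnp",
    "PolymorphismCounts",
    "CodonContext",
    "RefMismatchError",
    "map_snp_to_codon",
    "classify_gene_snps",
    "polymorphism_counts",
    "per_accession_means",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class RefMismatchError(ValueError):
    """VCF reference allele disagrees with the genome-derived codon base."""


@dataclass(frozen=True)
class CodonContext:
    """A SNP placed in a gene's codon frame (coding-strand orientation)."""

    codon_index: int
    within_codon_pos: int
    ref_codon: str
    alt_base: str
    cds_offset: int


@dataclass(frozen=True)
class ClassifiedSnp:
    """One SNP classified against one gene's reference codon."""

    gene_id: str
    codon_index: int
    within_codon_pos: int
    effect: Effect
    accession_count: int
    cds_offset: int


@dataclass(frozen=True)
class PolymorphismCounts:
    """Per-gene polymorphism summary feeding the MK framework."""

    gene_id: str
    Pn: int
    Ps: int
    dn_snp: float
    ds_snp: float
    ratio: float  # NaN when Ps == 0


def map_snp_to_codon(snp: SnpRecord, gene: GeneModel) -> CodonContext | None:
    """Place a SNP into ``gene``'s codon frame; None when outside the CDS.

    On minus-strand genes the ref/alt alleles are complemented and the
    position mirrored into coding-strand coordinates.  A disagreement
    between the VCF reference allele and the genome-derived codon base
    raises :class:`RefMismatchError`.
    """
    offset = gene.genomic_to_cds(snp.pos - 1)
    if offset is None:
        return None
    if gene.strand == "+":
        ref_cds, alt_cds = snp.ref, snp.alt
    else:
        ref_cds = snp.ref.translate(_COMPLEMENT)
        alt_cds = snp.alt.translate(_COMPLEMENT)
    if gene.cds_sequence[offset] != ref_cds:
        raise RefMismatchError(
            f"{gene.gene_id} @ {snp.chrom}:{snp.pos}: VCF ref {snp.ref!r} maps to "
            f"{ref_cds!r} in CDS frame but gene sequence has "
            f"{gene.cds_sequence[offset]!r}"
        )
    codon_index, within = divmod(offset, 3)
    ref_codon = gene.cds_sequence[3 * codon_index : 3 * codon_index + 3]
    return CodonContext(
        codon_index=codon_index,
        within_codon_pos=within,
        ref_codon=ref_codon,
        alt_base=alt_cds,
        cds_offset=offset,
    )


def classify_gene_snps(
    gene: GeneModel, snps: Iterable[SnpRecord]
) -> tuple[list[ClassifiedSnp], Counter]:
    """Classify every CDS-overlapping SNP of a gene against its reference codons.

    Returns the classified SNPs and a counter accounting for every input
    record: ``classified`` + ``not_in_cds`` + ``ref_mismatch`` +
    ``terminal_stop_codon`` equals the number of SNPs presented.
    """
    counters: Counter = Counter()
    out: list[ClassifiedSnp] = []
    for snp in snps:
        if snp.chrom != gene.chrom:
            counters["not_in_cds"] += 1
            continue
        try:
            ctx = map_snp_to_codon(snp, gene)
        except RefMismatchError:
            counters["ref_mismatch"] += 1
            continue
        if ctx is None:
            counters["not_in_cds"] += 1
            continue
        if is_stop(ctx.ref_codon):
            # terminal stop codons are excluded from all counting
            counters["terminal_stop_codon"] += 1
            continue
        effect = classify_point_mutation(ctx.ref_codon, ctx.within_codon_pos, ctx.alt_base)
        counters["classified"] += 1
        out.append(
            ClassifiedSnp(
                gene_id=gene.gene_id,
                codon_index=ctx.codon_index,
                within_codon_pos=ctx.within_codon_pos,
                effect=effect,
                accession_count=len(snp.accession_presence),
                cds_offset=ctx.cds_offset,
            )
        )
    return out, counters


def polymorphism_counts(
    gene: GeneModel,
    classified_snps: Sequence[ClassifiedSnp],
    site_counts: SiteCounts,
) -> PolymorphismCounts:
    """Distinct-segregating-site Pn/Ps and the dN_SNP/dS_SNP ratio.

    Sites are distinct CDS positions; a site with any amino-acid-changing
    record (nonsynonymous or nonsense) counts toward Pn, otherwise Ps.
    """
    site_is_nonsyn: dict[int, bool] = {}
    for snp in classified_snps:
        changing = snp.effect in (Effect.NONSYNONYMOUS, Effect.NONSENSE)
        site_is_nonsyn[snp.cds_offset] = site_is_nonsyn.get(snp.cds_offset, False) or changing
    pn = sum(1 for v in site_is_nonsyn.values() if v)
    ps = len(site_is_nonsyn) - pn
    dn = pn / site_counts.N
    ds = ps / site_counts.S
    ratio = dn / ds if ps > 0 else math.nan
    return PolymorphismCounts(
        gene_id=gene.gene_id, Pn=pn, Ps=ps, dn_snp=dn, ds_snp=ds, ratio=ratio
    )


def per_accession_means(
    classified_snps: Sequence[ClassifiedSnp], n_accessions: int
) -> tuple[float, float]:
    """Descriptive mean per-accession nonsynonymous and synonymous mutation counts.

    Averages allele occurrences over the accession panel (each accession
    contributes every alt allele it carries), complementing the
    distinct-site Pn/Ps used by the MK statistics.
    """
    if n_accessions <= 0:
        raise ValueError("n_accessions must be positive")
    nonsyn = sum(
        s.accession_count
        for s in classified_snps
        if s.effect in (Effect.NONSYNONYMOUS, Effect.NONSENSE)
    )
    syn = sum(s.accession_count for s in classified_snps if s.effect is Effect.SYNONYMOUS)
    return nonsyn / n_accessions, syn / n_accessions
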