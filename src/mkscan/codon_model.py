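"""Nei-Gojobori (NG86) codon arithmetic.

This module is the computational core shared by the polymorphism and
divergence stages: fractional synonymous/nonsynonymous site counts per
codon, effect classification of single-base changes, pathway-averaged
difference counting between codon pairs, and the Jukes-Cantor multiple-hit
correction used to turn raw difference proportions into rates.

Counting conventions (documented, testable choices):

* Standard nuclear genetic code only; the code table is held as data so an
  alternative table could be plugged in.
* Single-base changes that create a stop codon count as nonsynonymous in
  site counting, preserving the per-codon invariant ``syn + nonsyn == 3``.
* Mutational pathways between codons are weighted uniformly (unweighted
  NG86, no transition/transversion bias); pathways passing through a stop
  codon are discarded, with a documented all-pathways fallback when every
  pathway is inadmissible.
* Terminal stop codons are excluded from all site and difference counting.

Site fractions are kept as exact :class:`fractions.Fraction` values inside
per-codon results so conservation invariants hold exactly; gene-level
totals are exported as floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "GENETIC_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "Effect",
    "CodonSiteCounts",
    "SiteCounts",
    "PairwiseDiff",
    "CodonError",
    "StopCodonError",
    "AmbiguousBaseError",
    "InternalStopError",
    "FrameError",
    "SaturationError",
    "amino_acid",
    "is_stop",
    "count_codon_sites",
    "classify_point_mutation",
    "count_pairwise_codon_diff",
    "gene_site_totals",
    "jukes_cantor_correct",
    "codon_single_base_changes",
]

BASES: tuple[str, ...] = ("A", "C", "G", "T")

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))


class CodonError(ValueError):
    """Base class for codon-level input errors."""


class StopCodonError(CodonError):
    """A stop codon was supplied where a sense codon is required."""


class AmbiguousBaseError(CodonError):
    """A base outside {A, C, G, T} was encountered."""


class InternalStopError(CodonError):
    """A coding sequence contains an in-frame internal stop codon."""


class FrameError(CodonError):
    """A coding sequence length is not a multiple of three."""


class SaturationError(ValueError):
    """Difference proportion at or beyond the Jukes-Cantor pole (p >= 3/4)."""


class Effect(str, Enum):
    """Effect of a single-base change on the encoded amino acid."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class CodonSiteCounts:
    """Exact NG86 site decomposition of one sense codon."""

    codon: str
    syn_sites: Fraction
    nonsyn_sites: Fraction


@dataclass(frozen=True)
class SiteCounts:
    """Per-gene nonsynonymous (N) and synonymous (S) site totals."""

    gene_id: str
    N: float
    S: float
    n_codons: int


@dataclass(frozen=True)
class PairwiseDiff:
    """Pathway-averaged nonsynonymous/synonymous differences of a codon pair."""

    nd: Fraction
    sd: Fraction


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise AmbiguousBaseError(f"not an unambiguous DNA codon: {codon!r}")


def amino_acid(codon: str) -> str:
    """One-letter amino acid for ``codon`` ('*' for a stop codon)."""
    _check_codon(codon)
    return GENETIC_CODE[codon]


def is_stop(codon: str) -> bool:
    return amino_acid(codon) == "*"


def _check_sense(codon: str) -> None:
    _check_codon(codon)
    if GENETIC_CODE[codon] == "*":
        raise StopCodonError(f"stop codon not admissible here: {codon}")


@lru_cache(maxsize=None)
def count_codon_sites(codon: str) -> CodonSiteCounts:
    """NG86 synonymous/nonsynonymous site counts of one sense codon.

    Each codon position contributes the fraction of its three possible
    single-base changes that are synonymous; changes creating a stop codon
    count as nonsynonymous, so ``syn_sites + nonsyn_sites == 3`` exactly.
    """
    _check_sense(codon)
    aa = GENETIC_CODE[codon]
    syn = Fraction(0)
    for pos in range(3):
        n_syn = 0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if GENETIC_CODE[mutated] == aa:
                n_syn += 1
        syn += Fraction(n_syn, 3)
    return CodonSiteCounts(codon=codon, syn_sites=syn, nonsyn_sites=3 - syn)


def classify_point_mutation(codon: str, position: int, alt_base: str) -> Effect:
    """Classify the effect of substituting ``alt_base`` at ``position``.

    The reference codon may be a stop codon only when classifying a
    stop-loss change; a stop-to-stop change is synonymous.
    """
    _check_codon(codon)
    if position not in (0, 1, 2):
        raise ValueError(f"position must be 0, 1 or 2, got {position}")
    if alt_base not in BASES:
        raise AmbiguousBaseError(f"alt base must be one of ACGT, got {alt_base!r}")
    if alt_base == codon[position]:
        raise ValueError(
            f"alt base equals reference base {codon[position]!r} at position {position}"
        )
    aa_ref = GENETIC_CODE[codon]
    mutated = codon[:position] + alt_base + codon[position + 1 :]
    aa_alt = GENETIC_CODE[mutated]
    if aa_ref == "*":
        return Effect.SYNONYMOUS if aa_alt == "*" else Effect.STOP_LOSS
    if aa_alt == "*":
        return Effect.NONSENSE
    return Effect.SYNONYMOUS if aa_alt == aa_ref else Effect.NONSYNONYMOUS


def _pathway_steps(codon_a: str, codon_b: str, order: tuple[int, ...]) -> list[tuple[str, str]]:
    steps = []
    current = codon_a
    for pos in order:
        nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
        steps.append((current, nxt))
        current = nxt
    return steps


@lru_cache(maxsize=None)
def count_pairwise_codon_diff(codon_a: str, codon_b: str) -> PairwiseDiff:
    """NG86 pathway-averaged difference counts between two sense codons.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are discarded and the remainder averaged
    with equal weights.  If every pathway passes through a stop, all
    pathways are counted with stop-involving steps treated as
    nonsynonymous (documented fallback, keeps ``nd + sd`` equal to the
    Hamming distance).
    """
    _check_sense(codon_a)
    _check_sense(codon_b)
    diff_positions = tuple(i for i in range(3) if codon_a[i] != codon_b[i])
    if not diff_positions:
        return PairwiseDiff(nd=Fraction(0), sd=Fraction(0))

    admissible: list[list[tuple[str, str]]] = []
    all_paths: list[list[tuple[str, str]]] = []
    for order in permutations(diff_positions):
        steps = _pathway_steps(codon_a, codon_b, order)
        all_paths.append(steps)
        # the end codon is codon_b (sense); only intermediates can be stops
        if all(GENETIC_CODE[t] != "*" for _, t in steps[:-1]):
            admissible.append(steps)

    paths = admissible if admissible else all_paths
    nd = sd = Fraction(0)
    for steps in paths:
        for src, dst in steps:
            aa_src, aa_dst = GENETIC_CODE[src], GENETIC_CODE[dst]
            if aa_src == aa_dst and aa_src != "*":
                sd += 1
            else:
                nd += 1  # includes stop-involving steps in the fallback
    k = len(paths)
    return PairwiseDiff(nd=Fraction(nd, k), sd=Fraction(sd, k))


def iter_codons(cds_sequence: str) -> list[str]:
    """Split a frame-checked CDS into codons (no validation beyond frame)."""
    if len(cds_sequence) % 3 != 0:
        raise FrameError(
            f"CDS length {len(cds_sequence)} is not divisible by 3"
        )
    return [cds_sequence[i : i + 3] for i in range(0, len(cds_sequence), 3)]


def strip_terminal_stop(codons: list[str]) -> list[str]:
    """Drop a trailing stop codon if present (terminal stops never counted)."""
    if codons and codons[-1] in STOP_CODONS:
        return codons[:-1]
    return codons


def gene_site_totals(cds_sequence: str, gene_id: str = "") -> SiteCounts:
    """Sum NG86 site counts over the codons of one coding sequence.

    A terminal stop codon is excluded; internal stops and ambiguous bases
    raise named errors.
    """
    codons = strip_terminal_stop(iter_codons(cds_sequence.upper()))
    syn = Fraction(0)
    for i, codon in enumerate(codons):
        _check_codon(codon)
        if GENETIC_CODE[codon] == "*":
            raise InternalStopError(
                f"internal stop codon {codon} at codon index {i}"
                + (f" in gene {gene_id}" if gene_id else "")
            )
        syn += count_codon_sites(codon).syn_sites
    total = 3 * len(codons)
    return SiteCounts(gene_id=gene_id, N=float(total - syn), S=float(syn), n_codons=len(codons))


def jukes_cantor_correct(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) for a proportion ``p``.

    Raises :class:`SaturationError` at or beyond the pole ``p >= 3/4``.
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise SaturationError(f"difference proportion {p} is saturated (>= 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def codon_single_base_changes(codon: str) -> tuple[tuple[int, str, Effect], ...]:
    """All nine single-base changes of a sense codon with their effects.

    Convenience enumeration used by the coding-sequence simulator; returns
    tuples of ``(position, alt_base, effect)``.
    """
    _check_sense(codon)
    out = []
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            out.append((pos, alt, classify_point_mutation(codon, pos, alt)))
    return tuple(out)
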