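"""Inter-species divergence: RBH orthology, codon-aware alignment, KA/KS.

Ortholog pairs are detected by strict reciprocal best hit on
best-HSP-reduced similarity tables (admissibility: E-value < 1e-3 and
query coverage > 90% in each direction, the thresholds used for the
Arabidopsis thaliana / A. lyrata comparison).  Coding sequences are
aligned through their proteins (global alignment, BLOSUM62, affine gaps)
and back-translated so every amino-acid column maps to one codon column;
gap-containing and ambiguous columns are wholly excluded from counting.

Per pair, nonsynonymous/synonymous differences are summed with the NG86
pathway-averaged codon counter, divided by site counts averaged over the
two sequences, and Jukes-Cantor corrected into KA and KS.  The estimator
sits behind a small registry so an alternative backend (e.g. a
Yang-Nielsen-style counting program) can be plugged in without touching
callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .codon_model import (
    BASES,
    GENETIC_CODE,
    PairwiseDiff,
    SaturationError,
    count_codon_sites,
    count_pairwise_codon_diff,
    is_stop,
    iter_codons,
    jukes_cantor_correct,
    strip_terminal_stop,
)
from .seqio import SimilarityHit

__all__ = [
    "OrthologPair",
    "DivergenceCounts",
    "TranslationMismatchError",
    "reciprocal_best_hits",
    "align_proteins",
    "backtranslate_alignment",
    "pair_divergence",
    "compute_pair_divergence",
    "ESTIMATORS",
    "translate_cds",
]

EVALUE_MAX_DEFAULT = 1.0e-3
COVERAGE_MIN_DEFAULT = 0.90


class TranslationMismatchError(ValueError):
    """CDS translation disagrees with the supplied protein alignment row."""


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit ortholog pair between two species."""

    gene_a: str
    gene_b: str
    evalue_ab: float
    evalue_ba: float
    coverage_ab: float
    coverage_ba: float
    bitscore_ab: float
    bitscore_ba: float


@dataclass(frozen=True)
class DivergenceCounts:
    """Per-pair substitution counts and Jukes-Cantor-corrected rates."""

    pair_id: str
    Dn: float
    Ds: float
    N_avg: float
    S_avg: float
    pN: float
    pS: float
    KA: float
    KS: float
    ka_ks: float  # NaN when KS == 0 or saturated
    columns_counted: int
    na_reason: str | None = None


def _best_by_query(
    hits: Sequence[SimilarityHit], evalue_max: float, coverage_min: float
) -> dict[str, SimilarityHit]:
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        if not (hit.evalue < evalue_max and hit.query_coverage > coverage_min):
            continue
        cur = best.get(hit.query_id)
        if cur is None or (
            (-hit.bitscore, hit.evalue, hit.subject_id)
            < (-cur.bitscore, cur.evalue, cur.subject_id)
        ):
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(
    hits_a_to_b: Sequence[SimilarityHit],
    hits_b_to_a: Sequence[SimilarityHit],
    evalue_max: float = EVALUE_MAX_DEFAULT,
    coverage_min: float = COVERAGE_MIN_DEFAULT,
) -> list[OrthologPair]:
    """Strict reciprocal-best-hit ortholog pairs.

    A pair (a, b) is admitted iff b is a's best admissible hit and a is
    b's best admissible hit, where admissibility requires
    ``evalue < evalue_max`` and ``coverage > coverage_min`` and "best"
    means highest bitscore with deterministic ties (lower E-value, then
    lexicographic subject id).  Each gene appears in at most one pair.
    """
    best_ab = _best_by_query(hits_a_to_b, evalue_max, coverage_min)
    best_ba = _best_by_query(hits_b_to_a, evalue_max, coverage_min)
    pairs: list[OrthologPair] = []
    for a, hit_ab in sorted(best_ab.items()):
        hit_ba = best_ba.get(hit_ab.subject_id)
        if hit_ba is None or hit_ba.subject_id != a:
            continue
        pairs.append(
            OrthologPair(
                gene_a=a,
                gene_b=hit_ab.subject_id,
                evalue_ab=hit_ab.evalue,
                evalue_ba=hit_ba.evalue,
                coverage_ab=hit_ab.query_coverage,
                coverage_ba=hit_ba.query_coverage,
                bitscore_ab=hit_ab.bitscore,
                bitscore_ba=hit_ba.bitscore,
            )
        )
    return pairs


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_proteins(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, gap open -11 / extend -1).

    Returns the two gapped rows; tie-breaking is deterministic (the
    aligner's first reported optimal path).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty protein sequence")
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1])


def translate_cds(cds: str) -> str:
    """Translate a CDS (terminal stop stripped) into a protein string."""
    codons = strip_terminal_stop(iter_codons(cds.upper()))
    return "".join(GENETIC_CODE[c] for c in codons)


def backtranslate_alignment(
    protein_alignment: tuple[str, str], cds_a: str, cds_b: str
) -> list[tuple[str | None, str | None]]:
    """Map a protein alignment onto codon columns of the two CDSs.

    Each amino-acid column becomes one codon column; protein gaps become
    ``None`` codons.  The ungapped protein rows must equal the CDS
    translations exactly, otherwise :class:`TranslationMismatchError`
    names the first offending position.
    """
    row_a, row_b = protein_alignment
    codons_a = strip_terminal_stop(iter_codons(cds_a.upper()))
    codons_b = strip_terminal_stop(iter_codons(cds_b.upper()))
    for label, row, codons in (("a", row_a, codons_a), ("b", row_b, codons_b)):
        ungapped = row.replace("-", "")
        if len(ungapped) != len(codons):
            raise TranslationMismatchError(
                f"sequence {label}: protein row has {len(ungapped)} residues but CDS "
                f"has {len(codons)} codons"
            )
        for i, (aa, codon) in enumerate(zip(ungapped, codons)):
            if GENETIC_CODE.get(codon, "X") != aa:
                raise TranslationMismatchError(
                    f"sequence {label}: residue {i} is {aa!r} but codon {codon} "
                    f"translates to {GENETIC_CODE.get(codon, 'X')!r}"
                )
    columns: list[tuple[str | None, str | None]] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        codon_a = codon_b = None
        if ca != "-":
            codon_a = codons_a[ia]
            ia += 1
        if cb != "-":
            codon_b = codons_b[ib]
            ib += 1
        columns.append((codon_a, codon_b))
    return columns


def pair_divergence(
    aligned_codons: Sequence[tuple[str | None, str | None]], pair_id: str = ""
) -> DivergenceCounts:
    """NG86 divergence counts over gap-free, unambiguous codon columns.

    Dn and Ds sum the pathway-averaged per-column differences; N_avg and
    S_avg average the two sequences' site counts over the counted columns;
    pN and pS are Jukes-Cantor corrected into KA and KS.  Saturation or
    KS = 0 yields an NA ratio with a reason code.
    """
    nd_total = sd_total = 0.0
    syn_a = syn_b = 0.0
    counted = 0
    for codon_a, codon_b in aligned_codons:
        if codon_a is None or codon_b is None:
            continue
        if any(b not in BASES for b in codon_a + codon_b):
            continue
        if is_stop(codon_a) or is_stop(codon_b):
            continue
        diff: PairwiseDiff = count_pairwise_codon_diff(codon_a, codon_b)
        nd_total += float(diff.nd)
        sd_total += float(diff.sd)
        syn_a += float(count_codon_sites(codon_a).syn_sites)
        syn_b += float(count_codon_sites(codon_b).syn_sites)
        counted += 1
    if counted == 0:
        return DivergenceCounts(
            pair_id=pair_id, Dn=0.0, Ds=0.0, N_avg=0.0, S_avg=0.0, pN=math.nan,
            pS=math.nan, KA=math.nan, KS=math.nan, ka_ks=math.nan,
            columns_counted=0, na_reason="no_countable_columns",
        )
    s_avg = (syn_a + syn_b) / 2.0
    n_avg = 3.0 * counted - s_avg
    p_n = nd_total / n_avg
    p_s = sd_total / s_avg
    reason = None
    try:
        ka = jukes_cantor_correct(p_n)
    except SaturationError:
        ka, reason = math.nan, "saturated_pN"
    try:
        ks = jukes_cantor_correct(p_s)
    except SaturationError:
        ks, reason = math.nan, "saturated_pS"
    if reason is None and ks == 0.0:
        ratio, reason = math.nan, "ks_zero"
    elif reason is None:
        ratio = ka / ks
    else:
        ratio = math.nan
    return DivergenceCounts(
        pair_id=pair_id, Dn=nd_total, Ds=sd_total, N_avg=n_avg, S_avg=s_avg,
        pN=p_n, pS=p_s, KA=ka, KS=ks, ka_ks=ratio,
        columns_counted=counted, na_reason=reason,
    )


def compute_pair_divergence(
    cds_a: str,
    cds_b: str,
    pair_id: str = "",
    protein_alignment: tuple[str, str] | None = None,
) -> DivergenceCounts:
    """Full chain: protein alignment, back-translation, NG86 divergence.

    A pre-computed protein alignment (e.g. from an external aligner) may
    be supplied instead of the internal one.
    """
    if protein_alignment is None:
        protein_alignment = align_proteins(translate_cds(cds_a), translate_cds(cds_b))
    columns = backtranslate_alignment(protein_alignment, cds_a, cds_b)
    return pair_divergence(columns, pair_id=pair_id)


#: Pluggable divergence estimator backends keyed by name.
ESTIMATORS = {"ng86_jc": compute_pair_divergence}
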