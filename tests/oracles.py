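"""Independent brute-force oracles for the NG86 codon arithmetic.

Deliberately written against a different code path (Bio.Seq translation,
recursive pathway enumeration) than the implementation so agreement is
meaningful.  Exact rational arithmetic throughout.
"""

from fractions import Fraction

from Bio.Seq import Seq

BASES = "ACGT"


def oracle_aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_counts(codon: str) -> tuple[Fraction, Fraction]:
    """(syn, nonsyn) sites by direct enumeration of the nine neighbors."""
    aa = oracle_aa(codon)
    assert aa != "*"
    syn = Fraction(0)
    for pos in range(3):
        hits = 0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            if oracle_aa(codon[:pos] + alt + codon[pos + 1 :]) == aa:
                hits += 1
        syn += Fraction(hits, 3)
    return syn, 3 - syn


def _paths(current: str, target: str) -> list[list[tuple[str, str]]]:
    """All mutational pathways as step lists, by recursive position choice."""
    diffs = [i for i in range(3) if current[i] != target[i]]
    if not diffs:
        return [[]]
    out = []
    for i in diffs:
        nxt = current[:i] + target[i] + current[i + 1 :]
        for tail in _paths(nxt, target):
            out.append([(current, nxt)] + tail)
    return out


def oracle_pair_diff(codon_a: str, codon_b: str) -> tuple[Fraction, Fraction]:
    """Pathway-averaged (nd, sd), discarding stop-crossing pathways."""
    all_paths = _paths(codon_a, codon_b)
    admissible = [
        p for p in all_paths if all(oracle_aa(t) != "*" for _, t in p[:-1])
    ]
    paths = admissible or all_paths
    nd = sd = Fraction(0)
    for path in paths:
        for src, dst in path:
            if oracle_aa(src) == oracle_aa(dst) and oracle_aa(src) != "*":
                sd += 1
            else:
                nd += 1
    return Fraction(nd, len(paths)), Fraction(sd, len(paths))


def oracle_has_admissible_path(codon_a: str, codon_b: str) -> bool:
    return any(
        all(oracle_aa(t) != "*" for _, t in p[:-1]) for p in _paths(codon_a, codon_b)
    )
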