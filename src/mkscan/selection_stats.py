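"""McDonald-Kreitman framework statistics and positive-selection calls.

Per gene, the 2x2 MK table (Pn, Ps polymorphisms; Dn, Ds substitutions)
yields the neutrality index NI = (Pn/Ps)/(Dn/Ds) and the direction of
selection DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps).  Departure from neutrality is
tested with a Pearson chi-squared test (1 df, no continuity correction;
a Fisher-exact fallback is available behind a flag), p-values are
FDR-adjusted with Benjamini-Hochberg, and positively selected genes are
those with NI < 1 (or DoS > 0) and q < alpha.

Validity rules: NI is NA when Ps = 0 or Dn = 0; DoS is NA when either
table margin of its defining ratios is empty; the chi-squared p is NA
when a marginal is zero or any expected cell falls below 1 (sparse MK
tables are reported as NA rather than given unstable p-values).
Fractional, pathway-averaged Dn/Ds are rounded half-to-even for the
count-based test but kept exact for the ratio statistics.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "neutrality_index",
    "direction_of_selection",
    "mk_chi2",
    "fdr_adjust",
    "classify_positive_selection",
    "enrichment_test",
]


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def neutrality_index(Pn: float, Ps: float, Dn: float, Ds: float) -> float:
    """NI = (Pn/Ps) / (Dn/Ds); NaN when Ps = 0 or Dn = 0.

    NI < 1 indicates an excess of nonsynonymous divergence (positive
    selection), NI > 1 an excess of nonsynonymous polymorphism (negative
    selection).  When Ds = 0 (with Dn > 0) the divergence ratio is
    infinite and NI is 0.
    """
    _check_nonneg(Pn=Pn, Ps=Ps, Dn=Dn, Ds=Ds)
    if Ps == 0 or Dn == 0:
        return math.nan
    if Ds == 0:
        return 0.0
    return (Pn / Ps) / (Dn / Ds)


def direction_of_selection(Pn: float, Ps: float, Dn: float, Ds: float) -> float:
    """DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps); NaN when either sum is zero.

    DoS > 0 indicates positive selection, DoS < 0 weak negative selection,
    0 neutrality.
    """
    _check_nonneg(Pn=Pn, Ps=Ps, Dn=Dn, Ds=Ds)
    if Dn + Ds == 0 or Pn + Ps == 0:
        return math.nan
    return Dn / (Dn + Ds) - Pn / (Pn + Ps)


def mk_chi2(Pn: float, Ps: float, Dn: float, Ds: float, *, fisher: bool = False) -> float:
    """P-value for independence of the MK 2x2 table [[Pn, Ps], [Dn, Ds]].

    Pearson chi-squared with 1 df and no continuity correction.  NA when
    any marginal is zero; NA when any expected cell is below 1 unless the
    Fisher-exact fallback is requested.
    """
    _check_nonneg(Pn=Pn, Ps=Ps, Dn=Dn, Ds=Ds)
    table = np.array([[Pn, Ps], [Dn, Ds]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan
    if fisher:
        return float(stats.fisher_exact(np.rint(table).astype(int))[1])
    expected = stats.contingency.expected_freq(table)
    if (expected < 1.0).any():
        return math.nan
    result = stats.chi2_contingency(table, correction=False)
    return float(result.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries pass through."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() > 0:
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def classify_positive_selection(
    mk_tables: pd.DataFrame,
    alpha: float = 0.05,
    *,
    fisher: bool = False,
) -> pd.DataFrame:
    """Per-gene selection results from a frame of MK tables.

    ``mk_tables`` needs columns gene_id, Pn, Ps, Dn, Ds (one row per
    gene).  Returns the input augmented with NI, DoS, chi2_p, q_value and
    the two positive-selection flags; genes with NA statistics are never
    flagged and do not enter the FDR denominator.
    """
    required = {"gene_id", "Pn", "Ps", "Dn", "Ds"}
    missing = required - set(mk_tables.columns)
    if missing:
        raise ValueError(f"mk_tables missing columns: {sorted(missing)}")
    if mk_tables["gene_id"].duplicated().any():
        raise ValueError("mk_tables must contain one row per gene")
    df = mk_tables.copy()
    ni, dos, chi_p = [], [], []
    for row in df.itertuples(index=False):
        ni.append(neutrality_index(row.Pn, row.Ps, row.Dn, row.Ds))
        dos.append(direction_of_selection(row.Pn, row.Ps, row.Dn, row.Ds))
        # counts-based test uses half-to-even integer Dn/Ds
        chi_p.append(
            mk_chi2(row.Pn, row.Ps, float(np.rint(row.Dn)), float(np.rint(row.Ds)), fisher=fisher)
        )
    df["NI"] = ni
    df["DoS"] = dos
    df["chi2_p"] = chi_p
    df["q_value"] = fdr_adjust(df["chi2_p"].to_numpy())
    sig = df["q_value"] < alpha  # NaN compares False
    df["pos_sel_NI"] = (df["NI"] < 1.0) & sig
    df["pos_sel_DoS"] = (df["DoS"] > 0.0) & sig
    return df


def enrichment_test(
    selection_flags: Sequence[bool], gene_set_membership: Sequence[bool]
) -> dict:
    """Membership enrichment among selected vs other genes (2x2 chi-squared).

    Returns the selected/other membership proportions as percentages, the
    underlying counts, and the chi-squared p-value (NA when a marginal is
    empty).
    """
    sel = np.asarray(selection_flags, dtype=bool)
    mem = np.asarray(gene_set_membership, dtype=bool)
    if sel.shape != mem.shape:
        raise ValueError("selection_flags and gene_set_membership differ in length")
    n_sel = int(sel.sum())
    n_oth = int((~sel).sum())
    mem_sel = int((sel & mem).sum())
    mem_oth = int((~sel & mem).sum())
    table = np.array([[mem_sel, n_sel - mem_sel], [mem_oth, n_oth - mem_oth]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p = math.nan
    else:
        p = float(stats.chi2_contingency(table, correction=False).pvalue)
    return {
        "n_selected": n_sel,
        "members_in_selected": mem_sel,
        "prop_in_selected": 100.0 * mem_sel / n_sel if n_sel else math.nan,
        "n_others": n_oth,
        "members_in_others": mem_oth,
        "prop_in_others": 100.0 * mem_oth / n_oth if n_oth else math.nan,
        "chi2_p": p,
    }
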