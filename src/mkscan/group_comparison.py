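"""Gene-set assembly and rank-based comparison of per-gene statistics.

Reproduces the study's comparison pattern: assemble the sets {random
(10,000 genes by default), mQTG, mQTG with CNV, non-mQTG with CNV} from a
label table, then compare each per-gene metric (dN_SNP/dS_SNP, KA/KS, NI,
metabolite counts) between sets with the two-sided Wilcoxon rank-sum test
and box-plot summary statistics (median, 25/75% box, 1/99% whiskers;
type-7 linear-interpolation quantiles).

Genes with an NA metric are dropped per comparison (pairwise-complete)
and the reported n's count only non-NA genes.  The random set is drawn
from the full analyzed universe including labeled genes unless exclusion
is requested.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "sample_random_genes",
    "wilcoxon_rank_sum",
    "set_summary",
    "compare_gene_sets",
    "metabolite_count_comparison",
]

RANDOM_SET_SIZE_DEFAULT = 10_000


def sample_random_genes(
    universe: Sequence[str], n: int = RANDOM_SET_SIZE_DEFAULT, seed: int = 0
) -> list[str]:
    """Uniform sample of ``n`` gene ids without replacement, reproducibly.

    If the universe is smaller than ``n``, the whole universe is returned
    with a warning.
    """
    pool = sorted(universe)
    if len(pool) <= n:
        if len(pool) < n:
            warnings.warn(
                f"universe has {len(pool)} genes < requested {n}; using all genes",
                stacklevel=2,
            )
        return pool
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(picked)]


def wilcoxon_rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples have fewer than 20 observations
    and the pooled data are tie-free; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN values must be removed before testing")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all observations identical: statistic at null center
        return 1.0
    small = a.size < 20 and b.size < 20
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (small and tie_free) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def set_summary(values: Sequence[float]) -> dict:
    """Box-plot summary: median, 25/75% box, 1/99% whisker range (type-7)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {k: math.nan for k in ("n", "median", "q25", "q75", "p01", "p99")}
    q = np.quantile(v, [0.01, 0.25, 0.5, 0.75, 0.99], method="linear")
    return {
        "n": int(v.size),
        "median": float(q[2]),
        "q25": float(q[1]),
        "q75": float(q[3]),
        "p01": float(q[0]),
        "p99": float(q[4]),
    }


def _gene_sets(
    universe: Sequence[str],
    labels: pd.DataFrame,
    seed: int,
    random_set_size: int,
    exclude_labeled_from_random: bool,
) -> dict[str, set[str]]:
    lab = labels.set_index("gene_id")
    missing = set(universe) - set(lab.index)
    if missing:
        raise ValueError(
            f"label table does not cover the analyzed universe ({len(missing)} missing, "
            f"e.g. {sorted(missing)[:3]})"
        )
    lab = lab.loc[list(universe)]
    is_mqtg = lab["is_mqtg"].astype(bool)
    has_cnv = lab["has_cnv"].astype(bool)
    pool = (
        [g for g in universe if not (is_mqtg[g] or has_cnv[g])]
        if exclude_labeled_from_random
        else list(universe)
    )
    return {
        "random": set(sample_random_genes(pool, random_set_size, seed)),
        "mQTG": set(is_mqtg[is_mqtg].index),
        "mQTG_CNV": set(is_mqtg[is_mqtg & has_cnv].index),
        "non_mQTG_CNV": set(has_cnv[~is_mqtg & has_cnv].index),
    }


#: Comparison pattern of the study's figure plus its supplementary contrast.
COMPARISONS = [
    ("random", "mQTG"),
    ("random", "mQTG_CNV"),
    ("mQTG", "mQTG_CNV"),
    ("random", "non_mQTG_CNV"),
]


def compare_gene_sets(
    metric_table: pd.DataFrame,
    labels: pd.DataFrame,
    seed: int = 0,
    random_set_size: int = RANDOM_SET_SIZE_DEFAULT,
    exclude_labeled_from_random: bool = False,
) -> pd.DataFrame:
    """All pairwise set comparisons for every metric column.

    ``metric_table`` is indexed by gene_id with one column per metric;
    ``labels`` has columns gene_id, is_mqtg, has_cnv.  Returns one row per
    (metric, set pair) with non-NA sample sizes, box-plot summaries of
    both sets and the rank-sum p-value.
    """
    universe = list(metric_table.index)
    sets = _gene_sets(universe, labels, seed, random_set_size, exclude_labeled_from_random)
    rows = []
    for metric in metric_table.columns:
        series = metric_table[metric]
        for name_a, name_b in COMPARISONS:
            va = series.loc[series.index.isin(sets[name_a])].dropna().to_numpy()
            vb = series.loc[series.index.isin(sets[name_b])].dropna().to_numpy()
            summary_a, summary_b = set_summary(va), set_summary(vb)
            p = wilcoxon_rank_sum(va, vb) if va.size and vb.size else math.nan
            row = {"metric": metric, "set_a": name_a, "set_b": name_b,
                   "n_a": summary_a["n"], "n_b": summary_b["n"], "rank_sum_p": p}
            row.update({f"{k}_a": summary_a[k] for k in ("median", "q25", "q75", "p01", "p99")})
            row.update({f"{k}_b": summary_b[k] for k in ("median", "q25", "q75", "p01", "p99")})
            rows.append(row)
    return pd.DataFrame(rows)


def metabolite_count_comparison(
    gene_to_metabolite_counts: Mapping[str, float] | pd.Series,
    labels: pd.DataFrame,
) -> dict:
    """Compare associated-metabolite counts of mQTGs with vs without CNVs.

    Rank-sum test between the mQTG-with-CNV and mQTG-without-CNV sets on
    per-gene counts of associated specialized metabolites.
    """
    counts = pd.Series(gene_to_metabolite_counts, dtype=float)
    lab = labels.set_index("gene_id")
    mqtg = lab.index[lab["is_mqtg"].astype(bool)]
    with_cnv = [g for g in mqtg if lab.loc[g, "has_cnv"] and g in counts.index]
    without_cnv = [g for g in mqtg if not lab.loc[g, "has_cnv"] and g in counts.index]
    va = counts.loc[with_cnv].dropna().to_numpy()
    vb = counts.loc[without_cnv].dropna().to_numpy()
    p = wilcoxon_rank_sum(va, vb) if va.size and vb.size else math.nan
    return {
        "metric": "metabolite_count",
        "set_a": "mQTG_CNV",
        "set_b": "mQTG_without_CNV",
        "n_a": int(va.size),
        "n_b": int(vb.size),
        "median_a": float(np.median(va)) if va.size else math.nan,
        "median_b": float(np.median(vb)) if vb.size else math.nan,
        "rank_sum_p": p,
    }
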