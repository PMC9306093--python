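"""Cohort association analyses: group summaries, rank-sum and chi-square
tests, threshold tables, and per-gene score associations.

Conventions follow common clinical-table practice: medians/quartiles by
linear interpolation, sample standard deviation (n-1), percentages displayed
to one decimal, all tests two-sided, and no continuity correction on the
Pearson chi-square by default (a Yates correction is available by flag).
No multiple-testing adjustment is applied by default; a Benjamini-Hochberg
column is an opt-in extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Summary",
    "GroupComparison",
    "summarize",
    "rank_sum_test",
    "chi_square_test",
    "threshold_table",
    "gene_association",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Summary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q1, self.q3)


@dataclass(frozen=True)
class GroupComparison:
    """Per-group descriptive summaries plus one hypothesis test."""

    grouping: str
    groups: Mapping[str, Summary]
    test_name: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def summarize(scores: Sequence[float]) -> Summary:
    """n, mean, sample sd, median, and quartiles (linear interpolation)."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return Summary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def rank_sum_test(
    groups: Mapping[str, Sequence[float]], grouping: str = "group"
) -> GroupComparison:
    """Kruskal-Wallis rank-sum test across two or more groups.

    Uses the tie-corrected H statistic with the chi-square approximation on
    k-1 degrees of freedom (two-sided).  If every observation is identical
    the statistic is 0 and p is 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*arrays)
    return GroupComparison(
        grouping=grouping,
        groups={k: summarize(v) for k, v in groups.items()},
        test_name="kruskal-wallis",
        statistic=float(stat),
        p_value=float(p),
    )


def chi_square_test(
    table: Sequence[Sequence[int]], correction: bool = False, grouping: str = "table"
) -> GroupComparison:
    """Pearson chi-square test of independence on a 2 x K count table.

    No continuity correction by default; pass ``correction=True`` for the
    Yates-corrected variant on 2 x 2 tables.
    """
    arr = np.asarray(table)
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table must contain nonnegative integer counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    res = stats.chi2_contingency(arr, correction=correction)
    groups = {
        f"row{i}": Summary(
            n=int(arr[i].sum()),
            mean=float("nan"),
            sd=float("nan"),
            median=float("nan"),
            q1=float("nan"),
            q3=float("nan"),
        )
        for i in range(arr.shape[0])
    }
    return GroupComparison(
        grouping=grouping,
        groups=groups,
        test_name="pearson-chi-square" + ("-yates" if correction else ""),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def threshold_table(
    cohort: pd.DataFrame,
    grouping: str,
    cutoffs: Sequence[int] = (21, 30),
    score_col: str = "hrd_score",
) -> pd.DataFrame:
    """Per-group counts and percentages of patients at or above each cutoff.

    Missing covariate values form their own ``NA`` row, reported but excluded
    from the chi-square tests.  Percentages are always recomputed from raw
    counts and rounded to one decimal for display.
    """
    if grouping not in cohort.columns:
        raise KeyError(f"unknown covariate {grouping!r}")
    df = cohort[[grouping, score_col]].copy()
    is_na = df[grouping].isna() | (df[grouping].astype(str) == ".")
    df[grouping] = df[grouping].astype(str).where(~is_na, "NA")

    rows = []
    group_order = [g for g in df[grouping].unique() if g != "NA"]
    p_values: dict[int, float] = {}
    for cutoff in cutoffs:
        above = df[score_col] >= cutoff
        tested = df[~is_na]
        counts = []
        for g in group_order:
            scores_above = above[~is_na][tested[grouping] == g]
            counts.append([int((~scores_above).sum()), int(scores_above.sum())])
        tab = np.array(counts).T  # 2 x K: rows below/above
        if tab.shape[1] >= 2 and not (np.any(tab.sum(0) == 0) or np.any(tab.sum(1) == 0)):
            p_values[cutoff] = chi_square_test(tab, grouping=grouping).p_value
        else:
            p_values[cutoff] = float("nan")

    for g in group_order + (["NA"] if is_na.any() else []):
        scores = df.loc[df[grouping] == g, score_col]
        row = {"group": g, "n": int(len(scores))}
        for cutoff in cutoffs:
            k = int((scores >= cutoff).sum())
            row[f"n_ge{cutoff}"] = k
            row[f"pct_ge{cutoff}"] = round(100.0 * k / len(scores), 1) if len(scores) else float("nan")
            row[f"p_ge{cutoff}"] = p_values[cutoff] if g != "NA" else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def gene_association(
    cohort: pd.DataFrame,
    genes: Sequence[str] | None = None,
    min_mutated: int = 5,
    score_col: str = "hrd_score",
    adjust: bool = False,
) -> pd.DataFrame:
    """Rank-sum test of scores in mutant vs wildtype patients per gene.

    Only genes with at least ``min_mutated`` mutant patients are tested;
    the rest are silently excluded (logged).  Reported p values are
    unadjusted; ``adjust=True`` appends a Benjamini-Hochberg column as a
    clearly flagged extension.
    """
    if genes is None:
        genes = [
            c
            for c in cohort.columns
            if cohort[c].dtype == object
            and set(cohort[c].dropna().unique()) <= {"mutant", "wildtype", "."}
        ]
    rows = []
    for gene in genes:
        flags = cohort[gene]
        mut = cohort.loc[flags == "mutant", score_col]
        wt = cohort.loc[flags == "wildtype", score_col]
        if len(mut) < min_mutated:
            logger.info("gene %s excluded: only %d mutated cases", gene, len(mut))
            continue
        cmp = rank_sum_test({"mutant": mut, "wildtype": wt}, grouping=gene)
        rows.append(
            {
                "gene": gene,
                "n_mutant": len(mut),
                "n_wildtype": len(wt),
                "median_mutant": cmp.groups["mutant"].median,
                "median_wildtype": cmp.groups["wildtype"].median,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_mutant",
            "n_wildtype",
            "median_mutant",
            "median_wildtype",
            "statistic",
            "p_value",
        ],
    )
    if adjust and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["p_bh_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
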