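"""Statistical layer: one-way ANOVA, Tukey HSD letters, Pearson correlations.

The experimental unit is the vessel, and vessels are destructively sampled,
so observations at a given timepoint are independent across the treatment
groups and a per-timepoint one-way ANOVA with treatment as the single
factor is the appropriate model.  All-pairs Tukey HSD (Tukey-Kramer under
unequal group sizes) follows a significant ANOVA, summarized as a compact
letter display: groups sharing no letter differ at the chosen alpha.
Relationships between fermentation parameters are described by a
pairwise-complete Pearson correlation table carrying r, a two-sided p from
the t transform, and the number of complete pairs per cell.

No multiplicity correction is applied across analytes or timepoints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TukeyLetters",
    "CorrelationTable",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "pearson_pairwise",
    "anova_by_analyte",
]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    analyte: str = ""
    time_h: float = float("nan")


@dataclass
class TukeyLetters:
    """All-pairs Tukey comparison with its compact letter display."""

    pairwise_p: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float
    group_means: dict[str, float] = field(default_factory=dict)


@dataclass
class CorrelationTable:
    """Square symmetric Pearson table: coefficient, p-value, pairs used."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def one_way_anova(
    groups: list[np.ndarray] | dict[str, np.ndarray],
    *,
    analyte: str = "",
    time_h: float = float("nan"),
) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA F test.

    Degenerate input — identical group means with zero within-group
    variance — makes F an indeterminate 0/0; it is reported as F = 0,
    p = 1 (no evidence of any difference).
    """
    samples = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")

    k = len(samples)
    n_total = sum(len(s) for s in samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n_total - k

    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w, analyte, time_h)
        return AnovaResult(float("inf"), 0.0, df_b, df_w, analyte, time_h)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w, analyte, time_h)


def compact_letter_display(
    group_order: list[str], significant_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from a single letter column holding every group; each
    significant pair splits every column containing both members into two
    columns (one without each member), and columns that become subsets of
    another are absorbed.  The result guarantees that significantly
    different groups share no letter while every non-significant pair
    shares at least one.  Letter order follows ``group_order`` (typically
    the design-file order, or descending mean).
    """
    columns: list[set[str]] = [set(group_order)]
    for pair in significant_pairs:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for new in (col - {a}, col - {b}):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
        columns = [
            c
            for c in columns
            if not any(c < other for other in columns if other is not c)
        ]

    index = {g: i for i, g in enumerate(group_order)}
    columns.sort(key=lambda c: min(index[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in group_order}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g].append(letter)
    if len(columns) > len(alphabet):  # pragma: no cover - >26 distinct tiers
        raise ValueError("more letter columns than available letters")
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def tukey_hsd(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    *,
    order_by_mean: bool = True,
) -> TukeyLetters:
    """All-pairs Tukey HSD with a compact letter display.

    Pairwise p-values come from the studentized-range distribution; with
    unequal group sizes this is the Tukey-Kramer generalization.  Letters
    are ordered by descending group mean by default (set
    ``order_by_mean=False`` to keep the input order), with ties broken by
    input order.
    """
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")

    res = sps.tukey_hsd(*samples)
    pairwise: dict[tuple[str, str], float] = {}
    significant: set[frozenset[str]] = set()
    for i, j in itertools.combinations(range(len(labels)), 2):
        p = float(res.pvalue[i, j])
        pairwise[(labels[i], labels[j])] = p
        if p < alpha:
            significant.add(frozenset((labels[i], labels[j])))

    means = {g: float(s.mean()) for g, s in zip(labels, samples)}
    if order_by_mean:
        order = sorted(labels, key=lambda g: (-means[g], labels.index(g)))
    else:
        order = labels
    letters = compact_letter_display(order, significant)
    return TukeyLetters(pairwise_p=pairwise, letters=letters, alpha=alpha, group_means=means)


def pearson_pairwise(
    table: pd.DataFrame, min_pairs: int = 3
) -> CorrelationTable:
    """Pairwise-complete Pearson correlation matrix with p-values and n.

    For each pair of columns, rows where either value is missing are
    dropped; cells with fewer than ``min_pairs`` complete pairs are
    reported missing.  p is the two-sided probability from the t transform
    with n - 2 degrees of freedom.
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for c in cols:
        n.loc[c, c] = int(table[c].notna().sum())
    for a, b in itertools.combinations(cols, 2):
        pair = table[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(pair)
        if len(pair) < min_pairs:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        res = sps.pearsonr(pair[a], pair[b])
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return CorrelationTable(r=r, p=p, n=n)


def anova_by_analyte(
    records: pd.DataFrame,
    analytes: list[str],
    *,
    group_col: str = "treatment_id",
    time_col: str = "time_h",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per analyte x timepoint ANOVA and Tukey letters over all treatments.

    Returns ``(anova_df, letters_df)`` in long format; analyte/timepoint
    combinations without at least two groups of two observations are
    skipped.
    """
    anova_rows, letter_rows = [], []
    for t in sorted(records[time_col].dropna().unique()):
        at_t = records[records[time_col] == t]
        for analyte in analytes:
            if analyte not in at_t.columns:
                continue
            groups = {
                g: sub[analyte].dropna().to_numpy()
                for g, sub in at_t.groupby(group_col, sort=False)
            }
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            res = one_way_anova(groups, analyte=analyte, time_h=t)
            anova_rows.append(
                {
                    "analyte": analyte,
                    "time_h": t,
                    "f_stat": res.f_stat,
                    "p_value": res.p_value,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                }
            )
            tk = tukey_hsd(groups, alpha=alpha)
            for g, letter in tk.letters.items():
                letter_rows.append(
                    {
                        "analyte": analyte,
                        "time_h": t,
                        "treatment_id": g,
                        "mean": tk.group_means[g],
                        "letters": letter,
                        "alpha": alpha,
                    }
                )
    return pd.DataFrame(anova_rows), pd.DataFrame(letter_rows)
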