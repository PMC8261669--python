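"""Group comparisons: one-way ANOVA with Tukey HSD and letter displays.

Used to compare each image feature across flight heights and across
injury-score groups.  Groups sharing a lowercase letter in the compact
letter display are not significantly different at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    labels: list
    n: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    f_statistic: float
    p_value: float
    tukey_p: np.ndarray        # symmetric matrix of adjusted p-values
    letters: dict              # label -> letter string
    alpha: float = 0.05


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    return groups


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """F and p of a one-way ANOVA; all-constant-and-equal input → (0, 1).

    F = (SSB/(k−1)) / (SSW/(N−k)) with p from the F(k−1, N−k) distribution.
    """
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # no variation at all: conventional F=0, p=1
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def tukey_pvalues(groups: list[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of Tukey HSD adjusted p-values (studentized range)."""
    groups = _check_groups(groups)
    res = stats.tukey_hsd(*groups)
    return np.asarray(res.pvalue, dtype=float)


def compact_letter_display(labels: list, means: np.ndarray, pmat: np.ndarray,
                           alpha: float = 0.05) -> dict:
    """Insert-absorb compact letter display.

    Groups are considered in order of descending mean (ties broken by
    label); for each significant pair every letter column containing both
    members is split, then redundant (subset) columns are absorbed.
    Deterministic given the inputs.
    """
    k = len(labels)
    order = sorted(range(k), key=lambda i: (-means[i], str(labels[i])))
    rank = {g: r for r, g in enumerate(order)}
    columns: list[set] = [set(range(k))]
    pairs = [(i, j) for a, i in enumerate(order) for j in order[a + 1:]]
    for i, j in pairs:
        if pmat[i, j] >= alpha:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
        # absorb columns contained in another column
        columns = [c for c in columns
                   if c and not any(c < other for other in columns)]
        # drop duplicates, keep deterministic order
        seen, uniq = [], []
        for c in columns:
            if c not in seen:
                seen.append(c)
                uniq.append(c)
        columns = uniq
    # letter order: by the best (highest-mean) group each column contains
    columns.sort(key=lambda c: min(rank[g] for g in c))
    letters = {lab: "" for lab in labels}
    for idx, col in enumerate(columns):
        ch = chr(ord("a") + idx)
        for g in sorted(col, key=lambda g: rank[g]):
            letters[labels[g]] += ch
    return {lab: "".join(sorted(s)) for lab, s in letters.items()}


def compare_groups(values_by_group: dict, alpha: float = 0.05) -> GroupComparison:
    """Full comparison: ANOVA, Tukey HSD and the letter display."""
    labels = list(values_by_group)
    groups = _check_groups([values_by_group[lab] for lab in labels])
    f, p = one_way_anova(groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        pmat = np.ones((len(groups), len(groups)))
    else:
        pmat = tukey_pvalues(groups)
    means = np.array([g.mean() for g in groups])
    letters = compact_letter_display(labels, means, pmat, alpha)
    return GroupComparison(
        labels=labels,
        n=np.array([g.size for g in groups]),
        means=means,
        sds=np.array([g.std(ddof=1) for g in groups]),
        f_statistic=f, p_value=p, tukey_p=pmat, letters=letters, alpha=alpha)


def stats_report(features: pd.DataFrame, by: str, feature_cols: list[str],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature group comparison table (one row per group × feature)."""
    rows = []
    for col in feature_cols:
        sub = features[np.isfinite(features[col])]
        grouped = {lab: g[col].to_numpy() for lab, g in sub.groupby(by)}
        comp = compare_groups(grouped, alpha=alpha)
        for lab, n, mean, sd in zip(comp.labels, comp.n, comp.means, comp.sds):
            rows.append({"feature": col, by: lab, "n": int(n), "mean": mean,
                         "sd": sd, "F": comp.f_statistic, "p": comp.p_value,
                         "letters": comp.letters[lab]})
    return pd.DataFrame(rows)
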