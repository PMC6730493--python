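"""Nonparametric feature ranking and correlation-filtered greedy selection.

Features are ranked by two-sided Wilcoxon rank-sum p-values (two
classes) or Kruskal-Wallis p-values (three classes).  The two smallest
p-values are always selected; the remaining features are scanned in
p-value order and a candidate is added only if its absolute Pearson
correlation with every already-selected feature stays below the
threshold (default 0.2).  "Lower than 0.2" is read as |r| < 0.2:
negatively correlated features carry the same redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SelectionResult:
    ranked: pd.Series  # p-values, ascending (ties broken by name)
    selected: list[str]
    threshold: float


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 10 samples and the data
    are tie-free; otherwise the normal approximation with midranks and
    tie-corrected variance.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= 10
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _kruskal_p(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def rank_features(X: pd.DataFrame, y) -> pd.Series:
    """Per-feature p-values for class difference.

    Two classes use the Wilcoxon rank-sum test, three (or more) the
    Kruskal-Wallis test.  Every class must have at least two samples.
    """
    y = pd.Series(list(y), index=X.index)
    classes = sorted(y.unique())
    counts = y.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than two samples: {small}")
    groups_idx = [y.index[y == c] for c in classes]
    pvals = {}
    for name in X.columns:
        groups = [X.loc[idx, name].to_numpy(dtype=float) for idx in groups_idx]
        if len(classes) == 2:
            pvals[name] = _rank_sum_p(groups[0], groups[1])
        else:
            pvals[name] = _kruskal_p(groups)
    return pd.Series(pvals, name="p_value")


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson r|, defined as 0 when either vector is constant."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def greedy_select(
    p_values: pd.Series, X: pd.DataFrame, threshold: float = 0.2
) -> SelectionResult:
    """Low-correlation greedy subset in ascending p-value order.

    The first two features are taken unconditionally; each further
    candidate is added iff |Pearson r| with every selected feature is
    below ``threshold``.  Deterministic: p-value ties break by name.
    """
    if len(p_values) < 2:
        raise ValueError("need at least two features to select from")
    order = p_values.to_frame("p").assign(name=p_values.index)
    order = order.sort_values(["p", "name"], kind="mergesort")
    ranked = order["p"]
    names = list(ranked.index)
    selected = names[:2]
    cols = {n: X[n].to_numpy(dtype=float) for n in names}
    for cand in names[2:]:
        if all(_abs_corr(cols[cand], cols[s]) < threshold for s in selected):
            selected.append(cand)
    return SelectionResult(ranked=ranked, selected=selected, threshold=threshold)
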