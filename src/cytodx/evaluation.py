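"""Scoring automated gating against manual labels.

Two metrics compare a clustering (node or metacluster assignment) with
per-event manual population labels:

* weighted purity: each cluster contributes the count of its dominant
  manual population; the sum is divided by the number of co-labeled
  events, so large clusters weigh more;
* a population-matched F1 measure: every manual population is paired
  with one metacluster (greedy, by overlap), precision/recall/F1 are
  computed per pair, and the per-population scores are aggregated into
  one number.

Events without a manual label are excluded from both metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ContingencyTable", "contingency", "purity", "population_f1"]


@dataclass
class ContingencyTable:
    """Cluster x manual-population event counts."""

    counts: pd.DataFrame  # rows: clusters, columns: manual populations

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


def _labeled_mask(manual) -> np.ndarray:
    arr = pd.array(list(manual))
    mask = ~pd.isna(arr)
    return np.asarray(mask) & np.array([str(v) != "" for v in arr])


def contingency(cluster_ids, manual_labels) -> ContingencyTable:
    """Cross-tabulate cluster ids against manual labels, dropping
    unlabeled events."""
    cluster_ids = np.asarray(cluster_ids)
    manual = np.asarray(manual_labels, dtype=object)
    if cluster_ids.shape != manual.shape:
        raise ValueError("cluster ids and manual labels must align")
    mask = _labeled_mask(manual)
    ct = pd.crosstab(
        pd.Series(cluster_ids[mask], name="cluster"),
        pd.Series(manual[mask], name="population"),
    )
    return ContingencyTable(ct)


def purity(ct: ContingencyTable) -> float:
    """Event-weighted purity: (1/N) * sum over clusters of the count of
    the cluster's dominant manual population."""
    if ct.counts.size == 0 or ct.total == 0:
        raise ValueError("empty contingency table")
    return float(ct.counts.values.max(axis=1).sum() / ct.total)


def population_f1(
    meta_ids, manual_labels, average: str = "weighted"
) -> tuple[pd.DataFrame, float]:
    """Match manual populations to metaclusters and score them.

    Each manual population is matched to the metacluster with the
    largest overlap; matching is greedy by overlap size (ties favor the
    larger population, then lexicographic names) and each metacluster
    serves at most one population.  For a matched pair, TP is the
    overlap, FN the population's remaining events and FP the
    metacluster's events from other populations; unmatched populations
    score F1 = 0.

    ``average``: "weighted" (event-weighted mean of per-population F1,
    default) or "pooled" (micro: compute from summed TP/FP/FN).

    Returns (per-population table, aggregate F1).
    """
    ct = contingency(meta_ids, manual_labels).counts
    if ct.size == 0:
        raise ValueError("no co-labeled events")
    pops = list(ct.columns)
    pop_sizes = ct.sum(axis=0)
    meta_sizes = ct.sum(axis=1)

    pairs = [
        (int(ct.loc[m, p]), int(pop_sizes[p]), str(p), m, p)
        for m in ct.index
        for p in pops
        if ct.loc[m, p] > 0
    ]
    pairs.sort(key=lambda t: (-t[0], -t[1], t[2]))
    match: dict = {}
    used_meta: set = set()
    for overlap, _, _, m, p in pairs:
        if p in match or m in used_meta:
            continue
        match[p] = m
        used_meta.add(m)

    rows = []
    for p in pops:
        n_pop = int(pop_sizes[p])
        if p in match:
            m = match[p]
            tp = int(ct.loc[m, p])
            fp = int(meta_sizes[m]) - tp
            fn = n_pop - tp
        else:
            tp, fp, fn = 0, 0, n_pop
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        rows.append(
            {
                "population": p,
                "metacluster": match.get(p),
                "n_events": n_pop,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    table = pd.DataFrame(rows).set_index("population")
    if average == "weighted":
        agg = float(np.average(table["f1"], weights=table["n_events"]))
    elif average == "pooled":
        tp = table["tp"].sum()
        fp = table["fp"].sum()
        fn = table["fn"].sum()
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        agg = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
    else:
        raise ValueError(f"unknown average mode {average!r}")
    return table, agg


def metrics_json(
    panel: str,
    purity_cluster: float,
    purity_metacluster: float,
    f1: float,
    per_population: pd.DataFrame,
) -> str:
    """Serialize panel-level gating metrics."""
    return json.dumps(
        {
            "panel": panel,
            "purity_cluster": purity_cluster,
            "purity_metacluster": purity_metacluster,
            "f1": f1,
            "per_population": per_population["f1"].to_dict(),
        }
    )
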