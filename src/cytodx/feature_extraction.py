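"""Per-sample cluster features and healthy-control age normalization.

From a SOM mapping of one sample, five feature blocks are derived:

* ``percentages_clusters`` — % of kept events per node (K features);
* ``percentages_metaclusters`` — % per metacluster (k features);
* ``percentages_clusters_to_metaclusters`` — each node's share of its
  metacluster, in % (K features);
* ``MFI_cluster`` — median fluorescence intensity of every marker over
  each node's events (K*m features);
* ``MFI_metacluster`` — likewise per metacluster (k*m features).

Empty clusters/metaclusters get zero-imputed MFIs.  A panel with K
nodes, k metaclusters and m markers therefore yields
K + k + K + K*m + k*m features (1,696 for a 10x10 grid with 14
metaclusters and 13 markers).

Features are normalized per age group as z-scores against the healthy
controls of the training partition, removing age-linked immune
variation before classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cytodx.fcs_io import EventMatrix
from cytodx.som_gating import Assignment, SOMModel

logger = logging.getLogger(__name__)

BLOCKS = (
    "percentages_clusters",
    "percentages_metaclusters",
    "percentages_clusters_to_metaclusters",
    "MFI_cluster",
    "MFI_metacluster",
)


@dataclass
class FeatureTable:
    """Samples x named features, with per-feature block descriptors."""

    values: pd.DataFrame
    descriptors: pd.DataFrame  # index: feature name; block, cluster, meta, marker
    normalized: bool = False
    panel: str | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.descriptors.index):
            raise ValueError("descriptor index must match feature columns")
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    def block(self, *blocks: str) -> "FeatureTable":
        """Restrict to the named feature blocks."""
        unknown = set(blocks) - set(BLOCKS)
        if unknown:
            raise KeyError(f"unknown feature blocks: {sorted(unknown)}")
        keep = self.descriptors["block"].isin(blocks)
        names = self.descriptors.index[keep]
        return FeatureTable(
            values=self.values[names],
            descriptors=self.descriptors.loc[names],
            normalized=self.normalized,
            panel=self.panel,
        )

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.columns = pd.MultiIndex.from_frame(
            self.descriptors.reset_index()[["feature", "block", "cluster", "meta", "marker"]]
        )
        out.to_csv(path)


def feature_descriptors(model: SOMModel, panel: str | None = None) -> pd.DataFrame:
    """Deterministic feature naming/ordering for a SOM geometry."""
    K = model.n_nodes
    k = model.n_metaclusters
    markers = model.markers
    rows = []
    for c in range(1, K + 1):
        rows.append((f"percentages_clusters|c{c:03d}", "percentages_clusters", c, None, None))
    for g in range(1, k + 1):
        rows.append((f"percentages_metaclusters|m{g:02d}", "percentages_metaclusters", None, g, None))
    for c in range(1, K + 1):
        rows.append(
            (
                f"percentages_clusters_to_metaclusters|c{c:03d}",
                "percentages_clusters_to_metaclusters",
                c,
                int(model.metacluster[c - 1]),
                None,
            )
        )
    for c in range(1, K + 1):
        for mk in markers:
            rows.append((f"MFI_cluster|c{c:03d}|{mk}", "MFI_cluster", c, None, mk))
    for g in range(1, k + 1):
        for mk in markers:
            rows.append((f"MFI_metacluster|m{g:02d}|{mk}", "MFI_metacluster", None, g, mk))
    df = pd.DataFrame(rows, columns=["feature", "block", "cluster", "meta", "marker"])
    df["panel"] = panel
    return df.set_index("feature")


def extract(assignment: Assignment, E: EventMatrix, model: SOMModel) -> pd.Series:
    """Compute the five feature blocks for one sample.

    Percentages are of kept (QC-passed, live single) events.  MFIs are
    medians in transformed units; clusters or metaclusters without
    events are zero-imputed.
    """
    N = int(E.keep.sum())
    if N == 0:
        raise ValueError("no kept events to extract features from")
    if assignment.node.shape[0] != N:
        raise ValueError("assignment must cover exactly the kept events")
    K = model.n_nodes
    k = model.n_metaclusters
    markers = model.markers

    n_c = np.bincount(assignment.node, minlength=K + 1)[1:].astype(float)
    n_g = np.bincount(assignment.meta, minlength=k + 1)[1:].astype(float)
    pct_cluster = 100.0 * n_c / N
    pct_meta = 100.0 * n_g / N
    meta_of = model.metacluster  # node -> metacluster
    meta_sizes = n_g[meta_of - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_c2m = np.where(meta_sizes > 0, 100.0 * n_c / meta_sizes, 0.0)

    X = E.kept_values(markers)
    mfi_cluster = np.zeros((K, len(markers)))
    mfi_meta = np.zeros((k, len(markers)))
    df = pd.DataFrame(X)
    for ids, out in ((assignment.node, mfi_cluster), (assignment.meta, mfi_meta)):
        med = df.groupby(ids).median()
        out[med.index.to_numpy() - 1] = med.to_numpy()

    vec = np.concatenate(
        [pct_cluster, pct_meta, pct_c2m, mfi_cluster.ravel(), mfi_meta.ravel()]
    )
    names = feature_descriptors(model).index
    return pd.Series(vec, index=names)


def extract_table(
    assignments: dict[str, Assignment],
    events: dict[str, EventMatrix],
    model: SOMModel,
    panel: str | None = None,
) -> FeatureTable:
    """Stack per-sample feature vectors into a FeatureTable."""
    desc = feature_descriptors(model, panel=panel)
    rows = {
        sid: extract(assignments[sid], events[sid], model) for sid in assignments
    }
    values = pd.DataFrame(rows).T
    values = values[desc.index]
    return FeatureTable(values=values, descriptors=desc, panel=panel)


@dataclass
class ZScoreParams:
    """Healthy-control mean/SD per age group (with a pooled fallback)."""

    by_group: dict[int, tuple[pd.Series, pd.Series]]
    pooled: tuple[pd.Series, pd.Series]
    fallback_groups: list[int] = field(default_factory=list)


def fit_zscore(
    ft: FeatureTable, meta: pd.DataFrame, train_ids
) -> ZScoreParams:
    """Estimate per-age-group normalization from training healthy controls.

    ``meta`` is indexed by sample id with columns ``diagnosis`` and
    ``age_group``.  Means and sample SDs (n-1 denominator) come from the
    HC samples among ``train_ids`` only; an age group with fewer than
    two training HCs falls back to the pooled all-HC statistics (logged).
    """
    train_ids = list(train_ids)
    hc = [s for s in train_ids if meta.loc[s, "diagnosis"] == "HC"]
    if len(hc) < 2:
        raise ValueError("need at least two training healthy controls")
    hc_values = ft.values.loc[hc]
    pooled = (hc_values.mean(), hc_values.std(ddof=1).fillna(0.0))
    by_group: dict[int, tuple[pd.Series, pd.Series]] = {}
    fallback = []
    for g in sorted(meta["age_group"].unique()):
        g_hc = [s for s in hc if meta.loc[s, "age_group"] == g]
        if len(g_hc) >= 2:
            sub = ft.values.loc[g_hc]
            by_group[int(g)] = (sub.mean(), sub.std(ddof=1).fillna(0.0))
        else:
            by_group[int(g)] = pooled
            fallback.append(int(g))
    if fallback:
        logger.warning(
            "age groups %s have <2 training HCs; using pooled HC statistics",
            fallback,
        )
    return ZScoreParams(by_group=by_group, pooled=pooled, fallback_groups=fallback)


def apply_zscore(
    ft: FeatureTable, params: ZScoreParams, meta: pd.DataFrame
) -> FeatureTable:
    """Normalize each sample by its age group: z = (x - mu) / sigma.

    Features with sigma = 0 map to z = 0 so constant features stay inert.
    """
    out = ft.values.copy()
    for sid in out.index:
        g = int(meta.loc[sid, "age_group"])
        if g not in params.by_group:
            raise ValueError(f"no z-score parameters for age group {g}")
        mu, sd = params.by_group[g]
        z = (out.loc[sid] - mu) / sd.replace(0.0, np.nan)
        out.loc[sid] = z.fillna(0.0)
    return FeatureTable(
        values=out,
        descriptors=ft.descriptors,
        normalized=True,
        panel=ft.panel,
    )
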