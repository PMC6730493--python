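"""Self-organizing-map automated gating.

A SOM with a fixed rectangular grid (default 10 x 10) is trained on an
aggregate of events sampled evenly from all files of a panel.  Grid
nodes play the role of fine-grained clusters; they are grouped into
metaclusters (coarse cell types) by hierarchical clustering of the
codebook, and laid out as a minimum spanning tree for inspection.  New
samples are mapped onto a trained model by nearest-codebook-row search.

Node (cluster) ids are 1..K and metacluster ids are 1..k throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from cytodx.fcs_io import EventMatrix

__all__ = [
    "SOMModel",
    "Assignment",
    "aggregate",
    "train_som",
    "map_events",
    "metacluster",
    "build_mst",
]


@dataclass
class SOMModel:
    """A trained SOM with metaclustering and tree layout.

    ``codebook`` is (K, m) in transformed units, ``metacluster`` maps
    node id (1..K) to metacluster id (1..k), and ``mst_edges`` is a list
    of (node_u, node_v, euclidean_length) forming a spanning tree.
    """

    codebook: np.ndarray
    grid: tuple[int, int]
    markers: list[str]
    metacluster: np.ndarray
    mst_edges: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        rows, cols = self.grid
        if self.codebook.shape != (rows * cols, len(self.markers)):
            raise ValueError("codebook shape must be (rows*cols, n_markers)")
        self.metacluster = np.asarray(self.metacluster, dtype=int)
        if self.metacluster.shape != (rows * cols,):
            raise ValueError("metacluster must label every node")

    @property
    def n_nodes(self) -> int:
        return self.codebook.shape[0]

    @property
    def n_metaclusters(self) -> int:
        return int(self.metacluster.max())

    def save(self, path) -> None:
        payload = {
            "grid": list(self.grid),
            "markers": self.markers,
            "metacluster": self.metacluster.tolist(),
            "mst_edges": [[int(u), int(v), float(w)] for u, v, w in self.mst_edges],
            "seed": self.seed,
            "codebook": self.codebook.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "SOMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            codebook=np.array(d["codebook"], dtype=float),
            grid=tuple(d["grid"]),
            markers=list(d["markers"]),
            metacluster=np.array(d["metacluster"], dtype=int),
            mst_edges=[(int(u), int(v), float(w)) for u, v, w in d["mst_edges"]],
            seed=d.get("seed"),
        )


@dataclass
class Assignment:
    """Per-event node (1..K) and metacluster (1..k) assignments."""

    node: np.ndarray
    meta: np.ndarray

    def __post_init__(self) -> None:
        self.node = np.asarray(self.node, dtype=int)
        self.meta = np.asarray(self.meta, dtype=int)
        if self.node.shape != self.meta.shape:
            raise ValueError("node and meta must align")


def aggregate(
    files: list[EventMatrix], total_n: int, seed: int
) -> EventMatrix:
    """Sample ~``total_n`` kept events evenly across files.

    ceil(total_n / n_files) events are drawn uniformly without
    replacement from each file (all of them if a file is smaller) and
    concatenated with a 1-based source-file index channel "File".
    """
    if not files:
        raise ValueError("no files to aggregate")
    channels = files[0].channels
    for E in files[1:]:
        if E.channels != channels:
            raise ValueError("all files must share the same channels")
    if total_n < len(files):
        raise ValueError("total_n must be at least the number of files")
    per_file = int(np.ceil(total_n / len(files)))
    ss = np.random.SeedSequence(seed).spawn(len(files))
    blocks, file_ids = [], []
    for i, (E, child) in enumerate(zip(files, ss), start=1):
        kept_idx = np.nonzero(E.keep)[0]
        rng = np.random.default_rng(child)
        if kept_idx.size > per_file:
            kept_idx = np.sort(rng.choice(kept_idx, size=per_file, replace=False))
        blocks.append(E.values[kept_idx])
        file_ids.append(np.full(kept_idx.size, i, dtype=float))
    values = np.column_stack(
        [np.concatenate(blocks), np.concatenate(file_ids)]
    )
    agg = EventMatrix(
        values=values,
        channels=channels + ["File"],
        marker_map=dict(files[0].marker_map),
        transformed=np.append(files[0].transformed, False),
        ranges=dict(files[0].ranges),
    )
    return agg


@njit(cache=True)
def _som_online(codebook, data, order, nhb, radii, alphas):  # pragma: no cover
    n_nodes, m = codebook.shape
    for t in range(order.shape[0]):
        i = order[t]
        best = 0
        best_d = 1e300
        for k in range(n_nodes):
            d = 0.0
            for j in range(m):
                diff = data[i, j] - codebook[k, j]
                d += diff * diff
            if d < best_d:
                best_d = d
                best = k
        r = radii[t]
        al = alphas[t]
        for k in range(n_nodes):
            if nhb[best, k] <= r:
                for j in range(m):
                    codebook[k, j] += al * (data[i, j] - codebook[k, j])
    return codebook


def _grid_distances(rows: int, cols: int) -> np.ndarray:
    coords = np.array(
        [(r, c) for r in range(rows) for c in range(cols)], dtype=float
    )
    return cdist(coords, coords)


def train_som(
    E: EventMatrix,
    markers: list[str],
    grid: tuple[int, int] = (10, 10),
    rlen: int = 10,
    seed: int = 0,
    alpha: tuple[float, float] = (0.05, 0.01),
    track_quantization: bool = False,
):
    """Train an online SOM on the kept events of ``E``.

    The codebook is initialized from K distinct random events and
    updated event by event for ``rlen`` shuffled passes; the best
    matching unit (nearest codebook row, Euclidean) and all nodes within
    the current neighborhood radius move toward the event by a linearly
    decaying learning rate.  The radius shrinks linearly from the upper
    quartile of the grid-distance distribution to 0.  Deterministic for
    a fixed seed.

    Returns the (K, m) codebook, or (codebook, qe_per_pass) when
    ``track_quantization`` is set (mean event-to-BMU distance after each
    pass).
    """
    rows, cols = grid
    n_nodes = rows * cols
    X = E.kept_values(markers)
    if X.shape[0] < n_nodes:
        raise ValueError(
            f"{X.shape[0]} events cannot initialize a {rows}x{cols} grid"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite marker values in SOM training data")
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(X.shape[0], size=n_nodes, replace=False)
    codebook = X[init_idx].copy()

    nhb = _grid_distances(rows, cols)
    radius0 = float(np.quantile(squareform(nhb, checks=False), 0.75))
    n = X.shape[0]
    qe = []
    total = rlen * n
    step0 = 0
    for p in range(rlen):
        order = rng.permutation(n)
        steps = np.arange(step0, step0 + n, dtype=float)
        frac = steps / max(total - 1, 1)
        radii = radius0 * (1.0 - frac)
        alphas = alpha[0] + (alpha[1] - alpha[0]) * frac
        _som_online(codebook, X, order, nhb, radii, alphas)
        step0 += n
        if track_quantization:
            d = cdist(X, codebook)
            qe.append(float(d.min(axis=1).mean()))
    if track_quantization:
        return codebook, qe
    return codebook


def map_events(E: EventMatrix, model: SOMModel) -> Assignment:
    """Assign every kept event to its nearest codebook node.

    Ties go to the lowest node id.  Returns 1-based node and metacluster
    ids for the kept events, in event order.
    """
    X = E.kept_values(model.markers)
    d = cdist(X, model.codebook)
    node = d.argmin(axis=1) + 1
    meta = model.metacluster[node - 1]
    return Assignment(node=node, meta=meta)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids 1..k by decreasing member count (ties: by
    original label, for determinism)."""
    ids, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    remap = {int(ids[i]): rank + 1 for rank, i in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=int)


def metacluster(
    codebook: np.ndarray,
    k: int,
    mode: str = "hclust",
    seed: int = 0,
    n_resamples: int = 100,
    subsample: float = 0.9,
) -> np.ndarray:
    """Group SOM nodes into k metaclusters.

    ``hclust`` (default): average-linkage agglomerative clustering of
    the codebook rows on Euclidean distance, cut at k — deterministic.
    ``consensus``: repeated average-linkage clustering of node
    subsamples; the co-assignment consensus matrix is itself clustered
    at k (seeded).  Labels are renumbered 1..k by decreasing node count.
    """
    codebook = np.asarray(codebook, dtype=float)
    K = codebook.shape[0]
    if not 1 <= k <= K:
        raise ValueError(f"k={k} must be in 1..{K}")
    if mode == "hclust":
        Z = linkage(codebook, method="average", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif mode == "consensus":
        rng = np.random.default_rng(seed)
        n_sub = max(k, int(round(subsample * K)))
        hits = np.zeros((K, K))
        both = np.zeros((K, K))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(K, size=n_sub, replace=False))
            Z = linkage(codebook[idx], method="average", metric="euclidean")
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            both[np.ix_(idx, idx)] += 1
            hits[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            consensus = np.where(both > 0, hits / np.maximum(both, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        dist = 1.0 - consensus
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
    else:
        raise ValueError(f"unknown metaclustering mode {mode!r}")
    return _relabel_by_size(labels)


def build_mst(codebook: np.ndarray) -> list[tuple[int, int, float]]:
    """Minimum spanning tree of the complete Euclidean graph over nodes.

    Prim's algorithm on the dense distance matrix; equal-weight edges
    are broken by lexicographic (smaller-node-first) order.  Returns
    K - 1 edges as (node_u, node_v, length) with 1-based ids, u < v.
    """
    codebook = np.asarray(codebook, dtype=float)
    K = codebook.shape[0]
    if K < 2:
        raise ValueError("MST needs at least two nodes")
    D = cdist(codebook, codebook)
    in_tree = np.zeros(K, dtype=bool)
    in_tree[0] = True
    best_dist = D[0].copy()
    best_from = np.zeros(K, dtype=int)
    edges: list[tuple[int, int, float]] = []
    for _ in range(K - 1):
        cand = [
            (best_dist[v], min(best_from[v], v), max(best_from[v], v), v)
            for v in range(K)
            if not in_tree[v]
        ]
        w, u_small, u_big, v = min(cand)
        edges.append((int(u_small) + 1, int(u_big) + 1, float(w)))
        in_tree[v] = True
        closer = D[v] < best_dist
        best_dist = np.where(closer, D[v], best_dist)
        best_from = np.where(closer & ~in_tree, v, best_from)
    return edges


def fit_som_model(
    E: EventMatrix,
    markers: list[str],
    grid: tuple[int, int] = (10, 10),
    n_meta: int = 14,
    rlen: int = 10,
    seed: int = 0,
    meta_mode: str = "hclust",
) -> SOMModel:
    """Convenience wrapper: train, metacluster and lay out in one call."""
    codebook = train_som(E, markers, grid=grid, rlen=rlen, seed=seed)
    labels = metacluster(codebook, n_meta, mode=meta_mode, seed=seed)
    edges = build_mst(codebook)
    return SOMModel(
        codebook=codebook,
        grid=grid,
        markers=list(markers),
        metacluster=labels,
        mst_edges=edges,
        seed=seed,
    )
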