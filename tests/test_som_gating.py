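import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from cytodx.fcs_io import EventMatrix
from cytodx.som_gating import (
    Assignment,
    SOMModel,
    aggregate,
    build_mst,
    fit_som_model,
    map_events,
    metacluster,
    train_som,
)


def events(values, channels=None):
    values = np.asarray(values, dtype=float)
    channels = channels or [f"m{i}" for i in range(values.shape[1])]
    E = EventMatrix(values, channels)
    E.transformed[:] = True
    return E


class TestAggregate:
    def test_exhaustive_when_total_covers_all(self, rng):
        files = [events(rng.normal(size=(10, 3))) for _ in range(3)]
        agg = aggregate(files, total_n=30, seed=0)
        assert agg.n_events == 30
        assert agg.channels[-1] == "File"
        # every original event appears exactly once
        for i, f in enumerate(files, start=1):
            block = agg.values[agg.values[:, -1] == i][:, :3]
            assert sorted(map(tuple, block)) == sorted(map(tuple, f.values))

    def test_even_sampling_without_replacement(self, rng):
        files = [events(rng.normal(size=(1000, 2))) for _ in range(2)]
        agg = aggregate(files, total_n=10, seed=1)
        for i, f in enumerate(files, start=1):
            block = agg.values[agg.values[:, -1] == i][:, :2]
            assert block.shape[0] == 5
            rows = set(map(tuple, block))
            assert len(rows) == 5  # no within-file duplicates
            assert rows <= set(map(tuple, f.values))

    def test_deterministic(self, rng):
        files = [events(rng.normal(size=(100, 2))) for _ in range(3)]
        a1 = aggregate(files, total_n=30, seed=7)
        a2 = aggregate(files, total_n=30, seed=7)
        np.testing.assert_array_equal(a1.values, a2.values)

    def test_channel_mismatch(self, rng):
        f1 = events(rng.normal(size=(10, 2)), ["a", "b"])
        f2 = events(rng.normal(size=(10, 2)), ["a", "c"])
        with pytest.raises(ValueError):
            aggregate([f1, f2], total_n=10, seed=0)

    def test_respects_keep_mask(self, rng):
        f = events(rng.normal(size=(20, 2)))
        f.keep[:10] = False
        agg = aggregate([f], total_n=20, seed=0)
        assert agg.n_events == 10


class TestTrainSom:
    def test_identical_events_fixed_point(self):
        X = np.tile([2.0, -1.0, 0.5], (50, 1))
        E = events(X)
        cb = train_som(E, E.channels, grid=(2, 2), rlen=5, seed=0)
        np.testing.assert_allclose(cb, np.tile([2.0, -1.0, 0.5], (4, 1)), atol=1e-9)

    def test_separated_blobs_match_kmeans(self, rng):
        means = np.array([[0, 0], [6, 0], [0, 6], [6, 6]], dtype=float)
        sigma = 0.25
        X = np.vstack([rng.normal(m, sigma, (300, 2)) for m in means])
        E = events(X)
        cb = train_som(E, E.channels, grid=(2, 2), rlen=10, seed=3)
        km = KMeans(n_clusters=4, n_init=10, random_state=0).fit(X)
        d = cdist(cb, km.cluster_centers_)
        # nearest pairing: each codebook row sits near one distinct centroid
        assert set(d.argmin(axis=1)) == {0, 1, 2, 3}
        assert (d.min(axis=1) < 3 * sigma).all()

    def test_quantization_error_decreases(self, rng):
        X = np.vstack(
            [rng.normal(m, 0.3, (400, 2)) for m in [[0, 0], [5, 0], [0, 5]]]
        )
        E = events(X)
        _, qe = train_som(
            E, E.channels, grid=(3, 3), rlen=10, seed=1, track_quantization=True
        )
        # online SOM: allow tiny stochastic wiggle once converged
        assert all(b <= a * 1.02 for a, b in zip(qe, qe[1:]))
        assert qe[-1] < qe[0]

    def test_bit_reproducible(self, rng):
        X = rng.normal(size=(500, 3))
        E = events(X)
        cb1 = train_som(E, E.channels, grid=(3, 3), rlen=3, seed=11)
        cb2 = train_som(E, E.channels, grid=(3, 3), rlen=3, seed=11)
        np.testing.assert_array_equal(cb1, cb2)

    def test_too_few_events(self, rng):
        E = events(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            train_som(E, E.channels, grid=(2, 2))

    def test_nonfinite_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_som(events(X), ["m0", "m1"], grid=(2, 2))


def toy_model(codebook, meta=None):
    codebook = np.asarray(codebook, dtype=float)
    K = codebook.shape[0]
    meta = np.ones(K, dtype=int) if meta is None else np.asarray(meta)
    return SOMModel(
        codebook=codebook,
        grid=(K, 1),
        markers=[f"m{i}" for i in range(codebook.shape[1])],
        metacluster=meta,
    )


class TestMap:
    def test_event_on_codebook_row(self, rng):
        cb = rng.normal(size=(10, 3))
        model = toy_model(cb)
        E = events(cb[6:7])  # row 7 in 1-based ids
        assert map_events(E, model).node[0] == 7

    def test_matches_bruteforce_nearest_row(self, rng):
        cb = rng.normal(size=(100, 5))
        X = rng.normal(size=(200, 5))
        model = toy_model(cb)
        got = map_events(events(X), model).node
        expected = np.array(
            [min(range(100), key=lambda k: np.sum((x - cb[k]) ** 2)) + 1 for x in X]
        )
        np.testing.assert_array_equal(got, expected)

    def test_tie_goes_to_lowest_node(self):
        cb = np.array([[5.0], [1.0], [9.0], [0.0], [-1.0]])
        model = toy_model(cb)
        E = events(np.array([[5.0 + 2.0]]))  # equidistant to rows 1 (5) and 3 (9)
        assert map_events(E, model).node[0] == 1

    def test_permutation_equivariance(self, rng):
        cb = rng.normal(size=(16, 3))
        X = rng.normal(size=(50, 3))
        model = toy_model(cb)
        perm = rng.permutation(50)
        a = map_events(events(X), model).node
        b = map_events(events(X[perm]), model).node
        np.testing.assert_array_equal(a[perm], b)

    def test_meta_consistency(self, rng):
        cb = rng.normal(size=(8, 2))
        meta = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        model = toy_model(cb, meta)
        asg = map_events(events(rng.normal(size=(40, 2))), model)
        np.testing.assert_array_equal(asg.meta, meta[asg.node - 1])


class TestMetacluster:
    def test_k_equals_nodes(self, rng):
        cb = rng.normal(size=(6, 2))
        labels = metacluster(cb, k=6)
        assert sorted(labels) == [1, 2, 3, 4, 5, 6]

    def test_k_one(self, rng):
        labels = metacluster(rng.normal(size=(5, 2)), k=1)
        assert (labels == 1).all()

    def test_two_blobs_recovered(self, rng):
        blob_a = rng.normal([0, 0], 0.1, (4, 2))
        blob_b = rng.normal([10, 10], 0.1, (4, 2))
        cb = np.vstack([blob_a, blob_b])
        labels = metacluster(cb, k=2)
        # oracle: exhaustive 2-partition minimizing within-group variance
        best, best_ss = None, np.inf
        for mask_bits in range(1, 2**7):  # node 0 fixed in group 0
            mask = np.array([0] + [(mask_bits >> i) & 1 for i in range(7)])
            ss = sum(
                ((cb[mask == g] - cb[mask == g].mean(axis=0)) ** 2).sum()
                for g in (0, 1)
                if (mask == g).any()
            )
            if ss < best_ss:
                best, best_ss = mask, ss
        assert len(set(zip(labels, best))) == 2  # identical partitions

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            metacluster(rng.normal(size=(4, 2)), k=5)

    def test_labels_sorted_by_size(self, rng):
        cb = np.vstack(
            [rng.normal([0, 0], 0.1, (6, 2)), rng.normal([8, 8], 0.1, (2, 2))]
        )
        labels = metacluster(cb, k=2)
        assert (labels[:6] == 1).all() and (labels[6:] == 2).all()

    def test_consensus_mode_seeded(self, rng):
        cb = np.vstack(
            [rng.normal([0, 0], 0.2, (5, 2)), rng.normal([6, 6], 0.2, (5, 2))]
        )
        l1 = metacluster(cb, k=2, mode="consensus", seed=5)
        l2 = metacluster(cb, k=2, mode="consensus", seed=5)
        np.testing.assert_array_equal(l1, l2)
        assert len(set(zip(l1, [0] * 5 + [1] * 5))) == 2


def prufer_decode(seq, n):
    """Decode a Prufer sequence into tree edges (labels 0..n-1)."""
    degree = [1] * n
    for s in seq:
        degree[s] += 1
    edges = []
    seq = list(seq)
    for s in seq:
        for v in range(n):
            if degree[v] == 1:
                edges.append((v, s))
                degree[v] -= 1
                degree[s] -= 1
                break
    u, v = [v for v in range(n) if degree[v] == 1]
    edges.append((u, v))
    return edges


class TestMst:
    def test_collinear_points(self):
        edges = build_mst(np.array([[0.0], [1.0], [3.0]]))
        assert [(u, v) for u, v, _ in edges] == [(1, 2), (2, 3)]
        assert sum(w for _, _, w in edges) == pytest.approx(3.0)

    def test_total_weight_matches_cayley_enumeration(self, rng):
        pts = rng.normal(size=(6, 2))
        D = cdist(pts, pts)
        best = min(
            sum(D[u, v] for u, v in prufer_decode(seq, 6))
            for seq in itertools.product(range(6), repeat=4)
        )
        got = sum(w for _, _, w in build_mst(pts))
        assert got == pytest.approx(best, rel=1e-12)

    def test_tree_properties(self, rng):
        K = 20
        edges = build_mst(rng.normal(size=(K, 3)))
        assert len(edges) == K - 1
        import networkx as nx

        g = nx.Graph((u, v) for u, v, _ in edges)
        assert g.number_of_nodes() == K and nx.is_connected(g)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            build_mst(np.ones((1, 2)))


class TestModelRoundTrip:
    def test_save_load(self, rng, tmp_path):
        X = rng.normal(size=(300, 3))
        E = events(X)
        model = fit_som_model(E, E.channels, grid=(3, 3), n_meta=4, rlen=3, seed=2)
        assert sorted(set(model.metacluster)) == [1, 2, 3, 4]
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SOMModel.load(path)
        np.testing.assert_array_equal(loaded.codebook, model.codebook)
        np.testing.assert_array_equal(loaded.metacluster, model.metacluster)
        assert loaded.mst_edges == model.mst_edges
        assert loaded.markers == model.markers
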