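"""Taylor–Butina clustering: hand traces, brute-force oracle, updates."""

import numpy as np
import pytest

from ifacetess.cluster import (
    ClusterSet, MatrixValidationError, SimilarityMatrix, taylor_butina,
    update_clusters,
)


def _matrix(ids, entries, default=0.0):
    n = len(ids)
    m = np.full((n, n), default, dtype=float)
    np.fill_diagonal(m, 1.0)
    index = {x: i for i, x in enumerate(ids)}
    for (a, b), v in entries.items():
        m[index[a], index[b]] = m[index[b], index[a]] = v
    return SimilarityMatrix(ids, m)


def butina_oracle(ids, values, threshold):
    """Independent brute-force restatement of the clustering rule."""
    n = len(ids)
    nb = [ {j for j in range(n) if j != i and values[i][j] > threshold}
           for i in range(n) ]
    counts = [len(s) for s in nb]
    unassigned = set(range(n))
    clusters, singles = [], []
    while unassigned:
        pick = min(unassigned, key=lambda i: (-counts[i], ids[i]))
        members = {m for m in nb[pick] if m in unassigned and m != pick}
        unassigned.discard(pick)
        if members:
            unassigned -= members
            clusters.append((ids[pick],
                             [ids[pick]] + sorted(ids[m] for m in members)))
        else:
            singles.append(ids[pick])
    return clusters, sorted(singles)


class TestTaylorButina:
    def test_hand_traced_example(self):
        ids = [1, 2, 3, 4, 5]
        mat = _matrix(ids, {(1, 2): 0.8, (1, 3): 0.6, (2, 3): 0.7,
                            (4, 5): 0.9}, default=0.1)
        cs = taylor_butina(mat, threshold=0.5)
        assert cs.clusters == [(1, [1, 2, 3]), (4, [4, 5])]
        assert cs.singletons == []

    def test_everything_similar_single_cluster(self):
        ids = list("abcd")
        mat = _matrix(ids, {}, default=0.9)
        cs = taylor_butina(mat, threshold=0.5)
        assert len(cs.clusters) == 1
        assert sorted(cs.clusters[0][1]) == ids

    def test_nothing_similar_all_singletons(self):
        ids = list("abcd")
        cs = taylor_butina(_matrix(ids, {}, default=0.2), threshold=0.5)
        assert cs.clusters == []
        assert cs.singletons == ids

    def test_threshold_is_strict(self):
        mat = _matrix([0, 1], {(0, 1): 0.5})
        cs = taylor_butina(mat, threshold=0.5)
        assert cs.singletons == [0, 1]

    def test_invalid_matrices_rejected(self):
        with pytest.raises(MatrixValidationError):
            SimilarityMatrix([0, 1], np.array([[1.0, 0.3], [0.6, 1.0]]))
        with pytest.raises(MatrixValidationError):
            SimilarityMatrix([0, 1], np.array([[1.0, 1.7], [1.7, 1.0]]))
        with pytest.raises(MatrixValidationError):
            SimilarityMatrix([0, 1], np.array([[0.4, 0.3], [0.3, 0.4]]))

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        # coarse value grid → frequent exact ties
        vals = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        ids = list(range(n))
        mat = SimilarityMatrix(ids, vals)
        cs = taylor_butina(mat, threshold=0.5)
        oc, osing = butina_oracle(ids, vals, 0.5)
        assert cs.clusters == oc
        assert cs.singletons == osing

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_and_centroid_similarity_invariants(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 12))
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        ids = [f"i{k}" for k in range(n)]
        cs = taylor_butina(SimilarityMatrix(ids, vals), threshold=0.5)
        assert sorted(cs.all_items()) == sorted(ids)
        index = {x: i for i, x in enumerate(ids)}
        for centroid, members in cs.clusters:
            assert centroid in members
            for m in members:
                assert vals[index[m], index[centroid]] > 0.5 or m == centroid


class TestUpdateClusters:
    def _sim_from(self, vals, ids):
        index = {x: i for i, x in enumerate(ids)}

        def sim(a, b):
            return vals[index[a], index[b]]
        return sim

    def test_copy_of_centroid_joins_its_cluster(self):
        ids = ["a", "b", "new"]
        vals = np.array([[1.0, 0.8, 1.0],
                         [0.8, 1.0, 0.8],
                         [1.0, 0.8, 1.0]])
        existing = ClusterSet(level=None, clusters=[("a", ["a", "b"])])
        updated = update_clusters(existing, ["new"], self._sim_from(vals, ids))
        assert updated.clusters == [("a", ["a", "b", "new"])]

    def test_dissimilar_items_become_singletons(self):
        ids = ["a", "x", "y"]
        vals = np.full((3, 3), 0.1)
        np.fill_diagonal(vals, 1.0)
        existing = ClusterSet(level=None, singletons=["a"])
        updated = update_clusters(existing, ["x", "y"],
                                  self._sim_from(vals, ids))
        assert updated.singletons == ["a", "x", "y"]
        assert updated.clusters == []

    def test_existing_memberships_never_change(self):
        rng = np.random.default_rng(5)
        n = 10
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        ids = [f"i{k}" for k in range(n)]
        first = taylor_butina(SimilarityMatrix(ids[:6], vals[:6, :6]), 0.5)
        before = first.assignment()
        updated = update_clusters(first, ids[6:], self._sim_from(vals, ids))
        after = updated.assignment()
        for old_id in ids[:6]:
            # old items keep their centroid unless their singleton grew
            assert after[old_id] == before[old_id]

    @pytest.mark.parametrize("seed", range(3))
    def test_batch_vs_incremental_centroid_contract(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = 12
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        ids = [f"i{k:02d}" for k in range(n)]
        sim = self._sim_from(vals, ids)
        index = {x: i for i, x in enumerate(ids)}

        batch = taylor_butina(SimilarityMatrix(ids, vals), 0.5)
        half = taylor_butina(SimilarityMatrix(ids[:6], vals[:6, :6]), 0.5)
        increm = update_clusters(half, ids[6:], sim)

        for cs in (batch, increm):
            assert sorted(cs.all_items()) == sorted(ids)
            for centroid, members in cs.clusters:
                for m in members:
                    assert m == centroid or \
                        vals[index[m], index[centroid]] > 0.5
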