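import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from pktaxa import (
    DistanceMatrix,
    GeneratorConfig,
    agglomerative_cluster,
    gen_planted_partition,
    num_clusters_from_labels,
    rand_index,
    similarity_to_dissimilarity,
)
from pktaxa.clustering import ClusteringError, LINKAGES


def random_distance_matrix(rng, n):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(ids=tuple(f"m{i}" for i in range(n)), values=v)


def mst_cut_partition(D: DistanceMatrix, k: int):
    """Single-linkage oracle: delete the k-1 largest MST edges and take
    connected components."""
    mst = minimum_spanning_tree(D.values).toarray()
    edges = [(mst[i, j], i, j) for i, j in zip(*np.nonzero(mst))]
    edges.sort(reverse=True)
    keep = np.zeros_like(mst)
    for w, i, j in edges[k - 1:]:
        keep[i, j] = 1
    _, labels = connected_components(keep, directed=False)
    return list(labels)


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ClusteringError):
            DistanceMatrix(ids=("a", "b"), values=v)

    def test_negative_rejected(self):
        v = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ClusteringError):
            DistanceMatrix(ids=("a", "b"), values=v)

    def test_tiny_asymmetry_symmetrised(self):
        v = np.array([[0.0, 1.0], [1.0 + 1e-12, 0.0]])
        D = DistanceMatrix(ids=("a", "b"), values=v)
        assert D.values[0, 1] == D.values[1, 0]

    def test_csv_round_trip(self, rng, tmp_path):
        D = random_distance_matrix(rng, 6)
        path = tmp_path / "d.csv"
        D.to_csv(path)
        again = DistanceMatrix.from_csv(path)
        assert again.ids == D.ids
        assert np.allclose(again.values, D.values)


class TestAgglomerative:
    def test_k_equals_n(self, rng):
        D = random_distance_matrix(rng, 5)
        _, part = agglomerative_cluster(D, 5, "single")
        assert part.n_clusters == 5

    def test_k_equals_one(self, rng):
        D = random_distance_matrix(rng, 5)
        _, part = agglomerative_cluster(D, 1, "complete")
        assert part.n_clusters == 1

    def test_k_out_of_range(self, rng):
        D = random_distance_matrix(rng, 4)
        for bad in (0, 5):
            with pytest.raises(ClusteringError):
                agglomerative_cluster(D, bad, "single")

    def test_dendrogram_shape_and_monotone_heights(self, rng):
        D = random_distance_matrix(rng, 12)
        for lk in LINKAGES:
            dend, _ = agglomerative_cluster(D, 3, lk)
            assert len(dend.merges) == 11
            heights = [h for _, _, h in dend.merges]
            assert heights == sorted(heights)

    @pytest.mark.parametrize("seed", range(15))
    def test_single_linkage_equals_mst_cut(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        k = int(rng.integers(2, min(n, 8)))
        D = random_distance_matrix(rng, n)
        _, part = agglomerative_cluster(D, k, "single")
        oracle = mst_cut_partition(D, k)
        assert rand_index(oracle, part.as_list(D.ids)) == 1.0

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_planted_blocks_recovered(self, linkage):
        cfg = GeneratorConfig(seed=42, n_molecules=60, n_taxa=3)
        D, labels = gen_planted_partition(cfg)
        _, part = agglomerative_cluster(D, 3, linkage)
        assert rand_index(labels, part.as_list(D.ids)) == 1.0

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_matches_sklearn_on_random_matrices(self, linkage):
        from sklearn.cluster import AgglomerativeClustering

        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            D = random_distance_matrix(rng, 20)
            _, part = agglomerative_cluster(D, 4, linkage)
            ref = AgglomerativeClustering(
                n_clusters=4, metric="precomputed", linkage=linkage
            ).fit_predict(D.values)
            assert rand_index(list(ref), part.as_list(D.ids)) == 1.0

    def test_linkages_agree_on_ultrametric(self):
        # block-constant planted matrix with zero spread is ultrametric
        cfg = GeneratorConfig(
            seed=0, n_molecules=12, n_taxa=3,
            within_mean=0.2, within_spread=0.0,
            between_mean=1.0, between_spread=0.0,
        )
        D, labels = gen_planted_partition(cfg)
        parts = [
            agglomerative_cluster(D, 3, lk)[1].as_list(D.ids) for lk in LINKAGES
        ]
        assert parts[0] == parts[1] == parts[2]
        assert rand_index(labels, parts[0]) == 1.0

    def test_deterministic(self, rng):
        D = random_distance_matrix(rng, 15)
        a = agglomerative_cluster(D, 4, "average")
        b = agglomerative_cluster(D, 4, "average")
        assert a == b


class TestSimilarityConversion:
    def test_minmax_and_inversion(self):
        S = np.array([[3.0, 1.0, 2.0], [1.0, 3.0, 0.0], [2.0, 0.0, 3.0]])
        D = similarity_to_dissimilarity(S, ["a", "b", "c"])
        assert D.values[0, 0] == 0.0  # diagonal forced to 0
        assert D.values[1, 2] == 1.0  # least similar pair
        # order reversal: sim(a,c) > sim(a,b) => diss(a,c) < diss(a,b)
        assert D.values[0, 2] < D.values[0, 1]

    def test_constant_matrix_warns_and_zeroes(self, caplog):
        S = np.full((3, 3), 5.0)
        with caplog.at_level("WARNING"):
            D = similarity_to_dissimilarity(S, ["a", "b", "c"])
        assert np.all(D.values == 0.0)
        assert any("constant" in r.message for r in caplog.records)


class TestClusterCount:
    @pytest.mark.parametrize(
        "labels,expected",
        [(["x"] * 4, 1), (["x", "y", "x", "z"], 3), (list("abcd"), 4)],
    )
    def test_distinct_count(self, labels, expected):
        assert num_clusters_from_labels(labels) == expected

    def test_empty_rejected(self):
        with pytest.raises(ClusteringError):
            num_clusters_from_labels([])
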