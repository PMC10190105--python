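"""Streaming MST construction, threshold cut and noise pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sketchclust import (
    Edge,
    GenomeRecord,
    SketchParams,
    build_mst,
    build_sketch,
    clust_mst,
    cut_mst,
    load_mst,
    merge_final_mst,
    prune_noise,
    random_genome,
    save_mst,
    sketch_genomes,
    stream_blocks,
    update_sub_mst,
)
from sketchclust.mst_cluster import MSTState, _kruskal


def random_complete_graph(n, rng):
    """Complete graph with unique weights (unique -> unique MST)."""
    weights = rng.permutation(n * (n - 1) // 2) + 1
    edges = []
    idx = 0
    for u in range(n):
        for v in range(u + 1, n):
            edges.append(Edge(u, v, float(weights[idx]) / len(weights)))
            idx += 1
    return edges


def nx_mst_weight(edges, n):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_weighted_edges_from([(e.u, e.v, e.w) for e in edges])
    t = nx.minimum_spanning_tree(g)
    return sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in t.edges(data=True)
    )


class TestStreamBlocks:
    def _sketches(self, n, rng):
        params = SketchParams(k=13, sketch_size=100)
        return params, [
            build_sketch(GenomeRecord(f"g{i}", (random_genome(2000, rng),)), params)
            for i in range(n)
        ]

    def test_small_n_single_block(self, rng):
        _, sketches = self._sketches(5, rng)
        blocks = list(stream_blocks(sketches, block_rows=8))
        assert len(blocks) == 1 and len(blocks[0][0]) == 10

    def test_blocks_partition_all_pairs(self, rng):
        _, sketches = self._sketches(20, rng)
        blocks = list(stream_blocks(sketches, block_rows=8))
        assert len(blocks) == 3  # ceil(19 / 8)
        seen = [
            (e.u, e.v) for block, _ in blocks for e in block
        ]
        assert len(seen) == 190 == len(set(seen))
        assert set(seen) == {(u, v) for u in range(20) for v in range(u + 1, 20)}

    def test_identical_genomes_density(self, rng):
        seq = random_genome(2000, rng)
        params = SketchParams(k=13, sketch_size=100)
        sketches = [
            build_sketch(GenomeRecord(f"g{i}", (seq,)), params) for i in range(3)
        ]
        dens = np.zeros(3, dtype=np.int64)
        for _, inc in stream_blocks(sketches, threshold=0.05):
            dens += inc
        assert dens.tolist() == [2, 2, 2]


class TestSubMstUpdates:
    def test_triangle_enumeration(self):
        block = [Edge(0, 1, 0.1), Edge(0, 2, 0.2), Edge(1, 2, 0.3)]
        forest = update_sub_mst([], block, 3)
        assert set(forest) == {Edge(0, 1, 0.1), Edge(0, 2, 0.2)}

    def test_heavier_block_leaves_forest_unchanged(self):
        current = [Edge(0, 1, 0.1), Edge(1, 2, 0.2)]
        block = [Edge(0, 2, 0.9)]
        assert update_sub_mst(current, block, 3) == current

    def test_blockwise_equals_bruteforce(self, rng):
        edges = random_complete_graph(12, rng)
        forest = []
        for i in range(0, len(edges), 22):
            forest = update_sub_mst(forest, edges[i : i + 22], 12)
        assert sorted((e.u, e.v, e.w) for e in forest) == nx_mst_weight(edges, 12)


class TestMergeFinalMst:
    def test_single_worker_passthrough(self):
        sub = [Edge(0, 1, 0.1), Edge(1, 2, 0.2)]
        state = MSTState(n=3, sub_msts=[sub])
        assert merge_final_mst(state) == sub

    def test_worker_count_invariance(self, rng):
        params = SketchParams(k=13, sketch_size=100)
        sketches = [
            build_sketch(GenomeRecord(f"g{i}", (random_genome(3000, rng),)), params)
            for i in range(30)
        ]
        w1 = build_mst(sketches, workers=1)
        w4 = build_mst(sketches, workers=4)
        assert sum(e.w for e in w1.final_mst) == pytest.approx(
            sum(e.w for e in w4.final_mst)
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        n=st.integers(3, 20),
        block=st.integers(1, 15),
        workers=st.integers(1, 5),
        seed=st.integers(0, 10**6),
    )
    def test_streaming_merge_equals_bruteforce(self, n, block, workers, seed):
        """Edge-partition safety: any blocking/worker split reproduces the
        unique full-graph MST."""
        rng = np.random.default_rng(seed)
        edges = random_complete_graph(n, rng)
        subs = [[] for _ in range(workers)]
        for i, start in enumerate(range(0, len(edges), block)):
            wi = i % workers
            subs[wi] = update_sub_mst(subs[wi], edges[start : start + block], n)
        state = MSTState(n=n, sub_msts=subs)
        merged = merge_final_mst(state)
        assert sorted((e.u, e.v, e.w) for e in merged) == nx_mst_weight(edges, n)


class TestCutMst:
    def test_threshold_above_max_single_cluster(self):
        mst = [Edge(0, 1, 0.1), Edge(1, 2, 0.2)]
        assert cut_mst(mst, 0.5, 3).n_clusters == 1

    def test_threshold_below_min_all_singletons(self):
        mst = [Edge(0, 1, 0.1), Edge(1, 2, 0.2)]
        assert cut_mst(mst, 0.05, 3).n_clusters == 3

    def test_path_hand_trace(self):
        mst = [Edge(0, 1, 0.02), Edge(1, 2, 0.09)]
        clusters = cut_mst(mst, 0.05, 3)
        labs = clusters.labels
        assert labs["0"] == labs["1"] != labs["2"]

    def test_single_linkage_equivalence_scipy(self, rng):
        """cut_mst partitions equal naive single-linkage at every level."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform
        from sklearn.metrics import adjusted_rand_score

        n = 25
        edges = random_complete_graph(n, rng)
        mat = np.zeros((n, n))
        for e in edges:
            mat[e.u, e.v] = mat[e.v, e.u] = e.w
        mst = _kruskal(edges, n)
        z = linkage(squareform(mat), method="single")
        for thr in np.linspace(0.0, 1.0, 11):
            ours = [cut_mst(mst, thr, n).labels[str(i)] for i in range(n)]
            ref = fcluster(z, t=thr, criterion="distance")
            assert adjusted_rand_score(ours, ref) == 1.0


class TestPruneNoise:
    def _clustering(self, mst, thr, n):
        return cut_mst(mst, thr, n)

    def test_dense_cluster_unchanged(self):
        mst = [Edge(0, 1, 0.01), Edge(1, 2, 0.01), Edge(2, 3, 0.01)]
        clusters = self._clustering(mst, 0.05, 4)
        dens = np.array([3, 3, 3, 3])
        pruned = prune_noise(clusters, dens, mst, 0.05)
        assert pruned.labels == clusters.labels

    def test_first_quartile_rule_hand_computed(self):
        # densities [5,5,4,1]: Q1 = 3.25 (linear interpolation),
        # min(Q1,2) = 2, so only the density-1 vertex is noise.
        mst = [Edge(0, 1, 0.01), Edge(1, 2, 0.01), Edge(2, 3, 0.01)]
        clusters = self._clustering(mst, 0.05, 4)
        assert np.percentile([5, 5, 4, 1], 25) == pytest.approx(3.25)
        pruned = prune_noise(clusters, np.array([5, 5, 4, 1]), mst, 0.05)
        labs = pruned.labels
        assert labs["0"] == labs["1"] == labs["2"] != labs["3"]

    def test_bridge_vertex_splits_chained_clusters(self):
        """Two dense groups chained through one low-density bridge genome
        separate again once the bridge is pruned."""
        # vertices 0-3 dense, 4 = bridge, 5-8 dense
        mst = [
            Edge(0, 1, 0.01), Edge(1, 2, 0.01), Edge(2, 3, 0.01),
            Edge(3, 4, 0.04), Edge(4, 5, 0.04),
            Edge(5, 6, 0.01), Edge(6, 7, 0.01), Edge(7, 8, 0.01),
        ]
        clusters = self._clustering(mst, 0.05, 9)
        assert clusters.n_clusters == 1
        dens = np.array([3, 3, 3, 4, 2, 4, 3, 3, 3])
        dens[4] = 1  # bridge sees almost nothing nearby
        pruned = prune_noise(clusters, dens, mst, 0.05)
        labs = pruned.labels
        assert labs["0"] == labs["3"]
        assert labs["5"] == labs["8"]
        assert len({labs["0"], labs["5"], labs["4"]}) == 3


class TestClustMstPipeline:
    def _dataset(self, rng, n=12):
        base = [random_genome(20_000, rng) for _ in range(3)]
        genomes = []
        for bi, seq in enumerate(base):
            genomes.append(GenomeRecord(f"b{bi}", (seq,)))
            for mi in range(n // 3 - 1):
                from sketchclust import mutate

                genomes.append(
                    GenomeRecord(f"b{bi}m{mi}", (mutate(seq, 0.02, rng),))
                )
        return genomes

    def test_memory_contract(self, rng):
        genomes = self._dataset(rng, 12)
        params = SketchParams(k=15, sketch_size=200)
        sketches = sketch_genomes(genomes, params)
        state = build_mst(sketches, threshold=0.05, block_rows=3, workers=2)
        n = len(genomes)
        assert state.peak_edges <= 2 * (3 + 1) * n

    def test_mst_file_roundtrip_and_recut_identical(self, tmp_path, rng):
        genomes = self._dataset(rng, 12)
        params = SketchParams(k=15, sketch_size=200, threshold=0.05)
        sketches = sketch_genomes(genomes, params)
        clusters, state = clust_mst(sketches, params, threshold=0.05)
        path = tmp_path / "run.mst"
        save_mst(state, str(path))
        loaded = load_mst(str(path))
        reclusters, _ = clust_mst(mst_state=loaded, threshold=0.05)
        assert reclusters.labels == clusters.labels

    def test_recut_with_mismatched_params_errors(self, tmp_path, rng):
        from sketchclust import ParameterError

        genomes = self._dataset(rng, 12)
        params = SketchParams(k=15, sketch_size=200, threshold=0.05)
        sketches = sketch_genomes(genomes, params)
        _, state = clust_mst(sketches, params, threshold=0.05)
        path = tmp_path / "run.mst"
        save_mst(state, str(path))
        loaded = load_mst(str(path))
        other = SketchParams(k=17, sketch_size=200)
        with pytest.raises(ParameterError):
            clust_mst(mst_state=loaded, params=other)

    def test_determinism_across_worker_counts(self, rng):
        genomes = self._dataset(rng, 12)
        params = SketchParams(k=15, sketch_size=200, threshold=0.05)
        sketches = sketch_genomes(genomes, params)
        c1, s1 = clust_mst(sketches, params, workers=1)
        c3, s3 = clust_mst(sketches, params, workers=3)
        assert c1.labels == c3.labels
        assert s1.final_mst == s3.final_mst

    def test_threshold_zero_groups_identical_genomes(self, rng):
        seq = random_genome(20_000, rng)
        genomes = [
            GenomeRecord("a", (seq,)),
            GenomeRecord("b", (seq,)),
            GenomeRecord("c", (random_genome(20_000, rng),)),
        ]
        params = SketchParams(k=15, sketch_size=200, threshold=0.0)
        sketches = sketch_genomes(genomes, params)
        clusters, _ = clust_mst(sketches, params, threshold=0.0, prune=False)
        assert clusters.labels["a"] == clusters.labels["b"]
        assert clusters.labels["a"] != clusters.labels["c"]
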