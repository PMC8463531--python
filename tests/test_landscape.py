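import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from microscape.landscape import (
    CoverSpec,
    DistanceMatrix,
    MapperGraph,
    MapperLandscape,
    find_attractors,
    jsd_matrix,
    mapper,
    occupancy_summary,
    pcoa,
    preimage_clusters,
    prune_singletons,
)
from microscape.synthetic_data import SyntheticSpec, sample_cross_sectional
from microscape.table_io import CommunityTable, SampleMetadata


def _table(rows, relative=True):
    rows = np.asarray(rows, dtype=float)
    if relative:
        rows = rows / rows.sum(axis=1, keepdims=True)
    return CommunityTable(
        sample_ids=[f"s{i}" for i in range(rows.shape[0])],
        feature_ids=[f"f{j}" for j in range(rows.shape[1])],
        values=rows,
        is_relative=relative,
    )


def _brute_force_jsd(p, q):
    """Literal base-2 entropy formula, the independent oracle."""
    def H(v):
        v = np.asarray(v, dtype=np.longdouble)
        nz = v > 0
        return float(-(v[nz] * np.log2(v[nz])).sum())

    m = 0.5 * (np.asarray(p, dtype=np.longdouble) + np.asarray(q, dtype=np.longdouble))
    return H(m) - 0.5 * (H(p) + H(q))


class TestJSD:
    def test_identical_profiles_have_zero_divergence(self):
        D = jsd_matrix(_table([[0.2, 0.8], [0.2, 0.8]])).D
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_reach_one(self):
        D = jsd_matrix(_table([[1.0, 0.0], [0.0, 1.0]])).D
        assert D[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_entropy_formula(self):
        p, q = [0.5, 0.5], [0.25, 0.75]
        D = jsd_matrix(_table([p, q])).D
        assert D[0, 1] == pytest.approx(_brute_force_jsd(p, q), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_space_properties_on_random_compositions(self, seed):
        rng = np.random.default_rng(seed)
        table = _table(rng.dirichlet(np.full(8, 0.5), size=6))
        dm = jsd_matrix(table)
        D = dm.D
        assert np.all(D >= 0) and np.all(D <= 1)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert np.all(np.diag(D) == 0)
        # identity of indiscernibles: off-diagonal zero iff equal rows
        for i in range(6):
            for j in range(i + 1, 6):
                if D[i, j] < 1e-15:
                    np.testing.assert_allclose(table.values[i], table.values[j])

    def test_all_zero_sample_propagates_normalization_error(self):
        table = CommunityTable(["a", "b"], ["f1", "f2"],
                               np.array([[1.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="'b'"):
            jsd_matrix(table)


class TestPCoA:
    def test_two_points_give_single_axis_at_half_distance(self):
        d = 0.6
        dm = DistanceMatrix(["a", "b"], np.array([[0, d], [d, 0.0]]))
        res = pcoa(dm)
        assert res.n_axes == 1
        np.testing.assert_allclose(sorted(res.coordinates[:, 0]), [-d / 2, d / 2],
                                   atol=1e-12)
        assert res.relative_eigenvalues[0] == pytest.approx(1.0)

    def test_equilateral_triangle_splits_variance_evenly(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(["a", "b", "c"], D))
        assert res.n_axes == 2
        np.testing.assert_allclose(res.relative_eigenvalues, [0.5, 0.5], atol=1e-9)

    def test_collinear_points_are_rank_one(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = pcoa(DistanceMatrix(["a", "b", "c"], D))
        assert res.n_axes == 1
        assert res.relative_eigenvalues[0] == pytest.approx(1.0, abs=1e-9)

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(20, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(20)], D))
        coords = res.coordinates
        Dhat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(Dhat, D, atol=1e-8)

    def test_matches_reference_pcoa_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(12)], D))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        ref_eig = np.asarray(ref.eigvals)[: res.n_axes]
        np.testing.assert_allclose(res.eigenvalues, ref_eig, atol=1e-8)
        ref_coords = np.asarray(ref.samples)[:, : res.n_axes]
        for axis in range(res.n_axes):  # eigenvectors defined up to sign
            a, b = res.coordinates[:, axis], ref_coords[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_degenerate_all_zero_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestPreimageClusters:
    def test_singleton_member(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0.0]]))
        assert preimage_clusters({"a"}, dm, 10) == [frozenset({"a"})]

    def test_equal_distances_form_one_cluster(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0.0]]))
        assert preimage_clusters({"a", "b"}, dm, 10) == [frozenset({"a", "b"})]

    def test_two_tight_pairs_split_at_the_gap(self):
        ids = ["a", "b", "c", "d"]
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.01
        D[2, 3] = D[3, 2] = 0.01
        dm = DistanceMatrix(ids, D)
        clusters = preimage_clusters(set(ids), dm, 10)
        assert sorted(clusters, key=min) == [frozenset({"a", "b"}), frozenset({"c", "d"})]


class TestMapper:
    def test_single_cell_cover_yields_one_node(self, random_compositions):
        dm = jsd_matrix(random_compositions)
        graph = mapper(pcoa(dm), dm, CoverSpec(1, 0.0, 10))
        assert graph.n_nodes == 1
        assert graph.edges == set()
        assert graph.nodes[0] == frozenset(random_compositions.sample_ids)

    def test_separated_clouds_stay_in_separate_components(self):
        spec = SyntheticSpec(K=2, F=40, n_per_group=20, separation=1.0,
                             concentration=2000.0, seed=21)
        table, labels = sample_cross_sectional(spec)
        dm = jsd_matrix(table)
        graph = mapper(pcoa(dm), dm, CoverSpec(15, 0.70, 10))
        import networkx as nx

        components = list(nx.connected_components(graph.to_networkx()))
        assert len(components) >= 2
        truth = dict(zip(table.sample_ids, labels))
        for comp in components:
            members = set().union(*(graph.nodes[n] for n in comp))
            assert len({truth[s] for s in members}) == 1

    def test_zero_overlap_produces_disjoint_nodes(self, random_compositions):
        dm = jsd_matrix(random_compositions)
        graph = mapper(pcoa(dm), dm, CoverSpec(4, 0.0, 10))
        nodes = list(graph.nodes.values())
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                assert not (nodes[i] & nodes[j])
        assert graph.edges == set()


class TestPruneSingletons:
    def _graph(self, sizes):
        nodes = {}
        counter = 0
        for i, size in enumerate(sizes):
            nodes[i] = frozenset(f"s{counter + j}" for j in range(size))
            counter += size
        return MapperGraph(nodes=nodes, edges=set())

    def test_removes_only_singletons(self):
        graph = self._graph([3, 1, 2])
        pruned = prune_singletons(graph)
        assert sorted(len(m) for m in pruned.nodes.values()) == [2, 3]

    def test_all_singletons_give_empty_graph(self):
        pruned = prune_singletons(self._graph([1, 1, 1]))
        assert pruned.n_nodes == 0

    def test_idempotent(self):
        graph = self._graph([3, 1, 2])
        once = prune_singletons(graph)
        twice = prune_singletons(once)
        assert once.nodes == twice.nodes and once.edges == twice.edges

    def test_incident_edges_removed(self):
        nodes = {0: frozenset({"a", "b"}), 1: frozenset({"b"})}
        graph = MapperGraph(nodes=nodes, edges={frozenset((0, 1))})
        pruned = prune_singletons(graph)
        assert pruned.edges == set()


def _path_graph():
    """n0 - n1 - n2 sharing bridge samples."""
    nodes = {
        0: frozenset({"a", "x"}),
        1: frozenset({"x", "b", "y"}),
        2: frozenset({"y", "c"}),
    }
    edges = {frozenset((0, 1)), frozenset((1, 2))}
    ids = ["a", "x", "b", "y", "c"]
    D = np.zeros((5, 5))
    return MapperGraph(nodes=nodes, edges=edges), DistanceMatrix(ids, D)


class TestFindAttractors:
    def test_single_node_is_sole_attractor(self):
        nodes = {0: frozenset({"a", "b"})}
        graph = MapperGraph(nodes=nodes, edges=set())
        ids = ["a", "b", "c"]
        D = np.array([[0, 0.1, 0.5], [0.1, 0, 0.4], [0.5, 0.4, 0.0]])
        part = find_attractors(graph, DistanceMatrix(ids, D), knn_k=1)
        assert part.attractors == [frozenset({0})]
        assert part.basin_of_sample == {"a": 0, "b": 0}

    def test_monotone_path_descends_to_the_minimum(self):
        graph, dm = _path_graph()
        part = find_attractors(graph, dm, knn_k=1,
                               node_potential={0: 3.0, 1: 2.0, 2: 1.0})
        assert part.attractors == [frozenset({2})]
        assert part.basin_of_node == {0: 0, 1: 0, 2: 0}

    def test_double_well_ties_break_to_smallest_node_id(self):
        graph, dm = _path_graph()
        part = find_attractors(graph, dm, knn_k=1,
                               node_potential={0: 1.0, 1: 2.0, 2: 1.0})
        assert part.attractors == [frozenset({0}), frozenset({2})]
        assert part.basin_of_node[1] == 0  # tie between n0 and n2 -> smaller id

    def test_empty_graph_gives_empty_partition(self):
        graph = MapperGraph(nodes={}, edges=set())
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.3], [0.3, 0.0]]))
        part = find_attractors(graph, dm, knn_k=1)
        assert part.n_attractors == 0
        assert part.basin_of_sample == {}

    def test_sample_follows_its_lowest_potential_node(self):
        graph, dm = _path_graph()
        part = find_attractors(graph, dm, knn_k=1,
                               node_potential={0: 3.0, 1: 1.0, 2: 2.0})
        # x sits in n0 and n1; n1 has the lower potential and is the attractor
        assert part.basin_of_sample["x"] == part.basin_of_node[1]


class TestOccupancySummary:
    def _partition(self, mapping):
        from microscape.landscape import AttractorPartition

        return AttractorPartition(attractors=[frozenset({0})], basin_of_node={0: 0},
                                  basin_of_sample=mapping, knn_k=1)

    def _meta(self, rows):
        return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))

    def test_counts_per_generation(self):
        part = self._partition({f"s{i}": 0 for i in range(4)})
        meta = self._meta([{"sample_id": f"s{i}", "generation": g}
                           for i, g in enumerate([1, 1, 2, 2])])
        occ = occupancy_summary(part, meta, ["generation"])
        assert occ.to_dict("records") == [
            {"attractor": "A0", "generation": 1, "count": 2},
            {"attractor": "A0", "generation": 2, "count": 2},
        ]

    def test_missing_samples_counted_unassigned(self):
        part = self._partition({"s0": 0})
        meta = self._meta([{"sample_id": "s0", "generation": 1},
                           {"sample_id": "s1", "generation": 1}])
        occ = occupancy_summary(part, meta, ["generation"])
        counts = dict(zip(occ["attractor"], occ["count"]))
        assert counts == {"A0": 1, "unassigned": 1}

    def test_empty_partition_all_unassigned(self):
        from microscape.landscape import AttractorPartition

        part = AttractorPartition([], {}, {}, 1)
        meta = self._meta([{"sample_id": "s0", "generation": 1},
                           {"sample_id": "s1", "generation": 2}])
        occ = occupancy_summary(part, meta, ["generation"])
        assert set(occ["attractor"]) == {"unassigned"}
        assert occ["count"].sum() == 2

    def test_unknown_key_rejected(self):
        part = self._partition({"s0": 0})
        meta = self._meta([{"sample_id": "s0", "generation": 1}])
        with pytest.raises(KeyError, match="no_such_key"):
            occupancy_summary(part, meta, ["no_such_key"])


class TestMapperLandscapeEstimator:
    def test_sklearn_protocol(self, k3_dataset):
        table, labels = k3_dataset
        model = MapperLandscape(n_intervals=10)
        assert clone(model).get_params()["n_intervals"] == 10
        fitted = model.fit(table.values)
        assert fitted.labels_.shape == (table.n_samples,)
        assert fitted.n_attractors_ == len(fitted.partition_.attractors)

    def test_fit_predict_matches_labels(self, k3_dataset):
        table, _ = k3_dataset
        model = MapperLandscape()
        labels = model.fit_predict(table)
        np.testing.assert_array_equal(labels, model.labels_)

    def test_permutation_equivariance_of_the_full_chain(self, k3_dataset):
        table, _ = k3_dataset
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_samples)
        shuffled = CommunityTable(
            sample_ids=[table.sample_ids[i] for i in perm],
            feature_ids=list(table.feature_ids),
            values=table.values[perm],
            is_relative=True,
        )
        a = MapperLandscape().fit(table)
        b = MapperLandscape().fit(shuffled)
        def basins(model):
            out = {}
            for sample, basin in model.partition_.basin_of_sample.items():
                out.setdefault(basin, set()).add(sample)
            return {frozenset(v) for v in out.values()}
        assert basins(a) == basins(b)
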