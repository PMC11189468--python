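import numpy as np
import pandas as pd
import pytest

import endoscope as es
from endoscope.mapper import MapperGraph, MapperNode, OverlapCapError


def _expr_from_array(arr, patients=None):
    genes = [f"g{i}" for i in range(arr.shape[0])]
    patients = patients or [f"p{j:03d}" for j in range(arr.shape[1])]
    return es.ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=patients))


class TestCorrelationDistance:
    def test_self_distance_zero_and_symmetry(self):
        rng = np.random.default_rng(0)
        expr = _expr_from_array(rng.normal(size=(30, 8)))
        d = es.correlation_distance(expr)
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        assert (d.to_numpy() >= 0).all() and (d.to_numpy() <= 2).all()

    def test_perfect_anticorrelation(self):
        expr = _expr_from_array(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        d = es.correlation_distance(expr)
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_hand_pearson(self):
        expr = _expr_from_array(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 4.0]]))
        d = es.correlation_distance(expr)
        assert d.iloc[0, 1] == pytest.approx(0.018, abs=0.001)

    def test_constant_profile_names_patient(self):
        expr = _expr_from_array(np.column_stack([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
        with pytest.raises(ValueError, match="p001"):
            es.correlation_distance(expr)


def _two_blob_distance(n_per=30, seed=0):
    rng = np.random.default_rng(seed)
    profiles = np.vstack(
        [rng.normal(0, 0.05, size=(n_per, 3)) + [0, 0, 0],
         rng.normal(0, 0.05, size=(n_per, 3)) + [10, 0, 10]]
    )
    from scipy.spatial.distance import cdist

    d = cdist(profiles, profiles)
    ids = [f"p{j:03d}" for j in range(2 * n_per)]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestNeighborhoodLenses:
    def test_two_blobs_bimodal_lens(self):
        dist = _two_blob_distance()
        lens = es.neighborhood_lenses(dist, k=5)
        blob = np.array([0] * 30 + [1] * 30)
        l1 = lens["lens1"].to_numpy()
        means = [l1[blob == b].mean() for b in (0, 1)]
        pooled_sd = np.sqrt(np.mean([l1[blob == b].var() for b in (0, 1)]))
        assert abs(means[0] - means[1]) > 3 * pooled_sd

    def test_patient_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        expr = _expr_from_array(rng.normal(size=(40, 25)))
        d = es.correlation_distance(expr)
        lens = es.neighborhood_lenses(d, k=6)
        perm = rng.permutation(25)
        d2 = d.iloc[perm, perm]
        lens2 = es.neighborhood_lenses(d2, k=6)
        pd.testing.assert_frame_equal(lens.loc[lens2.index], lens2)

    def test_bad_k_rejected(self):
        dist = _two_blob_distance(n_per=5)
        with pytest.raises(ValueError):
            es.neighborhood_lenses(dist, k=0)
        with pytest.raises(ValueError):
            es.neighborhood_lenses(dist, k=10)

    def test_coordinates_in_unit_interval(self):
        dist = _two_blob_distance(seed=4)
        lens = es.neighborhood_lenses(dist, k=5)
        arr = lens.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 1


class TestBuildCover:
    def test_hand_interval_formula(self):
        lens = pd.DataFrame(
            {"lens1": [0.0, 0.5, 1.0], "lens2": [0.0, 0.0, 0.0]},
            index=["a", "b", "c"],
        )
        from endoscope.mapper import _axis_intervals

        intervals = _axis_intervals(np.array([0.0, 0.5, 1.0]), 2, 0.5)
        assert intervals[0] == pytest.approx((0.0, 0.625))
        assert intervals[1] == pytest.approx((0.375, 1.0))

    def test_every_patient_covered(self):
        rng = np.random.default_rng(1)
        lens = pd.DataFrame(
            rng.uniform(size=(100, 2)), columns=["lens1", "lens2"],
            index=[f"p{i}" for i in range(100)],
        )
        cover = es.build_cover(lens, 6, 0.35)
        covered = set()
        for members in cover.values():
            covered |= set(members)
        assert len(covered) == 100

    def test_zero_gain_limit_partitions_interior(self):
        rng = np.random.default_rng(2)
        lens = pd.DataFrame(
            {"lens1": rng.uniform(0.05, 0.95, 50), "lens2": 0.5},
            index=[f"p{i}" for i in range(50)],
        )
        cover = es.build_cover(lens, 5, 1e-9)
        counts = {}
        for members in cover.values():
            for m in members:
                counts[m] = counts.get(m, 0) + 1
        assert all(v == 1 for v in counts.values())

    def test_single_bin_when_resolution_one(self):
        lens = pd.DataFrame(
            {"lens1": [0.1, 0.9], "lens2": [0.2, 0.8]}, index=["a", "b"]
        )
        cover = es.build_cover(lens, 1, 0.35)
        assert len(cover) == 1 and set(next(iter(cover.values()))) == {"a", "b"}


class TestClusterBin:
    def _dist(self, points):
        from scipy.spatial.distance import cdist

        ids = [f"p{i}" for i in range(len(points))]
        d = cdist(np.atleast_2d(points).T, np.atleast_2d(points).T)
        return ids, pd.DataFrame(d, index=ids, columns=ids)

    def test_singleton(self):
        ids, d = self._dist([0.0])
        assert es.cluster_bin(["p0"], d) == [["p0"]]

    def test_two_tight_pairs_split(self):
        ids, d = self._dist([0.0, 0.1, 10.0, 10.1])
        clusters = es.cluster_bin(ids, d)
        assert sorted(map(sorted, clusters)) == [["p0", "p1"], ["p2", "p3"]]

    def test_equal_distances_stay_together(self):
        ids = ["p0", "p1", "p2"]
        d = pd.DataFrame(1.0 - np.eye(3), index=ids, columns=ids)
        assert es.cluster_bin(ids, d) == [ids]


class TestBuildGraph:
    def test_1d_two_clusters_no_edges(self):
        points = [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]
        ids = [f"p{i}" for i in range(6)]
        from scipy.spatial.distance import cdist

        d = pd.DataFrame(
            cdist(np.atleast_2d(points).T, np.atleast_2d(points).T),
            index=ids, columns=ids,
        )
        lens = pd.DataFrame({"lens1": points, "lens2": 0.0}, index=ids)
        cover = es.build_cover(lens, 2, 0.3)  # lens2 axis is degenerate (warned)
        clusters = {b: es.cluster_bin(m, d) for b, m in cover.items()}
        graph = es.build_graph(clusters)
        assert len(graph.nodes) == 2
        assert graph.edges == []

    def test_shared_patient_creates_edge(self):
        nodes = {
            (0, 0): [["p0", "p1", "p2"]],
            (1, 0): [["p2", "p3", "p4"]],
        }
        graph = es.build_graph(nodes)
        assert len(graph.edges) == 1
        assert graph.edges[0][2] == 1

    def test_conservation_of_patients(self):
        rng = np.random.default_rng(8)
        expr = _expr_from_array(rng.normal(size=(60, 80)))
        d = es.correlation_distance(expr)
        lens = es.neighborhood_lenses(d, k=8)
        cover = es.build_cover(lens, 4, 0.35)
        clusters = {b: es.cluster_bin(m, d) for b, m in cover.items()}
        graph = es.build_graph(clusters, min_node_size=1)
        in_bins = set()
        for members in cover.values():
            in_bins |= set(members)
        assert graph.patient_union() == in_bins


def _barbell_graph():
    # two 5-node cliques over 100 patients, joined by one shared patient
    left = [frozenset(f"L{i}_{j}" for j in range(10)) for i in range(5)]
    right = [frozenset(f"R{i}_{j}" for j in range(10)) for i in range(5)]
    right[0] = frozenset(set(right[0]) - {"R0_0"} | {"L4_9"})
    nodes = [
        MapperNode(i, patients, (i, 0)) for i, patients in enumerate(left + right)
    ]
    edges = []
    for i in range(5):
        for j in range(i + 1, 5):
            edges.append((i, j, 1))
            edges.append((5 + i, 5 + j, 1))
    edges = [(a, b, max(1, len(nodes[a].patients & nodes[b].patients))) for a, b, _ in edges]
    edges.append((4, 5, 1))
    return MapperGraph(nodes, edges)


class TestExtractGroups:
    def test_two_component_graph(self):
        nodes = [
            MapperNode(0, frozenset(f"a{i}" for i in range(10)), (0, 0)),
            MapperNode(1, frozenset(f"a{i}" for i in range(5, 15)), (1, 0)),
            MapperNode(2, frozenset(f"b{i}" for i in range(10)), (3, 0)),
            MapperNode(3, frozenset(f"b{i}" for i in range(5, 15)), (4, 0)),
        ]
        edges = [(0, 1, 5), (2, 3, 5)]
        groups = es.extract_groups(MapperGraph(nodes, edges), es.MapperConfig())
        assert len(groups.groups) == 2
        assert groups.shared_fraction == 0.0

    def test_barbell_shared_fraction(self):
        groups = es.extract_groups(_barbell_graph(), es.MapperConfig())
        assert len(groups.groups) == 2
        assert groups.shared_fraction == pytest.approx(1 / 99, abs=1e-9)

    def test_cap_violation_raises(self):
        nodes = [
            MapperNode(0, frozenset(f"p{i}" for i in range(10)), (0, 0)),
            MapperNode(1, frozenset(f"p{i}" for i in range(5, 15)), (2, 0)),
        ]
        graph = MapperGraph(nodes, [])  # no edge: two groups sharing 5 of 15
        with pytest.raises(OverlapCapError):
            es.extract_groups(graph, es.MapperConfig())


class TestMergeLowMortality:
    def _cohort(self, deaths_by_patient):
        return pd.DataFrame(
            {"mortality_28d": pd.Series(deaths_by_patient)},
        )

    def test_two_low_death_groups_merge(self):
        groups = es.EndotypeGroups(
            groups={"g1": {f"a{i}" for i in range(20)} | {"x"},
                    "g2": {f"b{i}" for i in range(20)} | {"x"},
                    "g3": {f"c{i}" for i in range(30)}},
            exclusive={},
            shared_fraction=0.0,
        )
        deaths = {}
        for i in range(20):
            deaths[f"a{i}"] = 1 if i < 3 else 0
            deaths[f"b{i}"] = 1 if i < 4 else 0
        for i in range(30):
            deaths[f"c{i}"] = 1 if i < 15 else 0
        deaths["x"] = 0
        merged = es.merge_low_mortality(groups, self._cohort(deaths), min_deaths=10)
        assert len(merged.groups) == 2
        assert "g1-g2" in merged.groups

    def test_identity_when_all_groups_have_enough_deaths(self):
        groups = es.EndotypeGroups(
            groups={"g1": {f"a{i}" for i in range(20)},
                    "g2": {f"b{i}" for i in range(20)}},
            exclusive={},
            shared_fraction=0.0,
        )
        deaths = {f"a{i}": 1 for i in range(20)} | {f"b{i}": 1 for i in range(20)}
        merged = es.merge_low_mortality(groups, self._cohort(deaths), min_deaths=10)
        assert set(merged.groups) == {"g1", "g2"}

    def test_merge_preserves_patient_multiset(self):
        groups = es.EndotypeGroups(
            groups={"g1": {"a", "b", "s"}, "g2": {"c", "d", "s"}},
            exclusive={},
            shared_fraction=0.2,
        )
        deaths = {p: 0 for p in "abcd"} | {"s": 1}
        merged = es.merge_low_mortality(groups, self._cohort(deaths), min_deaths=2)
        all_before = set().union(*groups.groups.values())
        all_after = set().union(*merged.groups.values())
        assert all_before == all_after


class TestEndToEnd:
    def test_default_run_properties(self, default_processed):
        _, _, cohort, truth, expr, _ = default_processed
        graph, groups = es.build_mapper_groups(expr, es.MapperConfig())
        assert groups.shared_fraction <= 0.10
        # repeated run is identical (determinism)
        graph2, groups2 = es.build_mapper_groups(expr, es.MapperConfig())
        assert groups.groups == groups2.groups
        assert [n.patients for n in graph.nodes] == [n.patients for n in graph2.nodes]
        # group labels ordered by mortality after relabeling
        labeled = groups.with_mortality(cohort["mortality_28d"])
        rates = [labeled.mortality[g] for g in sorted(labeled.mortality)]
        assert rates == sorted(rates, reverse=True)

    def test_group_count_in_expected_range(self, default_processed):
        _, _, _, _, expr, _ = default_processed
        _, groups = es.build_mapper_groups(expr, es.MapperConfig())
        assert 3 <= len(groups.groups) <= 8
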