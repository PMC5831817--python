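import numpy as np
import pytest

from hoxmap.align import SimilarityEdge
from hoxmap.annotations import AnnotatedSequence, Category, GroupLabel
from hoxmap.simmap import (
    LayoutParams,
    MapParseError,
    SimilarityGraph,
    apply_cutoff,
    center_distance,
    connected_components,
    layout,
    read_map,
    select_seed_clusters,
    write_map,
)


def _graph(n_nodes, edge_spec, cutoff=1e-2):
    seqs = [AnnotatedSequence(f"n{i}", "MKVL") for i in range(n_nodes)]
    edges = [
        SimilarityEdge.make(f"n{i}", f"n{j}", eab, eba) for i, j, eab, eba in edge_spec
    ]
    return SimilarityGraph(seqs, edges, cutoff)


class TestGraphInvariants:
    def test_self_edges_and_duplicates_are_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            _graph(2, [(0, 0, 1e-5, None)])
        with pytest.raises(ValueError, match="duplicate edge"):
            _graph(2, [(0, 1, 1e-5, None), (1, 0, None, 1e-5)])

    def test_edge_endpoints_must_be_nodes(self):
        seqs = [AnnotatedSequence("a", "MK")]
        edges = [SimilarityEdge.make("a", "zz", 1e-5, None)]
        with pytest.raises(ValueError, match="endpoint"):
            SimilarityGraph(seqs, edges, 1e-2)


class TestApplyCutoff:
    def test_same_cutoff_is_identity(self):
        g = _graph(3, [(0, 1, 1e-10, 1e-12), (1, 2, 1e-5, None)])
        g2 = apply_cutoff(g, g.cutoff)
        assert [(e.id_a, e.id_b, e.weight) for e in g2.edges] == [
            (e.id_a, e.id_b, e.weight) for e in g.edges
        ]

    def test_weights_are_recomputed_over_surviving_directions(self):
        g = _graph(2, [(0, 1, 1e-40, 1e-20)])
        g2 = apply_cutoff(g, 1e-30)
        assert g2.edges[0].weight == pytest.approx(40.0)
        assert g2.edges[0].evalue_ba is None

    def test_nodes_survive_even_when_all_edges_vanish(self):
        g = _graph(3, [(0, 1, 1e-10, 1e-10)])
        g2 = apply_cutoff(g, 1e-50)
        assert g2.edges == [] and g2.node_ids == g.node_ids

    def test_loosening_requires_realignment_and_is_an_error(self):
        g = _graph(2, [(0, 1, 1e-10, None)], cutoff=1e-5)
        with pytest.raises(ValueError, match="laxer"):
            apply_cutoff(g, 1e-2)

    def test_tightening_never_adds_edges_on_synthetic_data(self, scenario_graph):
        g33 = apply_cutoff(scenario_graph, 1e-33)
        g40 = apply_cutoff(scenario_graph, 1e-40)
        e33 = {(e.id_a, e.id_b) for e in g33.edges}
        e40 = {(e.id_a, e.id_b) for e in g40.edges}
        assert e40 <= e33


class TestComponents:
    def test_triangle_plus_isolated_node(self):
        g = _graph(4, [(0, 1, 1e-5, 1e-5), (1, 2, 1e-5, 1e-5), (0, 2, 1e-5, 1e-5)])
        comps = connected_components(g)
        assert [len(c) for c in comps] == [3, 1]

    def test_edgeless_graph_gives_singletons(self):
        comps = connected_components(_graph(5, []))
        assert [len(c) for c in comps] == [1] * 5

    def test_two_cliques_joined_by_a_bridge_are_one_component(self):
        spec = [(i, j, 1e-5, 1e-5) for i in range(10) for j in range(i + 1, 10)]
        spec += [(10 + i, 10 + j, 1e-5, 1e-5) for i in range(10) for j in range(i + 1, 10)]
        spec += [(0, 10, 1e-5, 1e-5)]
        comps = connected_components(_graph(20, spec))
        assert len(comps) == 1


class TestSeedClusters:
    def _comps(self):
        return [{"a", "b"}, {"c", "d"}, {"e"}]

    def test_single_component_selection(self):
        assert select_seed_clusters(self._comps(), {"a"}) == {"a", "b"}

    def test_union_over_seed_bearing_components(self):
        assert select_seed_clusters(self._comps(), {"a", "e"}) == {"a", "b", "e"}

    def test_all_components_seeded_gives_everything(self):
        assert select_seed_clusters(self._comps(), {"b", "c", "e"}) == {
            "a", "b", "c", "d", "e",
        }

    def test_empty_seed_set_is_an_error(self):
        with pytest.raises(ValueError):
            select_seed_clusters(self._comps(), set())


class TestLayout:
    def test_single_node_converges_immediately(self):
        st = layout(_graph(1, []), seed=0)
        assert st.converged and st.coords.shape == (1, 2)

    def test_identical_seed_gives_bitwise_identical_coordinates(self):
        g = _graph(2, [(0, 1, 1e-50, 1e-50)])
        s1 = layout(g, seed=7)
        s2 = layout(g, seed=7)
        assert np.array_equal(s1.coords, s2.coords)
        assert s1.converged

    def test_two_connected_nodes_settle_at_the_force_balance_distance(self):
        p = LayoutParams()
        g = _graph(2, [(0, 1, 1e-50, 1e-50)])
        st = layout(g, params=p, seed=3)
        d = float(np.linalg.norm(st.coords[0] - st.coords[1]))
        # attraction a*d == repulsion r/d^2  =>  d* = (r/a)^(1/3)
        d_star = (p.repulsion_scale / p.attraction_scale) ** (1 / 3)
        assert d == pytest.approx(d_star, rel=0.05)

    def test_three_cliques_separate_into_distinct_clusters(self):
        spec = []
        for k in range(3):
            base = 8 * k
            spec += [
                (base + i, base + j, 1e-50, 1e-50)
                for i in range(8)
                for j in range(i + 1, 8)
            ]
        g = _graph(24, spec)
        st = layout(g, seed=1)
        X = st.coords
        grp = np.repeat(np.arange(3), 8)
        for k in range(3):
            A = X[grp == k]
            intra = np.mean(
                [np.linalg.norm(a - b) for i, a in enumerate(A) for b in A[i + 1:]]
            )
            inter = min(
                np.mean([np.linalg.norm(a - b) for a in A for b in X[grp == m]])
                for m in range(3)
                if m != k
            )
            assert intra / inter < 1

    def test_coincident_points_are_jittered_not_crashed(self):
        g = _graph(3, [(0, 1, 1e-50, 1e-50)])
        p = LayoutParams(max_iter=50)
        st = layout(g, params=p, seed=0)
        assert np.isfinite(st.coords).all()

    def test_three_dimensional_layout(self):
        st = layout(_graph(4, [(0, 1, 1e-30, None)]), dims=3, seed=2)
        assert st.coords.shape == (4, 3)


class TestCenterDistance:
    def test_coincident_nodes_have_zero_distances(self):
        st = layout(_graph(1, []), seed=0)
        st.coords = np.zeros((1, 2))
        ranks = center_distance(st, {"n0": "g"})
        assert ranks == [("g", 0.0)]

    def test_translated_group_ranks_first(self):
        g = _graph(6, [])
        st = layout(g, seed=0)
        st.coords = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [10, 10], [11, 11]])
        groups = {f"n{i}": ("far" if i >= 4 else "near") for i in range(6)}
        ranks = center_distance(st, groups)
        assert ranks[0][0] == "far"

    def test_empty_groups_are_omitted_with_a_warning(self):
        st = layout(_graph(2, []), seed=0)
        with pytest.warns(UserWarning, match="ghost"):
            ranks = center_distance(st, {"n0": "a", "n1": "a", "zz": "ghost"})
        assert [g for g, _ in ranks] == ["a"]

    def test_statistics_are_invariant_under_rigid_motions(self):
        g = _graph(9, [(i, j, 1e-30, None) for i in range(4) for j in range(i + 1, 4)])
        st = layout(g, seed=5)
        groups = {f"n{i}": f"g{i % 3}" for i in range(9)}
        before = center_distance(st, groups)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        st.coords = st.coords @ R.T + np.array([5.0, -3.0])
        after = center_distance(st, groups)
        assert [g for g, _ in before] == [g for g, _ in after]
        for (_, d1), (_, d2) in zip(before, after):
            assert d1 == pytest.approx(d2)


def test_fast_evolving_groups_show_greater_than_average_center_distance():
    """Elevated Cdx/posterior rates push both groups farther from the map
    center than the average group (every replicate), and to the top two
    ranks outright in a frozen realization."""
    from hoxmap import align, simulate

    def ranks_for(seed):
        ds = simulate.hox_parahox_scenario("lba", severity=3.0, rng_seed=seed)
        hits = align.all_against_all(ds.sequences, align.ScoringScheme(), 1e-2)
        g = SimilarityGraph(ds.sequences, align.build_edges(hits, 1e-20), 1e-20)
        st = layout(g, seed=seed)
        return center_distance(st, {s.seq_id: s.common_name for s in ds.sequences})

    for seed in range(5):
        dist = dict(ranks_for(seed))
        slow_mean = np.mean(
            [v for k, v in dist.items() if k not in ("Cdx", "posterior")]
        )
        assert dist["Cdx"] > slow_mean
        assert dist["posterior"] > slow_mean

    frozen = ranks_for(0)
    assert {frozen[0][0], frozen[1][0]} == {"Cdx", "posterior"}


class TestMapFile:
    def _full_graph(self):
        seqs = [
            AnnotatedSequence("a", "MKVLW", "Hox3", "Mus musculus"),
            AnnotatedSequence("b", "MKVLY", "Xlox", "Capitella teleta"),
            AnnotatedSequence("c", "MKWWY", "", ""),
        ]
        edges = [
            SimilarityEdge.make("a", "b", 1.2345678912345e-41, 3.14159e-39),
            SimilarityEdge.make("b", "c", 7.77e-10, None),
        ]
        return SimilarityGraph(seqs, edges, 1e-2)

    def test_round_trip_is_bit_exact(self, tmp_path):
        g = self._full_graph()
        st = layout(g, seed=11)
        p = tmp_path / "map.txt"
        write_map(g, st, p)
        g2, st2 = read_map(p)
        assert g2.node_ids == g.node_ids
        assert g2.cutoff == g.cutoff
        for e1, e2 in zip(g.edges, g2.edges):
            assert (e1.evalue_ab, e1.evalue_ba, e1.weight) == (
                e2.evalue_ab, e2.evalue_ba, e2.weight,
            )
        assert np.array_equal(st.coords, st2.coords)
        assert [s.group for s in g2.sequences] == [s.group for s in g.sequences]

    def test_edgeless_map_is_valid(self, tmp_path):
        g = _graph(2, [])
        p = tmp_path / "empty.txt"
        write_map(g, None, p)
        g2, st2 = read_map(p)
        assert g2.edges == [] and st2 is None

    def test_hand_written_minimal_file_parses(self, tmp_path):
        p = tmp_path / "mini.txt"
        p.write_text(
            "[params]\ncutoff=0.01\n"
            "[sequences]\n>s1|Cdx|Mus musculus\nMKVL\n>s2\nMKVY\n>s3\nMMMM\n"
            "[edges]\n0\t1\t1e-20;1e-22\n"
        )
        g, st = read_map(p)
        assert len(g.sequences) == 3 and len(g.edges) == 1 and st is None
        assert g.sequences[0].group.category is Category.PARAHOX

    def test_unknown_section_tag_reports_the_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("[params]\ncutoff=0.01\n[bogus]\n")
        with pytest.raises(MapParseError, match=r"bad\.txt:3"):
            read_map(p)
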