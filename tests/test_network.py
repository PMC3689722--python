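"""Interaction-network construction, rates, connectivity categories, exports."""

import networkx as nx
import numpy as np
import pytest

from dyadnet import (
    CombinedState,
    ConnectivityProfile,
    GROUP_A,
    InteractionNetwork,
    Transition,
    build_network,
    compare_connectivity,
    connectivity_profile,
    export_network,
    generate_streams,
    harmonious_config,
)

from conftest import make_stream


def toy_network(edges, group=GROUP_A):
    """Network straight from an explicit weighted edge list."""
    g = nx.DiGraph()
    for u, v, w in edges:
        g.add_edge(u, v, count=w)
    for n in g.nodes:
        g.nodes[n].setdefault("dwell", 1)
        g.nodes[n].setdefault("n_dyads", 1)
        g.nodes[n].setdefault("mean_dwell", 1.0)
    net = InteractionNetwork(group=group, graph=g, total_transitions=0, n_dyads=1)
    net.recompute_rates()
    return net


class TestBuildNetwork:
    def test_toy_segment_three_edges_at_a_third_each(self, codebook):
        stream = make_stream([1, 1, 2, 2, 1], [11, 11, 11, 12, 12])
        net = build_network([stream], codebook, GROUP_A)
        assert net.total_transitions == 3
        assert net.n_edges == 3
        assert all(r == pytest.approx(100 / 3) for r in net.edge_rates().values())

    def test_rates_invariant_under_duplicating_dyads(self, codebook):
        s1 = make_stream([1, 1, 2, 2, 1], [11, 11, 11, 12, 12], dyad_id="d1")
        s2 = make_stream([1, 1, 2, 2, 1], [11, 11, 11, 12, 12], dyad_id="d2")
        net = build_network([s1, s2], codebook, GROUP_A)
        assert net.total_transitions == 6
        assert all(d["count"] == 2 for *_, d in net.graph.edges(data=True))
        assert all(r == pytest.approx(100 / 3) for r in net.edge_rates().values())

    def test_dyad_never_leaving_state_gives_isolated_node(self, codebook):
        net = build_network([make_stream([1] * 7, [11] * 7)], codebook, GROUP_A)
        assert net.n_edges == 0
        assert net.total_transitions == 0
        assert net.dwell(CombinedState(1, 11)) == 7
        assert net.meta.get("no_transitions")
        assert connectivity_profile(net).isolated_count == 1

    def test_no_transition_spans_dyads(self, codebook):
        # d1 ends in (1,11), d2 starts in (2,12): no edge between them
        s1 = make_stream([1, 1], [11, 11], dyad_id="d1")
        s2 = make_stream([2, 2], [12, 12], dyad_id="d2")
        net = build_network([s1, s2], codebook, GROUP_A)
        assert net.n_edges == 0

    def test_merge_consistency_over_disjoint_dyad_sets(self, codebook, rng):
        streams = generate_streams(harmonious_config(n_full_term=8, n_preterm=1, seed=4))
        group_a = [s for s in streams if s.group == GROUP_A]
        part1, part2 = group_a[:4], group_a[4:]
        counts = build_network(group_a, codebook, GROUP_A).edge_counts()
        c1 = build_network(part1, codebook, GROUP_A).edge_counts()
        c2 = build_network(part2, codebook, GROUP_A).edge_counts()
        merged = {t: c1.get(t, 0) + c2.get(t, 0) for t in set(c1) | set(c2)}
        assert counts == merged

    def test_rates_sum_to_hundred(self, codebook):
        streams = generate_streams(harmonious_config(n_full_term=5, n_preterm=1, seed=9))
        net = build_network(
            [s for s in streams if s.group == GROUP_A], codebook, GROUP_A
        )
        assert sum(net.edge_rates().values()) == pytest.approx(100.0, rel=1e-9)

    def test_mean_dwell_divides_by_observed_dyads(self, codebook):
        s1 = make_stream([1, 1, 1], [11, 11, 11], dyad_id="d1")
        s2 = make_stream([1, 2], [11, 11], dyad_id="d2")
        net = build_network([s1, s2], codebook, GROUP_A)
        node = net.graph.nodes[CombinedState(1, 11)]
        assert node["dwell"] == 4
        assert node["n_dyads"] == 2
        assert node["mean_dwell"] == pytest.approx(2.0)

    def test_wrong_group_stream_rejected(self, codebook):
        with pytest.raises(ValueError, match="group"):
            build_network(
                [make_stream([1], [11], group="preterm")], codebook, GROUP_A
            )


class TestConnectivityProfile:
    def test_chain_degrees_enumerated_by_hand(self):
        net = toy_network([("A", "B", 1), ("B", "C", 1)])
        profile = connectivity_profile(net)
        # A: no in -> c5; B: one in one out -> c1; C: no out -> c5
        assert (profile.c1, profile.c5) == (1, 2)
        assert profile.isolated_count == 0
        assert profile.n_nodes == 3

    def test_multiple_in_single_out_is_category_two(self):
        net = toy_network([("X", "A", 1), ("Y", "A", 1), ("A", "X", 1), ("X", "Y", 1)])
        profile = connectivity_profile(net)
        g = net.graph
        assert g.in_degree("A") == 2 and g.out_degree("A") == 1
        assert profile.c2 >= 1

    def test_categories_partition_nodes_on_random_networks(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.25, directed=True,
                                    seed=int(rng.integers(2**31)))
            net = toy_network([(u, v, 1) for u, v in g.edges] or [("A", "B", 1)])
            profile = connectivity_profile(net)
            assert profile.n_nodes == net.n_nodes
            assert profile.isolated_count <= profile.c5

    def test_reciprocal_pair_counts_single_in_and_out(self):
        net = toy_network([("A", "B", 3), ("B", "A", 7)])
        assert connectivity_profile(net).c1 == 2


class TestCompareConnectivity:
    def test_identical_profiles_give_zero_statistic(self):
        p = ConnectivityProfile(2, 3, 4, 5, 6, 1)
        result = compare_connectivity(p, p, focal=4)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_matches_textbook_expected_count_formula(self):
        # focal 18 of 20 vs 8 of 20
        result = compare_connectivity(
            ConnectivityProfile(0, 0, 0, 18, 2, 0),
            ConnectivityProfile(4, 4, 2, 8, 2, 0),
            focal=4,
        )
        table = [[18, 2], [8, 12]]
        n = 40
        expected = [[26 * 20 / n, 14 * 20 / n]] * 2
        stat = sum(
            (table[i][j] - expected[i][j]) ** 2 / expected[i][j]
            for i in range(2)
            for j in range(2)
        )
        assert result.statistic == pytest.approx(stat)
        assert result.df == 1

    def test_isolated_subcount_usable_as_focal(self):
        a = ConnectivityProfile(1, 1, 1, 10, 7, 6)
        b = ConnectivityProfile(1, 1, 1, 15, 2, 1)
        result = compare_connectivity(a, b, focal="isolated")
        assert result.table[0][0] == 6 and result.table[1][0] == 1


class TestExports:
    def test_graphml_sif_and_tables_roundtrip(self, tmp_path, codebook):
        streams = generate_streams(harmonious_config(n_full_term=3, n_preterm=1, seed=2))
        net = build_network([s for s in streams if s.group == GROUP_A], codebook, GROUP_A)
        paths = export_network(net, tmp_path / "net")
        assert all(p.exists() for p in paths)
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_edges() == net.n_edges
        sif_lines = (tmp_path / "net.sif").read_text().splitlines()
        assert len(sif_lines) == net.n_edges
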