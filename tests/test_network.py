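import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import strclock as sc
from strclock.io import Haplotype, LocusPanel
from strclock.network import (MJParams, build_mj_network, distance_matrix,
                              extract_parsimony_tree, infer_founder,
                              state_key, str_distance, tree_centroid)

from conftest import make_set


@pytest.fixture
def panel2():
    return LocusPanel(("A", "B"), 0.0039)


def mst_length(states, weight=1.0):
    """Oracle: minimum spanning tree length of a state set (complete graph)."""
    X = np.asarray(states, dtype=float)
    D = distance_matrix(X, np.full(X.shape[1], weight))
    g = nx.Graph()
    for i, j in itertools.combinations(range(len(states)), 2):
        g.add_edge(i, j, weight=D[i, j])
    return sum(d["weight"] for _, _, d in
               nx.minimum_spanning_edges(g, data=True))


class TestStrDistance:
    def test_identity(self, panel2):
        a = Haplotype("a", {"A": 13, "B": 29})
        assert str_distance(a, a, MJParams(), LocusPanel(("A", "B"), 0.01)) == 0

    def test_hand_arithmetic(self, panel2):
        a = Haplotype("a", {"A": 13, "B": 29})
        b = Haplotype("b", {"A": 14, "B": 31})
        assert str_distance(a, b, MJParams(weight=10), panel2) == 30  # 10*1 + 10*2

    def test_multicopy_minimum_assignment(self):
        panel = LocusPanel(("M",), 0.0039, multicopy=frozenset({"M"}))
        a = Haplotype("a", {"M": (11, 14)})
        b = Haplotype("b", {"M": (12, 14)})
        got = str_distance(a, b, MJParams(weight=10), panel)
        # exhaustive over both assignments of {11,14} onto {12,14}
        best = min(10 * (abs(11 - 12) + abs(14 - 14)),
                   10 * (abs(11 - 14) + abs(14 - 12)))
        assert got == best == 10

    def test_missing_loci_skipped(self, panel2):
        a = Haplotype("a", {"A": 13})
        b = Haplotype("b", {"A": 15, "B": 20})
        assert str_distance(a, b, MJParams(weight=1), panel2) == 2

    def test_no_shared_loci_raises(self, panel2):
        a = Haplotype("a", {"A": 13})
        b = Haplotype("b", {"B": 20})
        with pytest.raises(ValueError, match="shared"):
            str_distance(a, b, MJParams(), panel2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(8, 20), st.integers(8, 20),
                              st.integers(8, 20)), min_size=3, max_size=3))
    def test_metric_axioms(self, states):
        """Symmetry, identity of indiscernibles and the triangle inequality
        on single-copy loci."""
        panel = LocusPanel(("A", "B", "C"), 0.0039)
        a, b, c = (Haplotype(f"h{i}", dict(zip("ABC", s)))
                   for i, s in enumerate(states))
        p = MJParams(weight=10)
        dab = str_distance(a, b, p, panel)
        assert dab == str_distance(b, a, p, panel)
        assert (dab == 0) == (states[0] == states[1])
        assert dab <= str_distance(a, c, p, panel) + str_distance(c, b, p, panel)


class TestBuildNetwork:
    def test_two_states_one_edge(self, panel2, make_hs):
        hs = make_set(panel2, [(10, 10), (10, 11)])
        net = build_mj_network(hs)
        assert len(net.nodes) == 2 and net.graph.number_of_edges() == 1
        assert not net.median_nodes

    def test_median_insertion_beats_mst(self, panel3):
        """Three states on a unit cube: the consensus state is inserted and
        shortens the network below the observed-state MST, matching the
        brute-force Steiner optimum over the whole lattice."""
        states = [(10, 10, 10), (11, 11, 10), (11, 10, 11)]
        hs = make_set(panel3, states)
        net = build_mj_network(hs, MJParams(weight=1))
        assert state_key(np.array([11.0, 10, 10])) in net.graph
        assert net.total_length == 3 < mst_length(states) == 4
        # brute-force Steiner search over every lattice point in the bounding box
        best = mst_length(states)
        for extra in itertools.product((10, 11), repeat=3):
            best = min(best, mst_length(states + [extra]))
        assert net.total_length == best

    def test_every_observed_state_is_a_node(self, panel3):
        rng = np.random.default_rng(11)
        states = [tuple(rng.integers(10, 15, 3)) for _ in range(12)]
        hs = make_set(panel3, states)
        net = build_mj_network(hs, MJParams(weight=1))
        for s in states:
            assert state_key(np.array(s, dtype=float)) in net.graph
            assert net.graph.nodes[state_key(np.array(s, dtype=float))]["observed"]

    def test_multiplicity_and_population_tally(self, panel2):
        hs = make_set(panel2, [(10, 10), (10, 10), (12, 10)],
                      populations=["Erzya", "Moksha", "Erzya"])
        net = build_mj_network(hs)
        node = net.graph.nodes[(10, 10)]
        assert node["multiplicity"] == 2
        assert node["populations"] == {"Erzya": 1, "Moksha": 1}

    def test_single_state_raises(self, panel2):
        hs = make_set(panel2, [(10, 10), (10, 10)])
        with pytest.raises(ValueError, match="2 distinct"):
            build_mj_network(hs)

    @pytest.mark.parametrize("seed", range(10))
    def test_network_never_longer_than_mst(self, panel3, seed):
        rng = np.random.default_rng(seed)
        states = list({tuple(rng.integers(10, 14, 3)) for _ in range(8)})
        if len(states) < 2:
            pytest.skip("degenerate draw")
        net = build_mj_network(make_set(panel3, states), MJParams(weight=1))
        assert net.total_length <= mst_length(states) + 1e-9

    def test_epsilon_zero_distinct_distances_gives_mst(self, panel3):
        """With epsilon=0 and all pairwise distances distinct the relaxed
        spanning network is exactly the unique MST (checked against the
        networkx MST oracle); medians may only subdivide it."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            states = list({tuple(rng.integers(0, 30, 3)) for _ in range(6)})
            X = np.array(states, dtype=float)
            D = distance_matrix(X, np.ones(3))
            vals = D[np.triu_indices(len(states), 1)]
            if len(set(vals)) != len(vals):
                continue
            hs = make_set(panel3, states)
            net = build_mj_network(hs, MJParams(weight=1))
            if net.median_nodes:
                continue  # medians legitimately replace MST edges
            got = {frozenset((u, v)) for u, v, _ in net.mst_edges()}
            g = nx.Graph()
            for i, j in itertools.combinations(range(len(states)), 2):
                g.add_edge(states[i], states[j], weight=D[i, j])
            want = {frozenset((u, v)) for u, v in
                    nx.minimum_spanning_edges(g, data=False)}
            assert got == want

    def test_input_permutation_invariance(self, panel3):
        rng = np.random.default_rng(3)
        states = [tuple(rng.integers(10, 14, 3)) for _ in range(10)]
        net1 = build_mj_network(make_set(panel3, states), MJParams(weight=1))
        perm = states[::-1]
        net2 = build_mj_network(make_set(panel3, perm), MJParams(weight=1))
        assert set(net1.graph.nodes) == set(net2.graph.nodes)
        assert {frozenset(e) for e in net1.graph.edges} == \
               {frozenset(e) for e in net2.graph.edges}


class TestParsimonyTree:
    def test_tree_network_returned_unchanged(self, panel2):
        hs = make_set(panel2, [(10, 10), (10, 11), (10, 12)])
        net = build_mj_network(hs)
        tree = extract_parsimony_tree(net, (10, 10))
        assert set(map(frozenset, tree.tree.edges)) == \
               set(map(frozenset, net.graph.edges))

    def test_four_cycle_resolution_deterministic(self, panel2):
        states = [(10, 10), (10, 11), (11, 11), (11, 10)]
        hs = make_set(panel2, states)
        net = build_mj_network(hs, MJParams(weight=1))
        trees = [extract_parsimony_tree(net, (10, 10)) for _ in range(3)]
        edge_sets = [set(map(frozenset, t.tree.edges)) for t in trees]
        assert edge_sets[0] == edge_sets[1] == edge_sets[2]
        assert trees[0].total_length == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_spanning_tree_enumeration(self, panel3, seed):
        """On small reticulated networks the resolution attains the minimum
        total length over every spanning tree of the network."""
        rng = np.random.default_rng(seed)
        states = list({tuple(rng.integers(10, 13, 3)) for _ in range(6)})
        if len(states) < 3:
            pytest.skip("degenerate draw")
        net = build_mj_network(make_set(panel3, states), MJParams(weight=1))
        if net.graph.number_of_nodes() > 8:
            pytest.skip("oracle limited to tiny networks")
        root = net.nodes[0]
        tree = extract_parsimony_tree(net, root)
        best = min(sum(net.graph.edges[e]["length"] for e in t.edges)
                   for t in nx.SpanningTreeIterator(net.graph, weight="length"))
        assert tree.total_length == pytest.approx(best)

    def test_root_not_in_network_raises(self, panel2):
        net = build_mj_network(make_set(panel2, [(10, 10), (10, 11)]))
        with pytest.raises(ValueError, match="root"):
            extract_parsimony_tree(net, (99, 99))

    def test_path_mutations_and_tips_below(self, panel2):
        hs = make_set(panel2, [(10, 10), (10, 11), (10, 13)])
        net = build_mj_network(hs, MJParams(weight=1))
        tree = extract_parsimony_tree(net, (10, 10))
        assert tree.path_mutations((10, 13)) == 3
        below = tree.tips_below()
        assert below[tree.root] == 3  # all samples


class TestInferFounder:
    def test_star_center_observed(self, panel2):
        states = [(12, 12), (13, 12), (11, 12), (12, 13), (12, 11)]
        net = build_mj_network(make_set(panel2, states))
        assert infer_founder(net) == (12, 12)

    def test_star_center_median(self, panel3):
        # satellites around an unobserved center (14,14,14)
        states = [(15, 14, 14), (13, 14, 14), (14, 15, 14),
                  (14, 13, 14), (14, 14, 15), (14, 14, 13)]
        net = build_mj_network(make_set(panel3, states), MJParams(weight=1))
        assert infer_founder(net) == (14, 14, 14)
        assert not net.graph.nodes[(14, 14, 14)]["observed"]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_minimizer(self, panel3, seed):
        rng = np.random.default_rng(seed)
        states = [tuple(rng.integers(10, 15, 3)) for _ in range(10)]
        net = build_mj_network(make_set(panel3, states), MJParams(weight=1))
        got = infer_founder(net)
        w = np.ones(3)
        obs = [(net.state(k), net.graph.nodes[k]["multiplicity"])
               for k in net.observed_nodes]
        def score(k):
            return sum(m * np.abs(net.state(k) - v).sum() for v, m in obs)
        best = min(score(k) for k in net.nodes)
        assert score(got) == best

    def test_ancient_anchor_preferred_within_one_step(self, panel2):
        states = [(12, 12), (13, 12), (11, 12)]
        hs = make_set(panel2, states, ancient=[False, True, False])
        net = build_mj_network(hs)
        anchors = [k for k in net.nodes if net.graph.nodes[k].get("ancient")]
        assert infer_founder(net, anchors=anchors) == (13, 12)

    def test_empty_cluster_raises(self, panel2):
        net = build_mj_network(make_set(panel2, [(10, 10), (10, 11)]))
        with pytest.raises(ValueError, match="empty"):
            infer_founder(net, cluster_nodes=[])


def test_tree_centroid_balances_components(panel3):
    # chain of three radiations: centroid must be the middle state
    states = [(10, 10, 10)] * 3 + [(14, 10, 10)] * 3 + [(18, 10, 10)] * 3
    hs = make_set(panel3, [tuple(np.add(s, (0, i % 3, 0))) for i, s in enumerate(states)])
    net = build_mj_network(hs, MJParams(weight=1))
    tree = extract_parsimony_tree(net, infer_founder(net))
    cen = tree_centroid(tree)
    assert cen[0] == 14
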