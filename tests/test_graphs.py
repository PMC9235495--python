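"""Mixed-graph structure, mutilation, d-separation, projection, districts."""

import itertools

import numpy as np
import pytest

from causalpath.graphs import GraphError, MixedGraph, parse_graph
from helpers import d_separated_by_paths, random_latent_dag, random_mixed_graph

MEDIATED = parse_graph("latent U\nU -> X\nU -> Y\nX -> Z\nZ -> Y\n")


class TestConstruction:
    def test_rejects_cycles(self):
        with pytest.raises(GraphError, match="cyclic"):
            MixedGraph(directed={("A", "B"), ("B", "C"), ("C", "A")})

    def test_rejects_self_loops(self):
        with pytest.raises(GraphError):
            MixedGraph(directed={("A", "A")})

    def test_rejects_mixed_latent_and_bidirected(self):
        with pytest.raises(GraphError, match="explicit-latent DAG or an ADMG"):
            MixedGraph(nodes={"A", "B", "C"}, bidirected={frozenset(("A", "B"))}, latent={"C"})

    def test_rejects_bidirected_on_latent(self):
        with pytest.raises(GraphError):
            MixedGraph(nodes={"A", "B"}, bidirected={frozenset(("A", "B"))}, latent={"A"})

    def test_parser_roundtrip(self):
        g = parse_graph(MEDIATED.to_text())
        assert g == MEDIATED

    def test_dot_marks_bidirected_dashed(self):
        g = MixedGraph(directed={("X", "Z")}, bidirected={frozenset(("X", "Y"))})
        dot = g.to_dot()
        assert "style=dashed" in dot and '"X" -> "Z";' in dot


class TestMutilation:
    def test_incoming_severs_directed_and_bidirected(self):
        # intervening on X removes U->X but leaves the rest of the system
        g = MEDIATED.mutilate_incoming({"X"})
        assert ("U", "X") not in g.directed
        assert g.directed == frozenset({("U", "Y"), ("X", "Z"), ("Z", "Y")})

    def test_incoming_on_admg_cuts_latent_confounding(self):
        admg = MEDIATED.latent_project()
        g = admg.mutilate_incoming({"X"})
        assert not g.bidirected

    def test_outgoing(self):
        g = MEDIATED.mutilate_outgoing({"Z"})
        assert g.directed == frozenset({("U", "X"), ("U", "Y"), ("X", "Z")})

    def test_outgoing_leaves_are_noops_and_chain_empties(self):
        chain = MixedGraph(directed={("A", "B"), ("B", "C")})
        assert chain.mutilate_outgoing({"C"}) == chain
        assert not chain.mutilate_outgoing({"A", "B"}).directed

    def test_root_targets_are_noop_and_all_targets_empty(self):
        roots = MEDIATED.mutilate_incoming({"U"})
        assert roots == MEDIATED
        empty = MEDIATED.mutilate_incoming(MEDIATED.nodes)
        assert not empty.directed and not empty.bidirected

    def test_unknown_node_is_named_in_error(self):
        with pytest.raises(GraphError, match="bogus"):
            MEDIATED.mutilate_incoming({"bogus"})

    def test_idempotent_and_commuting(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = random_mixed_graph(rng, 6)
            nodes = sorted(g.nodes)
            t = set(rng.choice(nodes, size=2, replace=False))
            s = set(rng.choice(sorted(set(nodes) - t), size=2, replace=False))
            gi = g.mutilate_incoming(t)
            assert gi.mutilate_incoming(t) == gi
            go = g.mutilate_outgoing(s)
            assert go.mutilate_outgoing(s) == go
            assert gi.mutilate_outgoing(s) == go.mutilate_incoming(t)


class TestDSeparation:
    def test_overlapping_sets_error(self):
        with pytest.raises(GraphError, match="disjoint"):
            MEDIATED.d_separated({"X"}, {"X"}, ())

    def test_disconnected_nodes_always_separated(self):
        g = MixedGraph(nodes={"A", "B", "C"})
        assert g.d_separated({"A"}, {"B"}, ())
        assert g.d_separated({"A"}, {"B"}, {"C"})

    def test_collider_conditioning_opens_path(self):
        g = MixedGraph(directed={("A", "C"), ("B", "C"), ("C", "D")})
        assert g.d_separated({"A"}, {"B"}, ())
        assert not g.d_separated({"A"}, {"B"}, {"C"})
        # a descendant of the collider also opens it
        assert not g.d_separated({"A"}, {"B"}, {"D"})

    def test_napkin_backdoor_cannot_be_blocked(self):
        # hns is a collider and gadE its descendant: no observed set blocks the
        # back-door between lrp and topA
        g = MixedGraph(
            directed={("hns", "gadE"), ("gadE", "lrp"), ("lrp", "topA")},
            bidirected={frozenset(("hns", "lrp")), frozenset(("hns", "topA"))},
        )
        backdoor = g.mutilate_outgoing({"lrp"})
        others = g.nodes - {"lrp", "topA"}
        for r in range(len(others) + 1):
            for z in itertools.combinations(sorted(others), r):
                assert not backdoor.d_separated({"lrp"}, {"topA"}, z)

    def test_exhaustive_three_node_agreement_with_path_oracle(self):
        nodes = ["a", "b", "c"]
        pairs = list(itertools.permutations(nodes, 2))
        upairs = [frozenset(p) for p in itertools.combinations(nodes, 2)]
        count = 0
        for dirs in itertools.chain.from_iterable(
            itertools.combinations(pairs, r) for r in range(4)
        ):
            for bis in itertools.chain.from_iterable(
                itertools.combinations(upairs, r) for r in range(4)
            ):
                try:
                    g = MixedGraph(nodes, dirs, bis)
                except GraphError:
                    continue  # cyclic directed part
                for za, zb, zg in itertools.permutations(nodes):
                    got = g.d_separated({za}, {zb}, {zg})
                    want = d_separated_by_paths(g, {za}, {zb}, {zg})
                    assert got == want, (dirs, bis, za, zb, zg)
                    got0 = g.d_separated({za}, {zb}, ())
                    want0 = d_separated_by_paths(g, {za}, {zb}, ())
                    assert got0 == want0
                    count += 1
        assert count > 1000

    def test_random_graph_agreement_with_path_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(150):
            g = random_mixed_graph(rng, 6)
            nodes = sorted(g.nodes)
            perm = list(rng.permutation(nodes))
            a, b = {perm[0]}, {perm[1]}
            z = set(perm[2 : 2 + int(rng.integers(0, 3))])
            assert g.d_separated(a, b, z) == d_separated_by_paths(g, a, b, z)


class TestLatentProjection:
    def test_fig1_pipeline(self):
        from causalpath.casestudies import build_projection_demo

        g = build_projection_demo()
        simplified = g.simplify_latents()
        assert len(simplified.latent) == 1
        (u,) = simplified.latent
        assert simplified.children(u) == frozenset({"X1", "X2"})
        admg = g.latent_project()
        assert admg.bidirected == frozenset({frozenset(("X1", "X2"))})
        assert admg.directed == frozenset({("X1", "X3"), ("X2", "X4"), ("X3", "X4")})

    def test_no_latents_is_identity(self):
        g = MixedGraph(directed={("A", "B"), ("B", "C")})
        assert g.latent_project() == g

    def test_latent_chain_collapses_to_single_bidirected(self):
        g = parse_graph("latent l1\nlatent l2\nl1 -> l2\nl2 -> A\nl2 -> B\n")
        admg = g.latent_project()
        assert admg.bidirected == frozenset({frozenset(("A", "B"))})
        assert not admg.latent

    def test_projection_is_idempotent_and_latent_free(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            g = random_latent_dag(rng, 4, 3)
            admg = g.latent_project()
            assert not admg.latent
            assert admg.latent_project() == admg

    def test_rule_order_invariance_of_fixed_point(self):
        # the fixed point must not depend on which latent label gets visited
        # first: relabeling latents must give the same projection
        rng = np.random.default_rng(9)
        for _ in range(25):
            g = random_latent_dag(rng, 4, 3)
            relabel = {u: f"zz{u}" for u in g.latent}
            g2 = MixedGraph(
                [relabel.get(n, n) for n in g.nodes],
                {(relabel.get(a, a), relabel.get(b, b)) for a, b in g.directed},
                (),
                {relabel[u] for u in g.latent},
            )
            assert g.latent_project() == g2.latent_project()

    def test_admg_input_rejected(self):
        g = MixedGraph(nodes={"A", "B"}, bidirected={frozenset(("A", "B"))})
        with pytest.raises(GraphError):
            g.simplify_latents()


class TestOrderingAndDistricts:
    def test_topological_order_respects_edges(self):
        order = MEDIATED.topological_sort()
        assert order.index("U") < order.index("X") < order.index("Z") < order.index("Y")

    def test_edgeless_graph_sorted_lexicographically(self):
        g = MixedGraph(nodes={"b", "a", "c"})
        assert g.topological_sort() == ["a", "b", "c"]

    def test_random_dags_all_edges_forward(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            g = random_mixed_graph(rng, 8, p_bi=0.0)
            order = g.topological_sort()
            pos = {n: i for i, n in enumerate(order)}
            assert all(pos[a] < pos[b] for a, b in g.directed)

    def test_mutilated_targets_are_parentless_in_order(self):
        g = MEDIATED.latent_project().mutilate_incoming({"X"})
        assert not g.parents("X")

    def test_districts_match_bidirected_components(self):
        admg = MixedGraph(directed={("X", "Y")}, bidirected={frozenset(("X", "Y"))})
        assert admg.districts({"X", "Y"}) == [frozenset({"X", "Y"})]
        no_bi = MixedGraph(directed={("A", "B"), ("B", "C")})
        assert no_bi.districts() == [frozenset({"A"}), frozenset({"B"}), frozenset({"C"})]

    def test_districts_against_connected_components(self):
        import networkx as nx

        rng = np.random.default_rng(21)
        for _ in range(50):
            g = random_mixed_graph(rng, 8)
            got = g.districts()
            gb = nx.Graph()
            gb.add_nodes_from(g.observed)
            gb.add_edges_from(tuple(e) for e in g.bidirected)
            want = sorted((frozenset(c) for c in nx.connected_components(gb)),
                          key=lambda c: sorted(c))
            assert got == want
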