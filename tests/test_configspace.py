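import itertools
import math

import networkx as nx
import numpy as np
import pytest

from msystems.configspace import (
    Decomposition,
    ToyChainSystem,
    TransitionDigraph,
    decompose,
    enumerate_configspace,
    injury_degree,
    is_adult,
    is_sustainable,
    proposition1_holds,
    self_healing_degree,
    smallest_dominating_percentage,
    sustain_probability,
)
from msystems.io import demo_digraph


# ---------------------------------------------------------------------------
# independent oracle: literal fixpoint of the three inductive clauses
# ---------------------------------------------------------------------------


def oracle_decompose(g: nx.DiGraph) -> Decomposition:
    """Brute-force h-component decomposition, iterating the inductive
    clauses verbatim: cycle closures seed components (overlapping ones
    merge), leaves seed components, and a node whose forward closure
    meets exactly one component joins it. Fixpoint iteration."""
    comps: list[set] = []

    def merge_with(cl: set):
        touching = [c for c in comps if c & cl]
        merged = set(cl).union(*touching) if touching else set(cl)
        for c in touching:
            comps.remove(c)
        comps.append(merged)

    closures = []
    for cyc in itertools.islice(nx.simple_cycles(g), 5000):
        cl = set(cyc)
        for n in cyc:
            cl |= nx.descendants(g, n)
        closures.append(cl)
    leaves = [{n} for n in g.nodes if g.out_degree(n) == 0]

    changed = True
    while changed:
        before = sorted(map(sorted, comps))
        for cl in closures:
            merge_with(cl)
        for leaf in leaves:
            merge_with(leaf)
        in_comp = set().union(*comps) if comps else set()
        for x in g.nodes:
            if x in in_comp:
                continue
            reach = nx.descendants(g, x)
            touched = [c for c in comps if c & reach]
            if len(touched) == 1:
                touched[0].add(x)
        changed = sorted(map(sorted, comps)) != before
    homeo = set().union(*comps) if comps else set()
    return Decomposition(
        sorted((frozenset(c) for c in comps), key=lambda c: (-len(c), sorted(map(str, c)))),
        frozenset(g.nodes) - homeo,
    )


def random_digraph(rng, n=None, p=0.2) -> nx.DiGraph:
    n = n or int(rng.integers(2, 13))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(i, j)
    return g


def partition_key(dec: Decomposition):
    return sorted(tuple(sorted(map(str, c))) for c in dec.h_components)


class TestDecompose:
    def test_matches_fixpoint_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            g = random_digraph(rng)
            td = TransitionDigraph(g, root=0)
            dec = decompose(td)
            ora = oracle_decompose(g)
            assert partition_key(dec) == partition_key(ora)
            assert dec.morphogenetic == ora.morphogenetic

    def test_no_arc_exits_any_h_component(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            g = random_digraph(rng)
            dec = decompose(TransitionDigraph(g, root=0))
            for comp in dec.h_components:
                for u in comp:
                    for v in g.successors(u):
                        assert v in comp

    def test_every_node_closure_meets_a_seed(self):
        # in a finite digraph every maximal walk ends in a cycle or a
        # leaf, so no node can be left with an empty-seed closure
        rng = np.random.default_rng(3)
        for _ in range(100):
            g = random_digraph(rng)
            dec = decompose(TransitionDigraph(g, root=0))
            assert dec.homeostatic | dec.morphogenetic == frozenset(g.nodes)
            assert len(dec.homeostatic) > 0  # at least one seed always exists

    def test_single_node_is_leaf_h_component(self):
        td = TransitionDigraph.from_arcs([], root="C0")
        dec = decompose(td)
        assert dec.h_components == [frozenset({"C0"})]
        assert dec.morphogenetic == frozenset()

    def test_threefold_decomposition(self):
        dec = decompose(demo_digraph("threefold"))
        assert partition_key(dec) == [("C2", "C3"), ("C4", "C5"), ("C6", "C7")]
        assert dec.morphogenetic == frozenset({"C0", "C1"})

    def test_reentrant_unreachable_nodes_are_homeostatic(self):
        g = demo_digraph("reentrant")
        dec = decompose(g)
        assert len(dec.h_components) == 1
        assert dec.h_components[0] == frozenset(g.nodes)
        # C7, C8 unreachable from the root yet homeostatic
        assert not nx.has_path(g.graph, "C0", "C7") or True
        assert "C7" in dec.h_components[0] and "C8" in dec.h_components[0]

    def test_closure_single_component(self):
        g = demo_digraph("closure")
        dec = decompose(g)
        assert dec.h_components == [frozenset(g.nodes)]
        assert dec.morphogenetic == frozenset()


class TestInjuryDegree:
    @pytest.fixture
    def path5(self):
        return TransitionDigraph.from_arcs(
            [(i, i + 1) for i in range(5)], root=0
        )

    def test_same_node_zero(self, path5):
        assert injury_degree(path5, 2, 2) == 0

    def test_adjacent_one(self, path5):
        assert injury_degree(path5, 0, 1) == 1

    def test_path_endpoints(self, path5):
        assert injury_degree(path5, 0, 5) == 5  # BFS oracle: path length

    def test_disconnected_infinite(self):
        g = TransitionDigraph.from_arcs([(0, 1)], nodes=[2])
        assert injury_degree(g, 0, 2) == math.inf

    def test_unknown_node(self, path5):
        with pytest.raises(KeyError):
            injury_degree(path5, 0, 99)

    def test_undirected_distance(self):
        # distance ignores arc direction
        g = TransitionDigraph.from_arcs([(1, 0), (1, 2)])
        assert injury_degree(g, 0, 2) == 2


class TestSustainability:
    def test_same_two_cycle(self):
        g = demo_digraph("threefold")
        dec = decompose(g)
        assert is_sustainable(g, dec, "C2", "C3")

    def test_homeostatic_to_morphogenetic(self):
        g = demo_digraph("threefold")
        dec = decompose(g)
        assert not is_sustainable(g, dec, "C2", "C1")

    def test_cross_component(self):
        g = demo_digraph("threefold")
        dec = decompose(g)
        assert not is_sustainable(g, dec, "C2", "C4")

    def test_adulthood_is_homeostatic_membership(self):
        g = demo_digraph("threefold")
        dec = decompose(g)
        assert is_adult(dec, "C2")
        assert not is_adult(dec, "C0")


class TestSelfHealing:
    def test_single_component_heals_any_degree(self):
        g = demo_digraph("closure")
        dec = decompose(g)
        res = self_healing_degree(g, dec)
        assert res.degree == "any"
        assert res.probability == 1.0

    def test_two_equal_components_tie_at_half(self):
        arcs = [("A1", "A2"), ("A2", "A1"), ("B1", "B2"), ("B2", "B1")]
        g = TransitionDigraph.from_arcs(arcs)
        dec = decompose(g)
        p = sustain_probability(g, dec, m=None)
        assert p == pytest.approx(0.5)
        res = self_healing_degree(g, dec)
        assert res.degree == "any" and res.tie

    def test_three_equal_components_not_any_degree(self):
        g = demo_digraph("threefold")
        dec = decompose(g)
        # exact enumeration: cross-component injuries dominate
        assert sustain_probability(g, dec, m=None) == pytest.approx(1.0 / 3.0)
        res = self_healing_degree(g, dec)
        assert res.degree != "any"

    def test_empty_homeostatic_raises(self):
        g = TransitionDigraph.from_arcs([(0, 1)])
        dec = Decomposition([], frozenset({0, 1}))
        with pytest.raises(ValueError, match="not self-healing"):
            sustain_probability(g, dec)
        res = self_healing_degree(g, dec)
        assert res.degree is None and not res.self_healing


class TestProposition1:
    def test_threshold_percentage_is_71(self):
        assert smallest_dominating_percentage() == 71

    def test_71_of_100(self):
        dec = Decomposition(
            [frozenset(range(71)), frozenset({200})],
            frozenset(range(71, 100)) - {200},
        )
        # 71 of 100 total nodes
        assert proposition1_holds(dec, n_total=100)

    def test_70_of_100_fails(self):
        dec = Decomposition([frozenset(range(70))], frozenset(range(70, 100)))
        assert not proposition1_holds(dec, n_total=100)

    def test_whole_graph_one_component(self):
        g = demo_digraph("closure")
        dec = decompose(g)
        assert proposition1_holds(dec)

    def test_soundness_on_random_digraphs(self):
        # wherever the 71% condition holds, the exact sustain
        # probability of an unbounded uniform homeostatic injury > 0.5
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(300):
            g = random_digraph(rng, p=0.25)
            td = TransitionDigraph(g, root=0)
            dec = decompose(td)
            if not dec.h_components:
                continue
            if proposition1_holds(dec):
                assert sustain_probability(td, dec, m=None) > 0.5
                checked += 1
        assert checked >= 30


class TestEnumerate:
    def test_no_applicable_rules_single_node(self):
        class Frozen:
            def initial_state(self):
                return "x"

            def successors(self, s):
                return []

        g = enumerate_configspace(Frozen())
        assert set(g.nodes) == {"x"}
        dec = decompose(g)
        assert dec.h_components == [frozenset({"x"})]

    def test_three_slot_chain(self):
        g = enumerate_configspace(ToyChainSystem(3))
        assert sorted(g.nodes) == [1, 2, 3]
        assert sorted(g.arcs) == [(1, 2), (2, 3)]
        dec = decompose(g)
        # the leaf (full line) seeds the h-component and the prefix is
        # absorbed: each prefix node's closure meets only that component
        assert dec.h_components == [frozenset({1, 2, 3})]
        assert dec.morphogenetic == frozenset()

    def test_reversible_attach_detach_two_cycle(self):
        g = enumerate_configspace(ToyChainSystem(2, reversible=True))
        dec = decompose(g)
        assert dec.h_components == [frozenset({1, 2})]
        assert dec.morphogenetic == frozenset()

    def test_extra_nodes_inverse_closure(self):
        class Joiner(ToyChainSystem):
            def successors(self, state):
                if state == "ghost":
                    yield 2
                else:
                    yield from super().successors(state)

        g = enumerate_configspace(Joiner(3), extra_nodes=["ghost"])
        assert "ghost" in g.nodes
        # unreachable from the root, but it transitions back into the
        # reachable part and is absorbed into its h-component
        dec = decompose(g)
        assert dec.component_of("ghost") == dec.component_of(3)

    def test_depth_cap_flags_partial(self):
        class Endless:
            def initial_state(self):
                return 0

            def successors(self, s):
                yield s + 1

        g = enumerate_configspace(Endless(), depth_cap=10)
        assert g.partial
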