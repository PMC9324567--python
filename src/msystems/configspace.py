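"""Configuration-space analysis: homeostatic components and self-healing.

The configuration space of a morphogenetic system is a digraph M* whose
nodes are all distinct configurations (equivalent configurations merged
into one node) and whose arcs are single-rule transitions; it includes
configurations unreachable from the root that still transition back into
the reachable part.

A *homeostatic component* (h-component) is an inescapable region of M*,
defined inductively:

1. the transitive closure of every directed cycle belongs to an
   h-component;
2. every leaf node (no successors) belongs to an h-component;
3. every node whose transitive closure intersects exactly one
   h-component belongs to that h-component;

with overlapping seed closures merged into a single component. Nodes in
no h-component form the *morphogenetic phase*. The union of the
h-components is the homeostatic phase; an *adult* individual is one whose
current configuration lies in it.

An *injury* is an unprescribed transition (x, y); its *degree* is the
undirected distance between x and y in M*; it is *sustainable* iff x and
y lie in the same h-component. A system is *self-healing of degree m* if
a random injury of degree at most m to a random homeostatic node is
sustainable with probability at least 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TransitionDigraph",
    "Decomposition",
    "decompose",
    "injury_degree",
    "is_sustainable",
    "sustain_probability",
    "SelfHealingResult",
    "self_healing_degree",
    "proposition1_holds",
    "smallest_dominating_percentage",
    "is_adult",
    "enumerate_configspace",
    "ToyChainSystem",
]

#: Exact enumeration is used up to this many nodes; Monte Carlo beyond.
EXACT_ENUMERATION_LIMIT = 1000


@dataclass
class TransitionDigraph:
    """A configuration space: nodes, arcs (x, y), and a root node C_0.

    May contain nodes unreachable from the root.
    """

    graph: nx.DiGraph
    root: Hashable | None = None
    partial: bool = False  # True when enumeration hit a depth cap

    @staticmethod
    def from_arcs(
        arcs: Iterable[tuple[Hashable, Hashable]],
        root: Hashable | None = None,
        nodes: Iterable[Hashable] = (),
    ) -> "TransitionDigraph":
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(arcs)
        if root is not None:
            g.add_node(root)
        for u, v in g.edges:
            if u not in g or v not in g:  # pragma: no cover - nx guarantees this
                raise ValueError("arc references undeclared node")
        return TransitionDigraph(g, root)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def arcs(self):
        return self.graph.edges

    def __contains__(self, node) -> bool:
        return node in self.graph


@dataclass
class Decomposition:
    """Partition of a configuration space into h-components and the
    morphogenetic phase."""

    h_components: list[frozenset]
    morphogenetic: frozenset

    @property
    def homeostatic(self) -> frozenset:
        """The homeostatic phase: union of all h-components."""
        return frozenset().union(*self.h_components) if self.h_components else frozenset()

    def component_of(self, node) -> int | None:
        for i, comp in enumerate(self.h_components):
            if node in comp:
                return i
        return None

    def dominating_fraction(self, n_total: int | None = None) -> float:
        """Size of the largest h-component over the total node count."""
        if not self.h_components:
            return 0.0
        if n_total is None:
            n_total = sum(len(c) for c in self.h_components) + len(self.morphogenetic)
        return max(len(c) for c in self.h_components) / n_total


def decompose(g: TransitionDigraph) -> Decomposition:
    """Compute the h-component / morphogenetic-phase partition.

    Closed form of the inductive fixpoint: seeds are the forward closures
    of non-trivial strongly connected components (every directed cycle
    lies in one, and their closures coincide) plus singleton leaves;
    overlapping seeds are merged; a remaining node joins a merged seed
    group iff that group is the only one its forward closure meets.
    In a finite digraph every maximal walk ends in a cycle or a leaf, so
    every node's closure meets at least one seed and the remaining nodes
    (those meeting two or more groups) form the morphogenetic phase.
    """
    dg = g.graph
    if dg.number_of_nodes() == 0:
        return Decomposition([], frozenset())

    cond = nx.condensation(dg)  # DAG of SCCs; node attr "members"
    members = cond.nodes(data="members")
    is_seed_scc = {}
    for s, mem in members:
        nontrivial = len(mem) > 1 or any(dg.has_edge(v, v) for v in mem)
        leaf = cond.out_degree(s) == 0 and all(dg.out_degree(v) == 0 for v in mem)
        is_seed_scc[s] = nontrivial or leaf

    # Group label per seed SCC, merged through closure overlap: a seed's
    # closure contains every seed SCC reachable from it in the condensation.
    order = list(nx.topological_sort(cond))
    parent = {s: s for s in cond.nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    # Reachable seed groups per condensation node, propagated leaf-up.
    reach_groups: dict[int, frozenset] = {}
    for s in reversed(order):
        groups = set()
        for t in cond.successors(s):
            groups.update(reach_groups[t])
        if is_seed_scc[s]:
            # closure of this seed overlaps every seed group below it: merge
            for grp in groups:
                union(s, grp)
            groups = {s}
        reach_groups[s] = frozenset(groups)

    # Canonicalize after all unions.
    node_group: dict[Hashable, Hashable] = {}
    morpho = set()
    for s in order:
        groups = {find(x) for x in reach_groups[s]}
        mem = cond.nodes[s]["members"]
        if is_seed_scc[s] or len(groups) == 1:
            (grp,) = groups if not is_seed_scc[s] else {find(s)}
            for v in mem:
                node_group[v] = grp
        else:
            morpho.update(mem)

    comps: dict[Hashable, set] = {}
    for v, grp in node_group.items():
        comps.setdefault(grp, set()).add(v)
    h_components = sorted((frozenset(c) for c in comps.values()), key=lambda c: (-len(c), sorted(map(str, c))))
    return Decomposition(h_components, frozenset(morpho))


def injury_degree(g: TransitionDigraph, x, y) -> int | float:
    """Undirected graph distance between configurations x and y.

    Returns math.inf when x and y lie in different undirected components.
    """
    for node in (x, y):
        if node not in g:
            raise KeyError(f"unknown node {node!r}")
    if x == y:
        return 0
    ug = g.graph.to_undirected(as_view=True)
    try:
        return nx.shortest_path_length(ug, x, y)
    except nx.NetworkXNoPath:
        return math.inf


def is_sustainable(g: TransitionDigraph, dec: Decomposition, x, y) -> bool:
    """An injury (x, y) is sustainable iff x and y share an h-component."""
    cx, cy = dec.component_of(x), dec.component_of(y)
    return cx is not None and cx == cy


def is_adult(dec: Decomposition, node) -> bool:
    """Adulthood: the current configuration lies in the homeostatic phase."""
    return dec.component_of(node) is not None


def _balls(g: TransitionDigraph, sources: Sequence, m: int | None) -> dict:
    """Undirected distance-<=m neighbourhoods (None = unbounded)."""
    ug = g.graph.to_undirected(as_view=True)
    out = {}
    for x in sources:
        if m is None:
            out[x] = None  # sentinel: unrestricted
        else:
            out[x] = set(nx.single_source_shortest_path_length(ug, x, cutoff=m))
    return out


def sustain_probability(
    g: TransitionDigraph,
    dec: Decomposition,
    m: int | None = None,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Probability that a random injury of degree <= m is sustainable.

    The injured node x is uniform over the homeostatic phase; the target
    y is uniform over homeostatic nodes within undirected distance m of x
    (all homeostatic nodes when m is None, including disconnected ones;
    y = x, a degree-0 injury, is included and trivially sustainable).
    Exact enumeration below EXACT_ENUMERATION_LIMIT nodes, Monte Carlo
    with n_samples draws above.
    """
    hnodes = sorted(dec.homeostatic, key=str)
    if not hnodes:
        raise ValueError("empty homeostatic phase: system is not self-healing")
    exact = g.graph.number_of_nodes() <= EXACT_ENUMERATION_LIMIT and n_samples is None
    if exact:
        balls = _balls(g, hnodes, m)
        total = 0.0
        for x in hnodes:
            ball = balls[x]
            cand = hnodes if ball is None else [y for y in hnodes if y in ball]
            if not cand:
                total += 1.0  # only y = x available
                continue
            total += sum(is_sustainable(g, dec, x, y) for y in cand) / len(cand)
        return total / len(hnodes)
    rng = rng or np.random.default_rng(0)
    n_samples = n_samples or 10000
    hits = 0
    for _ in range(n_samples):
        x = hnodes[rng.integers(len(hnodes))]
        if m is None:
            cand = hnodes
        else:
            ug = g.graph.to_undirected(as_view=True)
            ball = nx.single_source_shortest_path_length(ug, x, cutoff=m)
            cand = [y for y in hnodes if y in ball]
        y = cand[rng.integers(len(cand))] if cand else x
        hits += is_sustainable(g, dec, x, y)
    return hits / n_samples


@dataclass
class SelfHealingResult:
    """Outcome of a self-healing degree estimate.

    degree: largest m with sustain probability >= 0.5; the string "any"
    when the unbounded probability is >= 0.5; None when not self-healing
    at any degree (or the homeostatic phase is empty).
    """

    degree: int | str | None
    probability: float
    tie: bool = False  # probability exactly at the 0.5 boundary
    per_degree: dict = field(default_factory=dict)

    @property
    def self_healing(self) -> bool:
        return self.degree is not None


def self_healing_degree(
    g: TransitionDigraph,
    dec: Decomposition,
    max_m: int | None = None,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> SelfHealingResult:
    """Largest degree m at which the system is self-healing.

    Tries the unbounded injury model first ("any degree"), then degrees
    max_m down to 1. Returns a not-self-healing marker when the
    homeostatic phase is empty or no degree reaches probability 0.5.
    """
    if not dec.homeostatic:
        return SelfHealingResult(None, 0.0)
    tol = 1e-12
    p_any = sustain_probability(g, dec, None, n_samples, rng)
    per = {"any": p_any}
    if p_any >= 0.5 - tol:
        return SelfHealingResult("any", p_any, tie=abs(p_any - 0.5) < tol, per_degree=per)
    if max_m is None:
        max_m = g.graph.number_of_nodes()
    for m in range(max_m, 0, -1):
        p = sustain_probability(g, dec, m, n_samples, rng)
        per[m] = p
        if p >= 0.5 - tol:
            return SelfHealingResult(m, p, tie=abs(p - 0.5) < tol, per_degree=per)
    return SelfHealingResult(None, p_any, per_degree=per)


DOMINATING_THRESHOLD = 0.71


def smallest_dominating_percentage() -> int:
    """Smallest integer percentage p with (p/100)^2 > 0.5.

    A dominating h-component holding at least this share of all nodes
    makes any random homeostatic injury land in it with probability
    > 0.5 (both endpoints independently fall in the component).
    """
    p = 1
    while (p / 100.0) ** 2 <= 0.5:
        p += 1
    return p


def proposition1_holds(dec: Decomposition, n_total: int | None = None) -> bool:
    """True iff one h-component holds >= 71% of all configuration-space
    nodes — a sufficient condition for self-healing of any degree."""
    return dec.dominating_fraction(n_total) >= DOMINATING_THRESHOLD - 1e-12


# ---------------------------------------------------------------------------
# toy-system enumeration
# ---------------------------------------------------------------------------


def enumerate_configspace(
    toy,
    depth_cap: int = 10000,
    extra_nodes: Iterable = (),
) -> TransitionDigraph:
    """BFS enumeration of a discrete toy system's configuration space.

    `toy` provides `initial_state()` (hashable) and `successors(state)`
    (iterable of hashable states); equivalent configurations hash equal
    and are merged into one node. `extra_nodes` seeds additional
    configurations (the inverse-closure part unreachable from the root).
    A graph truncated by `depth_cap` is returned with partial=True.
    """
    root = toy.initial_state()
    g = nx.DiGraph()
    g.add_node(root)
    frontier = [root] + [s for s in extra_nodes if s != root]
    g.add_nodes_from(frontier)
    seen = set(frontier)
    partial = False
    while frontier:
        if len(seen) > depth_cap:
            partial = True
            break
        nxt = []
        for s in frontier:
            for t in toy.successors(s):
                g.add_edge(s, t)
                if t not in seen:
                    seen.add(t)
                    nxt.append(t)
        frontier = nxt
    return TransitionDigraph(g, root, partial=partial)


class ToyChainSystem:
    """A 1-D lattice toy system: n slots filled left to right.

    Seeded with one tile in the first slot. One creation rule appends a
    tile to the next free slot; with reversible=True a destruction rule
    also removes the last added tile (never the seed), producing
    attach/detach 2-cycles. States are the number of filled slots — a
    fully discrete, hand-enumerable configuration space.
    """

    def __init__(self, n_slots: int, reversible: bool = False):
        if n_slots < 1:
            raise ValueError("n_slots must be >= 1")
        self.n_slots = n_slots
        self.reversible = reversible

    def initial_state(self) -> int:
        return 1

    def successors(self, state: int):
        if state < self.n_slots:
            yield state + 1
        if self.reversible and state > 1:
            yield state - 1
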