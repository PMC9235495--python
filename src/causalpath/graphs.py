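"""Mixed graphs for causal models over biomolecular pathways.

A :class:`MixedGraph` holds a directed acyclic graph over named nodes together
with either (i) a set of nodes flagged *latent* (an explicit-latent DAG, the
form in which pathway models are written down) or (ii) a set of *bidirected*
edges between observed nodes (an acyclic directed mixed graph, ADMG, the
canonical form consumed by identification).  Conversion from (i) to (ii) is the
latent projection.

All graph-surgical operations used elsewhere in the package live here:
mutilation (removing incoming/outgoing edges, which simulates interventions),
d-separation, latent projection, topological ordering and districts
(c-components).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "MixedGraph",
    "GraphError",
    "parse_graph",
    "read_graph",
]


class GraphError(ValueError):
    """Raised for structurally invalid graphs or unknown node labels."""


def _as_set(nodes) -> frozenset:
    if isinstance(nodes, str):
        return frozenset([nodes])
    return frozenset(nodes)


@dataclass(frozen=True)
class MixedGraph:
    """Directed + bidirected graph over named nodes.

    Parameters
    ----------
    nodes
        Node labels.
    directed
        Ordered pairs ``(parent, child)``.
    bidirected
        Unordered pairs ``{a, b}`` between observed nodes, each standing for an
        unnamed latent common cause.
    latent
        Subset of ``nodes`` flagged unobserved.  A graph uses either
        ``latent`` or ``bidirected``, never both: a model is written either as
        an explicit-latent DAG or as an ADMG.
    """

    nodes: frozenset = field(default_factory=frozenset)
    directed: frozenset = field(default_factory=frozenset)
    bidirected: frozenset = field(default_factory=frozenset)
    latent: frozenset = field(default_factory=frozenset)

    def __init__(self, nodes=(), directed=(), bidirected=(), latent=()):
        object.__setattr__(self, "nodes", _as_set(nodes) | {u for e in directed for u in e} | {u for e in bidirected for u in e} | _as_set(latent))
        object.__setattr__(self, "directed", frozenset((str(a), str(b)) for a, b in directed))
        object.__setattr__(self, "bidirected", frozenset(frozenset(e) for e in bidirected))
        object.__setattr__(self, "latent", _as_set(latent))
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        for a, b in self.directed:
            if a == b:
                raise GraphError(f"self-loop on node {a!r}")
        for e in self.bidirected:
            if len(e) != 2:
                raise GraphError(f"bidirected self-loop on {set(e)!r}")
        if self.latent - self.nodes:
            raise GraphError(f"latent labels not in node set: {sorted(self.latent - self.nodes)}")
        if self.latent and self.bidirected:
            raise GraphError("a graph is either an explicit-latent DAG or an ADMG; "
                             "it cannot carry both latent nodes and bidirected edges")
        for e in self.bidirected:
            bad = e & self.latent
            if bad:
                raise GraphError(f"bidirected edge touches latent node {sorted(bad)}")
        dg = self._digraph()
        if not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            raise GraphError(f"directed part is cyclic: {cycle}")

    def _digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def _check_nodes(self, nodes) -> frozenset:
        nodes = _as_set(nodes)
        unknown = nodes - self.nodes
        if unknown:
            raise GraphError(f"unknown node label(s): {sorted(unknown)}")
        return nodes

    # -- basic queries -------------------------------------------------------------

    @property
    def observed(self) -> frozenset:
        return self.nodes - self.latent

    def parents(self, node: str) -> frozenset:
        self._check_nodes([node])
        return frozenset(a for a, b in self.directed if b == node)

    def children(self, node: str) -> frozenset:
        self._check_nodes([node])
        return frozenset(b for a, b in self.directed if a == node)

    def ancestors(self, nodes) -> frozenset:
        """Ancestors of ``nodes`` (inclusive) along directed edges."""
        nodes = self._check_nodes(nodes)
        g = self._digraph()
        out = set(nodes)
        for n in nodes:
            out |= nx.ancestors(g, n)
        return frozenset(out)

    def descendants(self, nodes) -> frozenset:
        """Descendants of ``nodes`` (inclusive) along directed edges."""
        nodes = self._check_nodes(nodes)
        g = self._digraph()
        out = set(nodes)
        for n in nodes:
            out |= nx.descendants(g, n)
        return frozenset(out)

    def siblings(self, node: str) -> frozenset:
        """Nodes joined to ``node`` by a bidirected edge."""
        self._check_nodes([node])
        return frozenset(u for e in self.bidirected if node in e for u in e if u != node)

    # -- mutilation ----------------------------------------------------------------

    def mutilate_incoming(self, targets) -> "MixedGraph":
        """Remove all edges *into* ``targets`` — the graph :math:`G_{\\bar X}`.

        Both directed edges into a target and bidirected edges incident to a
        target are removed: an intervention cuts every incoming influence,
        latent confounding included.
        """
        targets = self._check_nodes(targets)
        directed = {(a, b) for a, b in self.directed if b not in targets}
        bidirected = {e for e in self.bidirected if not (e & targets)}
        return MixedGraph(self.nodes, directed, bidirected, self.latent)

    def mutilate_outgoing(self, sources) -> "MixedGraph":
        """Remove all directed edges *out of* ``sources`` — :math:`G_{\\underline Z}`.

        Bidirected edges stand for incoming latent arrows and are untouched.
        """
        sources = self._check_nodes(sources)
        directed = {(a, b) for a, b in self.directed if a not in sources}
        return MixedGraph(self.nodes, directed, self.bidirected, self.latent)

    def subgraph(self, nodes) -> "MixedGraph":
        nodes = self._check_nodes(nodes)
        return MixedGraph(
            nodes,
            {(a, b) for a, b in self.directed if a in nodes and b in nodes},
            {e for e in self.bidirected if e <= nodes},
            self.latent & nodes,
        )

    # -- d-separation --------------------------------------------------------------

    def expand_bidirected(self) -> "MixedGraph":
        """Replace each bidirected edge ``a — b`` by a fresh latent parent ``a ← λ → b``."""
        if not self.bidirected:
            return self
        directed = set(self.directed)
        latent = set(self.latent)
        for i, e in enumerate(sorted(self.bidirected, key=sorted)):
            a, b = sorted(e)
            lam = f"_lat_{i}_{a}_{b}"
            latent.add(lam)
            directed.add((lam, a))
            directed.add((lam, b))
        return MixedGraph(self.nodes | latent, directed, (), latent)

    def d_separated(self, set_a, set_b, given=()) -> bool:
        """True iff every path between ``set_a`` and ``set_b`` is blocked given ``given``.

        Bidirected edges are expanded to explicit latent common parents first,
        then standard d-separation applies (descendants of a conditioned-on
        collider unblock it).
        """
        set_a, set_b, given = map(self._check_nodes, (set_a, set_b, given))
        if (set_a & set_b) or (set_a & given) or (set_b & given):
            raise GraphError("d-separation requires disjoint node sets")
        if not set_a or not set_b:
            return True
        g = self.expand_bidirected()._digraph()
        return nx.is_d_separator(g, set(set_a), set(set_b), set(given))

    # -- latent projection ---------------------------------------------------------

    def simplify_latents(self) -> "MixedGraph":
        """Reduce an explicit-latent DAG to its canonical simplified form.

        Applies, to a fixed point: (1) drop latents with no children;
        (2) remove a latent with parents, wiring every parent to every child;
        (3) drop latent W when children(W) ⊆ children(U) for another latent U.
        The fixed point has only parentless latents with pairwise incomparable
        child sets.
        """
        if self.bidirected:
            raise GraphError("simplify_latents expects an explicit-latent DAG, not an ADMG")
        directed = set(self.directed)
        latent = set(self.latent)
        nodes = set(self.nodes)

        def _parents(n):
            return {a for a, b in directed if b == n}

        def _children(n):
            return {b for a, b in directed if a == n}

        changed = True
        while changed:
            changed = False
            # rule 1: latents with no children
            for u in sorted(latent):
                if not _children(u):
                    latent.discard(u)
                    nodes.discard(u)
                    directed = {(a, b) for a, b in directed if b != u}
                    changed = True
            # rule 2: latents with parents — bypass
            for u in sorted(latent):
                pa, ch = _parents(u), _children(u)
                if pa and ch:
                    directed |= {(p, c) for p in pa for c in ch}
                    directed = {(a, b) for a, b in directed if u not in (a, b)}
                    latent.discard(u)
                    nodes.discard(u)
                    changed = True
            # rule 3: nested child sets
            for w, u in itertools.permutations(sorted(latent), 2):
                if w in latent and u in latent and _children(w) <= _children(u):
                    latent.discard(w)
                    nodes.discard(w)
                    directed = {(a, b) for a, b in directed if w not in (a, b)}
                    changed = True
        return MixedGraph(nodes, directed, (), latent)

    def latent_project(self) -> "MixedGraph":
        """Project an explicit-latent DAG onto an ADMG over its observed nodes.

        Remaining latents after simplification become bidirected cliques among
        their children; a latent left with a single child carries no
        confounding information and is absorbed into that child's noise.
        Projecting a graph that is already an ADMG is the identity.
        """
        if self.bidirected:
            return self
        simplified = self.simplify_latents()
        observed = simplified.observed
        directed = {(a, b) for a, b in simplified.directed if a in observed and b in observed}
        bidirected = set()
        for u in simplified.latent:
            ch = sorted(simplified.children(u))
            for a, b in itertools.combinations(ch, 2):
                bidirected.add(frozenset((a, b)))
        return MixedGraph(observed, directed, bidirected, ())

    # -- ordering and districts ----------------------------------------------------

    def topological_sort(self) -> list:
        """Directed-parents-first node order; ties broken lexicographically."""
        return list(nx.lexicographical_topological_sort(self._digraph()))

    def districts(self, subset=None) -> list:
        """Partition ``subset`` (default: observed nodes) into c-components.

        A district is a maximal set connected by bidirected edges in the
        induced subgraph.  Returned as a list of frozensets, sorted for
        determinism.
        """
        if self.latent:
            raise GraphError("districts are defined on ADMGs; project latents first")
        subset = self._check_nodes(subset if subset is not None else self.observed)
        g = nx.Graph()
        g.add_nodes_from(subset)
        g.add_edges_from(tuple(e) for e in self.bidirected if e <= subset)
        comps = [frozenset(c) for c in nx.connected_components(g)]
        return sorted(comps, key=lambda c: sorted(c))

    # -- I/O -----------------------------------------------------------------------

    def to_text(self) -> str:
        lines = []
        for n in sorted(self.latent):
            lines.append(f"latent {n}")
        covered = {u for e in self.directed for u in e} | {u for e in self.bidirected for u in e}
        for n in sorted(self.nodes - covered - self.latent):
            lines.append(f"node {n}")
        for a, b in sorted(self.directed):
            lines.append(f"{a} -> {b}")
        for e in sorted(self.bidirected, key=sorted):
            a, b = sorted(e)
            lines.append(f"{a} <-> {b}")
        return "\n".join(lines) + "\n"

    def to_dot(self, name: str = "G") -> str:
        """DOT rendering; bidirected edges drawn dashed without arrowheads."""
        lines = [f"digraph {name} {{"]
        for n in sorted(self.nodes):
            style = ' [style=filled, fillcolor=gray]' if n in self.latent else ""
            lines.append(f'  "{n}"{style};')
        for a, b in sorted(self.directed):
            lines.append(f'  "{a}" -> "{b}";')
        for e in sorted(self.bidirected, key=sorted):
            a, b = sorted(e)
            lines.append(f'  "{a}" -> "{b}" [dir=none, style=dashed];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def parse_graph(text: str) -> MixedGraph:
    """Parse the plain-text edge-list dialect.

    One statement per line: ``A -> B`` (directed), ``A <-> B`` (bidirected),
    ``latent A``, ``node A``; ``#`` starts a comment.
    """
    nodes, directed, bidirected, latent = set(), set(), set(), set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) == 2 and parts[0] in ("latent", "node"):
            nodes.add(parts[1])
            if parts[0] == "latent":
                latent.add(parts[1])
        elif len(parts) == 3 and parts[1] == "->":
            directed.add((parts[0], parts[2]))
        elif len(parts) == 3 and parts[1] == "<->":
            bidirected.add(frozenset((parts[0], parts[2])))
        else:
            raise GraphError(f"cannot parse line {lineno}: {raw!r}")
    return MixedGraph(nodes, directed, bidirected, latent)


def read_graph(path) -> MixedGraph:
    with open(path) as fh:
        return parse_graph(fh.read())
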