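"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: d-separation is decided
by exhaustive path enumeration, and interventional truths on discrete models
by brute-force enumeration of the surgically-mutilated joint.
"""

from __future__ import annotations

import itertools

import numpy as np

from causalpath.graphs import MixedGraph
from causalpath.identify import DiscreteJoint


# ---------------------------------------------------------------------------
# path-enumeration d-separation
# ---------------------------------------------------------------------------


def _adjacency(graph: MixedGraph):
    """Neighbor map over the latent-expanded graph: (neighbor, arrow_into_self,
    arrow_into_neighbor) triples."""
    g = graph.expand_bidirected()
    adj: dict = {n: [] for n in g.nodes}
    for a, b in g.directed:
        adj[a].append((b, False, True))   # a -> b: arrow into b
        adj[b].append((a, True, False))
    return g, adj


def d_separated_by_paths(graph: MixedGraph, set_a, set_b, given) -> bool:
    """Exhaustive-path d-separation: every simple path must contain either a
    conditioned non-collider or an unconditioned collider with no conditioned
    descendant."""
    set_a, set_b, given = map(frozenset, (set_a, set_b, given))
    g, adj = _adjacency(graph)
    cond_closure = set(given)  # colliders are opened by conditioned descendants
    opened = {n for n in g.nodes if g.descendants([n]) & given}

    def path_open(path, arrows):
        # arrows[i] = (into_prev, into_cur) orientation of edge i
        for i in range(1, len(path) - 1):
            into_from_left = arrows[i - 1][1]
            into_from_right = arrows[i][0]
            node = path[i]
            is_collider = into_from_left and into_from_right
            if is_collider:
                if node not in cond_closure and node not in opened:
                    return False
            else:
                if node in given:
                    return False
        return True

    def dfs(node, target, path, arrows, visited):
        if node == target:
            return path_open(path, arrows)
        for nxt, into_self, into_next in adj[node]:
            if nxt in visited:
                continue
            if dfs(nxt, target, path + [nxt], arrows + [(into_self, into_next)],
                   visited | {nxt}):
                return True
        return False

    for a in set_a:
        for b in set_b:
            if dfs(a, b, [a], [], {a}):
                return False
    return True


# ---------------------------------------------------------------------------
# random graphs
# ---------------------------------------------------------------------------


def random_mixed_graph(rng: np.random.Generator, k: int, p_dir=0.35, p_bi=0.2) -> MixedGraph:
    nodes = [f"n{i}" for i in range(k)]
    order = list(rng.permutation(k))
    directed = set()
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < p_dir:
                directed.add((nodes[order[i]], nodes[order[j]]))
    bidirected = set()
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < p_bi:
                bidirected.add(frozenset((nodes[i], nodes[j])))
    return MixedGraph(nodes, directed, bidirected)


def random_latent_dag(rng: np.random.Generator, k_obs: int, k_lat: int) -> MixedGraph:
    obs = [f"v{i}" for i in range(k_obs)]
    lat = [f"u{i}" for i in range(k_lat)]
    nodes = obs + lat
    order = list(rng.permutation(len(nodes)))
    directed = set()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < 0.35:
                directed.add((nodes[order[i]], nodes[order[j]]))
    return MixedGraph(nodes, directed, (), lat)


# ---------------------------------------------------------------------------
# discrete SCM enumeration oracle
# ---------------------------------------------------------------------------


class DiscreteSCM:
    """Random CPTs on the latent expansion of an ADMG; exact joints by
    enumeration, with and without graph surgery."""

    def __init__(self, admg: MixedGraph, rng: np.random.Generator, k: int = 2,
                 concentration: float = 1.0):
        self.admg = admg
        g = admg.expand_bidirected()
        self.g = g
        self.order = g.topological_sort()
        self.obs = sorted(admg.observed)
        self.k = k
        self.cpts = {}
        for n in self.order:
            pa = sorted(g.parents(n))
            if pa:
                t = rng.dirichlet(np.full(k, concentration), size=tuple(k for _ in pa))
            else:
                t = rng.dirichlet(np.full(k, concentration))
            self.cpts[n] = (pa, np.asarray(t))

    def joint_under(self, do: dict) -> np.ndarray:
        """Exact joint over observed nodes (obs order), latents marginalized,
        with intervened nodes clamped by surgery."""
        k, order = self.k, self.order
        full = np.zeros(tuple(k for _ in order))
        for idx in itertools.product(range(k), repeat=len(order)):
            val = dict(zip(order, idx))
            p = 1.0
            for n in order:
                if n in do:
                    p *= 1.0 if val[n] == do[n] else 0.0
                else:
                    pa, t = self.cpts[n]
                    p *= t[tuple(val[q] for q in pa) + (val[n],)]
                if p == 0.0:
                    break
            full[idx] = p
        drop = tuple(i for i, n in enumerate(order) if n not in self.admg.observed)
        marg = full.sum(axis=drop) if drop else full
        remaining = [n for n in order if n in self.admg.observed]
        perm = [remaining.index(v) for v in self.obs]
        return np.transpose(marg, perm) if marg.ndim > 1 else marg

    def observational_joint(self) -> DiscreteJoint:
        support = {v: np.arange(self.k) for v in self.obs}
        return DiscreteJoint(support, self.joint_under({}))

    def interventional_marginal(self, do: dict, outcomes) -> np.ndarray:
        table = self.joint_under(do)
        keep = [v for v in self.obs if v in outcomes]
        drop = tuple(i for i, v in enumerate(self.obs) if v not in outcomes)
        out = table.sum(axis=drop) if drop else table
        perm = [keep.index(v) for v in sorted(outcomes)]
        return np.transpose(out, perm) if out.ndim > 1 else out
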