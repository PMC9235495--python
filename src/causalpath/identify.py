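"""Identifiability of interventional queries on ADMGs, and do-free estimands.

Given an ADMG over observed pathway variables and a causal query
``P(Y | do(X = x'))`` (or its expectation), this module decides whether the
query is identifiable and, if so, emits a do-free :class:`Estimand` — an
expression tree of sums, products, fractions and observational conditionals
that can be evaluated against any discrete joint table.

Three routes are tried in order, and the successful one is reported so that a
pathway analysis can state *how* its query was identified:

1. the back-door criterion (adjustment for observed confounders),
2. the front-door criterion (an unconfounded mediator),
3. the complete district-based recursive identification algorithm, which is
   sound and complete for queries of this form.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .graphs import GraphError, MixedGraph

__all__ = [
    "CausalQuery",
    "Estimand",
    "Conditional",
    "Marginalize",
    "Product",
    "Fraction",
    "IdentifyResult",
    "NotIdentifiableError",
    "check_backdoor",
    "check_frontdoor",
    "identify",
    "apply_rule",
    "DiscreteJoint",
    "evaluate_estimand",
]


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CausalQuery:
    """An interventional query: fix ``targets`` and ask about ``outcomes``.

    ``targets`` maps each intervened node to its intervention value x'.
    ``form`` is ``"distribution"`` for P(Y|do(x')) or ``"expectation"`` for
    E[Y|do(x')].
    """

    targets: dict
    outcomes: tuple
    form: str = "expectation"

    def __post_init__(self):
        object.__setattr__(self, "targets", dict(self.targets))
        outcomes = (self.outcomes,) if isinstance(self.outcomes, str) else tuple(self.outcomes)
        object.__setattr__(self, "outcomes", outcomes)
        if self.form not in ("distribution", "expectation"):
            raise ValueError(f"unknown query form {self.form!r}")
        if not self.targets:
            raise ValueError("query has no intervention targets")
        if not self.outcomes:
            raise ValueError("query has no outcomes")
        if set(self.targets) & set(self.outcomes):
            raise ValueError("intervention targets and outcomes must be disjoint")

    def validate_against(self, graph: MixedGraph) -> None:
        observed = graph.observed
        missing = (set(self.targets) | set(self.outcomes)) - observed
        if missing:
            raise GraphError(
                f"query references nodes that are not observed in the graph: {sorted(missing)} "
                "(interventions on latent nodes are not supported)"
            )


# ---------------------------------------------------------------------------
# estimand expression trees
# ---------------------------------------------------------------------------


class Estimand:
    """Base class for do-free estimand expression nodes."""

    def render(self) -> str:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def __repr__(self):
        return f"<{type(self).__name__}: {self.render()}>"

    def __eq__(self, other):
        return type(self) is type(other) and self.to_dict() == other.to_dict()

    def __hash__(self):
        return hash(self.to_json(sort_keys=True))

    @staticmethod
    def from_dict(d: dict) -> "Estimand":
        kind = d["kind"]
        if kind == "conditional":
            return Conditional(tuple(d["outcome"]), tuple(d["given"]))
        if kind == "marginalize":
            return Marginalize(tuple(d["vars"]), Estimand.from_dict(d["child"]))
        if kind == "product":
            return Product(tuple(Estimand.from_dict(c) for c in d["children"]))
        if kind == "fraction":
            return Fraction(Estimand.from_dict(d["num"]), Estimand.from_dict(d["den"]))
        raise ValueError(f"unknown estimand node kind {kind!r}")

    def variables(self) -> frozenset:
        raise NotImplementedError


class Conditional(Estimand):
    """Observational conditional term P(outcome | given)."""

    def __init__(self, outcome, given=()):
        self.outcome = (outcome,) if isinstance(outcome, str) else tuple(outcome)
        self.given = (given,) if isinstance(given, str) else tuple(given)
        if set(self.outcome) & set(self.given):
            raise ValueError("conditional outcome and given sets overlap")

    def render(self):
        out = ",".join(self.outcome)
        return f"P({out}|{','.join(self.given)})" if self.given else f"P({out})"

    def to_dict(self):
        return {"kind": "conditional", "outcome": list(self.outcome), "given": list(self.given)}

    def variables(self):
        return frozenset(self.outcome) | frozenset(self.given)


class Marginalize(Estimand):
    """Sum (or integral) of ``child`` over ``vars``."""

    def __init__(self, vars, child):
        self.vars = tuple(sorted((vars,) if isinstance(vars, str) else vars))
        self.child = child

    def render(self):
        if not self.vars:
            return self.child.render()
        return f"sum_{{{','.join(self.vars)}}} {self.child.render()}"

    def to_dict(self):
        return {"kind": "marginalize", "vars": list(self.vars), "child": self.child.to_dict()}

    def variables(self):
        return self.child.variables() - frozenset(self.vars)


class Product(Estimand):
    def __init__(self, children):
        flat = []
        for c in children:
            flat.extend(c.children if isinstance(c, Product) else [c])
        self.children = tuple(flat)

    def render(self):
        return " ".join(
            c.render() if isinstance(c, (Conditional, Fraction)) else f"[{c.render()}]"
            for c in self.children
        )

    def to_dict(self):
        return {"kind": "product", "children": [c.to_dict() for c in self.children]}

    def variables(self):
        out = frozenset()
        for c in self.children:
            out |= c.variables()
        return out


class Fraction(Estimand):
    def __init__(self, num, den):
        self.num, self.den = num, den

    def render(self):
        return f"[{self.num.render()}] / [{self.den.render()}]"

    def to_dict(self):
        return {"kind": "fraction", "num": self.num.to_dict(), "den": self.den.to_dict()}

    def variables(self):
        return self.num.variables() | self.den.variables()


def _marg(vars, child) -> Estimand:
    vars = tuple(sorted(vars))
    if not vars:
        return child
    if isinstance(child, Marginalize):
        return Marginalize(tuple(sorted(set(vars) | set(child.vars))), child.child)
    return Marginalize(vars, child)


def _prod(children) -> Estimand:
    children = [c for c in children if c is not None]
    if len(children) == 1:
        return children[0]
    return Product(tuple(children))


# ---------------------------------------------------------------------------
# identification results
# ---------------------------------------------------------------------------


@dataclass
class IdentifyResult:
    status: str  # "identifiable" | "not_identifiable"
    estimand: Estimand | None = None
    method: str | None = None  # "backdoor" | "frontdoor" | "id_algorithm"
    witness: frozenset | None = None  # adjustment / mediator set where applicable
    reason: str | None = None

    @property
    def identifiable(self) -> bool:
        return self.status == "identifiable"

    def __post_init__(self):
        if self.identifiable and self.estimand is None:
            raise ValueError("identifiable result must carry an estimand")
        if not self.identifiable and self.estimand is not None:
            raise ValueError("non-identifiable result must not carry an estimand")


class NotIdentifiableError(Exception):
    """Raised when a query admits no do-free estimand (a hedge was found)."""

    def __init__(self, message, witness=None):
        super().__init__(message)
        self.witness = witness


# ---------------------------------------------------------------------------
# graphical criteria
# ---------------------------------------------------------------------------


def _bidirected_connected(graph: MixedGraph, x: str, y: str) -> bool:
    seen, stack = {x}, [x]
    while stack:
        n = stack.pop()
        for s in graph.siblings(n):
            if s == y:
                return True
            if s not in seen:
                seen.add(s)
                stack.append(s)
    return False


def check_backdoor(admg: MixedGraph, x: str, y: str, z) -> bool:
    """Back-door criterion for (x, y) with adjustment set ``z``.

    Requires: no bidirected-only path from x to y; no member of z a descendant
    of x; z blocks every path between x and y that contains an arrow into x.
    """
    z = frozenset((z,) if isinstance(z, str) else z)
    if x in z or y in z:
        raise GraphError("adjustment set must exclude cause and outcome")
    admg._check_nodes({x, y} | z)
    if z - admg.observed:
        raise GraphError("adjustment set must be observed")
    if _bidirected_connected(admg, x, y):
        return False
    if z & admg.descendants([x]):
        return False
    # with x's outgoing directed edges removed, every remaining x–y path has an
    # arrow into x
    return admg.mutilate_outgoing([x]).d_separated([x], [y], z)


def _intercepts_all_directed_paths(admg: MixedGraph, x, y: str, z) -> bool:
    """True iff every directed path from ``x`` to ``y`` passes through ``z``."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(admg.nodes)
    g.add_edges_from(admg.directed)
    g.remove_nodes_from(z)
    return not any(nx.has_path(g, xi, y) for xi in x if xi in g and y in g)


def check_frontdoor(admg: MixedGraph, x, y: str, z) -> bool:
    """Front-door criterion for cause set ``x``, outcome ``y``, mediator set ``z``.

    ``z`` must intercept every directed x→y path; there must be no back-door
    path from x to z left open with the empty conditioning set; and every
    back-door path from z to y must be blocked by x.
    """
    x = frozenset((x,) if isinstance(x, str) else x)
    z = frozenset((z,) if isinstance(z, str) else z)
    if z & (x | {y}):
        raise GraphError("mediator set must exclude causes and outcome")
    admg._check_nodes(x | z | {y})
    if not z:
        return False
    if not _intercepts_all_directed_paths(admg, x, y, z):
        return False
    if not admg.mutilate_outgoing(x).d_separated(x, z, ()):
        return False
    return admg.mutilate_outgoing(z).d_separated(z, [y], x)


def apply_rule(rule: int, admg: MixedGraph, x, y, z, w=()) -> bool:
    """Check the d-separation premise of a do-calculus rule.

    Rule 1 (insert/delete observation):      (Y ⊥ Z | X, W) in G with incoming
    edges to X removed.  Rule 2 (action/observation exchange): same, with Z's
    outgoing edges also removed.  Rule 3 (insert/delete action): incoming
    edges removed for X and for Z(W), the members of Z that are not ancestors
    of W in G with X's incoming edges removed.
    """
    x, y, z, w = (frozenset((s,) if isinstance(s, str) else s) for s in (x, y, z, w))
    for a, b in itertools.combinations([x, y, z, w], 2):
        if a & b:
            raise GraphError("do-calculus rule premises require disjoint sets")
    if not z:
        return True
    g_x = admg.mutilate_incoming(x)
    if rule == 1:
        g = g_x
    elif rule == 2:
        g = g_x.mutilate_outgoing(z)
    elif rule == 3:
        z_w = z - (g_x.ancestors(w) if w else frozenset())
        g = g_x.mutilate_incoming(z_w)
    else:
        raise ValueError("rule must be 1, 2 or 3")
    return g.d_separated(y, z, x | w)


# ---------------------------------------------------------------------------
# complete identification (district-based recursion)
# ---------------------------------------------------------------------------


@dataclass
class _Dist:
    """The distribution carried through the ID recursion."""

    vars: frozenset
    expr: Estimand | None = None  # None => the base observational joint
    base: bool = True

    def as_expr(self) -> Estimand:
        if self.base:
            return Conditional(tuple(sorted(self.vars)), ())
        return self.expr

    def marginalized(self, drop) -> "_Dist":
        drop = frozenset(drop)
        if not drop:
            return self
        return _Dist(self.vars - drop, _marg(drop, self.as_expr()), base=False)

    def cond_factor(self, vi: str, prefix) -> Estimand:
        """P(vi | prefix) under this distribution."""
        prefix = frozenset(prefix) & self.vars
        if self.base:
            return Conditional((vi,), tuple(sorted(prefix)))
        num = _marg(self.vars - prefix - {vi}, self.expr)
        den = _marg(self.vars - prefix, self.expr)
        return Fraction(num, den)


def _id(y: frozenset, x: frozenset, P: _Dist, G: MixedGraph) -> Estimand:
    V = frozenset(G.observed)
    order = G.topological_sort()
    # 1: no intervention — marginal of Y
    if not x:
        return _marg(V - y, P.as_expr())
    # 2: restrict to ancestors of Y
    an_y = G.ancestors(y) & V
    if V != an_y:
        return _id(y, x & an_y, P.marginalized(V - an_y), G.subgraph(an_y))
    # 3: enlarge X with nodes that cannot influence Y once X is held fixed
    w = (V - x - y) - G.mutilate_incoming(x).ancestors(y)
    if w:
        return _id(y, x | w, P, G)
    # 4: factor across districts of G minus X
    districts_minus_x = G.districts(V - x)
    if len(districts_minus_x) > 1:
        terms = [_id(frozenset(s), V - s, P, G) for s in districts_minus_x]
        return _marg(V - (y | x), _prod(terms))
    S = districts_minus_x[0]
    districts_g = G.districts(V)
    # 5: a single district covering all of G is a hedge — not identifiable
    if len(districts_g) == 1:
        raise NotIdentifiableError(
            f"hedge: district {sorted(districts_g[0])} forms a single confounded "
            f"component containing the intervention set {sorted(x)}",
            witness=(districts_g[0], S),
        )
    # 6: S is itself a district of G — chain-factor it
    if S in districts_g:
        pred: list = []
        factors = []
        for vi in order:
            if vi not in V:
                continue
            if vi in S:
                factors.append(P.cond_factor(vi, pred))
            pred.append(vi)
        return _marg(S - y, _prod(factors))
    # 7: S sits strictly inside a district S' of G — recurse on S'
    S_prime = next(d for d in districts_g if S <= d)
    pred, factors = [], []
    for vi in order:
        if vi not in V:
            continue
        if vi in S_prime:
            factors.append(P.cond_factor(vi, pred))
        pred.append(vi)
    P_prime = _Dist(frozenset(S_prime), _prod(factors), base=False)
    return _id(y, x & S_prime, P_prime, G.subgraph(S_prime))


def id_algorithm(admg: MixedGraph, query: CausalQuery) -> Estimand:
    """Run the complete recursive identification algorithm; raises on failure."""
    query.validate_against(admg)
    y = frozenset(query.outcomes)
    x = frozenset(query.targets)
    P = _Dist(frozenset(admg.observed))
    return _id(y, x, P, admg)


# ---------------------------------------------------------------------------
# the identify entry point (fast paths + complete algorithm)
# ---------------------------------------------------------------------------

_MAX_SUBSETS = 4096


def _subsets_small_first(candidates, max_total=_MAX_SUBSETS):
    candidates = sorted(candidates)
    count = 0
    for r in range(len(candidates) + 1):
        for z in itertools.combinations(candidates, r):
            yield frozenset(z)
            count += 1
            if count >= max_total:
                return


def _backdoor_estimand(x: str, y, z) -> Estimand:
    z = tuple(sorted(z))
    y = tuple(sorted(y))
    term = Conditional(y, (x,) + z)
    if not z:
        return term
    return _marg(z, _prod([term, Conditional(z, ())]))


def _frontdoor_estimand(x, y, z) -> Estimand:
    x, z, y = tuple(sorted(x)), tuple(sorted(z)), tuple(sorted(y))
    inner = _marg(x, _prod([Conditional(y, x + z), Conditional(x, ())]))
    return _marg(z, _prod([Conditional(z, x), inner]))


def identify(admg: MixedGraph, query: CausalQuery) -> IdentifyResult:
    """Decide identifiability of ``query`` on ``admg`` and build its estimand.

    Back-door and front-door are tried first (they label the result for
    reporting); the complete district-based algorithm is the fallback and is
    what makes the decision exact: a query is declared non-identifiable only
    when the recursion finds a hedge.
    """
    query.validate_against(admg)
    x_nodes = frozenset(query.targets)
    y_nodes = frozenset(query.outcomes)
    observed = admg.observed

    if len(x_nodes) == 1 and len(y_nodes) == 1:
        (x,) = x_nodes
        (y,) = y_nodes
        candidates = observed - admg.descendants([x]) - {x, y}
        for z in _subsets_small_first(candidates):
            if check_backdoor(admg, x, y, z):
                return IdentifyResult(
                    "identifiable", _backdoor_estimand(x, (y,), z), "backdoor", frozenset(z)
                )
    if len(y_nodes) == 1:
        (y,) = y_nodes
        candidates = observed - x_nodes - {y}
        for z in _subsets_small_first(candidates):
            if z and check_frontdoor(admg, x_nodes, y, z):
                return IdentifyResult(
                    "identifiable", _frontdoor_estimand(x_nodes, (y,), z), "frontdoor", frozenset(z)
                )
    try:
        est = id_algorithm(admg, query)
    except NotIdentifiableError as err:
        return IdentifyResult("not_identifiable", None, None, witness=err.witness, reason=str(err))
    return IdentifyResult("identifiable", est, "id_algorithm")


# ---------------------------------------------------------------------------
# discrete evaluation (numeric oracle for estimands)
# ---------------------------------------------------------------------------


class DiscreteJoint:
    """A full discrete joint probability table over named variables.

    ``support`` maps each variable to its array of values; ``probs`` is an
    array with one axis per variable, in ``vars`` order, summing to 1.
    """

    def __init__(self, support: dict, probs: np.ndarray):
        self.vars = tuple(support.keys())
        self.support = {v: np.asarray(s) for v, s in support.items()}
        self.probs = np.asarray(probs, dtype=float)
        if self.probs.shape != tuple(len(self.support[v]) for v in self.vars):
            raise ValueError("probability table shape does not match supports")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative probabilities")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-8):
            raise ValueError(f"joint table sums to {self.probs.sum()}, not 1")

    def marginal(self, keep) -> np.ndarray:
        keep = list(keep)
        axes = tuple(i for i, v in enumerate(self.vars) if v not in keep)
        out = self.probs.sum(axis=axes)
        order = [v for v in self.vars if v in keep]
        perm = [order.index(v) for v in keep]
        return np.transpose(out, perm) if out.ndim > 1 else out

    def value_index(self, var: str, value) -> int:
        sup = self.support[var]
        idx = np.nonzero(np.isclose(sup, value))[0]
        if len(idx) == 0:
            raise ValueError(f"value {value!r} not in the support of {var!r}")
        return int(idx[0])


class _Factor:
    def __init__(self, vars: tuple, values: np.ndarray):
        self.vars = tuple(vars)
        self.values = np.asarray(values, dtype=float)

    def sum_out(self, drop):
        keep = [v for v in self.vars if v not in drop]
        axes = tuple(i for i, v in enumerate(self.vars) if v in drop)
        return _Factor(keep, self.values.sum(axis=axes)) if axes else self

    def fix(self, var, index):
        if var not in self.vars:
            return self
        ax = self.vars.index(var)
        return _Factor(
            tuple(v for v in self.vars if v != var), np.take(self.values, index, axis=ax)
        )


def _align(f: _Factor, vars: tuple, joint: DiscreteJoint) -> np.ndarray:
    """Broadcast factor values onto the axis order ``vars``."""
    shape = [1] * len(vars)
    src = f.values
    perm = [f.vars.index(v) for v in vars if v in f.vars]
    src = np.transpose(src, perm) if src.ndim > 1 else src
    it = iter(src.shape)
    for i, v in enumerate(vars):
        if v in f.vars:
            shape[i] = next(it)
    return src.reshape(shape)


def _safe_div(num, den):
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    num, den = np.broadcast_arrays(num, den)
    mask = den > 0
    out[mask] = num[mask] / den[mask]
    return out


def _eval(expr: Estimand, joint: DiscreteJoint, env: dict) -> _Factor:
    if isinstance(expr, Conditional):
        missing = (set(expr.outcome) | set(expr.given)) - set(joint.vars)
        if missing:
            raise ValueError(f"estimand references variables absent from the table: {sorted(missing)}")
        keep = [v for v in joint.vars if v in set(expr.outcome) | set(expr.given)]
        num = joint.marginal(keep)
        f = _Factor(tuple(keep), num)
        if expr.given:
            den_keep = [v for v in keep if v in expr.given]
            den = _Factor(tuple(den_keep), joint.marginal(den_keep))
            vals = _safe_div(_align(f, tuple(keep), joint), _align(den, tuple(keep), joint))
            f = _Factor(tuple(keep), vals)
        for var, value in env.items():
            if var in f.vars:
                f = f.fix(var, joint.value_index(var, value))
        return f
    if isinstance(expr, Marginalize):
        inner_env = {k: v for k, v in env.items() if k not in expr.vars}
        f = _eval(expr.child, joint, inner_env)
        return f.sum_out(set(expr.vars))
    if isinstance(expr, Product):
        factors = [_eval(c, joint, env) for c in expr.children]
        vars = tuple(dict.fromkeys(v for f in factors for v in f.vars))
        vals = np.ones([1] * len(vars)) if vars else np.array(1.0)
        shaped = [_align(f, vars, joint) for f in factors]
        out = shaped[0]
        for s in shaped[1:]:
            out = out * s
        return _Factor(vars, out)
    if isinstance(expr, Fraction):
        num = _eval(expr.num, joint, env)
        den = _eval(expr.den, joint, env)
        vars = tuple(dict.fromkeys(list(num.vars) + list(den.vars)))
        vals = _safe_div(_align(num, vars, joint), _align(den, vars, joint))
        return _Factor(vars, vals)
    raise TypeError(f"not an estimand node: {expr!r}")


def evaluate_estimand(
    estimand: Estimand, joint: DiscreteJoint, targets: dict, outcomes=None
) -> "_Factor":
    """Numerically evaluate a do-free estimand on a discrete joint table.

    ``targets`` maps intervened variables to their (supported) values.
    Conditionals on zero-mass events contribute zero (the front-door
    positivity convention P(x, z) > 0 is assumed for exactness).  The result
    is a factor over the outcome variables, normalized to sum to 1.

    Ratio-form estimands (e.g. the napkin) may carry free *context* variables
    whose value is provably irrelevant under the model; each positive-mass
    context slice is a valid copy of the query, so slices are averaged with
    weights proportional to the context's observational probability.
    """
    for var, value in targets.items():
        joint.value_index(var, value)  # raise early on unsupported values
    f = _eval(estimand, joint, dict(targets))
    if outcomes is not None:
        extra = [v for v in f.vars if v not in outcomes]
        if extra:
            ctx = _Factor(tuple(extra), joint.marginal(extra))
            perm = tuple(v for v in f.vars if v in outcomes) + tuple(extra)
            vals = np.transpose(f.values, [f.vars.index(v) for v in perm])
            n_out = len(perm) - len(extra)
            flat = vals.reshape(vals.shape[:n_out] + (-1,))
            w = _align(ctx, tuple(extra), joint).reshape(-1)
            mass = flat.sum(axis=tuple(range(n_out)))
            ok = mass > 1e-12
            if not ok.any():
                raise ValueError("estimand evaluated to zero mass; positivity is violated")
            norm = np.where(ok, mass, 1.0)
            w = np.where(ok, w, 0.0)
            w = w / w.sum()
            avg = ((flat / norm) * w).sum(axis=-1)
            f = _Factor(perm[:n_out], avg)
    total = f.values.sum()
    if total <= 0:
        raise ValueError("estimand evaluated to zero mass; positivity is violated")
    return _Factor(f.vars, f.values / total)
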