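"""Causal latent-variable models: per-node parametric families, priors, sampling.

A :class:`CausalLVM` couples an explicit-latent DAG with one :class:`NodeSpec`
per node.  Each node follows a parametric family whose location is a function
of a linear predictor ``eta = intercept + sum_p w_p * parent_p``:

``gaussian_linear``
    value = eta + Normal(0, sigma); the workhorse for (log-)expression data.
``bernoulli_logit``
    P(value = 1) = logistic(eta); binarized regulatory states.
``gamma``
    Gamma with mean exp(eta) (log link keeps the mean positive) and shape
    ``shape``; fluorescent-reporter style intensity measurements.
``hill_sigmoid``
    Normal(scale_cap * logistic(eta), sigma): a saturating Hill-type response
    capped at ``scale_cap`` (default 100, the initial molecule count used in
    the stochastic simulations).  Weights carry sign constraints: positive for
    *increase* edges, negative for *decrease* edges.  The sign convention is
    chosen so that a positive weight increases the mean.
``point``
    A point mass; only produced by graph mutilation of intervened nodes.

Interventions are simulated by :func:`mutilate_model` (clear the target's
parents, replace its family by a point mass), matching graph mutilation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .graphs import MixedGraph

__all__ = [
    "PriorSpec",
    "NodeSpec",
    "CausalLVM",
    "Dataset",
    "ModelError",
    "mutilate_model",
    "validate_model",
    "FAMILIES",
]


class ModelError(ValueError):
    pass


_ETA_CLIP = 30.0  # linear predictors are clipped before exp/logistic for stability


def _clip(eta):
    return np.clip(eta, -_ETA_CLIP, _ETA_CLIP)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------


class _Gaussian:
    name = "gaussian_linear"
    dispersion = "sigma"

    @staticmethod
    def mean(eta, disp, cap=None):
        return eta

    @staticmethod
    def sample(rng, eta, disp, cap=None):
        return eta + disp * rng.standard_normal(np.shape(eta))

    @staticmethod
    def logp(v, eta, disp, cap=None):
        r = (v - eta) / disp
        ll = -0.5 * np.log(2 * np.pi) - np.log(disp) - 0.5 * r * r
        g_eta = r / disp
        g_logdisp = float(np.sum(r * r - 1.0))
        return float(ll.sum()), g_eta, g_logdisp


class _BernoulliLogit:
    name = "bernoulli_logit"
    dispersion = None

    @staticmethod
    def mean(eta, disp=None, cap=None):
        return special.expit(eta)

    @staticmethod
    def sample(rng, eta, disp=None, cap=None):
        return (rng.random(np.shape(eta)) < special.expit(eta)).astype(float)

    @staticmethod
    def logp(v, eta, disp=None, cap=None):
        eta = _clip(eta)
        ll = v * eta - np.logaddexp(0.0, eta)
        g_eta = v - special.expit(eta)
        return float(ll.sum()), g_eta, 0.0


class _Gamma:
    """Gamma with log-link mean exp(eta) and shape parameter ``shape``."""

    name = "gamma"
    dispersion = "shape"

    @staticmethod
    def mean(eta, disp, cap=None):
        return np.exp(_clip(eta))

    @staticmethod
    def sample(rng, eta, disp, cap=None):
        mu = np.exp(_clip(eta))
        return rng.gamma(shape=disp, scale=mu / disp)

    @staticmethod
    def logp(v, eta, disp, cap=None):
        k = disp
        eta = _clip(eta)
        ll = k * np.log(k) - k * eta + (k - 1.0) * np.log(v) - k * v * np.exp(-eta) - special.gammaln(k)
        g_eta = k * (v * np.exp(-eta) - 1.0)
        dk = np.log(k) + 1.0 - eta + np.log(v) - v * np.exp(-eta) - special.digamma(k)
        return float(ll.sum()), g_eta, float(dk.sum() * k)


class _HillSigmoid:
    name = "hill_sigmoid"
    dispersion = "sigma"

    @staticmethod
    def mean(eta, disp=None, cap=100.0):
        return cap * special.expit(eta)

    @staticmethod
    def sample(rng, eta, disp, cap=100.0):
        return cap * special.expit(eta) + disp * rng.standard_normal(np.shape(eta))

    @staticmethod
    def logp(v, eta, disp, cap=100.0):
        p = special.expit(_clip(eta))
        m = cap * p
        r = (v - m) / disp
        ll = -0.5 * np.log(2 * np.pi) - np.log(disp) - 0.5 * r * r
        g_eta = (r / disp) * cap * p * (1.0 - p)
        g_logdisp = float(np.sum(r * r - 1.0))
        return float(ll.sum()), g_eta, g_logdisp


class _Point:
    name = "point"
    dispersion = None

    @staticmethod
    def mean(eta, disp=None, cap=None):
        return eta

    @staticmethod
    def sample(rng, eta, disp=None, cap=None):
        return np.asarray(eta, dtype=float).copy()

    @staticmethod
    def logp(v, eta, disp=None, cap=None):
        return 0.0, np.zeros(np.shape(v)), 0.0


FAMILIES = {f.name: f for f in (_Gaussian, _BernoulliLogit, _Gamma, _HillSigmoid, _Point)}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior for one scalar parameter, optionally sign-constrained."""

    location: float = 0.0
    scale: float = 10.0
    constraint: str = "none"  # none | positive | negative
    family: str = "normal"

    def __post_init__(self):
        if self.scale <= 0:
            raise ModelError("prior scale must be positive")
        if self.constraint not in ("none", "positive", "negative"):
            raise ModelError(f"unknown constraint {self.constraint!r}")
        if self.family != "normal":
            raise ModelError("only normal priors are supported")

    def sample(self, rng) -> float:
        if self.constraint == "none":
            return float(rng.normal(self.location, self.scale))
        a, b = ((0, np.inf) if self.constraint == "positive" else (-np.inf, 0))
        lo, hi = (a - self.location) / self.scale, (b - self.location) / self.scale
        return float(
            stats.truncnorm.rvs(lo, hi, loc=self.location, scale=self.scale, random_state=rng)
        )

    def satisfied_by(self, value: float) -> bool:
        if self.constraint == "positive":
            return value > 0
        if self.constraint == "negative":
            return value < 0
        return True


NONINFORMATIVE = PriorSpec(0.0, 10.0)


@dataclass(frozen=True)
class NodeSpec:
    """Family, parents and priors of one node.

    ``priors`` maps parameter names — ``w_<parent>`` for each parent weight,
    ``intercept``, and the family's dispersion (``sigma`` or ``shape``) — to
    :class:`PriorSpec`; unlisted parameters get the non-informative N(0, 10).
    """

    name: str
    family: str
    parents: tuple = ()
    priors: dict = field(default_factory=dict)
    scale_cap: float = 100.0

    def __post_init__(self):
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "priors", dict(self.priors))
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r} for node {self.name!r}")
        if self.scale_cap <= 0:
            raise ModelError("scale_cap must be positive")

    def parameter_names(self) -> list:
        if self.family == "point":
            return ["value"]
        names = [f"w_{p}" for p in self.parents] + ["intercept"]
        disp = FAMILIES[self.family].dispersion
        if disp:
            names.append(disp)
        return names

    def prior_for(self, param: str) -> PriorSpec:
        if param in self.priors:
            return self.priors[param]
        disp = FAMILIES[self.family].dispersion
        if param == disp:
            # dispersions are positive; default to a weakly-informative half-normal
            return PriorSpec(0.0, 10.0, constraint="positive")
        return NONINFORMATIVE

    def eta(self, params: dict, parent_values: dict) -> np.ndarray:
        eta = np.asarray(params["intercept"], dtype=float)
        for p in self.parents:
            eta = eta + params[f"w_{p}"] * np.asarray(parent_values[p], dtype=float)
        return eta


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Observations, one column per observed node, one row per replicate."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"kind": "observational"})

    def __post_init__(self):
        if len(self.frame) < 1:
            raise ModelError("a dataset needs at least one row")
        if self.frame.isna().any().any():
            raise ModelError("dataset contains missing entries")

    @property
    def columns(self):
        return list(self.frame.columns)

    @property
    def n(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        frame = pd.read_csv(path)
        try:
            with open(str(path) + ".json") as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            prov = {"kind": "observational"}
        return cls(frame, prov)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


@dataclass
class CausalLVM:
    """An explicit-latent DAG plus one parametric spec per node.

    This is the *model* object: build it once, then ``sample_observational``
    / ``sample_interventional`` to generate data, or ``fit`` (posterior
    sampling, see :mod:`causalpath.inference`) to obtain a
    :class:`~causalpath.inference.TrainedLVM` results object.
    """

    graph: MixedGraph
    node_specs: dict

    def __post_init__(self):
        self.node_specs = dict(self.node_specs)
        problems = validate_model(self)
        if problems:
            raise ModelError("invalid model: " + "; ".join(problems))

    # -- bookkeeping ---------------------------------------------------------

    @property
    def observed(self):
        return self.graph.observed

    @property
    def latent(self):
        return self.graph.latent

    def spec(self, node: str) -> NodeSpec:
        return self.node_specs[node]

    def admg(self) -> MixedGraph:
        """The latent projection of the model's graph."""
        return self.graph.latent_project()

    # -- parameters ----------------------------------------------------------

    def parameter_index(self) -> list:
        """(node, parameter) pairs in topological node order."""
        out = []
        for node in self.graph.topological_sort():
            for p in self.node_specs[node].parameter_names():
                out.append((node, p))
        return out

    def random_parameters(self, seed, overrides=None) -> dict:
        """Draw a full true-parameter assignment from the priors.

        Each parameter is drawn from its prior truncated to its sign
        constraint.  ``overrides`` maps ``node`` to ``{param: PriorSpec}`` and
        lets experiment builders draw selected parameters from a narrower
        generating law than the (possibly non-informative) inference prior.
        """
        rng = np.random.default_rng(seed)
        overrides = overrides or {}
        theta: dict = {}
        for node in self.graph.topological_sort():
            spec = self.node_specs[node]
            theta[node] = {}
            for p in spec.parameter_names():
                prior = overrides.get(node, {}).get(p, spec.prior_for(p))
                theta[node][p] = prior.sample(rng)
        return theta

    def check_theta(self, theta: dict) -> None:
        for node in self.graph.nodes:
            spec = self.node_specs[node]
            for p in spec.parameter_names():
                if node not in theta or p not in theta[node]:
                    raise ModelError(f"missing parameter {p!r} for node {node!r}")
                if not spec.prior_for(p).satisfied_by(theta[node][p]):
                    raise ModelError(f"parameter {node}.{p} violates its sign constraint")
            disp = FAMILIES[spec.family].dispersion
            if disp and theta[node][disp] <= 0:
                raise ModelError(f"dispersion {node}.{disp} must be positive")

    # -- sampling ------------------------------------------------------------

    def _ancestral(self, theta, n, rng, do_map=None) -> pd.DataFrame:
        do_map = do_map or {}
        values: dict = {}
        for node in self.graph.topological_sort():
            if node in do_map:
                values[node] = np.full(n, float(do_map[node]))
                continue
            spec = self.node_specs[node]
            fam = FAMILIES[spec.family]
            if spec.family == "point":
                eta = np.full(n, float(theta[node]["value"]))
                disp = None
            else:
                eta = spec.eta(theta[node], values)
                eta = np.broadcast_to(np.asarray(eta, dtype=float), (n,))
                disp = theta[node].get(fam.dispersion) if fam.dispersion else None
            values[node] = fam.sample(rng, eta, disp, cap=spec.scale_cap)
        return pd.DataFrame(values)

    def sample_observational(self, theta, n, seed, return_latent=False) -> Dataset:
        """Ancestral sampling in topological order; latent columns are dropped
        from the returned dataset unless ``return_latent``."""
        self.check_theta(theta)
        rng = np.random.default_rng(seed)
        frame = self._ancestral(theta, int(n), rng)
        cols = sorted(frame.columns) if return_latent else sorted(self.observed)
        return Dataset(frame[cols], {"kind": "observational", "n": int(n), "seed": seed})

    def sample_interventional(self, theta, do_map: dict, n, seed, return_latent=False) -> Dataset:
        """Sampling from the mutilated model with targets held at their do-values."""
        self.check_theta(theta)
        bad = set(do_map) - self.observed
        if bad:
            raise ModelError(
                f"interventions must target observed nodes; latent/unknown: {sorted(bad)}"
            )
        rng = np.random.default_rng(seed)
        frame = self._ancestral(theta, int(n), rng, do_map=do_map)
        cols = sorted(frame.columns) if return_latent else sorted(self.observed)
        return Dataset(
            frame[cols], {"kind": "interventional", "do": dict(do_map), "n": int(n), "seed": seed}
        )

    def mutilate(self, do_map: dict) -> "CausalLVM":
        return mutilate_model(self, do_map)

    def fit(self, data: Dataset, **settings):
        from .inference import fit

        return fit(self, data, **settings)

    # -- config I/O ----------------------------------------------------------

    def to_config(self) -> dict:
        nodes = []
        for node in self.graph.topological_sort():
            spec = self.node_specs[node]
            nodes.append(
                {
                    "name": node,
                    "family": spec.family,
                    "parents": list(spec.parents),
                    "latent": node in self.latent,
                    "scale_cap": spec.scale_cap,
                    "priors": {
                        p: {
                            "location": pr.location,
                            "scale": pr.scale,
                            "constraint": pr.constraint,
                        }
                        for p, pr in spec.priors.items()
                    },
                }
            )
        return {"nodes": nodes}

    @classmethod
    def from_config(cls, config: dict) -> "CausalLVM":
        directed, latent, specs = set(), set(), {}
        names = set()
        for nd in config["nodes"]:
            name = nd["name"]
            names.add(name)
            if nd.get("latent"):
                latent.add(name)
            for p in nd.get("parents", ()):
                directed.add((p, name))
            priors = {
                k: PriorSpec(v.get("location", 0.0), v.get("scale", 10.0), v.get("constraint", "none"))
                for k, v in nd.get("priors", {}).items()
            }
            specs[name] = NodeSpec(
                name,
                nd["family"],
                tuple(nd.get("parents", ())),
                priors,
                nd.get("scale_cap", 100.0),
            )
        graph = MixedGraph(names, directed, (), latent)
        return cls(graph, specs)

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CausalLVM":
        import yaml

        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def mutilate_model(lvm: CausalLVM, do_map: dict) -> CausalLVM:
    """The model analogue of graph mutilation: clear the targets' parents and
    replace their family by a point mass at the do-value.  The input model is
    not modified."""
    bad = set(do_map) - lvm.observed
    if bad:
        raise ModelError(f"interventions must target observed nodes; latent/unknown: {sorted(bad)}")
    graph = lvm.graph.mutilate_incoming(set(do_map))
    specs = dict(lvm.node_specs)
    for node, value in do_map.items():
        specs[node] = NodeSpec(node, "point", (), {"value": PriorSpec(float(value), 1e-9)})
    return CausalLVM(graph, specs)


def validate_model(lvm) -> list:
    """Structural invariant check; returns a list of violations (empty = valid)."""
    problems = []
    graph, specs = lvm.graph, lvm.node_specs
    if graph.bidirected:
        problems.append("model graphs are explicit-latent DAGs; project ADMGs separately")
    for node in graph.nodes:
        if node not in specs:
            problems.append(f"node {node!r} has no spec")
            continue
        spec = specs[node]
        if spec.name != node:
            problems.append(f"spec name {spec.name!r} does not match node {node!r}")
        if frozenset(spec.parents) != graph.parents(node):
            problems.append(
                f"parents of {node!r} in spec {sorted(spec.parents)} != graph {sorted(graph.parents(node))}"
            )
        if len(spec.parents) != len(set(spec.parents)):
            problems.append(f"duplicate parents in spec of {node!r}")
        for p, pr in spec.priors.items():
            if p not in spec.parameter_names():
                problems.append(f"prior for unknown parameter {node}.{p}")
    for node in specs:
        if node not in graph.nodes:
            problems.append(f"spec for unknown node {node!r}")
    return problems
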