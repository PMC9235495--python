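"""Interventional query estimation from a trained causal LVM.

The main entry point, :func:`estimate_query`, follows the
identify–mutilate–sample recipe: check that the query is identifiable on the
model's latent projection (refusing otherwise), mutilate the model, then for
each of S posterior parameter draws ancestrally sample all variables L times
and pool the outcome values.  The result is a posterior-predictive
interventional distribution (or its expectation).

The module also houses the independent estimators used to cross-check the
machinery: plug-in evaluations of the back-door and front-door adjustment
formulas computed directly from observational data (no posterior sampling
involved), the exact closed form for all-Gaussian models, and the
simulation ground truth obtained by sampling the true-parameter model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import derive_seed
from .identify import (
    CausalQuery,
    DiscreteJoint,
    IdentifyResult,
    evaluate_estimand,
    identify,
)
from .inference import TrainedLVM
from .scm import CausalLVM, Dataset, ModelError, mutilate_model

__all__ = [
    "QueryEstimate",
    "NonIdentifiableQueryError",
    "estimate_query",
    "ground_truth_query",
    "plugin_backdoor",
    "plugin_frontdoor",
    "closed_form_linear_gaussian",
    "distribution_discrepancy",
]


class NonIdentifiableQueryError(Exception):
    """Principled refusal: the query has no do-free estimand on this graph."""

    def __init__(self, result: IdentifyResult):
        self.result = result
        super().__init__(
            "query is not identifiable on the model's latent projection"
            + (f": {result.reason}" if result.reason else "")
        )


@dataclass
class QueryEstimate:
    """Pooled interventional outcome draws with density and expectation summaries.

    ``draws`` holds S*L pooled rows (one column per outcome plus ``_theta``,
    the posterior-draw index each row came from); ``per_theta`` the per-draw
    outcome means (S rows), which reproduce the thin per-parameter predictive
    curves of the convergence displays.
    """

    draws: pd.DataFrame
    per_theta: pd.DataFrame
    expectation: dict
    meta: dict = field(default_factory=dict)

    @property
    def outcomes(self) -> list:
        return [c for c in self.draws.columns if c != "_theta"]

    def density(self, outcome: str | None = None, grid_size: int = 512):
        """Gaussian KDE with Silverman bandwidth on a grid spanning the draws
        plus three bandwidths on each side.  Returns (grid, pdf)."""
        outcome = outcome or self.outcomes[0]
        x = self.draws[outcome].to_numpy()
        if np.std(x) < 1e-12:
            grid = np.linspace(x.mean() - 1, x.mean() + 1, grid_size)
            pdf = np.zeros(grid_size)
            pdf[np.argmin(np.abs(grid - x.mean()))] = 1.0 / (grid[1] - grid[0])
            return grid, pdf
        kde = stats.gaussian_kde(x, bw_method="silverman")
        bw = kde.factor * x.std(ddof=1)
        grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
        return grid, kde(grid)

    def to_json_dict(self) -> dict:
        return {"expectation": self.expectation, "meta": self.meta}

    def save(self, prefix) -> None:
        import json

        self.draws.to_csv(f"{prefix}_draws.csv", index=False)
        grid, pdf = self.density()
        pd.DataFrame({"grid": grid, "pdf": pdf}).to_csv(f"{prefix}_density.csv", index=False)
        with open(f"{prefix}.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=float)


def _pooled_estimate(lvm_mut, thetas, query, l_draws, seed, meta) -> QueryEstimate:
    outcomes = list(query.outcomes)
    rows = []
    per_theta = []
    rng = np.random.default_rng(seed)
    do_patch = {k: {"value": float(v)} for k, v in query.targets.items()}
    for s, theta in enumerate(thetas):
        th = {**theta, **do_patch}
        d = lvm_mut.sample_observational(th, l_draws, seed=int(rng.integers(2**31)))
        block = d.frame[outcomes]
        rows.append(block.assign(_theta=s))
        per_theta.append(block.mean())
    draws = pd.concat(rows, ignore_index=True)
    per_theta = pd.DataFrame(per_theta)
    expectation = {o: float(draws[o].mean()) for o in outcomes}
    return QueryEstimate(draws, per_theta, expectation, meta)


def estimate_query(
    trained: TrainedLVM,
    query: CausalQuery,
    s_draws: int = 500,
    l_draws: int = 20,
    seed: int = 0,
    force_nonidentifiable: bool = False,
) -> QueryEstimate:
    """Estimate an identifiable causal query from a trained LVM.

    Refuses non-identifiable queries with :class:`NonIdentifiableQueryError`
    unless ``force_nonidentifiable`` is set — that flag exists solely to
    demonstrate the bias of estimates whose queries are not identified.
    """
    if s_draws < 1 or l_draws < 1:
        raise ValueError("s_draws and l_draws must both be at least 1")
    query.validate_against(trained.lvm.graph)
    result = identify(trained.lvm.admg(), query)
    if not result.identifiable and not force_nonidentifiable:
        raise NonIdentifiableQueryError(result)
    mut = mutilate_model(trained.lvm, query.targets)
    rng = np.random.default_rng(derive_seed(seed, "theta-subsample"))
    idx = rng.integers(0, trained.n_draws, size=s_draws)
    thetas = [trained.parameter_assignment(int(i)) for i in idx]
    meta = {
        "S": s_draws,
        "L": l_draws,
        "seed": seed,
        "identify_method": result.method,
        "identifiable": result.identifiable,
        "forced": bool(not result.identifiable),
        "do": dict(query.targets),
        "form": query.form,
    }
    return _pooled_estimate(mut, thetas, query, l_draws, seed, meta)


def ground_truth_query(
    lvm: CausalLVM, theta_true: dict, query: CausalQuery, n: int = 10000, seed: int = 0
) -> QueryEstimate:
    """The simulation ground truth: the same mutilate-and-sample procedure with
    the posterior replaced by a point mass at the true parameters."""
    lvm.check_theta(theta_true)
    mut = mutilate_model(lvm, query.targets)
    meta = {"S": 1, "L": n, "seed": seed, "identify_method": "ground_truth",
            "do": dict(query.targets), "form": query.form}
    return _pooled_estimate(mut, [theta_true], query, n, seed, meta)


# ---------------------------------------------------------------------------
# plug-in adjustment estimators (independent of the HMC machinery)
# ---------------------------------------------------------------------------


def _is_discrete(cols) -> bool:
    return all(np.allclose(c, np.round(c)) and len(np.unique(c)) <= 12 for c in cols)


def _empirical_joint(data: Dataset, cols) -> DiscreteJoint:
    arrays = [data.column(c) for c in cols]
    support = {c: np.unique(a) for c, a in zip(cols, arrays)}
    shape = tuple(len(support[c]) for c in cols)
    counts = np.zeros(shape)
    idx = tuple(np.searchsorted(support[c], a) for c, a in zip(cols, arrays))
    np.add.at(counts, idx, 1.0)
    return DiscreteJoint(support, counts / counts.sum())


def _design(columns, degree=2):
    """Polynomial design matrix with pairwise interactions (degree <= 2)."""
    cols = [np.ones_like(columns[0])]
    cols.extend(columns)
    if degree >= 2:
        for i in range(len(columns)):
            for j in range(i, len(columns)):
                cols.append(columns[i] * columns[j])
    return np.column_stack(cols)


def _ols(y, columns):
    X = _design(columns)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    return beta, float(np.sqrt(resid @ resid / dof))


def _predict(beta, columns):
    return _design(columns) @ beta


def plugin_backdoor(data: Dataset, x_node: str, y_node: str, z_set, x_value) -> float:
    """Back-door adjustment E[Y|do(x')] = sum_z E[Y|x', z] P(z), evaluated from
    observational data by regression (continuous) or exact tables (discrete)."""
    z_set = [z_set] if isinstance(z_set, str) else sorted(z_set)
    cols = [x_node, y_node] + list(z_set)
    arrays = [data.column(c) for c in cols]
    if _is_discrete(arrays):
        joint = _empirical_joint(data, cols)
        from .identify import _backdoor_estimand

        est = _backdoor_estimand(x_node, (y_node,), tuple(z_set))
        f = evaluate_estimand(est, joint, {x_node: x_value}, outcomes=(y_node,))
        return float(np.sum(joint.support[y_node] * f.values))
    x = data.column(x_node)
    if np.std(x) < 1e-12:
        raise ModelError("degenerate support: the cause never varies (P(x, z) > 0 fails)")
    y = data.column(y_node)
    zs = [data.column(z) for z in z_set]
    beta, _ = _ols(y, [x] + zs)
    xs = np.full_like(y, float(x_value))
    return float(np.mean(_predict(beta, [xs] + zs)))


def plugin_frontdoor(
    data: Dataset, x_node: str, y_node: str, z_node: str, x_value, seed: int = 0, m_z: int = 2000
) -> float:
    """Front-door adjustment E[Y|do(x')] = int_z P(z|x') int_x E[Y|z,x] P(x).

    Continuous data: regress E[Y|x, z] flexibly, model P(z|x') as Gaussian
    around a regression of z on x, and average by Monte Carlo.  Discrete data:
    exact evaluation on the empirical joint table.
    """
    cols = [x_node, y_node, z_node]
    arrays = [data.column(c) for c in cols]
    if _is_discrete(arrays):
        joint = _empirical_joint(data, cols)
        from .identify import _frontdoor_estimand

        est = _frontdoor_estimand((x_node,), (y_node,), (z_node,))
        f = evaluate_estimand(est, joint, {x_node: x_value}, outcomes=(y_node,))
        return float(np.sum(joint.support[y_node] * f.values))
    x, y, z = arrays
    if np.std(x) < 1e-12 or np.std(z) < 1e-12:
        raise ModelError(
            "degenerate support for the front-door plug-in (its precondition P(x, z) > 0 fails)"
        )
    beta_y, _ = _ols(y, [x, z])
    beta_z, sd_z = _ols(z, [x])
    rng = np.random.default_rng(seed)
    z_mean = float(_predict(beta_z, [np.array([float(x_value)])])[0])
    z_samp = z_mean + sd_z * rng.standard_normal(m_z)
    # E over observed x of E[Y | x, z] for each sampled z
    sub = x if len(x) <= 2000 else rng.choice(x, size=2000, replace=False)
    total = 0.0
    for zv in z_samp:
        zz = np.full_like(sub, zv)
        total += float(np.mean(_predict(beta_y, [sub, zz])))
    return total / m_z


# ---------------------------------------------------------------------------
# exact linear-Gaussian truth
# ---------------------------------------------------------------------------


def closed_form_linear_gaussian(lvm: CausalLVM, theta: dict, query: CausalQuery):
    """Exact interventional mean and variance for all-Gaussian models, by
    propagating means and covariances through the mutilated graph.

    Returns ``(mean, variance)`` floats for a single outcome, else two dicts.
    """
    for node in lvm.graph.nodes:
        fam = lvm.spec(node).family
        if fam not in ("gaussian_linear", "point"):
            raise ModelError(f"closed form requires gaussian_linear nodes; {node!r} is {fam!r}")
    lvm.check_theta(theta)
    query.validate_against(lvm.graph)
    graph = lvm.graph.mutilate_incoming(set(query.targets))
    order = graph.topological_sort()
    idx = {n: i for i, n in enumerate(order)}
    d = len(order)
    mean = np.zeros(d)
    cov = np.zeros((d, d))
    for node in order:
        j = idx[node]
        if node in query.targets:
            mean[j] = float(query.targets[node])
            continue
        spec = lvm.spec(node)
        if spec.family == "point":
            mean[j] = float(theta[node]["value"])
            continue
        th = theta[node]
        mean[j] = th["intercept"] + sum(
            th[f"w_{p}"] * mean[idx[p]] for p in graph.parents(node)
        )
        pa = sorted(graph.parents(node))
        w = np.array([th[f"w_{p}"] for p in pa])
        pidx = [idx[p] for p in pa]
        for k in range(d):
            if k == j:
                continue
            cov[j, k] = cov[k, j] = float(w @ cov[np.ix_(pidx, [k])].ravel()) if pa else 0.0
        cov[j, j] = float(w @ cov[np.ix_(pidx, pidx)] @ w) + th["sigma"] ** 2 if pa else th["sigma"] ** 2
    means = {o: float(mean[idx[o]]) for o in query.outcomes}
    variances = {o: float(cov[idx[o], idx[o]]) for o in query.outcomes}
    if len(query.outcomes) == 1:
        (o,) = query.outcomes
        return means[o], variances[o]
    return means, variances


# ---------------------------------------------------------------------------
# comparison metric for predictive distributions
# ---------------------------------------------------------------------------


def distribution_discrepancy(draws_a: np.ndarray, draws_b: np.ndarray) -> float:
    """Total-variation-style distance between two sample sets: half the L1
    distance between their Silverman-KDE densities on a common grid."""
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.1 * (hi - lo + 1e-9)
    grid = np.linspace(lo - pad, hi + pad, 512)
    fa = stats.gaussian_kde(a, bw_method="silverman")(grid)
    fb = stats.gaussian_kde(b, bw_method="silverman")(grid)
    return float(0.5 * np.trapezoid(np.abs(fa - fb), grid))
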