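"""Posterior inference for causal LVMs with Hamiltonian Monte Carlo.

The joint log density is the model's product of node conditionals,
``prod_j P(Vj | Pa(Vj)) * prod_l P(Ul | Pa(Ul))``, with the per-replicate
values of every latent node treated as local latent parameters (sampled, not
analytically marginalized, so the scheme is family-generic).  Latent Gaussian
nodes use a non-centered parameterization ``u_i = eta_i + sigma * eps_i`` with
standard-normal ``eps_i``, which keeps the HMC geometry benign at small n.

Sampling is a No-U-Turn sampler with dual-averaging step-size adaptation and
a diagonal mass matrix estimated during warmup; gradients of the log posterior
are computed analytically per family (see :mod:`causalpath.scm`).  Constrained
parameters (positive dispersions, sign-constrained weights) are sampled on a
log scale with the appropriate Jacobian.

``fit`` returns a :class:`TrainedLVM` results object: posterior draws,
split-R-hat / effective-sample-size diagnostics (via arviz), a ``summary()``
table, and draw extraction for interventional query estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import spawn_seeds
from .scm import FAMILIES, CausalLVM, Dataset, ModelError

__all__ = ["fit", "TrainedLVM", "SamplerSettings", "diagnostics_report"]


# ---------------------------------------------------------------------------
# parameter packing and the log posterior
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    node: str
    param: str  # parameter name, or "_eps" for per-row latent innovations
    start: int
    size: int
    transform: str  # identity | exp | negexp | eps


class _Posterior:
    """Flat-vector log posterior with analytic gradient for one (lvm, data) pair.

    ``latent_param`` selects the parameterization of per-replicate latent
    values: ``"noncentered"`` (u = eta + sigma * eps, eps ~ N(0,1)) suits
    weakly-informed latents (small n); ``"centered"`` (u sampled directly with
    prior N(eta, sigma)) suits strongly-informed latents (large n), where the
    non-centered form creates pathological curvature.
    """

    def __init__(self, lvm: CausalLVM, data: Dataset, latent_param: str = "noncentered"):
        if latent_param not in ("centered", "noncentered"):
            raise ModelError(f"unknown latent parameterization {latent_param!r}")
        self.latent_param = latent_param
        if set(data.columns) != set(lvm.observed):
            raise ModelError(
                f"data columns {sorted(data.columns)} do not match observed nodes "
                f"{sorted(lvm.observed)}"
            )
        self.lvm = lvm
        self.n = data.n
        self.order = lvm.graph.topological_sort()
        self.data = {c: data.column(c) for c in data.columns}
        for c, v in self.data.items():
            if not np.all(np.isfinite(v)):
                raise ModelError(f"non-finite values in data column {c!r}")
        self.blocks: list[_Block] = []
        pos = 0
        for node in self.order:
            spec = lvm.spec(node)
            if spec.family == "point":
                continue
            if node in lvm.latent and spec.family != "gaussian_linear":
                raise ModelError(
                    f"latent node {node!r} must be gaussian_linear for HMC "
                    f"(got {spec.family!r})"
                )
            for p in spec.parameter_names():
                prior = spec.prior_for(p)
                disp = FAMILIES[spec.family].dispersion
                if p == disp or prior.constraint == "positive":
                    tr = "exp"
                elif prior.constraint == "negative":
                    tr = "negexp"
                else:
                    tr = "identity"
                self.blocks.append(_Block(node, p, pos, 1, tr))
                pos += 1
            if node in lvm.latent:
                self.blocks.append(_Block(node, "_eps", pos, self.n, "eps"))
                pos += self.n
        self.dim = pos
        self._scalar_blocks = [b for b in self.blocks if b.param != "_eps"]
        self._eps_blocks = {b.node: b for b in self.blocks if b.param == "_eps"}

    # -- transforms ----------------------------------------------------------

    def unpack(self, q: np.ndarray) -> dict:
        """Constrained global parameter values keyed by (node, param)."""
        out = {}
        for b in self._scalar_blocks:
            z = q[b.start]
            if b.transform == "exp":
                out[(b.node, b.param)] = math.exp(min(max(z, -60.0), 50.0))
            elif b.transform == "negexp":
                out[(b.node, b.param)] = -math.exp(min(max(z, -60.0), 50.0))
            else:
                out[(b.node, b.param)] = z
        return out

    def _initial_values(self) -> dict:
        """Data-informed starting values per (node, param).

        Saturating families (Hill sigmoid, and any sign-constrained weight on
        an abundance-scale parent) must start in their responsive region: a
        weight of order 1 on a ~100-molecule parent pins the sigmoid at its
        cap where the weight gradient vanishes and the sampler cannot escape.
        Weights therefore start at a scale inverse to their parent's spread,
        and intercepts at the value matching the observed node mean.
        """
        init: dict = {}
        for node in self.order:
            spec = self.lvm.spec(node)
            if spec.family == "point":
                continue
            col = self.data.get(node)
            parent_stats = {}
            for p in spec.parents:
                if p in self.data:
                    parent_stats[p] = (float(self.data[p].mean()), float(self.data[p].std()))
                else:
                    parent_stats[p] = (0.0, 1.0)  # latent parents are unit-scale
            eta0 = 0.0
            for p in spec.parents:
                prior = spec.prior_for(f"w_{p}")
                m, s = parent_stats[p]
                if prior.constraint in ("positive", "negative"):
                    w0 = 0.25 / max(s, 1e-3)
                    if prior.constraint == "negative":
                        w0 = -w0
                else:
                    w0 = 0.0
                init[(node, f"w_{p}")] = w0
                eta0 += w0 * m
            prior = spec.prior_for("intercept")
            if prior.scale <= 2.0 and prior.location != 0.0:
                init[(node, "intercept")] = prior.location  # informative prior centre
            elif col is None:
                init[(node, "intercept")] = 0.0
            elif spec.family == "gaussian_linear":
                init[(node, "intercept")] = float(col.mean()) - eta0
            elif spec.family == "gamma":
                init[(node, "intercept")] = float(np.log(max(col.mean(), 1e-6))) - eta0
            elif spec.family in ("bernoulli_logit", "hill_sigmoid"):
                cap = spec.scale_cap if spec.family == "hill_sigmoid" else 1.0
                m = min(max(float(col.mean()) / cap, 0.05), 0.95)
                init[(node, "intercept")] = float(np.log(m / (1 - m))) - eta0
            else:
                init[(node, "intercept")] = 0.0
            disp = FAMILIES[spec.family].dispersion
            if disp == "sigma":
                init[(node, "sigma")] = float(max(col.std(), 0.1)) if col is not None else 1.0
            elif disp == "shape":
                init[(node, "shape")] = 2.0
        return init

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        q = np.zeros(self.dim)
        init = self._initial_values()
        for b in self.blocks:
            if b.param == "_eps":
                q[b.start : b.start + b.size] = 0.1 * rng.standard_normal(b.size)
                continue
            v = init.get((b.node, b.param))
            if v is None or (b.transform == "exp" and v <= 0) or (b.transform == "negexp" and v >= 0):
                v = {"exp": 1.0, "negexp": -1.0}.get(b.transform, 0.0 if v is None else v)
            if b.transform == "exp":
                z = math.log(max(v, 1e-3))
            elif b.transform == "negexp":
                z = math.log(max(-v, 1e-3))
            else:
                z = v
            q[b.start] = z + 0.05 * rng.standard_normal()
        return q

    # -- log posterior and gradient -----------------------------------------

    def logp_grad(self, q: np.ndarray):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp, grad = self._logp_grad_raw(q)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(q)
        return lp, grad

    def _logp_grad_raw(self, q: np.ndarray):
        grad = np.zeros_like(q)
        lp = 0.0
        params: dict = {}
        # scalar parameters: transform, prior, Jacobian
        for b in self._scalar_blocks:
            z = q[b.start]
            prior = self.lvm.spec(b.node).prior_for(b.param)
            if b.transform == "identity":
                v = z
                dv = 1.0
            else:
                z = min(max(z, -60.0), 50.0)
                v = math.exp(z)
                if b.transform == "negexp":
                    v = -v
                dv = v  # d(value)/d(z) = value for value = ±exp(z)
                lp += z  # log-Jacobian of the log transform
                grad[b.start] += 1.0
            params[(b.node, b.param)] = v
            r = (v - prior.location) / prior.scale
            lp += -0.5 * r * r - math.log(prior.scale) - 0.5 * math.log(2 * math.pi)
            grad[b.start] += -(r / prior.scale) * dv
        # forward pass: latent values; likelihood of observed nodes
        values: dict = {}
        dval: dict = {}
        eps: dict = {}
        for node in self.order:
            spec = self.lvm.spec(node)
            if spec.family == "point":
                values[node] = np.full(self.n, params[(node, "value")])
                continue
            if node in self.lvm.latent:
                blk = self._eps_blocks[node]
                raw = q[blk.start : blk.start + self.n]
                eta = np.full(self.n, params[(node, "intercept")])
                for p in spec.parents:
                    eta = eta + params[(node, f"w_{p}")] * values[p]
                sigma = params[(node, "sigma")]
                if self.latent_param == "noncentered":
                    values[node] = eta + sigma * raw
                    eps[node] = raw
                    lp += -0.5 * float(raw @ raw) - 0.5 * self.n * math.log(2 * math.pi)
                else:
                    values[node] = raw
                    r = (raw - eta) / sigma
                    eps[node] = r
                    lp += (
                        -0.5 * float(r @ r)
                        - self.n * math.log(sigma)
                        - 0.5 * self.n * math.log(2 * math.pi)
                    )
                dval[node] = np.zeros(self.n)
                continue
            v = self.data[node]
            eta = np.full(self.n, params[(node, "intercept")])
            for p in spec.parents:
                src = values[p] if p in self.lvm.latent or self.lvm.spec(p).family == "point" else self.data[p]
                eta = eta + params[(node, f"w_{p}")] * src
            fam = FAMILIES[spec.family]
            disp = params.get((node, fam.dispersion)) if fam.dispersion else None
            ll, g_eta, g_logdisp = fam.logp(v, eta, disp, cap=spec.scale_cap)
            lp += ll
            self._scatter_eta_grads(node, spec, g_eta, g_logdisp, params, values, dval, grad, q)
        # backward pass through latent values
        for node in reversed(self.order):
            if node not in self.lvm.latent:
                continue
            spec = self.lvm.spec(node)
            d = dval[node]
            blk = self._eps_blocks[node]
            sigma = params[(node, "sigma")]
            b_sig = self._index()[(node, "sigma")]
            if self.latent_param == "noncentered":
                e = eps[node]
                grad[blk.start : blk.start + self.n] += d * sigma - e
                self._grad_scalar(node, "intercept", float(d.sum()), params, grad)
                # sigma is sampled as log(sigma): d(value)/d(log sigma) = sigma * eps
                grad[b_sig.start] += float((d * e).sum()) * sigma
                for p in spec.parents:
                    src = values[p] if p in self.lvm.latent else self.data[p]
                    self._grad_scalar(node, f"w_{p}", float((d * src).sum()), params, grad)
                    if p in self.lvm.latent:
                        dval[p] += d * params[(node, f"w_{p}")]
            else:
                r = eps[node]  # (u - eta) / sigma
                grad[blk.start : blk.start + self.n] += d - r / sigma
                self._grad_scalar(node, "intercept", float((r / sigma).sum()), params, grad)
                grad[b_sig.start] += float((r * r).sum()) - self.n
                for p in spec.parents:
                    src = values[p] if p in self.lvm.latent else self.data[p]
                    self._grad_scalar(node, f"w_{p}", float(((r / sigma) * src).sum()),
                                      params, grad)
                    if p in self.lvm.latent:
                        dval[p] += (r / sigma) * params[(node, f"w_{p}")]
        return lp, grad

    def _index(self):
        if not hasattr(self, "_idx"):
            self._idx = {(b.node, b.param): b for b in self._scalar_blocks}
        return self._idx

    def _grad_scalar(self, node, param, g_value, params, grad, logscale_direct=None):
        """Add d(lp)/d(value) * d(value)/d(coordinate) for one scalar parameter."""
        b = self._index()[(node, param)]
        if b.transform == "identity":
            grad[b.start] += g_value
        else:
            if logscale_direct is not None:
                grad[b.start] += logscale_direct
            else:
                grad[b.start] += g_value * abs(params[(node, param)]) * (
                    1.0 if b.transform == "exp" else -1.0
                )

    def _scatter_eta_grads(self, node, spec, g_eta, g_logdisp, params, values, dval, grad, q):
        idx = self._index()
        fam = FAMILIES[spec.family]
        b_int = idx[(node, "intercept")]
        grad[b_int.start] += float(g_eta.sum())
        for p in spec.parents:
            w = params[(node, f"w_{p}")]
            src = values[p] if p in self.lvm.latent or self.lvm.spec(p).family == "point" else self.data[p]
            g_w = float((g_eta * src).sum())
            b_w = idx[(node, f"w_{p}")]
            if b_w.transform == "identity":
                grad[b_w.start] += g_w
            else:
                grad[b_w.start] += g_w * w  # d(w)/d(z) = w for w = ±exp(z)
            if p in self.lvm.latent:
                dval[p] += g_eta * w
        if fam.dispersion:
            b_d = idx[(node, fam.dispersion)]
            grad[b_d.start] += g_logdisp  # families return d/d log(disp)


class _CollapsedGaussianPosterior:
    """Collapsed likelihood for all-Gaussian models.

    When every node is ``gaussian_linear`` the per-replicate latent values can
    be marginalized exactly: with strictly-triangular weight matrix B,
    intercepts b and noise variances D, the observed vector is multivariate
    normal with mean ``(A b)_O`` and covariance ``(A D A^T)_OO`` where
    ``A = (I - B)^{-1}``.  The likelihood then depends on the data only through
    its first two moments, making the gradient cost independent of n.
    """

    def __init__(self, lvm: CausalLVM, data: Dataset):
        if set(data.columns) != set(lvm.observed):
            raise ModelError("data columns do not match observed nodes")
        if any(lvm.spec(nd).family != "gaussian_linear" for nd in lvm.graph.nodes):
            raise ModelError("collapsed likelihood requires all-gaussian models")
        self.lvm = lvm
        self.n = data.n
        self.order = lvm.graph.topological_sort()
        self.idx = {nd: i for i, nd in enumerate(self.order)}
        self.obs = [i for i, nd in enumerate(self.order) if nd in lvm.observed]
        X = np.column_stack([data.column(nd) for nd in self.order if nd in lvm.observed])
        if not np.all(np.isfinite(X)):
            raise ModelError("non-finite values in data")
        self.xbar = X.mean(axis=0)
        Xc = X - self.xbar
        self.S = (Xc.T @ Xc) / self.n
        self.data = {c: data.column(c) for c in data.columns}  # for initialization
        self.blocks: list[_Block] = []
        pos = 0
        for node in self.order:
            spec = lvm.spec(node)
            for p in spec.parameter_names():
                prior = spec.prior_for(p)
                if p == "sigma" or prior.constraint == "positive":
                    tr = "exp"
                elif prior.constraint == "negative":
                    tr = "negexp"
                else:
                    tr = "identity"
                self.blocks.append(_Block(node, p, pos, 1, tr))
                pos += 1
        self.dim = pos
        self._scalar_blocks = self.blocks

    unpack = _Posterior.unpack
    initial_position = _Posterior.initial_position
    _initial_values = _Posterior._initial_values
    _index = _Posterior._index

    def logp_grad(self, q: np.ndarray):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                lp, grad = self._logp_grad_raw(q)
            except np.linalg.LinAlgError:
                return -np.inf, np.zeros_like(q)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(q)
        return lp, grad

    def _logp_grad_raw(self, q: np.ndarray):
        grad = np.zeros_like(q)
        lp = 0.0
        params: dict = {}
        for b in self._scalar_blocks:
            z = q[b.start]
            prior = self.lvm.spec(b.node).prior_for(b.param)
            if b.transform == "identity":
                v, dv = z, 1.0
            else:
                z = min(max(z, -60.0), 50.0)
                v = math.exp(z)
                if b.transform == "negexp":
                    v = -v
                dv = v
                lp += z
                grad[b.start] += 1.0
            params[(b.node, b.param)] = v
            r = (v - prior.location) / prior.scale
            lp += -0.5 * r * r - math.log(prior.scale) - 0.5 * math.log(2 * math.pi)
            grad[b.start] += -(r / prior.scale) * dv
        d = len(self.order)
        B = np.zeros((d, d))
        bvec = np.zeros(d)
        sig = np.zeros(d)
        for node in self.order:
            j = self.idx[node]
            bvec[j] = params[(node, "intercept")]
            sig[j] = params[(node, "sigma")]
            for p in self.lvm.spec(node).parents:
                B[j, self.idx[p]] = params[(node, f"w_{p}")]
        A = np.linalg.inv(np.eye(d) - B)
        mu = A @ bvec
        Sigma = (A * (sig**2)) @ A.T
        O = self.obs
        M = Sigma[np.ix_(O, O)]
        L = np.linalg.cholesky(M)
        Minv = np.linalg.inv(M)
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        r = self.xbar - mu[O]
        n = self.n
        d_o = len(O)
        lp += -0.5 * n * (logdet + float(np.trace(Minv @ self.S)) + float(r @ Minv @ r)
                          + d_o * math.log(2 * math.pi))
        G_mu = n * (Minv @ r)                       # d lp / d mu_O
        G_M = 0.5 * n * (Minv @ (self.S + np.outer(r, r)) @ Minv - Minv)
        T = A[O, :]                                 # t_j = A[O, j] columns
        SigO = Sigma[O, :]                          # Sigma_full[O, i] columns
        gb = T.T @ G_mu                             # d lp / d b_j
        GT = G_M @ T                                # columns G_M t_j
        idxmap = self._index()
        for node in self.order:
            j = self.idx[node]
            blk = idxmap[(node, "intercept")]
            grad[blk.start] += float(gb[j])
            blk = idxmap[(node, "sigma")]
            grad[blk.start] += float(T[:, j] @ G_M @ T[:, j]) * 2.0 * sig[j] ** 2
            for p in self.lvm.spec(node).parents:
                i = self.idx[p]
                g_w = float(gb[j] * mu[i] + 2.0 * (GT[:, j] @ SigO[:, i]))
                blk = idxmap[(node, f"w_{p}")]
                if blk.transform == "identity":
                    grad[blk.start] += g_w
                else:
                    grad[blk.start] += g_w * params[(node, f"w_{p}")]
        return lp, grad


# ---------------------------------------------------------------------------
# the No-U-Turn sampler
# ---------------------------------------------------------------------------

_DIVERGENCE = 1000.0


def _leapfrog(logp_grad, q, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    q = q + eps * (r * inv_mass)
    lp, grad = logp_grad(q)
    r = r + 0.5 * eps * grad
    return q, r, lp, grad


def _find_reasonable_epsilon(logp_grad, q, rng, inv_mass):
    eps = 1.0
    lp, grad = logp_grad(q)
    r = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * float(r * inv_mass @ r)
    q1, r1, lp1, _ = _leapfrog(logp_grad, q, r, grad, eps, inv_mass)
    h1 = lp1 - 0.5 * float(r1 * inv_mass @ r1)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        q1, r1, lp1, _ = _leapfrog(logp_grad, q, r, grad, eps, inv_mass)
        h1 = lp1 - 0.5 * float(r1 * inv_mass @ r1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * math.log(0.5):
            break
    return max(eps, 1e-8)


class _Tree:
    __slots__ = ("q_minus", "r_minus", "g_minus", "q_plus", "r_plus", "g_plus",
                 "q_prop", "lp_prop", "g_prop", "n_valid", "stop", "diverged",
                 "alpha", "n_alpha")


def _build_tree(logp_grad, q, r, grad, log_u, direction, depth, eps, h0, inv_mass, rng):
    t = _Tree()
    if depth == 0:
        q1, r1, lp1, g1 = _leapfrog(logp_grad, q, r, grad, direction * eps, inv_mass)
        h1 = lp1 - 0.5 * float(r1 * inv_mass @ r1) if np.isfinite(lp1) else -np.inf
        t.q_minus = t.q_plus = t.q_prop = q1
        t.r_minus = t.r_plus = r1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        t.n_valid = 1 if log_u <= h1 else 0
        t.diverged = (h1 - h0) < -_DIVERGENCE or not np.isfinite(h1)
        t.stop = t.diverged
        t.alpha = min(1.0, math.exp(min(h1 - h0, 0.0))) if np.isfinite(h1) else 0.0
        t.n_alpha = 1
        return t
    t1 = _build_tree(logp_grad, q, r, grad, log_u, direction, depth - 1, eps, h0, inv_mass, rng)
    if t1.stop:
        return t1
    if direction == 1:
        t2 = _build_tree(logp_grad, t1.q_plus, t1.r_plus, t1.g_plus, log_u, direction,
                         depth - 1, eps, h0, inv_mass, rng)
        t1.q_plus, t1.r_plus, t1.g_plus = t2.q_plus, t2.r_plus, t2.g_plus
    else:
        t2 = _build_tree(logp_grad, t1.q_minus, t1.r_minus, t1.g_minus, log_u, direction,
                         depth - 1, eps, h0, inv_mass, rng)
        t1.q_minus, t1.r_minus, t1.g_minus = t2.q_minus, t2.r_minus, t2.g_minus
    total = t1.n_valid + t2.n_valid
    if total > 0 and rng.random() < t2.n_valid / total:
        t1.q_prop, t1.lp_prop, t1.g_prop = t2.q_prop, t2.lp_prop, t2.g_prop
    dq = t1.q_plus - t1.q_minus
    t1.diverged = t1.diverged or t2.diverged
    t1.stop = (
        t2.stop
        or (dq * inv_mass) @ t1.r_minus < 0
        or (dq * inv_mass) @ t1.r_plus < 0
    )
    t1.n_valid = total
    t1.alpha = t1.alpha + t2.alpha
    t1.n_alpha = t1.n_alpha + t2.n_alpha
    return t1


def _adaptation_windows(n_warmup):
    """Stan-style schedule: initial fast window, doubling slow windows for mass
    estimation, final fast window for step size only.  Returns the iteration
    indices at which the mass matrix is re-estimated."""
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.10 * n_warmup), 10)
    ends, start, size = [], init, max(int(0.10 * n_warmup), 25)
    while start + size < n_warmup - term:
        ends.append(start + size)
        start += size
        size *= 2
    if ends:
        ends[-1] = n_warmup - term
    elif n_warmup - term > init + 10:
        ends = [n_warmup - term]
    return ends


def _nuts_chain(logp_grad, q0, n_warmup, n_draws, rng, target_accept=0.9, max_depth=8):
    dim = q0.size
    inv_mass = np.ones(dim)
    q = q0.copy()
    lp, grad = logp_grad(q)
    eps = _find_reasonable_epsilon(logp_grad, q, rng, inv_mass)
    mu, log_eps_bar, h_bar = math.log(10 * eps), 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    window = []
    mass_updates = _adaptation_windows(n_warmup)
    draws = np.empty((n_draws, dim))
    divergences = 0
    accepts = []
    depths = []
    m_adapt = 0
    for m in range(n_warmup + n_draws):
        if m == n_warmup and n_warmup > 0:
            eps = math.exp(log_eps_bar)
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * float(r * inv_mass @ r)
        log_u = h0 + math.log(max(rng.random(), 1e-300))
        q_minus = q_plus = q
        r_minus = r_plus = r
        g_minus = g_plus = grad
        q_prop, lp_prop, g_prop = q, lp, grad
        n_valid, depth, stop = 1, 0, False
        alpha, n_alpha = 0.0, 1
        diverged = False
        while not stop and depth < max_depth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                t = _build_tree(logp_grad, q_plus, r_plus, g_plus, log_u, 1, depth, eps, h0, inv_mass, rng)
                q_plus, r_plus, g_plus = t.q_plus, t.r_plus, t.g_plus
            else:
                t = _build_tree(logp_grad, q_minus, r_minus, g_minus, log_u, -1, depth, eps, h0, inv_mass, rng)
                q_minus, r_minus, g_minus = t.q_minus, t.r_minus, t.g_minus
            if not t.stop and t.n_valid > 0 and rng.random() < min(1.0, t.n_valid / n_valid):
                q_prop, lp_prop, g_prop = t.q_prop, t.lp_prop, t.g_prop
            n_valid += t.n_valid
            alpha, n_alpha = t.alpha, t.n_alpha
            diverged = diverged or t.diverged
            dq = q_plus - q_minus
            stop = t.stop or (dq * inv_mass) @ r_minus < 0 or (dq * inv_mass) @ r_plus < 0
            depth += 1
        q, lp, grad = q_prop, lp_prop, g_prop
        accept_stat = alpha / max(n_alpha, 1)
        depths.append(depth)
        if m < n_warmup:
            m_adapt += 1
            frac = 1.0 / (m_adapt + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - math.sqrt(m_adapt) / gamma * h_bar
            eta = m_adapt ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            if m >= max(int(0.15 * n_warmup), 10) // 2:
                window.append(q.copy())
            if m + 1 in mass_updates and len(window) > 10:
                var = np.var(np.asarray(window), axis=0)
                k = len(window)
                inv_mass = (k / (k + 5.0)) * var + 1e-3 * (5.0 / (k + 5.0))
                window = []
                eps = _find_reasonable_epsilon(logp_grad, q, rng, inv_mass)
                mu, log_eps_bar, h_bar, m_adapt = math.log(10 * eps), 0.0, 0.0, 0
        else:
            draws[m - n_warmup] = q
            accepts.append(accept_stat)
            if diverged:
                divergences += 1
    return draws, {
        "step_size": eps,
        "mean_accept": float(np.mean(accepts)) if accepts else float("nan"),
        "mean_tree_depth": float(np.mean(depths)) if depths else float("nan"),
        "divergences": int(divergences),
    }


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------


@dataclass
class SamplerSettings:
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    target_accept: float = 0.9
    max_depth: int = 8
    seed: int = 0
    store_latent: bool = True


@dataclass
class TrainedLVM:
    """Posterior draws and diagnostics for a fitted causal LVM.

    ``posterior`` maps ``"node.param"`` to a (chains, draws) array on the
    constrained scale.  ``latent_rows`` maps a latent node name to a
    (chains, draws, n) array of its per-replicate values.
    """

    lvm: CausalLVM
    posterior: dict
    latent_rows: dict
    sampler_meta: dict
    _diag: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.posterior.values()))
        return first.shape[0] * first.shape[1]

    def to_inference_data(self):
        import arviz as az

        data = {k: v for k, v in self.posterior.items()}
        for node, arr in self.latent_rows.items():
            data[f"{node}._rows"] = arr
        return az.from_dict(posterior=data)

    def diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and bulk ESS per sampled parameter (latent rows are
        summarized by their worst row)."""
        if self._diag is not None:
            return self._diag
        import arviz as az

        rows = []
        for name, arr in self.posterior.items():
            da = az.convert_to_dataset({"x": arr})
            rhat = float(az.rhat(da)["x"].values)
            ess = float(az.ess(da)["x"].values)
            rows.append({"parameter": name, "rhat": rhat, "ess_bulk": ess})
        for node, arr in self.latent_rows.items():
            da = az.convert_to_dataset({"x": arr})
            rhat = az.rhat(da)["x"].values
            ess = az.ess(da)["x"].values
            rows.append(
                {"parameter": f"{node}.rows[worst]", "rhat": float(np.nanmax(rhat)),
                 "ess_bulk": float(np.nanmin(ess))}
            )
        self._diag = pd.DataFrame(rows).set_index("parameter")
        return self._diag

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd/interval plus convergence diagnostics per parameter."""
        diag = self.diagnostics()
        rows = []
        for name, arr in self.posterior.items():
            flat = arr.reshape(-1)
            lo, hi = np.percentile(flat, [3, 97])
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "hdi_3%": lo,
                    "hdi_97%": hi,
                    "rhat": diag.loc[name, "rhat"],
                    "ess_bulk": diag.loc[name, "ess_bulk"],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def parameter_assignment(self, index: int) -> dict:
        """The full theta of pooled draw ``index``, keyed node -> param -> value."""
        theta: dict = {}
        for key, arr in self.posterior.items():
            node, param = key.rsplit(".", 1)
            c, d = divmod(index, arr.shape[1])
            theta.setdefault(node, {})[param] = float(arr[c, d])
        for node in self.lvm.graph.nodes:
            spec = self.lvm.spec(node)
            if spec.family == "point" and node not in theta:
                theta[node] = {"value": 0.0}
        return theta

    def posterior_to_csv(self, path) -> None:
        flat = {k: v.reshape(-1) for k, v in self.posterior.items()}
        pd.DataFrame(flat).to_csv(path, index=False)

    def estimate_query(self, query, **kw):
        from .query import estimate_query

        return estimate_query(self, query, **kw)


def fit(lvm: CausalLVM, data: Dataset, chains=2, warmup=500, draws=500, seed=0,
        target_accept=0.85, max_depth=8, store_latent=True, method="auto",
        latent_param="auto") -> TrainedLVM:
    """Fit a causal LVM to observational data with NUTS.

    ``method`` selects the likelihood: ``"full"`` samples per-replicate latent
    values (family-generic), ``"collapsed"`` marginalizes them exactly
    (all-Gaussian models only), ``"auto"`` picks collapsed when available.
    ``latent_param`` chooses the per-row latent parameterization on the full
    path: non-centered (the default) suits latents that are weakly informed
    per replicate — the usual situation for hidden pathway regulators —
    while centered suits strongly-informed latents.
    Returns a :class:`TrainedLVM`; reproducible given ``seed``.
    """
    all_gauss = all(lvm.spec(nd).family == "gaussian_linear" for nd in lvm.graph.nodes)
    if method == "auto":
        method = "collapsed" if all_gauss else "full"
    if latent_param == "auto":
        latent_param = "noncentered"
    if method == "collapsed":
        post = _CollapsedGaussianPosterior(lvm, data)
        store_latent = False
    else:
        post = _Posterior(lvm, data, latent_param=latent_param)
    seeds = spawn_seeds(seed, chains)
    all_draws = []
    metas = []
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        q0 = post.initial_position(rng)
        d, meta = _nuts_chain(post.logp_grad, q0, warmup, draws, rng,
                              target_accept=target_accept, max_depth=max_depth)
        all_draws.append(d)
        metas.append(meta)
    stacked = np.asarray(all_draws)  # (chains, draws, dim)
    posterior: dict = {}
    latent_rows: dict = {}
    for b in post.blocks:
        if b.param == "_eps":
            continue
        z = stacked[:, :, b.start]
        if b.transform == "exp":
            v = np.exp(np.minimum(z, 50.0))
        elif b.transform == "negexp":
            v = -np.exp(np.minimum(z, 50.0))
        else:
            v = z
        posterior[f"{b.node}.{b.param}"] = v
    if store_latent and hasattr(post, "_eps_blocks"):
        for node, b in post._eps_blocks.items():
            raw = stacked[:, :, b.start : b.start + b.size]
            if post.latent_param == "centered":
                latent_rows[node] = raw
                continue
            spec = lvm.spec(node)
            eta = posterior[f"{node}.intercept"][..., None]
            for p in spec.parents:
                # latent nodes with latent parents: reconstruct recursively
                if p in lvm.latent and p in latent_rows:
                    eta = eta + posterior[f"{node}.w_{p}"][..., None] * latent_rows[p]
                elif p not in lvm.latent:
                    eta = eta + posterior[f"{node}.w_{p}"][..., None] * data.column(p)[None, None, :]
            latent_rows[node] = eta + posterior[f"{node}.sigma"][..., None] * raw
    meta = {
        "chains": chains,
        "warmup": warmup,
        "draws": draws,
        "seed": seed,
        "method": method,
        "latent_param": getattr(post, "latent_param", None),
        "target_accept": target_accept,
        "divergences": int(sum(m["divergences"] for m in metas)),
        "step_sizes": [m["step_size"] for m in metas],
        "mean_accept": [m["mean_accept"] for m in metas],
        "n_rows": data.n,
    }
    return TrainedLVM(lvm, posterior, latent_rows, meta)


def diagnostics_report(trained: TrainedLVM, rhat_max: float = 1.05, ess_min: float = 100.0) -> dict:
    """Flag parameters with high R-hat, low ESS, or divergent transitions.

    A fit of a non-identified model can pass at the data level while individual
    parameters mix poorly; the report therefore separates parameter-level flags
    from sampler-level ones rather than collapsing them into one verdict.
    """
    first = next(iter(trained.posterior.values()))
    if first.shape[0] * first.shape[1] < 4 or first.shape[1] < 2:
        return {
            "status": "insufficient_draws",
            "message": "convergence diagnostics need at least 2 draws per chain and 4 total",
        }
    diag = trained.diagnostics()
    high_rhat = diag[diag["rhat"] > rhat_max].index.tolist()
    low_ess = diag[diag["ess_bulk"] < ess_min].index.tolist()
    divergences = trained.sampler_meta.get("divergences", 0)
    status = "pass" if not high_rhat and divergences == 0 else "warn"
    return {
        "status": status,
        "rhat_max_threshold": rhat_max,
        "high_rhat": high_rhat,
        "low_ess": low_ess,
        "divergences": divergences,
        "worst_rhat": float(diag["rhat"].max()),
        "min_ess": float(diag["ess_bulk"].min()),
    }
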