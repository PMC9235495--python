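"""Exact stochastic simulation (Gillespie SSA) of mass-action reaction networks.

Used to generate signaling-pathway data whose true generative process is a
jump process rather than any parametric LVM: the fitted Hill-sigmoid models
only *approximate* it, which is exactly the situation the robustness results
address.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._util import derive_seed, spawn_seeds
from ..scm import Dataset

__all__ = ["ReactionNetwork", "gillespie", "simulate_replicates", "cs3_reaction_network"]


@dataclass
class ReactionNetwork:
    """Species, mass-action reactions and initial integer counts.

    Each reaction is ``(reactants, products, rate)`` with count maps; its
    propensity is ``rate * prod_s falling_factorial(count_s, stoich_s)``.
    """

    species: list
    reactions: list
    initial: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.reactions:
            raise ValueError("a reaction network needs at least one reaction")
        for reactants, products, rate in self.reactions:
            if rate <= 0:
                raise ValueError(f"reaction rates must be positive (got {rate})")
            for m in (reactants, products):
                unknown = set(m) - set(self.species)
                if unknown:
                    raise ValueError(f"unknown species {sorted(unknown)}")
        for s, c in self.initial.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"initial counts must be non-negative integers ({s}={c})")

    def with_fixed(self, fixed: dict) -> "ReactionNetwork":
        """Clamp species to constant values: drop every reaction that changes
        them (an intervention on the jump process)."""
        keep = []
        for reactants, products, rate in self.reactions:
            delta = {s: products.get(s, 0) - reactants.get(s, 0) for s in set(reactants) | set(products)}
            if any(s in fixed and d != 0 for s, d in delta.items()):
                continue
            keep.append((reactants, products, rate))
        initial = dict(self.initial)
        initial.update({s: int(v) for s, v in fixed.items()})
        return ReactionNetwork(self.species, keep, initial)


def _propensity(rate, reactants, counts):
    a = rate
    for s, k in reactants.items():
        c = counts[s]
        for j in range(k):
            a *= max(c - j, 0)
    return a


def gillespie(network: ReactionNetwork, t_max: float, seed: int, record: bool = True):
    """Run one exact SSA trajectory to ``t_max``.

    Returns ``(frame, final)``: an event-time table (empty when ``record`` is
    False) and the final count map.
    """
    rng = np.random.default_rng(seed)
    species = list(network.species)
    sidx = {s: i for i, s in enumerate(species)}
    counts = [int(network.initial.get(s, 0)) for s in species]
    # precompile reactions: multiplicity-expanded reactant indices and deltas
    compiled = []
    for reactants, products, rate in network.reactions:
        ridx = [sidx[s] for s, k in reactants.items() for _ in range(k)]
        delta = {}
        for s, k in reactants.items():
            delta[sidx[s]] = delta.get(sidx[s], 0) - k
        for s, k in products.items():
            delta[sidx[s]] = delta.get(sidx[s], 0) + k
        compiled.append((rate, ridx, list(delta.items())))
    t = 0.0
    times, rows = [0.0], [list(counts)]
    exp = rng.exponential
    uni = rng.random
    while True:
        total = 0.0
        props = []
        for rate, ridx, _ in compiled:
            a = rate
            seen: dict = {}
            for i in ridx:
                a *= max(counts[i] - seen.get(i, 0), 0)
                seen[i] = seen.get(i, 0) + 1
            props.append(a)
            total += a
        if total <= 0:
            break
        t += exp(1.0 / total)
        if t > t_max:
            break
        u = uni() * total
        acc = 0.0
        for (rate, ridx, delta), a in zip(compiled, props):
            acc += a
            if u <= acc:
                for i, d in delta:
                    counts[i] += d
                break
        if record:
            times.append(t)
            rows.append(list(counts))
    final = dict(zip(species, counts))
    frame = (
        pd.DataFrame(rows, columns=species, index=pd.Index(times, name="time"))
        if record
        else pd.DataFrame()
    )
    return frame, final


def simulate_replicates(
    network: ReactionNetwork,
    n: int,
    t_max: float,
    seed: int,
    init_sampler=None,
    observed=None,
    fixed: dict | None = None,
) -> Dataset:
    """Endpoint counts of ``n`` independent trajectories as a Dataset.

    ``init_sampler(rng) -> dict`` randomizes initial counts per replicate
    (e.g. the growth-factor inputs); ``fixed`` clamps intervened species.
    """
    net = network.with_fixed(fixed) if fixed else network
    seeds = spawn_seeds(seed, n)
    rows = []
    rng = np.random.default_rng(derive_seed(seed, "init"))
    for i in range(n):
        if init_sampler is not None:
            ini = dict(net.initial)
            ini.update({k: int(v) for k, v in init_sampler(rng).items() if k not in (fixed or {})})
            net_i = ReactionNetwork(net.species, net.reactions, ini)
        else:
            net_i = net
        _, final = gillespie(net_i, t_max, seeds[i], record=False)
        rows.append(final)
    frame = pd.DataFrame(rows)
    cols = observed if observed is not None else net.species
    return Dataset(
        frame[list(cols)].astype(float),
        {"kind": "gillespie", "n": n, "t_max": t_max, "seed": seed, "do": dict(fixed or {})},
    )


# ---------------------------------------------------------------------------
# the signaling-network reaction system
# ---------------------------------------------------------------------------

_CS3_SPECIES = ["EGF", "IGF", "SOS", "Ras", "PI3K", "Akt", "Raf", "Mek", "Erk"]
_CS3_ACTIVATIONS = [
    ("EGF", "SOS"), ("IGF", "SOS"), ("EGF", "PI3K"), ("IGF", "PI3K"),
    ("SOS", "Ras"), ("SOS", "Raf"), ("Ras", "PI3K"), ("PI3K", "Akt"),
    ("Raf", "Mek"), ("Mek", "Erk"),
]


def cs3_reaction_network(k_deg: float = 0.5, k_inh: float = 0.002) -> ReactionNetwork:
    """Mass-action version of the growth-factor cascade.

    Activation edges A -> B are catalytic productions ``A -> A + B``; every
    non-input species decays at ``k_deg``; the Akt -| Raf inhibition is a
    catalytic degradation ``Akt + Raf -> Akt``.  Each target's per-edge
    production rate is ``k_deg / (number of activators)`` so that, with inputs
    near 100 molecules, every species fluctuates around the 100-molecule
    scale.  The published system is characterized only up to its stochastic
    dynamics, so these constants are package choices and configurable.
    """
    n_act: dict = {}
    for _, b in _CS3_ACTIVATIONS:
        n_act[b] = n_act.get(b, 0) + 1
    reactions = []
    for a, b in _CS3_ACTIVATIONS:
        reactions.append(({a: 1}, {a: 1, b: 1}, k_deg / n_act[b]))
    for s in _CS3_SPECIES[2:]:
        reactions.append(({s: 1}, {}, k_deg))
    reactions.append(({"Akt": 1, "Raf": 1}, {"Akt": 1}, k_inh))
    initial = {s: 100 for s in _CS3_SPECIES}
    return ReactionNetwork(_CS3_SPECIES, reactions, initial)


def cs3_input_sampler(rng: np.random.Generator) -> dict:
    """Replicates differ by random growth-factor input levels."""
    return {"EGF": int(rng.integers(40, 161)), "IGF": int(rng.integers(40, 161))}
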