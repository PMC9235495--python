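"""Builders for the benchmark pathway systems.

Each case study couples a gene-regulatory or signaling motif with a causal
query whose identification route is known:

``confounded_pair`` / ``mediated_pair``
    The two motivating linear-Gaussian systems: a confounded cause-effect pair
    (non-identifiable) and the same system with a mediator (front-door).
``cs1_multicause_frontdoor``
    A multi-cause feed-forward transcriptional motif from *E. coli*: the sRNA
    dsrA and the regulators gadX and fis act on cas2 through the global
    silencer hns, with latent co-regulation of causes and effect; three-target
    front-door query.
``cs2_napkin``
    The napkin motif around lrp → topA: the back-door cannot be blocked (hns
    is a collider whose descendant gadE sits on the only blocking route) and
    no mediator exists, so only the full do-calculus identifies the query.
``cs3_signaling``
    Insulin-like/epidermal growth-factor signaling into Erk (SOS–Ras–PI3K–
    Akt–Raf–Mek cascade with EGF and IGF latent); Hill-sigmoid responses
    capped at 100 molecules; data can come from Gillespie simulation.
``cs4_sarscov2``
    The cytokine-release cascade of severe SARS-CoV-2 infection; two drug
    queries on one model (tocilizumab's target sIL6Ra: back-door; gefitinib's
    target EGFR: do-calculus only).
``cs5_frontdoor`` / ``cs6_napkin``
    Single-cause front-door (soxS → rob → ybiT, lrp latent) and napkin
    (fur → grcA with crp ancestor) motifs, all-Gaussian, standing in for
    RNA-seq expression compendium structures.

Every case carries a *correct* model and a *misspecified-latent* variant that
projects onto the same ADMG (the robustness premise): correct models carry
extra latents with nested child sets, misspecified variants drop or duplicate
them.

The figure edge lists were reconstructed from the running descriptions of the
systems (stated node names, collider/mediator structure, and the documented
identification route of each query); the identification catalog test pins the
reconstruction to those properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..graphs import MixedGraph, parse_graph
from ..identify import CausalQuery
from ..scm import CausalLVM, NodeSpec, PriorSpec

__all__ = ["CaseStudySpec", "build_example", "build_case", "build_projection_demo", "CASE_NAMES"]

CASE_NAMES = (
    "cs1_multicause_frontdoor",
    "cs2_napkin",
    "cs3_signaling",
    "cs4_sarscov2",
    "cs5_frontdoor",
    "cs6_napkin",
)

# Priors used across the case studies
_N01 = PriorSpec(0.0, 1.0)
_N01_POS = PriorSpec(0.0, 1.0, "positive")
_WIDE = PriorSpec(0.0, 10.0)
_WIDE_POS = PriorSpec(0.0, 10.0, "positive")
_WIDE_NEG = PriorSpec(0.0, 10.0, "negative")


def _latent(name: str) -> NodeSpec:
    """Latent confounders are standard-normal-scale Gaussian roots with N(0,1)
    priors on their location and scale."""
    return NodeSpec(name, "gaussian_linear", (), {"intercept": _N01, "sigma": _N01_POS})


def _gauss(name, parents, weight_prior=_WIDE) -> NodeSpec:
    priors = {f"w_{p}": weight_prior for p in parents}
    priors["intercept"] = _N01
    priors["sigma"] = _N01_POS
    return NodeSpec(name, "gaussian_linear", tuple(parents), priors)


@dataclass
class CaseStudySpec:
    """One benchmark system: correct and latent-misspecified models, the causal
    query, the generating law for true parameters, and the data mode."""

    name: str
    correct: CausalLVM
    misspecified: CausalLVM
    query: CausalQuery
    theta_seed: int = 0
    data_mode: str = "parametric"  # parametric | gillespie
    generator_overrides: dict = field(default_factory=dict)
    description: str = ""

    def __post_init__(self):
        a = self.correct.admg()
        b = self.misspecified.admg()
        if not (a.directed == b.directed and a.bidirected == b.bidirected and a.nodes == b.nodes):
            raise ValueError(
                f"{self.name}: correct and misspecified variants must latent-project "
                "onto the same ADMG"
            )

    def model(self, variant: str) -> CausalLVM:
        if variant not in ("correct", "misspecified"):
            raise ValueError(f"unknown variant {variant!r}")
        return self.correct if variant == "correct" else self.misspecified

    def true_theta(self) -> dict:
        """The fixed true parameters of the data-generating process."""
        return self.correct.random_parameters(self.theta_seed, self.generator_overrides)

    def export(self, outdir) -> None:
        """Write the graph file, both model configs and the query for this case."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{self.name}_graph.txt").write_text(self.correct.graph.to_text())
        (outdir / f"{self.name}_admg.dot").write_text(self.correct.admg().to_dot(self.name))
        self.correct.save(outdir / f"{self.name}_correct.yaml")
        self.misspecified.save(outdir / f"{self.name}_misspecified.yaml")
        (outdir / f"{self.name}_query.json").write_text(
            json.dumps(
                {"targets": self.query.targets, "outcomes": list(self.query.outcomes),
                 "form": self.query.form},
                indent=2,
            )
        )


def _gen_overrides(lvm: CausalLVM, weight=(0.8, 0.3), intercept=(0.0, 1.0),
                   sigma=(1.0, 0.25), shape=(3.0, 0.5), special=None) -> dict:
    """Moderate generating laws for the true parameters.

    Weights near +-0.8, unit-scale intercepts and noise: regulatory effects
    that are clearly present but do not saturate logits, sigmoids or gamma
    means (saturated nodes would make the benchmark queries degenerate).
    """
    out: dict = {}
    for node in lvm.graph.nodes:
        spec = lvm.spec(node)
        ov: dict = {}
        for p in spec.parameter_names():
            prior = spec.prior_for(p)
            if p.startswith("w_"):
                loc = -weight[0] if prior.constraint == "negative" else weight[0]
                ov[p] = PriorSpec(loc, weight[1], prior.constraint)
            elif p == "intercept":
                ov[p] = PriorSpec(intercept[0], intercept[1])
            elif p == "sigma":
                ov[p] = PriorSpec(sigma[0], sigma[1], "positive")
            elif p == "shape":
                ov[p] = PriorSpec(shape[0], shape[1], "positive")
        out[node] = ov
    for node, params in (special or {}).items():
        out.setdefault(node, {}).update(params)
    return out


# ---------------------------------------------------------------------------
# motivating examples
# ---------------------------------------------------------------------------


def build_example(which: str, x_value: float = 2.0) -> CaseStudySpec:
    """The two motivating systems: ``confounded_pair`` (confounded pair, non-identifiable
    query) and ``mediated_pair`` (mediated, front-door identifiable)."""
    if which == "confounded_pair":
        graph = parse_graph("latent U\nU -> X\nU -> Y\nX -> Y\n")
        specs = {
            "U": _latent("U"),
            "X": _gauss("X", ("U",), weight_prior=_N01),
            "Y": _gauss("Y", ("X", "U")),
        }
    elif which == "mediated_pair":
        graph = parse_graph("latent U\nU -> X\nU -> Y\nX -> Z\nZ -> Y\n")
        specs = {
            "U": _latent("U"),
            "X": _gauss("X", ("U",), weight_prior=_N01),
            "Z": _gauss("Z", ("X",)),
            "Y": _gauss("Y", ("Z", "U")),
        }
    else:
        raise ValueError(f"unknown example {which!r} (expected confounded_pair or mediated_pair)")
    lvm = CausalLVM(graph, specs)
    query = CausalQuery({"X": x_value}, ("Y",), "distribution")
    # the example systems have no misspecified variant; reuse the model itself
    return CaseStudySpec(
        name=which,
        correct=lvm,
        misspecified=lvm,
        query=query,
        theta_seed=20 if which == "confounded_pair" else 21,
        generator_overrides=_gen_overrides(lvm),
        description="motivating linear-Gaussian example",
    )


# ---------------------------------------------------------------------------
# the six case studies
# ---------------------------------------------------------------------------


def _build_cs1() -> CaseStudySpec:
    def model(latents):
        text = ["dsrA -> hns", "gadX -> hns", "fis -> hns", "hns -> cas2"]
        specs = {}
        lat_children = {"U1": ("dsrA", "gadX", "fis", "cas2"), "U2": ("gadX", "fis", "cas2")}
        parents = {"dsrA": [], "gadX": [], "fis": [], "hns": ["dsrA", "gadX", "fis"], "cas2": ["hns"]}
        for u in latents:
            text.append(f"latent {u}")
            for c in lat_children[u]:
                text.append(f"{u} -> {c}")
                parents[c].append(u)
            specs[u] = _latent(u)
        for node, pa in parents.items():
            specs[node] = NodeSpec(
                node, "bernoulli_logit", tuple(pa),
                {f"w_{p}": _WIDE for p in pa} | {"intercept": _WIDE},
            )
        return CausalLVM(parse_graph("\n".join(text)), specs)

    correct = model(("U1", "U2"))
    missp = model(("U1",))
    query = CausalQuery({"dsrA": 0.0, "gadX": 0.0, "fis": 0.0}, ("cas2",), "expectation")
    return CaseStudySpec(
        "cs1_multicause_frontdoor", correct, missp, query, theta_seed=31,
        generator_overrides=_gen_overrides(correct, weight=(1.0, 0.3), intercept=(0.0, 0.7)),
        description="multi-cause feed-forward motif; three-target front-door query",
    )


def _build_cs2(lrp_value: float = 0.0) -> CaseStudySpec:
    def model(topA_latents):
        lats = ["U1"] + list(topA_latents)
        text = ["dsr -> hns", "fis -> hns", "hns -> gadE", "gadE -> lrp", "lrp -> topA",
                "latent U1", "U1 -> hns", "U1 -> lrp"]
        for u in topA_latents:
            text += [f"latent {u}", f"{u} -> hns", f"{u} -> topA"]
        graph = parse_graph("\n".join(text))
        hns_parents = tuple(sorted(["dsr", "fis"] + lats))
        specs = {u: _latent(u) for u in lats}
        specs["dsr"] = _gauss("dsr", ())
        specs["fis"] = _gauss("fis", ())
        specs["hns"] = NodeSpec(
            "hns", "gamma", hns_parents,
            {f"w_{p}": PriorSpec(0, 10) for p in hns_parents}
            | {"intercept": _WIDE, "shape": _WIDE_POS},
        )
        specs["gadE"] = _gauss("gadE", ("hns",))
        specs["lrp"] = NodeSpec(
            "lrp", "bernoulli_logit", ("U1", "gadE"),
            {"w_U1": _WIDE, "w_gadE": _WIDE, "intercept": _WIDE},
        )
        topA_parents = tuple(sorted(["lrp"] + list(topA_latents)))
        specs["topA"] = _gauss("topA", topA_parents)
        return CausalLVM(graph, specs)

    correct = model(("U2",))
    missp = model(("U2", "U3"))  # wrongly assumes two latents between hns and topA
    query = CausalQuery({"lrp": lrp_value}, ("topA",), "expectation")
    special = {
        # gamma reporter node: small weights and a log-scale intercept keep the
        # mean in a realistic intensity range
        "hns": {f"w_{p}": PriorSpec(0.3, 0.08) for p in correct.spec("hns").parents}
        | {"intercept": PriorSpec(1.2, 0.2), "shape": PriorSpec(4.0, 0.5, "positive")},
    }
    return CaseStudySpec(
        "cs2_napkin", correct, missp, query, theta_seed=32,
        generator_overrides=_gen_overrides(correct, special=special),
        description="napkin motif around lrp -> topA; do-calculus-only query",
    )


_CS3_EDGES = [
    ("SOS", "Ras", "increase"),
    ("SOS", "Raf", "increase"),
    ("Ras", "PI3K", "increase"),
    ("PI3K", "Akt", "increase"),
    ("Akt", "Raf", "decrease"),
    ("Raf", "Mek", "increase"),
    ("Mek", "Erk", "increase"),
]


def _build_cs3() -> CaseStudySpec:
    def model(latents):
        text = [f"{a} -> {b}" for a, b, _ in _CS3_EDGES]
        parents = {n: [] for n in "SOS Ras PI3K Akt Raf Mek Erk".split()}
        signs = {}
        for a, b, kind in _CS3_EDGES:
            parents[b].append(a)
            signs[(b, a)] = kind
        for u in latents:
            text.append(f"latent {u}")
            for c in ("SOS", "PI3K"):
                text.append(f"{u} -> {c}")
                parents[c].append(u)
                signs[(c, u)] = "increase"
        specs = {u: _latent(u) for u in latents}
        for node, pa in parents.items():
            priors = {
                f"w_{p}": (_WIDE_POS if signs[(node, p)] == "increase" else _WIDE_NEG)
                for p in pa
            }
            priors["intercept"] = _WIDE
            priors["sigma"] = PriorSpec(0, 10, "positive")
            specs[node] = NodeSpec(node, "hill_sigmoid", tuple(pa), priors, scale_cap=100.0)
        return CausalLVM(parse_graph("\n".join(text)), specs)

    correct = model(("EGF", "IGF"))
    missp = model(("EGF",))  # omits IGF
    query = CausalQuery({"SOS": 70.0}, ("Erk",), "expectation")
    special = {
        node: {"sigma": PriorSpec(5.0, 1.0, "positive"), "intercept": PriorSpec(0.0, 0.5)}
        for node in "SOS Ras PI3K Akt Raf Mek Erk".split()
    }
    # Hill-node inputs are on the 0-100 molecule scale; weights must be small
    # for the sigmoid to respond over that range rather than saturate.
    for node in "Ras PI3K Akt Raf Mek Erk".split():
        for p in correct.spec(node).parents:
            sign = -1.0 if correct.spec(node).prior_for(f"w_{p}").constraint == "negative" else 1.0
            special[node][f"w_{p}"] = PriorSpec(sign * 0.04, 0.008,
                                                "negative" if sign < 0 else "positive")
        special[node]["intercept"] = PriorSpec(-2.0, 0.3)
    for p in correct.spec("SOS").parents:  # latent inputs are unit-scale
        special["SOS"][f"w_{p}"] = PriorSpec(0.8, 0.2, "positive")
        special["PI3K"][f"w_{p}"] = PriorSpec(0.8, 0.2, "positive")
    return CaseStudySpec(
        "cs3_signaling", correct, missp, query, theta_seed=33, data_mode="gillespie",
        generator_overrides=_gen_overrides(correct, special=special),
        description="growth-factor signaling cascade; Hill-sigmoid responses",
    )


_CS4_DIRECTED = [
    ("SARS_CoV2", "AngII"), ("AngII", "AGTR1"), ("AGTR1", "ADAM17"),
    ("ADAM17", "TNF"), ("ADAM17", "sIL6Ra"), ("ADAM17", "EGF"),
    ("EGF", "EGFR"), ("EGFR", "NF_kB"), ("TNF", "NF_kB"),
    ("SARS_CoV2", "PRR"), ("PRR", "NF_kB"),
    ("sIL6Ra", "IL6_STAT3"), ("NF_kB", "IL6_AMP"), ("IL6_STAT3", "IL6_AMP"),
    ("IL6_AMP", "Cytokine"),
]
# dotted edges: latent confounding between these pairs; the first three carry
# two latent variables each in the correct model
_CS4_DOUBLE_PAIRS = [("SARS_CoV2", "AngII"), ("ADAM17", "sIL6Ra"), ("PRR", "NF_kB")]
_CS4_SINGLE_PAIRS = [("AGTR1", "EGFR"), ("AGTR1", "Cytokine")]


def _build_cs4() -> CaseStudySpec:
    def model(double: bool):
        text = [f"{a} -> {b}" for a, b in _CS4_DIRECTED]
        parents: dict = {}
        for a, b in _CS4_DIRECTED:
            parents.setdefault(b, []).append(a)
            parents.setdefault(a, [])
        latents = []
        for i, (a, b) in enumerate(_CS4_DOUBLE_PAIRS + _CS4_SINGLE_PAIRS):
            copies = 2 if (double and (a, b) in _CS4_DOUBLE_PAIRS) else 1
            for c in range(copies):
                u = f"L{i}{'ab'[c]}"
                latents.append(u)
                text.append(f"latent {u}")
                for node in (a, b):
                    text.append(f"{u} -> {node}")
                    parents[node].append(u)
        specs = {u: _latent(u) for u in latents}
        informative = PriorSpec(30.0, 1.0)  # abundance-scale locations
        for node, pa in parents.items():
            if node == "Cytokine":
                specs[node] = NodeSpec(
                    node, "bernoulli_logit", tuple(pa),
                    {f"w_{p}": _WIDE for p in pa} | {"intercept": _WIDE},
                )
                continue
            priors = {f"w_{p}": _WIDE for p in pa}
            priors["intercept"] = informative if not pa else _WIDE
            priors["sigma"] = PriorSpec(0, 10, "positive")
            specs[node] = NodeSpec(node, "hill_sigmoid", tuple(pa), priors, scale_cap=100.0)
        return CausalLVM(parse_graph("\n".join(text)), specs)

    correct = model(double=True)
    missp = model(double=False)  # one latent per dotted edge
    query = CausalQuery({"sIL6Ra": 20.0}, ("Cytokine",), "expectation")
    special: dict = {}
    for node in correct.graph.observed:
        if node == "Cytokine":
            special[node] = {"w_IL6_AMP": PriorSpec(0.08, 0.015), "intercept": PriorSpec(-4.0, 0.4)}
            continue
        sp: dict = {"sigma": PriorSpec(5.0, 1.0, "positive")}
        pa = correct.spec(node).parents
        obs_pa = [p for p in pa if p not in correct.latent]
        sp["intercept"] = PriorSpec(-1.5, 0.3) if obs_pa else PriorSpec(0.0, 0.5)
        for p in pa:
            sp[f"w_{p}"] = PriorSpec(0.04, 0.01) if p in obs_pa else PriorSpec(0.8, 0.2)
        special[node] = sp
    return CaseStudySpec(
        "cs4_sarscov2", correct, missp, query, theta_seed=34,
        generator_overrides=_gen_overrides(correct, special=special),
        description="cytokine-release cascade; two drug queries on one model",
    )


def cs4_queries() -> dict:
    """The two drug queries of the SARS-CoV-2 system."""
    return {
        "toci": CausalQuery({"sIL6Ra": 20.0}, ("Cytokine",), "expectation"),
        "gefi": CausalQuery({"EGFR": 20.0}, ("Cytokine",), "expectation"),
    }


def _build_cs5() -> CaseStudySpec:
    def model(latents):
        text = ["soxS -> rob", "rob -> ybiT"]
        specs = {}
        parents = {"soxS": [], "rob": ["soxS"], "ybiT": ["rob"]}
        for u in latents:
            text.append(f"latent {u}")
            for c in ("soxS", "ybiT"):
                text.append(f"{u} -> {c}")
                parents[c].append(u)
            specs[u] = _latent(u)
        for node, pa in parents.items():
            specs[node] = _gauss(node, tuple(sorted(pa)))
        return CausalLVM(parse_graph("\n".join(text)), specs)

    correct = model(("lrp",))
    missp = model(("lrp", "lrp2"))  # wrongly assumes two latent variables
    query = CausalQuery({"soxS": 0.0}, ("ybiT",), "distribution")
    return CaseStudySpec(
        "cs5_frontdoor", correct, missp, query, theta_seed=35,
        generator_overrides=_gen_overrides(correct),
        description="single-cause feed-forward motif; front-door via rob",
    )


def _build_cs6() -> CaseStudySpec:
    def model(grcA_latents):
        lats = ["U1"] + list(grcA_latents)
        text = ["crp -> oxyR", "oxyR -> fur", "fur -> grcA",
                "latent U1", "U1 -> crp", "U1 -> fur"]
        for u in grcA_latents:
            text += [f"latent {u}", f"{u} -> crp", f"{u} -> grcA"]
        graph = parse_graph("\n".join(text))
        specs = {u: _latent(u) for u in lats}
        specs["crp"] = _gauss("crp", tuple(sorted(lats)))
        specs["oxyR"] = _gauss("oxyR", ("crp",))
        specs["fur"] = _gauss("fur", tuple(sorted(["oxyR", "U1"])))
        specs["grcA"] = _gauss("grcA", tuple(sorted(["fur"] + list(grcA_latents))))
        return CausalLVM(graph, specs)

    correct = model(("U2",))
    missp = model(("U2", "U3"))  # wrongly assumes two latents between crp and grcA
    query = CausalQuery({"fur": 0.0}, ("grcA",), "distribution")
    return CaseStudySpec(
        "cs6_napkin", correct, missp, query, theta_seed=36,
        generator_overrides=_gen_overrides(correct),
        description="napkin motif around fur -> grcA",
    )


_BUILDERS = {
    "cs1_multicause_frontdoor": _build_cs1,
    "cs2_napkin": _build_cs2,
    "cs3_signaling": _build_cs3,
    "cs4_sarscov2": _build_cs4,
    "cs5_frontdoor": _build_cs5,
    "cs6_napkin": _build_cs6,
}


def build_case(which: str, **kw) -> CaseStudySpec:
    """Build one of the six case-study systems by name."""
    try:
        builder = _BUILDERS[which]
    except KeyError:
        raise ValueError(f"unknown case study {which!r}; choose from {sorted(_BUILDERS)}")
    return builder(**kw)


def build_projection_demo() -> MixedGraph:
    """A 4-observed / 5-latent DAG whose latent projection collapses to a
    single latent confounder of X1 and X2 (then one bidirected edge)."""
    return parse_graph(
        """
        latent L1
        latent L2
        latent L3
        latent L4
        latent L5
        L5 -> L1
        L1 -> X1
        L1 -> X2
        L2 -> X1
        L2 -> X2
        X3 -> L4
        L4 -> X4
        X1 -> X3
        X2 -> X4
        """
    )
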