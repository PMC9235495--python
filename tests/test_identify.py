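"""Identification: criteria, the complete algorithm, and numeric soundness."""

import itertools

import numpy as np
import pytest

from causalpath.casestudies import CASE_NAMES, build_case, build_example
from causalpath.casestudies.builders import cs4_queries
from causalpath.graphs import GraphError, MixedGraph
from causalpath.identify import (
    CausalQuery,
    Conditional,
    Estimand,
    Fraction,
    Marginalize,
    Product,
    apply_rule,
    check_backdoor,
    check_frontdoor,
    evaluate_estimand,
    identify,
)
from helpers import DiscreteSCM, random_mixed_graph

FRONTDOOR = MixedGraph(directed={("X", "Z"), ("Z", "Y")}, bidirected={frozenset(("X", "Y"))})
BOW = MixedGraph(directed={("X", "Y")}, bidirected={frozenset(("X", "Y"))})
NAPKIN = MixedGraph(
    directed={("W", "R"), ("R", "X"), ("X", "Y")},
    bidirected={frozenset(("W", "X")), frozenset(("W", "Y"))},
)


class TestQueryValidation:
    def test_overlapping_targets_and_outcomes(self):
        with pytest.raises(ValueError, match="disjoint"):
            CausalQuery({"X": 1}, ("X",))

    def test_empty_pieces(self):
        with pytest.raises(ValueError):
            CausalQuery({}, ("Y",))
        with pytest.raises(ValueError):
            CausalQuery({"X": 1}, ())

    def test_latent_target_rejected(self):
        g = build_example("mediated_pair").correct.graph
        with pytest.raises(GraphError, match="latent"):
            CausalQuery({"U": 1}, ("Y",)).validate_against(g)


class TestCriteria:
    def test_backdoor_trivial_unconfounded(self):
        g = MixedGraph(directed={("X", "Y")})
        assert check_backdoor(g, "X", "Y", ())

    def test_backdoor_fails_on_bow(self):
        others = BOW.observed - {"X", "Y"}
        assert not check_backdoor(BOW, "X", "Y", ())

    def test_backdoor_rejects_bad_adjustment_set(self):
        with pytest.raises(GraphError):
            check_backdoor(BOW, "X", "Y", {"Y"})

    def test_frontdoor_holds_on_mediated_graph(self):
        assert check_frontdoor(FRONTDOOR, {"X"}, "Y", {"Z"})

    def test_frontdoor_fails_on_bow_any_mediator(self):
        assert not check_frontdoor(BOW, {"X"}, "Y", ())

    def test_cs5_mediator_rob(self):
        spec = build_case("cs5_frontdoor")
        admg = spec.correct.admg()
        assert check_frontdoor(admg, {"soxS"}, "ybiT", {"rob"})
        assert not check_backdoor(admg, "soxS", "ybiT", ())

    def test_cs4_toci_backdoor_witness(self):
        spec = build_case("cs4_sarscov2")
        admg = spec.correct.admg()
        assert check_backdoor(admg, "sIL6Ra", "Cytokine", {"ADAM17", "AGTR1"})


class TestDoCalculusRules:
    def test_empty_z_trivially_true(self):
        for rule in (1, 2, 3):
            assert apply_rule(rule, FRONTDOOR, {"X"}, {"Y"}, set(), set())

    def test_rule2_frontdoor_step(self):
        # exchanging do(X) for observing X requires Y indep X given Z with X's
        # outgoing edges cut — false here because of the X<->Y confounding
        assert not apply_rule(2, FRONTDOOR, set(), {"Y"}, {"X"}, {"Z"})
        # but Z indep X holds in the outgoing-mutilated graph
        assert apply_rule(2, FRONTDOOR, set(), {"Z"}, {"X"}, set())

    def test_overlap_rejected(self):
        with pytest.raises(GraphError, match="disjoint"):
            apply_rule(1, FRONTDOOR, {"X"}, {"X"}, {"Z"}, set())

    def test_rules_match_brute_force_mutilation(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            g = random_mixed_graph(rng, 6)
            nodes = list(rng.permutation(sorted(g.nodes)))
            x, y, z, w = {nodes[0]}, {nodes[1]}, {nodes[2]}, {nodes[3]}
            g1 = g.mutilate_incoming(x)
            assert apply_rule(1, g, x, y, z, w) == g1.d_separated(y, z, x | w)
            assert apply_rule(2, g, x, y, z, w) == g1.mutilate_outgoing(z).d_separated(y, z, x | w)
            z_w = z - g1.ancestors(w)
            g3 = g1.mutilate_incoming(z_w)
            assert apply_rule(3, g, x, y, z, w) == g3.d_separated(y, z, x | w)


class TestIdentifyCatalog:
    """The known identification statuses of every benchmark system."""

    def test_bow_not_identifiable(self):
        res = identify(BOW, CausalQuery({"X": 1.0}, ("Y",)))
        assert not res.identifiable
        assert res.estimand is None
        assert res.witness is not None

    def test_frontdoor_estimand_structure(self):
        res = identify(FRONTDOOR, CausalQuery({"X": 1.0}, ("Y",)))
        assert res.identifiable and res.method == "frontdoor" and res.witness == {"Z"}
        assert res.estimand.render() == "sum_{Z} P(Z|X) [sum_{X} P(Y|X,Z) P(X)]"

    def test_napkin_ratio_form(self):
        res = identify(NAPKIN, CausalQuery({"X": 1.0}, ("Y",)))
        assert res.identifiable and res.method == "id_algorithm"
        assert isinstance(res.estimand, Fraction) or any(
            isinstance(c, Fraction) for c in getattr(res.estimand, "children", ())
        )

    @pytest.mark.parametrize(
        "case,expected",
        [
            ("confounded_pair", None),
            ("mediated_pair", "frontdoor"),
            ("cs1_multicause_frontdoor", "frontdoor"),
            ("cs2_napkin", "id_algorithm"),
            ("cs3_signaling", "id_algorithm"),
            ("cs5_frontdoor", "frontdoor"),
            ("cs6_napkin", "id_algorithm"),
        ],
    )
    def test_case_catalog(self, case, expected):
        spec = build_example(case) if not case.startswith("cs") else build_case(case)
        res = identify(spec.correct.admg(), spec.query)
        if expected is None:
            assert not res.identifiable
        else:
            assert res.identifiable and res.method == expected

    def test_cs4_two_queries_one_model(self):
        spec = build_case("cs4_sarscov2")
        admg = spec.correct.admg()
        queries = cs4_queries()
        toci = identify(admg, queries["toci"])
        gefi = identify(admg, queries["gefi"])
        assert toci.identifiable and toci.method == "backdoor"
        assert gefi.identifiable and gefi.method == "id_algorithm"

    def test_misspecified_variants_project_to_same_admg(self):
        for name in CASE_NAMES:
            spec = build_case(name)
            a, b = spec.correct.admg(), spec.misspecified.admg()
            assert (a.nodes, a.directed, a.bidirected) == (b.nodes, b.directed, b.bidirected)


class TestEstimandObjects:
    def test_json_roundtrip(self):
        res = identify(NAPKIN, CausalQuery({"X": 1.0}, ("Y",)))
        again = Estimand.from_dict(res.estimand.to_dict())
        assert again == res.estimand

    def test_render_mentions_only_observed_vars(self):
        res = identify(FRONTDOOR, CausalQuery({"X": 1.0}, ("Y",)))
        assert res.estimand.variables() <= {"X", "Y", "Z"}
        assert "do" not in res.estimand.render()


def _soundness_admgs():
    cs1 = build_case("cs1_multicause_frontdoor")
    return {
        "frontdoor": (FRONTDOOR, CausalQuery({"X": 1}, ("Y",), "distribution")),
        "napkin": (NAPKIN, CausalQuery({"X": 1}, ("Y",), "distribution")),
        "cs1": (cs1.correct.admg(),
                CausalQuery({"dsrA": 0, "gadX": 0, "fis": 0}, ("cas2",), "distribution")),
    }


class TestEvaluationSoundness:
    def test_trivial_marginal(self):
        rng = np.random.default_rng(0)
        scm = DiscreteSCM(FRONTDOOR, rng)
        joint = scm.observational_joint()
        f = evaluate_estimand(Conditional(("Y",), ()), joint, {}, outcomes=("Y",))
        np.testing.assert_allclose(f.values, joint.marginal(["Y"]), atol=1e-12)

    def test_missing_variable_raises(self):
        rng = np.random.default_rng(0)
        joint = DiscreteSCM(FRONTDOOR, rng).observational_joint()
        with pytest.raises(ValueError, match="absent"):
            evaluate_estimand(Conditional(("Q",), ()), joint, {})

    @pytest.mark.parametrize("name", ["frontdoor", "napkin", "cs1"])
    def test_estimand_matches_surgery_enumeration(self, name):
        admg, query = _soundness_admgs()[name]
        res = identify(admg, query)
        assert res.identifiable
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(60):
            scm = DiscreteSCM(admg, rng)
            joint = scm.observational_joint()
            got = evaluate_estimand(res.estimand, joint, query.targets, outcomes=query.outcomes)
            want = scm.interventional_marginal({k: int(v) for k, v in query.targets.items()},
                                               set(query.outcomes))
            worst = max(worst, float(np.abs(got.values - want).max()))
        assert worst < 1e-10

    def test_backdoor_and_id_agree_numerically(self):
        # a graph where plain adjustment and the district factorization coexist
        g = MixedGraph(directed={("Z", "X"), ("Z", "Y"), ("X", "Y")})
        query = CausalQuery({"X": 1}, ("Y",), "distribution")
        res_bd = identify(g, query)
        assert res_bd.method == "backdoor"
        from causalpath.identify import id_algorithm

        est_id = id_algorithm(g, query)
        rng = np.random.default_rng(23)
        for _ in range(40):
            scm = DiscreteSCM(g, rng)
            joint = scm.observational_joint()
            a = evaluate_estimand(res_bd.estimand, joint, query.targets, outcomes=("Y",))
            b = evaluate_estimand(est_id, joint, query.targets, outcomes=("Y",))
            np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_multi_outcome_query_matches_surgery(self):
        # joint interventional distribution over two downstream outcomes
        g = MixedGraph(directed={("X", "Z"), ("Z", "Y"), ("Z", "W")},
                       bidirected={frozenset(("X", "Y"))})
        query = CausalQuery({"X": 1}, ("Y", "W"), "distribution")
        res = identify(g, query)
        assert res.identifiable
        rng = np.random.default_rng(29)
        for _ in range(30):
            scm = DiscreteSCM(g, rng)
            joint = scm.observational_joint()
            got = evaluate_estimand(res.estimand, joint, query.targets, outcomes=query.outcomes)
            want = scm.interventional_marginal({"X": 1}, {"Y", "W"})
            perm = [sorted(("Y", "W")).index(v) for v in got.vars]
            np.testing.assert_allclose(got.values, np.transpose(want, perm), atol=1e-10)

    def test_never_returns_estimand_for_bow(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            g = random_mixed_graph(rng, 5)
            x, y = sorted(g.observed)[:2]
            res = identify(g, CausalQuery({x: 0}, (y,), "distribution"))
            if res.identifiable:
                scm = DiscreteSCM(g, rng)
                joint = scm.observational_joint()
                got = evaluate_estimand(res.estimand, joint, {x: 0}, outcomes=(y,))
                want = scm.interventional_marginal({x: 0}, {y})
                np.testing.assert_allclose(got.values, want, atol=1e-8)
            else:
                assert res.estimand is None
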