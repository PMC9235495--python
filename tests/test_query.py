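"""Query estimation: Algorithm-1 sampling, plug-ins, closed forms, refusal."""

import numpy as np
import pytest

from causalpath.casestudies import build_example
from causalpath.graphs import parse_graph
from causalpath.identify import CausalQuery
from causalpath.query import (
    NonIdentifiableQueryError,
    closed_form_linear_gaussian,
    distribution_discrepancy,
    estimate_query,
    ground_truth_query,
    plugin_backdoor,
    plugin_frontdoor,
)
from causalpath.scm import CausalLVM, Dataset, ModelError, NodeSpec, PriorSpec


class TestQueryEstimate:
    def test_expectation_is_mean_of_draws(self, mediated_trained, mediated_spec):
        est = estimate_query(mediated_trained, mediated_spec.query, s_draws=100, l_draws=10, seed=1)
        assert est.expectation["Y"] == pytest.approx(est.draws["Y"].mean())
        assert len(est.draws) == 100 * 10
        assert est.meta["identify_method"] == "frontdoor"

    def test_density_integrates_to_one(self, mediated_trained, mediated_spec):
        est = estimate_query(mediated_trained, mediated_spec.query, s_draws=100, l_draws=10, seed=2)
        grid, pdf = est.density("Y")
        assert abs(np.trapezoid(pdf, grid) - 1.0) < 1e-3

    def test_zero_draws_rejected(self, mediated_trained, mediated_spec):
        with pytest.raises(ValueError):
            estimate_query(mediated_trained, mediated_spec.query, s_draws=0, l_draws=10)

    def test_save_artifacts(self, mediated_trained, mediated_spec, tmp_path):
        est = estimate_query(mediated_trained, mediated_spec.query, s_draws=20, l_draws=5, seed=3)
        est.save(tmp_path / "q")
        assert (tmp_path / "q_draws.csv").exists()
        assert (tmp_path / "q_density.csv").exists()
        assert (tmp_path / "q.json").exists()


class TestRefusal:
    def test_nonidentifiable_refused_with_identify_result(self, confounded_spec):
        theta = confounded_spec.true_theta()
        d = confounded_spec.correct.sample_observational(theta, 120, seed=4)
        tr = confounded_spec.correct.fit(d, chains=2, warmup=120, draws=80, seed=5)
        with pytest.raises(NonIdentifiableQueryError) as exc:
            estimate_query(tr, confounded_spec.query, s_draws=10, l_draws=5)
        assert exc.value.result.status == "not_identifiable"
        # forcing produces an estimate anyway (for the bias demonstration)
        est = estimate_query(tr, confounded_spec.query, s_draws=50, l_draws=10, seed=6,
                             force_nonidentifiable=True)
        assert est.meta["forced"] and np.isfinite(est.expectation["Y"])


class TestTrivialInvariances:
    def test_do_on_nondescendant_matches_observational_marginal(self, mediated_trained):
        """Intervening on Z cannot move X (rule 3): the interventional X
        distribution equals the posterior-predictive observational one."""
        q = CausalQuery({"Z": 2.0}, ("X",), "distribution")
        est = estimate_query(mediated_trained, q, s_draws=200, l_draws=10, seed=7)
        obs = estimate_query(mediated_trained, CausalQuery({"Z": -2.0}, ("X",), "distribution"),
                             s_draws=200, l_draws=10, seed=8)
        # two different interventions on Z: X's marginal is unchanged
        assert abs(est.expectation["X"] - obs.expectation["X"]) < 0.15
        assert distribution_discrepancy(est.draws["X"], obs.draws["X"]) < 0.1


class TestGroundTruth:
    def test_matches_closed_form(self, mediated_spec, mediated_theta):
        mean, var = closed_form_linear_gaussian(mediated_spec.correct, mediated_theta, mediated_spec.query)
        gt = ground_truth_query(mediated_spec.correct, mediated_theta, mediated_spec.query,
                                n=20000, seed=9)
        se = np.sqrt(var / 20000)
        assert abs(gt.expectation["Y"] - mean) < 4 * se

    def test_reproducible_under_seed(self, mediated_spec, mediated_theta):
        a = ground_truth_query(mediated_spec.correct, mediated_theta, mediated_spec.query, n=500, seed=10)
        b = ground_truth_query(mediated_spec.correct, mediated_theta, mediated_spec.query, n=500, seed=10)
        assert a.expectation == b.expectation


class TestClosedForm:
    def test_chain_do_substitution(self):
        g = parse_graph("X -> Z\nZ -> Y\n")
        m = CausalLVM(g, {n: NodeSpec(n, "gaussian_linear", tuple(g.parents(n))) for n in g.nodes})
        theta = {"X": {"intercept": 0, "sigma": 1},
                 "Z": {"w_X": 1.2, "intercept": -0.3, "sigma": 0.5},
                 "Y": {"w_Z": 0.9, "intercept": 0.2, "sigma": 0.7}}
        mean, var = closed_form_linear_gaussian(m, theta, CausalQuery({"X": 2.0}, ("Y",)))
        assert mean == pytest.approx(0.9 * (1.2 * 2 - 0.3) + 0.2)
        assert var == pytest.approx(0.9**2 * 0.5**2 + 0.7**2)

    def test_do_on_only_parent_gives_noise_variance(self):
        g = parse_graph("Z -> Y")
        m = CausalLVM(g, {"Z": NodeSpec("Z", "gaussian_linear", ()),
                          "Y": NodeSpec("Y", "gaussian_linear", ("Z",))})
        theta = {"Z": {"intercept": 0, "sigma": 1},
                 "Y": {"w_Z": 2.0, "intercept": 1.0, "sigma": 0.6}}
        mean, var = closed_form_linear_gaussian(m, theta, CausalQuery({"Z": 3.0}, ("Y",)))
        assert mean == pytest.approx(7.0)
        assert var == pytest.approx(0.36)

    def test_nongaussian_family_rejected(self):
        g = parse_graph("X -> Y")
        m = CausalLVM(g, {"X": NodeSpec("X", "gaussian_linear", ()),
                          "Y": NodeSpec("Y", "bernoulli_logit", ("X",))})
        theta = {"X": {"intercept": 0, "sigma": 1}, "Y": {"w_X": 1.0, "intercept": 0.0}}
        with pytest.raises(ModelError, match="gaussian"):
            closed_form_linear_gaussian(m, theta, CausalQuery({"X": 1.0}, ("Y",)))


def _binary_frontdoor_model():
    g = parse_graph("latent U\nU -> X\nU -> Y\nX -> Z\nZ -> Y\n")
    specs = {
        "U": NodeSpec("U", "gaussian_linear", (),
                      {"intercept": PriorSpec(0, 1), "sigma": PriorSpec(0, 1, "positive")}),
        "X": NodeSpec("X", "bernoulli_logit", ("U",)),
        "Z": NodeSpec("Z", "bernoulli_logit", ("X",)),
        "Y": NodeSpec("Y", "bernoulli_logit", ("Z", "U")),
    }
    m = CausalLVM(g, specs)
    theta = {
        "U": {"intercept": 0.0, "sigma": 1.0},
        "X": {"w_U": 1.2, "intercept": 0.2},
        "Z": {"w_X": 1.5, "intercept": -0.6},
        "Y": {"w_Z": 1.1, "w_U": 0.9, "intercept": -0.4},
    }
    return m, theta


class TestPlugins:
    def test_discrete_frontdoor_matches_interventional_truth(self):
        m, theta = _binary_frontdoor_model()
        d = m.sample_observational(theta, 60000, seed=11)
        truth = m.sample_interventional(theta, {"X": 1.0}, 60000, seed=12).frame["Y"].mean()
        got = plugin_frontdoor(d, "X", "Y", "Z", 1.0)
        assert abs(got - truth) < 0.02

    def test_continuous_frontdoor_matches_closed_form(self, mediated_spec, mediated_theta):
        mean, var = closed_form_linear_gaussian(mediated_spec.correct, mediated_theta, mediated_spec.query)
        d = mediated_spec.correct.sample_observational(mediated_theta, 8000, seed=13)
        got = plugin_frontdoor(d, "X", "Y", "Z", 2.0, seed=14)
        assert abs(got - mean) < 0.15

    def test_independent_mediator_makes_plugin_flat_in_x(self, mediated_spec, mediated_theta):
        theta = {k: dict(v) for k, v in mediated_theta.items()}
        theta["Z"]["w_X"] = 0.0  # x independent of z: effect vanishes
        m = mediated_spec.correct
        d = m.sample_observational(theta, 6000, seed=15)
        lo = plugin_frontdoor(d, "X", "Y", "Z", -2.0, seed=16)
        hi = plugin_frontdoor(d, "X", "Y", "Z", 2.0, seed=16)
        assert abs(hi - lo) < 0.1

    def test_degenerate_support_cites_positivity(self, mediated_spec, mediated_theta):
        d = mediated_spec.correct.sample_interventional(mediated_theta, {"X": 1.0}, 200, seed=17)
        with pytest.raises(ModelError, match="P\\(x, z\\) > 0"):
            plugin_frontdoor(d, "X", "Y", "Z", 1.0)

    def test_backdoor_no_confounding_reduces_to_regression(self):
        g = parse_graph("X -> Y")
        m = CausalLVM(g, {"X": NodeSpec("X", "gaussian_linear", ()),
                          "Y": NodeSpec("Y", "gaussian_linear", ("X",))})
        theta = {"X": {"intercept": 0, "sigma": 1},
                 "Y": {"w_X": 1.4, "intercept": 0.5, "sigma": 0.5}}
        d = m.sample_observational(theta, 6000, seed=18)
        got = plugin_backdoor(d, "X", "Y", (), 1.5)
        assert abs(got - (1.4 * 1.5 + 0.5)) < 0.05

    def test_discrete_backdoor_matches_interventional_truth(self):
        g = parse_graph("Z -> X\nZ -> Y\nX -> Y\n")
        specs = {
            "Z": NodeSpec("Z", "bernoulli_logit", ()),
            "X": NodeSpec("X", "bernoulli_logit", ("Z",)),
            "Y": NodeSpec("Y", "bernoulli_logit", ("X", "Z")),
        }
        m = CausalLVM(g, specs)
        theta = {"Z": {"intercept": 0.3}, "X": {"w_Z": 1.0, "intercept": -0.2},
                 "Y": {"w_X": 1.3, "w_Z": 0.8, "intercept": -0.5}}
        d = m.sample_observational(theta, 60000, seed=19)
        truth = m.sample_interventional(theta, {"X": 1.0}, 60000, seed=20).frame["Y"].mean()
        got = plugin_backdoor(d, "X", "Y", {"Z"}, 1.0)
        assert abs(got - truth) < 0.02


class TestDiscrepancyMetric:
    def test_identical_samples_near_zero(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(2000)
        assert distribution_discrepancy(x, x) < 1e-9

    def test_shifted_samples_large(self):
        rng = np.random.default_rng(22)
        x = rng.standard_normal(2000)
        assert distribution_discrepancy(x, x + 5.0) > 0.9
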