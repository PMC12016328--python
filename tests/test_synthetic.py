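import numpy as np
import pytest

from predcurve import PopulationSpec, generate, population_oracle, summarize
from tests.conftest import FEVER


class TestSpecValidation:
    def test_rejects_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            PopulationSpec("gamma", {})

    def test_rejects_bad_two_point_order(self):
        with pytest.raises(ValueError):
            PopulationSpec("two_point", {"w": 0.5, "a": 0.8, "b": 0.2})

    def test_sampled_mode_needs_seed(self):
        with pytest.raises(ValueError, match="seed"):
            PopulationSpec("beta", {"alpha": 2.0, "beta": 8.0},
                           mode="sampled", n=100)


class TestGenerate:
    def test_fever_exact_prevalence(self, fever_sample):
        assert fever_sample.mean_risk() == pytest.approx(0.147, abs=5e-4)

    def test_perfect_atoms(self):
        s = generate(PopulationSpec("perfect", {"pi": 0.25}))
        assert sorted(s.risks.tolist()) == [0.0, 1.0]
        assert s.weights[s.risks == 1.0][0] == pytest.approx(0.25)

    def test_beta_grid_recovers_closed_form_ev(self):
        s = generate(PopulationSpec("beta", {"alpha": 2.0, "beta": 8.0}))
        ev = summarize(s, "risks").ev_ind
        assert ev == pytest.approx(1.0 / 11.0, abs=1e-4)

    def test_exact_outcome_mass_is_calibrated(self, fever_population):
        assert fever_population.mean_outcome() == pytest.approx(
            fever_population.mean_risk(), abs=1e-15)

    def test_sampled_mode_is_seed_reproducible(self):
        spec = PopulationSpec("logistic_gaussian",
                              {"intercept": -2.0, "slope": 1.0},
                              mode="sampled", n=500, seed=42)
        s1, s2 = generate(spec), generate(spec)
        assert np.array_equal(s1.risks, s2.risks)
        assert np.array_equal(s1.outcomes, s2.outcomes)

    def test_sampled_mode_converges_to_exact_mode(self):
        params = dict(FEVER)
        exact = summarize(generate(PopulationSpec("two_point", params)), "risks")
        for n in (1_000, 10_000, 100_000):
            spec = PopulationSpec("two_point", params, mode="sampled",
                                  n=n, seed=7)
            est = summarize(generate(spec), "risks")
            # Monte-Carlo band for STG: dominated by binomial noise of the
            # group split; 3 * 0.5/sqrt(n) is a conservative envelope
            assert abs(est.stg - exact.stg) < 3 * 0.5 / np.sqrt(n)


class TestPopulationOracle:
    def test_two_point_matches_estimators(self, fever_spec, fever_sample):
        oracle = population_oracle(fever_spec)
        flat = summarize(fever_sample, "risks").as_dict()
        for key in ("prevalence", "q0", "a_n", "a_s", "dn1", "dn2", "ds1",
                    "ds2", "ev_ind", "tg", "stg"):
            assert flat[key] == pytest.approx(oracle[key], abs=1e-10)

    def test_uninformative_all_zero(self):
        oracle = population_oracle(PopulationSpec("uninformative", {"pi": 0.3}))
        for key in ("a_n", "a_s", "tg", "stg", "dn1", "dn2", "ds1", "ds2",
                    "ev_ind", "c_d", "aard"):
            assert oracle[key] == pytest.approx(0.0, abs=1e-12)

    def test_beta_ev_closed_form(self):
        oracle = population_oracle(PopulationSpec("beta", {"alpha": 2.0,
                                                           "beta": 8.0}))
        assert oracle["ev_ind"] == pytest.approx(1.0 / 11.0, abs=1e-8)

    @pytest.mark.parametrize("family,params", [
        ("beta", {"alpha": 2.0, "beta": 8.0}),
        ("logistic_gaussian", {"intercept": -2.0, "slope": 1.0}),
        ("logistic_gaussian", {"intercept": -1.0, "slope": -1.5}),
    ])
    def test_exact_grid_estimators_match_oracle(self, family, params):
        spec = PopulationSpec(family, params, grid_size=200_001)
        sample = generate(spec)
        oracle = population_oracle(spec)
        flat = summarize(sample, "risks").as_dict()
        for key in ("prevalence", "q0", "dn1", "dn2", "ds1", "ds2",
                    "ev_ind", "stg"):
            assert flat[key] == pytest.approx(oracle[key], abs=5e-5), key
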