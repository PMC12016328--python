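import numpy as np
import pytest

from predcurve import (PopulationSpec, RiskSample, aard, areas, ev_ind,
                       generate, nec_suff, population_oracle, sens_spec,
                       summarize, tg_stg, tjur_cd)
from tests.conftest import FEVER_PREV


@pytest.fixture(scope="module")
def perfect():
    return generate(PopulationSpec("perfect", {"pi": 0.25}))


@pytest.fixture(scope="module")
def uninformative():
    return generate(PopulationSpec("uninformative", {"pi": 0.25}))


class TestAreas:
    def test_fever_rectangles(self, fever_sample):
        dec = areas(fever_sample, FEVER_PREV)
        assert round(dec.a_n, 3) == 0.018
        assert dec.a_n == pytest.approx(dec.a_s, abs=1e-15)  # calibrated
        assert dec.tg == dec.a_n + dec.a_s

    def test_constant_risks_have_zero_area(self):
        dec = areas(RiskSample([0.3, 0.3]), 0.3)
        assert dec.a_n == 0.0 and dec.a_s == 0.0

    def test_perfect_marker_area(self, perfect):
        dec = areas(perfect, 0.25)
        assert dec.a_n == pytest.approx(0.1875, abs=1e-15)
        assert dec.a_s == pytest.approx(0.1875, abs=1e-15)


class TestNecSuff:
    def test_fever_table_row(self, fever_sample):
        ns = nec_suff(fever_sample, FEVER_PREV)
        assert round(ns.dn1, 2) == 0.27 and round(ns.dn2, 2) == 0.27
        assert round(ns.ds1, 2) == 0.04 and round(ns.ds2, 2) == 0.04

    def test_perfect_marker_scores_one(self, perfect):
        ns = nec_suff(perfect, 0.25)
        assert ns.dn1 == ns.dn2 == ns.ds1 == ns.ds2 == 1.0

    def test_uninformative_scores_zero(self, uninformative):
        ns = nec_suff(uninformative, 0.25)
        assert ns.dn1 == ns.dn2 == ns.ds1 == ns.ds2 == 0.0
        assert ns.frac_tied == 1.0

    def test_beta_grid_matches_quadrature(self):
        # a fine equal-probability grid of the Beta(2,8) law reproduces the
        # defining expectations integrated by adaptive quadrature
        spec = PopulationSpec("beta", {"alpha": 2.0, "beta": 8.0},
                              grid_size=2_000_001)
        sample = generate(spec)
        oracle = population_oracle(spec)
        prev = sample.mean_risk()
        ns = nec_suff(sample, prev)
        for est, ref in [(ns.dn1, oracle["dn1"]), (ns.dn2, oracle["dn2"]),
                         (ns.ds1, oracle["ds1"]), (ns.ds2, oracle["ds2"])]:
            assert est == pytest.approx(ref, abs=1e-6)


class TestExplainedVariation:
    def test_fever_value(self, fever_sample):
        assert round(ev_ind(fever_sample, FEVER_PREV), 2) == 0.01

    def test_constant_risks(self):
        assert ev_ind(RiskSample([0.3, 0.3]), 0.3) == 0.0

    @pytest.mark.parametrize("a,b", [(2.0, 8.0), (1.5, 1.5)])
    def test_beta_closed_form(self, a, b):
        # Var/(mu(1-mu)) for Beta(a,b) is 1/(a+b+1)
        sample = generate(PopulationSpec("beta", {"alpha": a, "beta": b}))
        assert ev_ind(sample, sample.mean_risk()) == pytest.approx(
            1.0 / (a + b + 1.0), abs=1e-4)


class TestTjur:
    def test_risks_equal_outcomes(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert tjur_cd(RiskSample(y.copy(), outcomes=y)) == 1.0

    def test_constant_risks(self):
        assert tjur_cd(RiskSample([0.5, 0.5], outcomes=[0, 1])) == 0.0

    def test_fever_population_mixture_value(self, fever_population):
        # P1(D) - P0(D) from exact mixture algebra of the two printed risks
        er2 = 0.45 * 0.107**2 + 0.55 * 0.180**2
        expected = er2 / FEVER_PREV - (FEVER_PREV - er2) / (1 - FEVER_PREV)
        assert tjur_cd(fever_population) == pytest.approx(expected, abs=1e-12)
        assert tjur_cd(fever_population) == pytest.approx(0.0105, abs=5e-5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            tjur_cd(RiskSample([0.2, 0.4], outcomes=[1, 1]))


class TestTotalGain:
    def test_fever_stg(self, fever_sample):
        _, stg = tg_stg(areas(fever_sample, FEVER_PREV))
        assert round(stg, 2) == 0.14

    def test_perfect_marker(self, perfect):
        _, stg = tg_stg(areas(perfect, 0.25))
        assert stg == pytest.approx(1.0, abs=1e-15)

    def test_uninformative_marker(self, uninformative):
        _, stg = tg_stg(areas(uninformative, 0.25))
        assert stg == 0.0


class TestAARD:
    def test_perfect_marker(self):
        s = generate(PopulationSpec("perfect", {"pi": 0.25}),
                     include_outcomes=True)
        assert aard(s, 0.25) == pytest.approx(1.0)

    def test_uninformative_marker(self):
        s = generate(PopulationSpec("uninformative", {"pi": 0.25}),
                     include_outcomes=True)
        assert aard(s, 0.25) == 0.0

    def test_fever_population_bayes_inversion(self, fever_population):
        # fraction below prevalence among non-events / events, from Bayes
        q0_non = 0.45 * (1 - 0.107) / (1 - FEVER_PREV)
        q0_ev = 0.45 * 0.107 / FEVER_PREV
        expected = q0_non - q0_ev
        assert aard(fever_population, FEVER_PREV) == pytest.approx(expected, abs=1e-12)
        assert aard(fever_population, FEVER_PREV) == pytest.approx(0.144, abs=5e-4)
        sens, spec = sens_spec(fever_population, FEVER_PREV)
        assert sens == pytest.approx(1 - q0_ev, abs=1e-12)
        assert spec == pytest.approx(q0_non, abs=1e-12)
        # Youden identity at a tie-free threshold
        assert sens + spec - 1 == pytest.approx(expected, abs=1e-12)


class TestSummarize:
    def test_fever_report_row(self, fever_sample):
        flat = summarize(fever_sample, "risks").as_dict()
        rounded = {k: round(flat[k], 2)
                   for k in ("ev_ind", "dn1", "ds1", "dn2", "ds2", "stg")}
        assert rounded == {"ev_ind": 0.01, "dn1": 0.27, "ds1": 0.04,
                           "dn2": 0.27, "ds2": 0.04, "stg": 0.14}

    def test_uninformative_all_zero(self, uninformative):
        flat = summarize(uninformative, "risks").as_dict()
        for k in ("ev_ind", "dn1", "ds1", "dn2", "ds2", "tg", "stg"):
            assert flat[k] == 0.0

    def test_perfect_all_one(self):
        s = generate(PopulationSpec("perfect", {"pi": 0.25}),
                     include_outcomes=True)
        flat = summarize(s, "risks").as_dict()
        for k in ("ev_ind", "dn1", "ds1", "dn2", "ds2", "stg", "c_d", "aard"):
            assert flat[k] == pytest.approx(1.0, abs=1e-12)

    def test_outcome_fields_absent_without_outcomes(self, fever_sample):
        summ = summarize(fever_sample, "risks")
        assert summ.c_d is None and summ.aard is None
        assert summ.sens_at_prev is None
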