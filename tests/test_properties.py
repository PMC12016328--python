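"""Property-based checks of the exact identities and inequality chains."""

import numpy as np
from hypothesis import given, settings, strategies as st

from predcurve import (RiskSample, areas, dichotomize_at_risk, ev_ind,
                       nec_suff, summarize, tg_stg)

TOL = 1e-12


@st.composite
def risk_samples(draw, tie_free=True, max_size=60):
    n = draw(st.integers(3, max_size))
    risks = draw(st.lists(
        st.floats(1e-4, 1.0 - 1e-4, allow_nan=False), min_size=n, max_size=n,
        unique=tie_free,
    ))
    weights = draw(st.lists(st.floats(0.05, 3.0), min_size=n, max_size=n))
    sample = RiskSample(np.array(risks), weights=np.array(weights))
    mu = sample.mean_risk()
    return sample if 0.0 < mu < 1.0 else RiskSample(np.array(risks))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(risk_samples())
def test_area_identities(sample):
    """DN2 and DS2 equal the hatched areas over their denominator rectangles."""
    prev = sample.mean_risk()
    dec = areas(sample, prev)
    ns = nec_suff(sample, prev)
    if ns.frac_protective > 0:
        assert abs(ns.dn2 - dec.a_n / (prev * ns.frac_protective)) <= TOL
    if ns.frac_harmful > 0:
        assert abs(ns.ds2 - dec.a_s / ((1 - prev) * ns.frac_harmful)) <= TOL


@settings(max_examples=200, derandomize=True, deadline=None)
@given(risk_samples(tie_free=False))
def test_rms_dominates_mean(sample):
    """DN1 >= DN2 and DS1 >= DS2 on every input (RMS >= mean)."""
    prev = sample.mean_risk()
    ns = nec_suff(sample, prev)
    assert ns.dn1 >= ns.dn2 - TOL
    assert ns.ds1 >= ns.ds2 - TOL
    assert 0.0 <= ns.dn2 <= 1.0 and 0.0 <= ns.ds2 <= 1.0
    assert abs(ns.frac_protective + ns.frac_harmful + ns.frac_tied - 1.0) <= TOL


@settings(max_examples=200, derandomize=True, deadline=None)
@given(risk_samples())
def test_bound_chain_on_calibrated_samples(sample):
    """DN2 * DS2 <= EV <= STG when the prevalence is the mean risk."""
    prev = sample.mean_risk()
    ns = nec_suff(sample, prev)
    ev = ev_ind(sample, prev)
    _, stg = tg_stg(areas(sample, prev))
    assert ns.dn2 * ns.ds2 <= ev + TOL
    assert ev <= stg + TOL


@settings(max_examples=200, derandomize=True, deadline=None)
@given(risk_samples())
def test_calibration_symmetry(sample):
    """A_N equals A_S whenever prevalence equals the mean risk."""
    dec = areas(sample, sample.mean_risk())
    assert abs(dec.a_n - dec.a_s) <= TOL


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.floats(0.05, 0.95), st.floats(0.001, 0.45), st.floats(0.55, 0.999))
def test_dichotomous_exactness(w, a, b):
    """Two-point locally calibrated samples: DN1=DN2, DS1=DS2, EV=DN1*DS1."""
    sample = RiskSample(np.array([a, b]), weights=np.array([w, 1 - w]))
    prev = sample.mean_risk()
    ns = nec_suff(sample, prev)
    ev = ev_ind(sample, prev)
    assert abs(ns.dn1 - ns.dn2) <= TOL
    assert abs(ns.ds1 - ns.ds2) <= TOL
    assert abs(ev - ns.dn1 * ns.ds1) <= TOL


@settings(max_examples=200, derandomize=True, deadline=None)
@given(risk_samples())
def test_dichotomization_invariance(sample):
    """Coarsening at the mean risk preserves DN2/DS2/STG; EV/DN1/DS1 shrink."""
    prev = sample.mean_risk()
    if not (sample.risks < prev).any() or not (sample.risks > prev).any():
        return  # flat sample: nothing to coarsen
    if (sample.risks == prev).any():
        return  # invariance is stated for samples tie-free at the prevalence
    before = summarize(sample, "risks").as_dict()
    coarse = dichotomize_at_risk(sample, prev)
    after = summarize(coarse, "risks").as_dict()
    for key in ("dn2", "ds2", "stg"):
        assert abs(before[key] - after[key]) <= TOL
    for key in ("ev_ind", "dn1", "ds1"):
        assert after[key] <= before[key] + TOL


@settings(max_examples=100, derandomize=True, deadline=None)
@given(risk_samples(tie_free=False), st.randoms(use_true_random=False))
def test_permutation_invariance(sample, rnd):
    """All measures depend only on the multiset of (risk, weight) pairs."""
    order = list(range(sample.n))
    rnd.shuffle(order)
    perm = RiskSample(sample.risks[order], weights=sample.weights[order])
    prev = sample.mean_risk()
    assert summarize(sample, "risks").as_dict() == \
        summarize(RiskSample(sample.risks, weights=sample.weights), "risks").as_dict()
    a0, a1 = areas(sample, prev), areas(perm, prev)
    assert abs(a0.a_n - a1.a_n) <= TOL and abs(a0.a_s - a1.a_s) <= TOL
    n0, n1 = nec_suff(sample, prev), nec_suff(perm, prev)
    assert abs(n0.dn1 - n1.dn1) <= TOL and abs(n0.ds1 - n1.ds1) <= TOL
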