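import numpy as np
import pytest

from predcurve import PopulationSpec, RiskSample, generate

# The worked two-point example: a dichotomous marker assigning risk 0.107 to
# 45% of the population and 0.180 to the remaining 55%.  Its mixture mean
# (the prevalence under calibration) is 0.14715.
FEVER = dict(w=0.45, a=0.107, b=0.180)
FEVER_PREV = 0.45 * 0.107 + 0.55 * 0.180


@pytest.fixture(scope="session")
def fever_spec() -> PopulationSpec:
    return PopulationSpec("two_point", dict(FEVER))


@pytest.fixture(scope="session")
def fever_sample(fever_spec) -> RiskSample:
    """Exact-weights two-point sample, no outcomes."""
    return generate(fever_spec)


@pytest.fixture(scope="session")
def fever_population(fever_spec) -> RiskSample:
    """Exact-weights two-point sample with Bernoulli(risk) outcome mass."""
    return generate(fever_spec, include_outcomes=True)


def random_calibrated_sample(rng: np.random.Generator,
                             n_min: int = 5, n_max: int = 200) -> RiskSample:
    """A tie-free weighted risk sample; calibrated when prevalence = mean risk."""
    n = int(rng.integers(n_min, n_max))
    risks = rng.beta(rng.uniform(0.3, 5.0), rng.uniform(0.3, 5.0), n)
    weights = rng.uniform(0.1, 2.0, n)
    return RiskSample(risks, weights=weights)
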