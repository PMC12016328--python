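"""Synthetic risk populations with known ground truth.

Families
--------
``two_point``
    A dichotomous marker: risk ``a`` on a weight-``w`` stratum and risk ``b``
    on the rest.  The predictiveness curve is a single step.
``beta``
    Risks drawn from a Beta(alpha, beta) law; explained variation has the
    closed form 1 / (alpha + beta + 1).
``logistic_gaussian``
    A logistic model expit(intercept + slope * X) with standard-normal X —
    the smallest family with a smooth, asymmetric predictiveness curve.
``uninformative``
    Constant risk equal to the prevalence; every measure is 0.
``perfect``
    Risks in {0, 1}; every measure is 1.

Two modes: ``exact_weights`` encodes the population law itself as a weighted
sample (two-point families exactly; continuous laws on an equal-probability
quantile grid with uniform weights, so tie handling and step integration stay
exact), while ``sampled`` draws n subjects with outcomes Bernoulli(risk),
hence calibrated in expectation.

:func:`population_oracle` evaluates the defining expectations of every
measure by adaptive quadrature (or finite sums) over the risk law — a
brute-force reference that never touches the sample estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats
from scipy.special import expit, logit

from .sample import RiskSample

__all__ = ["PopulationSpec", "generate", "population_oracle"]

_FAMILIES = ("two_point", "beta", "logistic_gaussian", "uninformative", "perfect")


@dataclass(frozen=True)
class PopulationSpec:
    """A synthetic risk population.

    Parameters
    ----------
    family : str
        One of ``two_point``, ``beta``, ``logistic_gaussian``,
        ``uninformative``, ``perfect``.
    params : dict
        Family parameters: two_point ``{w, a, b}`` (0 <= a <= b <= 1,
        0 < w < 1); beta ``{alpha, beta}`` (> 0); logistic_gaussian
        ``{intercept, slope}``; uninformative/perfect ``{pi}`` (prevalence
        in (0, 1)).
    mode : {"exact_weights", "sampled"}
    n : int, optional
        Sample size (sampled mode; >= 2).
    seed : int, optional
        Required in sampled mode.
    grid_size : int
        Number of equal-probability grid atoms used to discretize continuous
        laws in exact mode.
    """

    family: str
    params: dict = field(default_factory=dict)
    mode: str = "exact_weights"
    n: int | None = None
    seed: int | None = None
    grid_size: int = 10_001

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.mode not in ("exact_weights", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        p = self.params
        if self.family == "two_point":
            w, a, b = p["w"], p["a"], p["b"]
            if not (0.0 <= a <= b <= 1.0):
                raise ValueError("two_point requires 0 <= a <= b <= 1")
            if not 0.0 < w < 1.0:
                raise ValueError("two_point requires 0 < w < 1")
        elif self.family == "beta":
            if p["alpha"] <= 0.0 or p["beta"] <= 0.0:
                raise ValueError("beta requires alpha, beta > 0")
        elif self.family == "logistic_gaussian":
            p["intercept"], p["slope"]  # KeyError if missing
        else:
            if not 0.0 < p["pi"] < 1.0:
                raise ValueError("prevalence pi must lie in (0, 1)")
        if self.mode == "sampled":
            if self.n is None or self.n < 2:
                raise ValueError("sampled mode requires n >= 2")
            if self.seed is None:
                raise ValueError("sampled mode requires a seed")


def _atoms(spec: PopulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Finite (risk, probability-mass) representation of the law."""
    p = spec.params
    if spec.family == "two_point":
        return (np.array([p["a"], p["b"]]), np.array([p["w"], 1.0 - p["w"]]))
    if spec.family == "uninformative":
        return (np.array([p["pi"], p["pi"]]), np.array([0.5, 0.5]))
    if spec.family == "perfect":
        return (np.array([0.0, 1.0]), np.array([1.0 - p["pi"], p["pi"]]))
    # continuous laws: midpoint quantile grid, equal weights
    m = spec.grid_size
    q = (np.arange(m) + 0.5) / m
    if spec.family == "beta":
        risks = stats.beta.ppf(q, p["alpha"], p["beta"])
    else:  # logistic_gaussian
        risks = expit(p["intercept"] + p["slope"] * stats.norm.ppf(q))
    return risks, np.full(m, 1.0 / m)


def generate(spec: PopulationSpec, include_outcomes: bool = False) -> RiskSample:
    """Realize a :class:`PopulationSpec` as a :class:`RiskSample`.

    In exact-weights mode the returned sample encodes the law itself; with
    ``include_outcomes=True`` each atom is split into an event and a
    non-event row with Bernoulli(risk) mass, so outcome-dependent measures
    (Tjur, AARD) are also exact.  In sampled mode risks are drawn from the
    law and outcomes are drawn Bernoulli(risk), bit-reproducible under the
    spec's seed.
    """
    if spec.mode == "exact_weights":
        risks, mass = _atoms(spec)
        if not include_outcomes:
            return RiskSample(risks, weights=mass)
        r = np.repeat(risks, 2)
        y = np.tile([0.0, 1.0], risks.size)
        w = np.repeat(mass, 2) * np.where(y == 1.0, r, 1.0 - r)
        keep = w > 0.0
        return RiskSample(r[keep], outcomes=y[keep], weights=w[keep])

    rng = np.random.default_rng(spec.seed)
    p = spec.params
    n = spec.n
    if spec.family == "two_point":
        low = rng.random(n) < p["w"]
        risks = np.where(low, p["a"], p["b"])
    elif spec.family == "beta":
        risks = rng.beta(p["alpha"], p["beta"], size=n)
    elif spec.family == "logistic_gaussian":
        risks = expit(p["intercept"] + p["slope"] * rng.standard_normal(n))
    elif spec.family == "uninformative":
        risks = np.full(n, p["pi"])
    else:  # perfect
        risks = (rng.random(n) < p["pi"]).astype(float)
    outcomes = (rng.random(n) < risks).astype(float)
    return RiskSample(risks, outcomes=outcomes)


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------

def _discrete_oracle(risks: np.ndarray, mass: np.ndarray) -> dict:
    prev = float(np.sum(mass * risks))
    below = risks < prev
    above = risks > prev
    m0 = float(mass[below].sum())
    m1 = float(mass[above].sum())
    i1n = float(np.sum(mass[below] * (prev - risks[below])))
    i2n = float(np.sum(mass[below] * (prev - risks[below]) ** 2))
    i1s = float(np.sum(mass[above] * (risks[above] - prev)))
    i2s = float(np.sum(mass[above] * (risks[above] - prev) ** 2))
    var = float(np.sum(mass * (risks - prev) ** 2))
    er2 = float(np.sum(mass * risks**2))
    elow = float(np.sum(mass[below] * risks[below]))
    return dict(prev=prev, m0=m0, m1=m1, i1n=i1n, i2n=i2n, i1s=i1s, i2s=i2s,
                var=var, er2=er2, elow=elow)


def _continuous_oracle(spec: PopulationSpec) -> dict:
    """Adaptive quadrature of the defining expectations over the risk law."""
    p = spec.params
    if spec.family == "beta":
        a, b = p["alpha"], p["beta"]
        pdf, lo, hi = stats.beta(a, b).pdf, 0.0, 1.0
        risk_of = lambda t: t  # integrate directly over the risk scale
        prev = a / (a + b)
    else:  # logistic_gaussian over the latent X scale
        c0, c1 = p["intercept"], p["slope"]
        pdf, lo, hi = stats.norm.pdf, -np.inf, np.inf
        risk_of = lambda t: expit(c0 + c1 * t)
        prev = integrate.quad(lambda t: risk_of(t) * pdf(t), lo, hi)[0]

    def expect(fn, lower, upper):
        val, _ = integrate.quad(lambda t: fn(risk_of(t)) * pdf(t), lower, upper,
                                limit=200)
        return val

    # split the domain at the point where risk == prev (both families are
    # monotone in the integration variable)
    if spec.family == "beta":
        t0 = prev
    else:
        t0 = (logit(prev) - p["intercept"]) / p["slope"]
    lo_side, hi_side = ((lo, t0), (t0, hi))
    if spec.family == "logistic_gaussian" and p["slope"] < 0:
        lo_side, hi_side = (t0, hi), (lo, t0)

    return dict(
        prev=prev,
        m0=expect(lambda r: 1.0, *lo_side),
        m1=expect(lambda r: 1.0, *hi_side),
        i1n=expect(lambda r: prev - r, *lo_side),
        i2n=expect(lambda r: (prev - r) ** 2, *lo_side),
        i1s=expect(lambda r: r - prev, *hi_side),
        i2s=expect(lambda r: (r - prev) ** 2, *hi_side),
        var=expect(lambda r: (r - prev) ** 2, lo, hi),
        er2=expect(lambda r: r**2, lo, hi),
        elow=expect(lambda r: r, *lo_side),
    )


def population_oracle(spec: PopulationSpec) -> dict:
    """Population values of every measure, by direct integration.

    Returns a dict with keys ``prevalence, q0, a_n, a_s, tg, stg, dn1, dn2,
    ds1, ds2, ev_ind, c_d, aard``.  Computed from the defining expectations
    of each measure — not from the sample estimators — so it can serve as an
    independent reference for them.
    """
    if spec.family in ("two_point", "uninformative", "perfect"):
        risks, mass = _atoms(spec)
        g = _discrete_oracle(risks, mass)
    else:
        g = _continuous_oracle(spec)

    prev, m0, m1 = g["prev"], g["m0"], g["m1"]
    a_n, a_s = g["i1n"], g["i1s"]
    tg = a_n + a_s
    stg = tg / (2.0 * prev * (1.0 - prev))
    dn2 = g["i1n"] / (prev * m0) if m0 > 0 else 0.0
    dn1 = np.sqrt(g["i2n"] / m0) / prev if m0 > 0 else 0.0
    ds2 = g["i1s"] / ((1.0 - prev) * m1) if m1 > 0 else 0.0
    ds1 = np.sqrt(g["i2s"] / m1) / (1.0 - prev) if m1 > 0 else 0.0
    ev = g["var"] / (prev * (1.0 - prev))
    # Tjur: P1(D) = E[R^2]/P(D), P0(D) = E[R(1-R)]/(1-P(D))
    p1 = g["er2"] / prev
    p0 = (prev - g["er2"]) / (1.0 - prev)
    # AARD: q0^0 = E[(1-R); R<prev]/(1-prev), q0^1 = E[R; R<prev]/prev
    q0_non = (m0 - g["elow"]) / (1.0 - prev)
    q0_ev = g["elow"] / prev
    return {
        "prevalence": prev,
        "q0": m0,
        "a_n": a_n,
        "a_s": a_s,
        "tg": tg,
        "stg": stg,
        "dn1": float(dn1),
        "dn2": dn2,
        "ds1": float(ds1),
        "ds2": ds2,
        "ev_ind": ev,
        "c_d": p1 - p0,
        "aard": q0_non - q0_ev,
    }
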