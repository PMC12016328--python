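"""The predictiveness curve R(q): risk as a function of the risk quantile.

R(q) is the left-continuous empirical quantile function of the predicted
risks — risks sorted from lowest to highest against their cumulative weight
share.  It is a nondecreasing step function on [0, 1] whose height at
quantile q answers "what risk does the subject at the q-th percentile of the
risk distribution carry?".  The quantile q0 where R crosses the prevalence
P(D) splits the population into the protective range (risk below prevalence)
and the harmful range (risk above).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sample import RiskSample

__all__ = [
    "PredictivenessCurve",
    "StratifiedCurves",
    "build_curve",
    "compute_q0",
    "risk_at_quantile",
    "stratified",
]


@dataclass(frozen=True)
class PredictivenessCurve:
    """Step representation of R(q).

    Attributes
    ----------
    sorted_risks : ndarray
        Risks in nondecreasing order.
    cum_shares : ndarray
        Cumulative weight share at each sorted risk; last entry is 1.
    prevalence : float
        The horizontal reference line P(D).
    q0 : float
        Weight fraction of subjects with risk strictly below the prevalence
        (the crossing quantile; ties at the prevalence sit at q >= q0).
    """

    sorted_risks: np.ndarray
    cum_shares: np.ndarray
    prevalence: float
    q0: float

    def __call__(self, q):
        """Evaluate R(q); scalar or vector q in [0, 1]."""
        return risk_at_quantile(self, q)


def compute_q0(sample: RiskSample, prevalence: float) -> float:
    """Quantile at which the curve reaches the prevalence.

    Empirically this is the weight fraction of subjects whose risk is
    *strictly* below the prevalence; mass tied exactly at the prevalence is
    counted neither here nor in the harmful range.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    below = sample.risks < prevalence
    return float(sample.weights[below].sum() / sample.total_weight)


def build_curve(sample: RiskSample, prevalence: float) -> PredictivenessCurve:
    """Sort risks into the step function R(q) and locate q0.

    The result depends only on the multiset of (risk, weight) pairs, never on
    input order.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    order = np.argsort(sample.risks, kind="stable")
    sorted_risks = sample.risks[order]
    cum = np.cumsum(sample.weights[order])
    cum_shares = cum / cum[-1]
    cum_shares[-1] = 1.0  # guard against fp drift at the top
    return PredictivenessCurve(
        sorted_risks=sorted_risks,
        cum_shares=cum_shares,
        prevalence=float(prevalence),
        q0=compute_q0(sample, prevalence),
    )


def risk_at_quantile(curve: PredictivenessCurve, q):
    """Left-continuous step evaluation of R at quantile(s) q.

    R(q) is the smallest sorted risk whose cumulative weight share reaches q
    (the generalized inverse of the risk CDF, left-continuous at jumps);
    q = 0 maps to the minimum risk, q = 1 to the maximum.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0.0) or np.any(q_arr > 1.0):
        raise ValueError("quantiles must lie in [0, 1]")
    idx = np.searchsorted(curve.cum_shares, q_arr, side="left")
    idx = np.minimum(idx, curve.sorted_risks.size - 1)
    out = curve.sorted_risks[idx]
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out


@dataclass(frozen=True)
class StratifiedCurves:
    """Predictiveness curves restricted to events and to non-events.

    The event curve sits above the non-event curve for any informative,
    calibrated marker.  ``p1`` and ``p0`` are the mean risks in the two
    strata; their difference is Tjur's coefficient of discrimination.
    ``q0_events`` (q0^1) and ``q0_nonevents`` (q0^0) are the fractions of
    each stratum with risk strictly below ``threshold``; their difference
    q0^0 - q0^1 is the above-average risk difference (AARD), which equals
    Youden's index at the same threshold for tie-free risks.
    """

    curve_events: PredictivenessCurve
    curve_nonevents: PredictivenessCurve
    p1: float
    p0: float
    q0_events: float
    q0_nonevents: float
    threshold: float


def stratified(sample: RiskSample, threshold: float) -> StratifiedCurves:
    """Build event- and non-event-restricted curves with their crossings."""
    if sample.outcomes is None:
        raise ValueError("stratified curves require outcomes")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    events = sample.outcomes == 1.0
    if not events.any() or events.all():
        raise ValueError("both outcome classes must be non-empty")
    s1 = sample.subset(events)
    s0 = sample.subset(~events)
    return StratifiedCurves(
        curve_events=build_curve(s1, threshold),
        curve_nonevents=build_curve(s0, threshold),
        p1=s1.mean_risk(),
        p0=s0.mean_risk(),
        q0_events=compute_q0(s1, threshold),
        q0_nonevents=compute_q0(s0, threshold),
        threshold=float(threshold),
    )
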