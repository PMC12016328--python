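"""Predictiveness measures and their area representations.

Everything here is computed from a weighted vector of predicted risks
(optionally with outcomes) against a prevalence P(D):

* areas ``A_N`` / ``A_S`` between the curve and the prevalence line, total
  gain ``TG = A_N + A_S`` and standardized total gain
  ``STG = TG / (2 P(D) (1 - P(D)))``;
* degrees of necessity ``DN1``, ``DN2`` and of sufficiency ``DS1``, ``DS2``
  — generalized attributable risks averaged over the protective range
  {risk < P(D)} and the harmful range {risk > P(D)}; variant 1 is the
  root-mean-square analogue of the plain mean in variant 2, so
  ``DN1 >= DN2`` and ``DS1 >= DS2`` always;
* explained variation ``EV_ind = Var(risk) / (P(D)(1 - P(D)))``;
* Tjur's coefficient of discrimination ``C_D = P1(D) - P0(D)``;
* the above-average risk difference ``AARD = q0^0 - q0^1``.

The area identities ``DN2 = A_N / (P(D) q0)`` and
``DS2 = A_S / ((1 - P(D))(1 - q0))`` hold to machine precision by
construction, and ``DN2 * DS2 <= EV_ind <= STG`` for calibrated samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .curve import compute_q0
from .sample import RiskSample, prevalence as _prevalence

__all__ = [
    "AreaDecomposition",
    "NecSuffMeasures",
    "PredictivenessSummary",
    "areas",
    "nec_suff",
    "ev_ind",
    "tjur_cd",
    "tg_stg",
    "aard",
    "sens_spec",
    "summarize",
]


@dataclass(frozen=True)
class AreaDecomposition:
    """Areas between the predictiveness curve and the prevalence line.

    ``a_n`` is the area below the line (protective side), ``a_s`` the area
    above (harmful side).  ``denom_n = P(D) q0`` and
    ``denom_s = (1 - P(D))(1 - q0)`` are the rectangles that bound them,
    and the ratios a_n/denom_n, a_s/denom_s are DN2 and DS2.  ``tg`` is the
    total gain A_N + A_S with maximum ``tg_max = 2 P(D)(1 - P(D))``.
    """

    a_n: float
    a_s: float
    denom_n: float
    denom_s: float
    tg: float
    tg_max: float


@dataclass(frozen=True)
class NecSuffMeasures:
    """Degrees of necessity (DN) and sufficiency (DS), both variants.

    ``frac_protective``/``frac_harmful``/``frac_tied`` partition the weight
    by risk strictly below / strictly above / exactly equal to the
    prevalence; tied mass contributes to no expectation and no area.
    """

    dn1: float
    dn2: float
    ds1: float
    ds2: float
    frac_protective: float
    frac_harmful: float
    frac_tied: float


@dataclass(frozen=True)
class PredictivenessSummary:
    """One row of all predictiveness measures for a marker (Table-style).

    Outcome-dependent fields (``c_d``, ``aard``, ``sens_at_prev``,
    ``spec_at_prev``) are ``None`` when the sample carries no outcomes.
    """

    prevalence: float
    q0: float
    ev_ind: float
    tg: float
    stg: float
    areas: AreaDecomposition
    nec_suff: NecSuffMeasures
    c_d: float | None = None
    aard: float | None = None
    sens_at_prev: float | None = None
    spec_at_prev: float | None = None

    def as_dict(self) -> dict:
        """Flat dict of the scalar measures (full precision)."""
        d = {
            "prevalence": self.prevalence,
            "q0": self.q0,
            "ev_ind": self.ev_ind,
            "dn1": self.nec_suff.dn1,
            "ds1": self.nec_suff.ds1,
            "dn2": self.nec_suff.dn2,
            "ds2": self.nec_suff.ds2,
            "c_d": self.c_d,
            "tg": self.tg,
            "stg": self.stg,
            "aard": self.aard,
            "a_n": self.areas.a_n,
            "a_s": self.areas.a_s,
            "sens_at_prev": self.sens_at_prev,
            "spec_at_prev": self.spec_at_prev,
            "frac_protective": self.nec_suff.frac_protective,
            "frac_harmful": self.nec_suff.frac_harmful,
            "frac_tied": self.nec_suff.frac_tied,
        }
        return d


def areas(sample: RiskSample, prevalence: float) -> AreaDecomposition:
    """Exact step-function areas A_N and A_S around the prevalence line.

    Because R(q) is a step function, the integrals reduce to weighted means:
    ``A_N = E[max(P(D) - risk, 0)]`` and ``A_S = E[max(risk - P(D), 0)]``;
    no quadrature error is involved.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    w = sample.weights / sample.total_weight
    a_n = float(np.sum(w * np.maximum(prevalence - sample.risks, 0.0)))
    a_s = float(np.sum(w * np.maximum(sample.risks - prevalence, 0.0)))
    q0 = compute_q0(sample, prevalence)
    return AreaDecomposition(
        a_n=a_n,
        a_s=a_s,
        denom_n=prevalence * q0,
        denom_s=(1.0 - prevalence) * (1.0 - q0),
        tg=a_n + a_s,
        tg_max=2.0 * prevalence * (1.0 - prevalence),
    )


def nec_suff(sample: RiskSample, prevalence: float) -> NecSuffMeasures:
    """Degrees of necessity and of sufficiency.

    DN2 averages the relative risk reduction (P(D) - risk)/P(D) over the
    protective range {risk < P(D)}; DN1 is the root mean square of the same
    quantity, giving extra weight to extreme risks.  DS2 and DS1 do the same
    with (risk - P(D))/(1 - P(D)) over the harmful range {risk > P(D)}.
    An empty range scores 0 (an uninformative marker is neither necessary
    nor sufficient), never NaN.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    w = sample.weights / sample.total_weight
    protective = sample.risks < prevalence
    harmful = sample.risks > prevalence
    frac_p = float(w[protective].sum())
    frac_h = float(w[harmful].sum())
    frac_t = max(1.0 - frac_p - frac_h, 0.0)

    if frac_p > 0.0:
        rel = (prevalence - sample.risks[protective]) / prevalence
        wp = w[protective] / frac_p
        dn2 = float(np.sum(wp * rel))
        dn1 = float(np.sqrt(np.sum(wp * rel**2)))
    else:
        dn1 = dn2 = 0.0

    if frac_h > 0.0:
        rel = (sample.risks[harmful] - prevalence) / (1.0 - prevalence)
        wh = w[harmful] / frac_h
        ds2 = float(np.sum(wh * rel))
        ds1 = float(np.sqrt(np.sum(wh * rel**2)))
    else:
        ds1 = ds2 = 0.0

    return NecSuffMeasures(
        dn1=dn1, dn2=dn2, ds1=ds1, ds2=ds2,
        frac_protective=frac_p, frac_harmful=frac_h, frac_tied=frac_t,
    )


def ev_ind(sample: RiskSample, prevalence: float) -> float:
    """Explained variation: Var(risk) / (P(D)(1 - P(D))).

    The variance is taken around the weighted mean risk, so for a calibrated
    sample (mean risk == prevalence) this is the plug-in proportion of
    outcome variation explained by the marker; it then lies in [0, 1].
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    mu = sample.mean_risk()
    var = float(np.average((sample.risks - mu) ** 2, weights=sample.weights))
    return var / (prevalence * (1.0 - prevalence))


def tjur_cd(sample: RiskSample) -> float:
    """Tjur's coefficient of discrimination P1(D) - P0(D).

    The mean predicted risk among events minus the mean among non-events;
    asymptotically equal to the plug-in explained variation for a logistic
    model fitted with intercept.
    """
    if sample.outcomes is None:
        raise ValueError("Tjur's coefficient requires outcomes")
    events = sample.outcomes == 1.0
    if not events.any() or events.all():
        raise ValueError("both outcome classes must be non-empty")
    p1 = float(np.average(sample.risks[events], weights=sample.weights[events]))
    p0 = float(np.average(sample.risks[~events], weights=sample.weights[~events]))
    cd = p1 - p0
    if cd < 0.0:
        warnings.warn(
            f"negative coefficient of discrimination ({cd:.4f}): risks are "
            "inversely related to the outcome", UserWarning, stacklevel=2,
        )
    return cd


def tg_stg(decomposition: AreaDecomposition) -> tuple[float, float]:
    """Total gain and standardized total gain from an area decomposition."""
    return decomposition.tg, decomposition.tg / decomposition.tg_max


def sens_spec(sample: RiskSample, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity of classifying risk > threshold positive.

    Ties at the threshold count as negative, matching the strict-inequality
    convention of the protective/harmful ranges.
    """
    if sample.outcomes is None:
        raise ValueError("sensitivity/specificity require outcomes")
    events = sample.outcomes == 1.0
    if not events.any() or events.all():
        raise ValueError("both outcome classes must be non-empty")
    positive = sample.risks > threshold
    w = sample.weights
    sens = float(w[events & positive].sum() / w[events].sum())
    spec = float(w[~events & ~positive].sum() / w[~events].sum())
    return sens, spec


def aard(sample: RiskSample, threshold: float) -> float:
    """Above-average risk difference q0^0 - q0^1 at a risk threshold.

    The fraction of non-events with risk strictly below the threshold minus
    the same fraction among events.  At the prevalence threshold this equals
    Youden's index (sensitivity + specificity - 1) whenever no risk ties the
    threshold exactly.
    """
    if sample.outcomes is None:
        raise ValueError("AARD requires outcomes")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    events = sample.outcomes == 1.0
    if not events.any() or events.all():
        raise ValueError("both outcome classes must be non-empty")
    q0_non = compute_q0(sample.subset(~events), threshold)
    q0_ev = compute_q0(sample.subset(events), threshold)
    value = q0_non - q0_ev
    if value < 0.0:
        warnings.warn(
            f"negative AARD ({value:.4f}): risks are inversely related to "
            "the outcome", UserWarning, stacklevel=2,
        )
    return value


def summarize(
    sample: RiskSample,
    prevalence_mode: str | None = None,
    threshold: float | None = None,
) -> PredictivenessSummary:
    """Compute every predictiveness measure for one marker.

    Parameters
    ----------
    sample : RiskSample
    prevalence_mode : {"outcomes", "risks"}, optional
        Defaults to ``"outcomes"`` when outcomes are present, else
        ``"risks"``.
    threshold : float, optional
        Risk threshold for AARD and sensitivity/specificity; defaults to the
        prevalence.
    """
    if prevalence_mode is None:
        prevalence_mode = "outcomes" if sample.has_outcomes else "risks"
    prev = _prevalence(sample, mode=prevalence_mode)
    dec = areas(sample, prev)
    ns = nec_suff(sample, prev)
    tg, stg = tg_stg(dec)
    ev = ev_ind(sample, prev)
    q0 = ns.frac_protective

    cd = aard_val = sens = spec = None
    if sample.has_outcomes:
        t = prev if threshold is None else threshold
        events = sample.outcomes == 1.0
        if events.any() and not events.all():
            cd = tjur_cd(sample)
            aard_val = aard(sample, t)
            sens, spec = sens_spec(sample, t)

    return PredictivenessSummary(
        prevalence=prev,
        q0=q0,
        ev_ind=ev,
        tg=tg,
        stg=stg,
        areas=dec,
        nec_suff=ns,
        c_d=cd,
        aard=aard_val,
        sens_at_prev=sens,
        spec_at_prev=spec,
    )
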