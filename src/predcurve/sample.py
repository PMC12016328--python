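"""Per-subject risk samples: the empirical carrier of all predictiveness measures.

A :class:`RiskSample` holds one predicted event probability per subject,
optionally paired with the observed binary outcome and with nonnegative
frequency weights.  Weights allow a finite population law (e.g. a two-point
mixture) to be represented exactly, without sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RiskSample", "CalibrationWarning", "prevalence", "dichotomize_at_risk"]

#: |mean risk - mean outcome| above which a calibration warning is raised
CALIBRATION_TOL = 0.005


class CalibrationWarning(UserWarning):
    """Risks are not globally calibrated against the observed outcomes."""


@dataclass(frozen=True)
class RiskSample:
    """Predicted risks P(D|X) for a set of subjects.

    Parameters
    ----------
    risks : array-like of float
        Predicted event probabilities, one per subject, each in [0, 1].
    outcomes : array-like of {0, 1}, optional
        Observed event indicators D, same length as ``risks``.
    weights : array-like of float, optional
        Nonnegative frequency weights; default is all ones.  Weights let a
        population mixture be encoded exactly (e.g. mass 0.45 on one risk
        value and 0.55 on another).
    """

    risks: np.ndarray
    outcomes: np.ndarray | None = None
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        risks = np.asarray(self.risks, dtype=float)
        if risks.ndim != 1:
            raise ValueError("risks must be a one-dimensional vector")
        if risks.size < 2:
            raise ValueError("a risk sample needs at least 2 subjects")
        if np.any(~np.isfinite(risks)) or risks.min() < 0.0 or risks.max() > 1.0:
            raise ValueError("every risk must be a probability in [0, 1]")
        object.__setattr__(self, "risks", risks)

        if self.outcomes is not None:
            outcomes = np.asarray(self.outcomes, dtype=float)
            if outcomes.shape != risks.shape:
                raise ValueError("outcomes must have the same length as risks")
            if not np.all(np.isin(outcomes, (0.0, 1.0))):
                raise ValueError("outcomes must be coded 0/1")
            object.__setattr__(self, "outcomes", outcomes)

        if self.weights is None:
            weights = np.ones_like(risks)
        else:
            weights = np.asarray(self.weights, dtype=float)
            if weights.shape != risks.shape:
                raise ValueError("weights must have the same length as risks")
            if np.any(~np.isfinite(weights)) or weights.min() < 0.0:
                raise ValueError("weights must be finite and nonnegative")
            if weights.sum() <= 0.0:
                raise ValueError("weights must have positive total mass")
        object.__setattr__(self, "weights", weights)

    # -- basic aggregates ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of rows (subjects or population atoms)."""
        return int(self.risks.size)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def has_outcomes(self) -> bool:
        return self.outcomes is not None

    def mean_risk(self) -> float:
        """Weighted mean of the predicted risks."""
        return float(np.average(self.risks, weights=self.weights))

    def mean_outcome(self) -> float:
        """Weighted event rate; requires outcomes."""
        if self.outcomes is None:
            raise ValueError("sample has no outcomes")
        return float(np.average(self.outcomes, weights=self.weights))

    def subset(self, mask: np.ndarray) -> "RiskSample":
        """Restrict to the rows selected by a boolean mask.

        Unlike the constructor, a one-row subset is allowed: strata of a
        valid sample (e.g. the events of a two-atom marker) may hold a
        single row, and their values were already validated on the parent.
        """
        if not mask.any():
            raise ValueError("subset mask selects no rows")
        risks = self.risks[mask]
        outcomes = None if self.outcomes is None else self.outcomes[mask]
        weights = self.weights[mask]
        if weights.sum() <= 0.0:
            raise ValueError("subset has zero total weight")
        sub = object.__new__(RiskSample)
        object.__setattr__(sub, "risks", risks)
        object.__setattr__(sub, "outcomes", outcomes)
        object.__setattr__(sub, "weights", weights)
        return sub


def prevalence(sample: RiskSample, mode: str = "outcomes") -> float:
    """Event prevalence P(D): weighted mean outcome or weighted mean risk.

    Parameters
    ----------
    sample : RiskSample
    mode : {"outcomes", "risks"}
        ``"outcomes"`` uses the observed event rate (requires outcomes);
        ``"risks"`` uses the mean predicted risk, appropriate for population
        fixtures or when the model is trusted to be calibrated.

    Raises
    ------
    ValueError
        If outcomes are requested but absent, or the prevalence is degenerate
        (exactly 0 or 1), which would void every downstream denominator.
    """
    if mode == "outcomes":
        if sample.outcomes is None:
            raise ValueError("mode='outcomes' requires outcomes in the sample")
        p = sample.mean_outcome()
    elif mode == "risks":
        p = sample.mean_risk()
    else:
        raise ValueError(f"unknown prevalence mode {mode!r}")
    if p <= 0.0 or p >= 1.0:
        raise ValueError(
            f"prevalence is {p}; measures are undefined at prevalence 0 or 1"
        )
    return p


def check_calibration(sample: RiskSample, *, warn: bool = True) -> float:
    """Return mean-risk minus mean-outcome, warning when it exceeds 0.005.

    The area identities and bound chains of the predictiveness framework hold
    exactly only for globally calibrated risks (mean risk == prevalence);
    violations are surfaced, never hidden.
    """
    diff = sample.mean_risk() - sample.mean_outcome()
    if warn and abs(diff) > CALIBRATION_TOL:
        warnings.warn(
            f"risks appear miscalibrated: mean risk - event rate = {diff:+.4f}",
            CalibrationWarning,
            stacklevel=2,
        )
    return diff


def dichotomize_at_risk(sample: RiskSample, threshold: float) -> RiskSample:
    """Coarsen risks to a two-group, locally calibrated model.

    Each subject's risk is replaced by the weighted mean risk of its side of
    ``threshold`` (risk <= threshold goes to the low group).  This is the
    locally calibrated risk model of the dichotomized marker: within each
    group the assigned risk equals the group's true mean risk.  When the
    threshold is the overall mean risk of a calibrated sample, the
    between-group measures DN2, DS2 and STG are unchanged by this operation,
    while EV, DN1 and DS1 can only decrease (they lose the within-group
    variation).

    Outcomes and weights are carried through unchanged.
    """
    low = sample.risks <= threshold
    high = ~low
    if not low.any() or not high.any():
        raise ValueError("both sides of the threshold must be non-empty")
    mean_low = np.average(sample.risks[low], weights=sample.weights[low])
    mean_high = np.average(sample.risks[high], weights=sample.weights[high])
    new_risks = np.where(low, mean_low, mean_high)
    return RiskSample(new_risks, sample.outcomes, sample.weights)
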