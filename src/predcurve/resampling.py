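"""Bootstrap inference for predictiveness measures.

Three services, all subject-level resampling with replacement:

* percentile confidence intervals for every measure;
* Harrell-style optimism correction when a model is refit per replicate
  (apparent performance on the replicate minus the replicate model's
  performance on the original data, averaged over replicates);
* a paired comparison of two markers on the same subjects — identical
  bootstrap indices for both markers, percentile CI and a two-sided
  bootstrap p-value for the difference.  This is a standard paired
  percentile bootstrap, not a reconstruction of any particular published
  comparison test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Dataset, fit_risks
from .measures import summarize
from .sample import RiskSample

__all__ = ["BootstrapResult", "MarkerComparison", "bootstrap_measures", "compare_markers"]

logger = logging.getLogger(__name__)

#: measures reported by default
MEASURES = ("ev_ind", "dn1", "ds1", "dn2", "ds2", "c_d", "tg", "stg", "aard")


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate with a percentile CI (and optional optimism correction)."""

    measure: str
    point: float
    b: int
    level: float
    ci_lower: float
    ci_upper: float
    seed: int
    optimism: float | None = None
    corrected: float | None = None


@dataclass(frozen=True)
class MarkerComparison:
    """Paired-bootstrap difference of one measure between two markers."""

    measure: str
    point_a: float
    point_b: float
    difference: float
    ci_lower: float
    ci_upper: float
    p_value: float
    b: int
    level: float
    seed: int


def _resample_indices(rng: np.ndarray, n: int, outcomes, max_tries: int) -> np.ndarray:
    """Draw bootstrap indices, redrawing single-class replicates (capped)."""
    for _ in range(max_tries):
        idx = rng.integers(0, n, size=n)
        if outcomes is None:
            return idx
        y = outcomes[idx]
        if y.min() < y.max():
            return idx
    raise RuntimeError(
        f"could not draw a two-class bootstrap replicate in {max_tries} tries"
    )


def _measure_values(sample: RiskSample, prevalence_mode: str | None) -> dict:
    flat = summarize(sample, prevalence_mode=prevalence_mode).as_dict()
    return {m: flat[m] for m in MEASURES if flat[m] is not None}


def bootstrap_measures(
    sample: RiskSample | None = None,
    *,
    data: Dataset | None = None,
    b: int = 1000,
    level: float = 0.95,
    seed: int,
    prevalence_mode: str | None = None,
) -> dict[str, BootstrapResult]:
    """Percentile bootstrap CIs for all measures.

    Pass either a ``sample`` (resamples (risk, outcome) rows as they stand)
    or a ``data`` Dataset with outcome + predictors (the logistic model is
    refit on every replicate, and the optimism of each measure — mean of
    apparent-on-replicate minus replicate-model-on-original — is reported
    together with the corrected estimate).
    """
    if b < 100:
        raise ValueError("b >= 100 is required for percentile CIs")
    if (sample is None) == (data is None):
        raise ValueError("pass exactly one of sample or data")
    refit = data is not None
    if refit:
        sample = fit_risks(data)
    assert sample is not None

    point = _measure_values(sample, prevalence_mode)
    names = list(point)
    reps = {m: np.empty(b) for m in names}
    optim = {m: np.empty(b) for m in names} if refit else None

    rng = np.random.default_rng(seed)
    n = sample.n
    for i in range(b):
        idx = _resample_indices(rng, n, sample.outcomes, max_tries=10 * b)
        if refit:
            boot_data = Dataset(
                table=data.table.iloc[idx].reset_index(drop=True),
                outcome_col=data.outcome_col,
                predictor_cols=data.predictor_cols,
                risk_col=data.risk_col,
            )
            boot_sample = fit_risks(boot_data)
            apparent = _measure_values(boot_sample, prevalence_mode)
            # replicate model applied to the original subjects
            import statsmodels.api as sm

            X = sm.add_constant(
                data.table[list(data.predictor_cols)].astype(float), has_constant="add"
            )
            Xb = sm.add_constant(
                boot_data.table[list(data.predictor_cols)].astype(float),
                has_constant="add",
            )
            res = sm.Logit(
                boot_data.table[data.outcome_col].to_numpy(float), Xb
            ).fit(disp=0, maxiter=200, tol=1e-10)
            orig_sample = RiskSample(
                np.clip(np.asarray(res.predict(X)), 0.0, 1.0),
                outcomes=data.table[data.outcome_col].to_numpy(float),
            )
            test = _measure_values(orig_sample, prevalence_mode)
            for m in names:
                reps[m][i] = apparent[m]
                optim[m][i] = apparent[m] - test[m]
        else:
            boot = RiskSample(
                sample.risks[idx],
                None if sample.outcomes is None else sample.outcomes[idx],
                sample.weights[idx],
            )
            vals = _measure_values(boot, prevalence_mode)
            for m in names:
                reps[m][i] = vals[m]

    alpha = 1.0 - level
    out: dict[str, BootstrapResult] = {}
    for m in names:
        lo, hi = np.percentile(reps[m], [100 * alpha / 2, 100 * (1 - alpha / 2)])
        if not lo <= point[m] <= hi:
            logger.warning(
                "percentile CI for %s (%.4f, %.4f) excludes the point estimate %.4f",
                m, lo, hi, point[m],
            )
        opt = corr = None
        if optim is not None:
            opt = float(optim[m].mean())
            corr = point[m] - opt
        out[m] = BootstrapResult(
            measure=m, point=point[m], b=b, level=level,
            ci_lower=float(lo), ci_upper=float(hi), seed=seed,
            optimism=opt, corrected=corr,
        )
    return out


def compare_markers(
    sample_a: RiskSample,
    sample_b: RiskSample,
    measure: str = "ev_ind",
    *,
    b: int = 1000,
    level: float = 0.95,
    seed: int,
    prevalence_mode: str | None = None,
) -> MarkerComparison:
    """Paired percentile bootstrap of a measure difference (A minus B).

    Both samples must describe the same subjects in the same row order; the
    same bootstrap indices are applied to both, which removes the shared
    sampling noise from the difference.  The two-sided p-value is
    ``2 * min(share <= 0, share >= 0)`` of the replicate differences, with a
    +1/(b+1) continuity adjustment.
    """
    if b < 100:
        raise ValueError("b >= 100 is required for percentile CIs")
    if sample_a.n != sample_b.n:
        raise ValueError("paired comparison requires samples of equal length")
    point_a = _measure_values(sample_a, prevalence_mode)[measure]
    point_b = _measure_values(sample_b, prevalence_mode)[measure]

    rng = np.random.default_rng(seed)
    n = sample_a.n
    outcomes = sample_a.outcomes if sample_a.outcomes is not None else sample_b.outcomes
    diffs = np.empty(b)
    for i in range(b):
        idx = _resample_indices(rng, n, outcomes, max_tries=10 * b)
        va = _measure_values(
            RiskSample(sample_a.risks[idx],
                       None if sample_a.outcomes is None else sample_a.outcomes[idx],
                       sample_a.weights[idx]),
            prevalence_mode,
        )[measure]
        vb = _measure_values(
            RiskSample(sample_b.risks[idx],
                       None if sample_b.outcomes is None else sample_b.outcomes[idx],
                       sample_b.weights[idx]),
            prevalence_mode,
        )[measure]
        diffs[i] = va - vb

    alpha = 1.0 - level
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p = 2.0 * min(
        (np.sum(diffs <= 0.0) + 1.0) / (b + 1.0),
        (np.sum(diffs >= 0.0) + 1.0) / (b + 1.0),
    )
    return MarkerComparison(
        measure=measure, point_a=point_a, point_b=point_b,
        difference=point_a - point_b,
        ci_lower=float(lo), ci_upper=float(hi),
        p_value=float(min(p, 1.0)), b=b, level=level, seed=seed,
    )
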