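"""Model/Results interface for predictiveness analysis.

:class:`PredictivenessModel` is built from per-subject predicted risks (or
from a raw table via a logistic fit); its :meth:`~PredictivenessModel.fit`
evaluates every measure and returns a :class:`PredictivenessResults` object
carrying the estimates, a ``summary()`` table, bootstrap confidence
intervals and the plotting methods::

    model = PredictivenessModel(risks, outcomes)
    res = model.fit()
    print(res.summary())
    res.bootstrap(b=500, seed=7)
    res.plot("curve.svg")
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .curve import PredictivenessCurve, StratifiedCurves, build_curve, stratified
from .io import (CalibrationReport, Dataset, calibration_check, export_summary,
                 fit_risks, round_half_up, summary_row, to_sample)
from .measures import PredictivenessSummary, summarize
from .plotting import PlotConfig, plot_predictiveness, plot_stratified
from .resampling import BootstrapResult, bootstrap_measures
from .sample import RiskSample

__all__ = ["PredictivenessModel", "PredictivenessResults"]


class PredictivenessModel:
    """Predictiveness analysis of a risk marker for a binary event.

    Parameters
    ----------
    risks : array-like
        Predicted event probabilities in [0, 1], one per subject.
    outcomes : array-like of {0, 1}, optional
        Observed event indicators; enable Tjur's C_D, AARD and the
        sensitivity/specificity read-offs.
    weights : array-like, optional
        Nonnegative frequency weights.
    prevalence_mode : {"outcomes", "risks"}, optional
        Source of P(D); defaults to the event rate when outcomes are
        present, else the mean risk.
    """

    def __init__(self, risks, outcomes=None, weights=None,
                 prevalence_mode: str | None = None):
        self.sample = RiskSample(np.asarray(risks, float), outcomes, weights)
        self.prevalence_mode = prevalence_mode or (
            "outcomes" if self.sample.has_outcomes else "risks"
        )
        self._data: Dataset | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_sample(cls, sample: RiskSample, prevalence_mode: str | None = None):
        m = cls.__new__(cls)
        m.sample = sample
        m.prevalence_mode = prevalence_mode or (
            "outcomes" if sample.has_outcomes else "risks"
        )
        m._data = None
        return m

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, risk_col: str,
                       outcome_col: str | None = None,
                       weight_col: str | None = None,
                       prevalence_mode: str | None = None):
        """Build from a table that already carries a risk column."""
        return cls(
            frame[risk_col].to_numpy(float),
            None if outcome_col is None else frame[outcome_col].to_numpy(float),
            None if weight_col is None else frame[weight_col].to_numpy(float),
            prevalence_mode=prevalence_mode,
        )

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame,
                     prevalence_mode: str | None = None):
        """Fit a plain logistic model ``"y ~ x1 + x2"`` and use its risks.

        Only additive main-effect formulas are supported; the intercept is
        always included.
        """
        lhs, rhs = (side.strip() for side in formula.split("~", 1))
        predictors = tuple(t.strip() for t in rhs.split("+") if t.strip() not in ("1", ""))
        dataset = Dataset(table=data, outcome_col=lhs, predictor_cols=predictors)
        m = cls.from_sample(fit_risks(dataset), prevalence_mode=prevalence_mode)
        m._data = dataset
        return m

    # -- estimation ---------------------------------------------------------

    def fit(self, threshold: float | None = None) -> "PredictivenessResults":
        """Evaluate all measures; returns a results object."""
        summary = summarize(self.sample, prevalence_mode=self.prevalence_mode,
                            threshold=threshold)
        curve = build_curve(self.sample, summary.prevalence)
        return PredictivenessResults(self, summary, curve, threshold)


class PredictivenessResults:
    """Estimates from a fitted :class:`PredictivenessModel`.

    Scalar measures are exposed as attributes (``ev_ind``, ``dn1``, ``ds1``,
    ``dn2``, ``ds2``, ``c_d``, ``tg``, ``stg``, ``aard``, ``prevalence``,
    ``q0``); structured pieces as ``measures`` (the full summary record) and
    ``curve``.
    """

    def __init__(self, model: PredictivenessModel, summary: PredictivenessSummary,
                 curve: PredictivenessCurve, threshold: float | None):
        self.model = model
        self.measures = summary
        self.curve = curve
        self.threshold = threshold if threshold is not None else summary.prevalence
        self._bootstrap: dict[str, BootstrapResult] | None = None

    # scalar attribute access -------------------------------------------------

    def __getattr__(self, name: str):
        flat = self.measures.as_dict()
        if name in flat:
            return flat[name]
        raise AttributeError(name)

    # diagnostics -------------------------------------------------------------

    def calibration(self) -> CalibrationReport:
        """Mean-risk vs event-rate diagnostic (requires outcomes)."""
        return calibration_check(self.model.sample)

    def stratified_curves(self) -> StratifiedCurves:
        """Event/non-event curves at the analysis threshold."""
        return stratified(self.model.sample, self.threshold)

    # inference ---------------------------------------------------------------

    def bootstrap(self, b: int = 1000, level: float = 0.95, *,
                  seed: int, refit: bool = False) -> dict[str, BootstrapResult]:
        """Percentile bootstrap CIs for every measure.

        With ``refit=True`` (requires a model built via ``from_formula``)
        the logistic model is refit on every replicate and optimism-corrected
        estimates are reported.
        """
        if refit:
            if self.model._data is None:
                raise ValueError("refit bootstrap requires a from_formula model")
            out = bootstrap_measures(data=self.model._data, b=b, level=level,
                                     seed=seed,
                                     prevalence_mode=self.model.prevalence_mode)
        else:
            out = bootstrap_measures(self.model.sample, b=b, level=level,
                                     seed=seed,
                                     prevalence_mode=self.model.prevalence_mode)
        self._bootstrap = out
        return out

    # presentation ------------------------------------------------------------

    def summary(self, digits: int = 2) -> str:
        """Text table of all measures (half-up rounding), statsmodels-style."""
        from statsmodels.iolib.table import SimpleTable

        flat = self.measures.as_dict()
        labels = [
            ("Prevalence P(D)", "prevalence"), ("q0", "q0"),
            ("Explained variation EV", "ev_ind"),
            ("Necessity DN1", "dn1"), ("Necessity DN2", "dn2"),
            ("Sufficiency DS1", "ds1"), ("Sufficiency DS2", "ds2"),
            ("Tjur C_D", "c_d"),
            ("Total gain TG", "tg"), ("Standardized TG", "stg"),
            ("AARD", "aard"),
            ("Area A_N", "a_n"), ("Area A_S", "a_s"),
            ("Sensitivity at threshold", "sens_at_prev"),
            ("Specificity at threshold", "spec_at_prev"),
        ]
        rows, stubs = [], []
        for label, key in labels:
            v = flat[key]
            if v is None:
                continue
            stubs.append(label)
            cell = [f"{round_half_up(v, digits):.{digits}f}"]
            if self._bootstrap and key in self._bootstrap:
                ci = self._bootstrap[key]
                cell.append(f"({ci.ci_lower:.{digits}f}, {ci.ci_upper:.{digits}f})")
            else:
                cell.append("")
            rows.append(cell)
        table = SimpleTable(
            rows, headers=["estimate", "bootstrap CI"], stubs=stubs,
            title="Predictiveness analysis",
        )
        return str(table)

    def report_row(self, digits: int = 2) -> dict:
        """The classic EV/DN1/DS1/DN2/DS2/C_D/STG row, rounded."""
        return summary_row(self.measures, digits)

    def to_json(self, path, prevalence_mode: str | None = None) -> Path:
        return export_summary(self.measures, path, fmt="json",
                              prevalence_mode=prevalence_mode or self.model.prevalence_mode)

    def to_tsv(self, path) -> Path:
        return export_summary(self.measures, path, fmt="tsv")

    def curve_table(self) -> pd.DataFrame:
        """Two-column (q, R) representation of the step curve."""
        shares = np.concatenate([[0.0], self.curve.cum_shares])
        q = np.repeat(shares, 2)[1:-1]
        r = np.repeat(self.curve.sorted_risks, 2)
        return pd.DataFrame({"q": q, "R": r})

    # plotting ----------------------------------------------------------------

    def plot(self, path, **kwargs) -> Path:
        """Render the predictiveness curve with areas; see PlotConfig."""
        fmt = Path(path).suffix.lstrip(".") or "svg"
        config = PlotConfig(output_path=path, format=fmt, **kwargs)
        return plot_predictiveness(self.measures, self.curve, config)

    def plot_stratified(self, path, **kwargs) -> Path:
        """Render event/non-event curves with C_D and AARD annotations."""
        fmt = Path(path).suffix.lstrip(".") or "svg"
        config = PlotConfig(output_path=path, format=fmt, **kwargs)
        return plot_stratified(self.stratified_curves(), config)
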