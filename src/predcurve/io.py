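"""Tabular input, the logistic-model adapter, and result export.

The measures themselves are model-agnostic: they only need a vector of
predicted risks.  This module supplies the two standard ways of obtaining
one from a delimited text table — reading a precomputed risk column, or
fitting a plain maximum-likelihood logistic regression (always with
intercept, no regularization) on outcome + predictor columns — plus
calibration diagnostics and JSON/TSV export of a summary row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .measures import PredictivenessSummary
from .sample import CALIBRATION_TOL, RiskSample

__all__ = [
    "Dataset",
    "CalibrationReport",
    "load_dataset",
    "fit_risks",
    "calibration_check",
    "export_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dataset:
    """A typed table with named outcome / predictor / risk columns."""

    table: pd.DataFrame
    outcome_col: str | None = None
    predictor_cols: tuple[str, ...] = ()
    risk_col: str | None = None

    @property
    def n(self) -> int:
        return len(self.table)


def _looks_headerless(columns) -> bool:
    """A header row made of numbers means the file has no header."""
    for c in columns:
        try:
            float(str(c))
        except ValueError:
            continue
        return True
    return False


def load_dataset(
    path: str | Path,
    outcome_col: str | None = None,
    predictor_cols: tuple[str, ...] | list[str] = (),
    risk_col: str | None = None,
    sep: str | None = None,
) -> Dataset:
    """Read a delimited text file (CSV/TSV, header required) into a Dataset.

    Rows with missing values in any used column are dropped with a logged
    count (complete-case policy; no imputation).  The outcome column must be
    coded 0/1.  The delimiter is inferred from the extension unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    if _looks_headerless(table.columns):
        raise ValueError(f"{path}: first row looks numeric; a header row is required")

    used = [c for c in (outcome_col, risk_col, *predictor_cols) if c is not None]
    missing = [c for c in used if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(table.columns)}")
    if not used:
        used = list(table.columns)

    n0 = len(table)
    table = table.dropna(subset=used).reset_index(drop=True)
    if n0 - len(table):
        logger.warning("dropped %d row(s) with missing values in %s", n0 - len(table), used)
    if table.empty:
        raise ValueError(f"{path}: no complete rows")

    if outcome_col is not None:
        y = pd.to_numeric(table[outcome_col], errors="coerce")
        if y.isna().any() or not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError(f"outcome column {outcome_col!r} must be coded 0/1")
        table[outcome_col] = y.astype(float)

    return Dataset(
        table=table,
        outcome_col=outcome_col,
        predictor_cols=tuple(predictor_cols),
        risk_col=risk_col,
    )


def to_sample(data: Dataset) -> RiskSample:
    """Build a RiskSample from a precomputed risk column."""
    if data.risk_col is None:
        raise ValueError("dataset has no risk column; use fit_risks instead")
    outcomes = None if data.outcome_col is None else data.table[data.outcome_col].to_numpy()
    return RiskSample(data.table[data.risk_col].to_numpy(float), outcomes=outcomes)


def fit_risks(data: Dataset) -> RiskSample:
    """Maximum-likelihood logistic fit; risks are the fitted probabilities.

    The intercept is always included, so the mean fitted risk equals the
    event rate (score equation of the intercept); this is asserted as a
    self-check.  Separation or non-convergence raises rather than returning
    silently unstable risks.
    """
    if data.outcome_col is None or not data.predictor_cols:
        raise ValueError("fitting requires an outcome column and >= 1 predictor")
    y = data.table[data.outcome_col].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit is undefined")
    X = sm.add_constant(data.table[list(data.predictor_cols)].astype(float), has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(
            f"logistic fit failed ({exc}); consider penalized alternatives "
            "(out of scope here)"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge; risks would be unreliable")
    risks = np.clip(np.asarray(res.predict(X)), 0.0, 1.0)
    if abs(risks.mean() - y.mean()) > 1e-8:
        raise AssertionError("fitted risks do not average to the event rate")
    return RiskSample(risks, outcomes=y)


@dataclass(frozen=True)
class CalibrationReport:
    """Global calibration diagnostic: does mean risk match the event rate?"""

    mean_risk: float
    mean_outcome: float
    difference: float
    ok: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = "pass" if self.ok else "WARN"
        return (f"calibration {flag}: mean risk {self.mean_risk:.4f}, "
                f"event rate {self.mean_outcome:.4f}, diff {self.difference:+.4f}")


def calibration_check(sample: RiskSample) -> CalibrationReport:
    """Compare mean predicted risk with the event rate (0.005 tolerance)."""
    if sample.outcomes is None:
        raise ValueError("calibration check requires outcomes")
    mr, mo = sample.mean_risk(), sample.mean_outcome()
    diff = mr - mo
    return CalibrationReport(mr, mo, diff, ok=abs(diff) <= CALIBRATION_TOL)


def round_half_up(x: float, digits: int = 2) -> float:
    """Half-up decimal rounding, as used in printed summary tables."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


#: column order of the 2-decimal report row
REPORT_COLUMNS = ("ev_ind", "dn1", "ds1", "dn2", "ds2", "c_d", "stg")


def summary_row(summary: PredictivenessSummary, digits: int = 2) -> dict:
    """The classic report row (EV, DN1, DS1, DN2, DS2, C_D, STG), rounded."""
    flat = summary.as_dict()
    return {
        k: (None if flat[k] is None else round_half_up(flat[k], digits))
        for k in REPORT_COLUMNS
    }


def export_summary(
    summary: PredictivenessSummary,
    path: str | Path,
    fmt: str = "json",
    prevalence_mode: str | None = None,
) -> Path:
    """Write a summary to disk as full-precision JSON or a 2-decimal TSV row."""
    from . import __version__

    if str(path) == "":
        raise ValueError("empty output path")
    path = Path(path)
    if fmt == "json":
        payload = {
            "measures": summary.as_dict(),
            "metadata": {
                "prevalence_mode": prevalence_mode,
                "frac_tied": summary.nec_suff.frac_tied,
                "software": f"predcurve {__version__}",
            },
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "tsv":
        row = summary_row(summary)
        header = "\t".join(REPORT_COLUMNS)
        values = "\t".join("" if row[c] is None else f"{row[c]:.2f}" for c in REPORT_COLUMNS)
        path.write_text(header + "\n" + values + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path
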