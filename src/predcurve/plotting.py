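"""Predictiveness-curve figures.

Two displays:

* :func:`plot_predictiveness` — the curve with the horizontal prevalence
  line, optionally hatching the areas A_N / A_S between curve and line
  (split at q0) and shading their denominator rectangles
  [0, q0] x [0, P(D)] and [q0, 1] x [P(D), 1], whose area ratios are DN2
  and DS2.
* :func:`plot_stratified` — the event-restricted (solid) and
  non-event-restricted (dashed) curves, with horizontal guides at P1(D)
  and P0(D) (vertical gap = Tjur's C_D) and vertical guides at q0^1 and
  q0^0 (horizontal gap = AARD).

All hatched areas are drawn from the same numbers as the numeric report —
no re-integration happens in plot code.  Rendering is deterministic:
identical inputs and config produce identical output bytes (fixed SVG hash
salt, no embedded date).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # non-interactive; keeps output reproducible
import matplotlib.pyplot as plt
import numpy as np

from .curve import PredictivenessCurve, StratifiedCurves
from .measures import PredictivenessSummary

__all__ = ["PlotConfig", "plot_predictiveness", "plot_stratified"]

_RC = {
    "svg.hashsalt": "predcurve",
    "svg.fonttype": "none",
    "font.family": "DejaVu Sans",
    "figure.dpi": 100,
}


@dataclass(frozen=True)
class PlotConfig:
    """Display options for the predictiveness figures."""

    show_areas: bool = True
    show_denominators: bool = False
    smooth: bool = False
    annotate: bool = True
    threshold: float | None = None
    output_path: str | Path = "predictiveness.svg"
    format: str = "svg"

    def __post_init__(self) -> None:
        if self.format not in ("png", "svg", "pdf"):
            raise ValueError(f"unsupported format {self.format!r}")


def _step_xy(curve: PredictivenessCurve) -> tuple[np.ndarray, np.ndarray]:
    """Dense (x, y) polyline of the step curve, from q=0 to q=1."""
    shares = np.concatenate([[0.0], curve.cum_shares])
    xs, ys = [], []
    for i, r in enumerate(curve.sorted_risks):
        xs += [shares[i], shares[i + 1]]
        ys += [r, r]
    return np.asarray(xs), np.asarray(ys)


def _smooth_display(x: np.ndarray, y: np.ndarray, window: int = 51) -> tuple[np.ndarray, np.ndarray]:
    """Cosmetic smoother: moving average on a fine grid, forced monotone."""
    grid = np.linspace(0.0, 1.0, 501)
    yg = np.interp(grid, x, y)
    kernel = np.ones(window) / window
    pad = window // 2
    smoothed = np.convolve(np.pad(yg, pad, mode="edge"), kernel, mode="valid")
    return grid, np.maximum.accumulate(smoothed)


def _save(fig, config: PlotConfig) -> Path:
    path = Path(config.output_path)
    with matplotlib.rc_context(_RC):
        fig.savefig(path, format=config.format, metadata=_metadata(config.format))
    plt.close(fig)
    return path


def _metadata(fmt: str) -> dict | None:
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return None


def plot_predictiveness(
    summary: PredictivenessSummary,
    curve: PredictivenessCurve,
    config: PlotConfig = PlotConfig(),
) -> Path:
    """Render the predictiveness curve with its area decomposition."""
    prev, q0 = curve.prevalence, curve.q0
    with matplotlib.rc_context(_RC):
        fig, ax = plt.subplots(figsize=(5.0, 4.0))
        x, y = _step_xy(curve)

        if config.show_denominators:
            ax.add_patch(plt.Rectangle((0.0, 0.0), q0, prev,
                                       facecolor="0.85", edgecolor="none"))
            ax.add_patch(plt.Rectangle((q0, prev), 1.0 - q0, 1.0 - prev,
                                       facecolor="0.85", edgecolor="none"))
        if config.show_areas:
            below = np.minimum(y, prev)
            above = np.maximum(y, prev)
            ax.fill_between(x, below, prev, where=x <= q0, facecolor="none",
                            edgecolor="0.3", hatch="///", linewidth=0.0)
            ax.fill_between(x, prev, above, where=x >= q0, facecolor="none",
                            edgecolor="0.3", hatch="\\\\\\", linewidth=0.0)

        if config.smooth:
            xs, ys = _smooth_display(x, y)
            ax.plot(xs, ys, color="0.5", linewidth=1.0, linestyle=":")
        ax.plot(x, y, color="black", linewidth=1.5)
        ax.axhline(prev, color="black", linewidth=0.8)

        if config.annotate:
            ax.axvline(q0, color="0.4", linewidth=0.8, linestyle="--")
            ax.text(0.02, prev + 0.02, f"P(D) = {prev:.3f}", fontsize=8)
            ax.text(q0 + 0.01, 0.02, f"$q_0$ = {q0:.2f}", fontsize=8)
            ax.text(
                0.02, 0.92,
                f"$A_N$ = {summary.areas.a_n:.3f}   $A_S$ = {summary.areas.a_s:.3f}\n"
                f"STG = {summary.stg:.2f}   EV = {summary.ev_ind:.2f}",
                fontsize=8, va="top",
            )
        if config.threshold is not None:
            ax.axhline(config.threshold, color="0.4", linewidth=0.8, linestyle=":")

        ax.set_xlim(0.0, 1.0)
        ax.set_ylim(0.0, 1.0)
        ax.set_xlabel("risk quantile $q$")
        ax.set_ylabel("predicted risk $R(q)$")
        fig.tight_layout()
    return _save(fig, config)


def plot_stratified(
    strat: StratifiedCurves,
    config: PlotConfig = PlotConfig(),
) -> Path:
    """Render event/non-event curves with C_D and AARD guides."""
    with matplotlib.rc_context(_RC):
        fig, ax = plt.subplots(figsize=(5.0, 4.0))
        x1, y1 = _step_xy(strat.curve_events)
        x0, y0 = _step_xy(strat.curve_nonevents)
        ax.plot(x1, y1, color="black", linewidth=1.5, label="events")
        ax.plot(x0, y0, color="black", linewidth=1.5, linestyle="--",
                label="non-events")
        ax.axhline(strat.threshold, color="0.6", linewidth=0.8)

        if config.annotate:
            ax.axhline(strat.p1, color="0.3", linewidth=0.8, linestyle=":")
            ax.axhline(strat.p0, color="0.3", linewidth=0.8, linestyle=":")
            ax.annotate(
                "", xy=(0.05, strat.p1), xytext=(0.05, strat.p0),
                arrowprops=dict(arrowstyle="<->", linewidth=0.8),
            )
            ax.text(0.07, (strat.p0 + strat.p1) / 2.0,
                    f"$C_D$ = {strat.p1 - strat.p0:.4f}", fontsize=8, va="center")
            ax.axvline(strat.q0_events, color="0.3", linewidth=0.8, linestyle=":")
            ax.axvline(strat.q0_nonevents, color="0.3", linewidth=0.8, linestyle=":")
            ax.annotate(
                "", xy=(strat.q0_events, 0.9), xytext=(strat.q0_nonevents, 0.9),
                arrowprops=dict(arrowstyle="<->", linewidth=0.8),
            )
            ax.text((strat.q0_events + strat.q0_nonevents) / 2.0, 0.93,
                    f"AARD = {strat.q0_nonevents - strat.q0_events:.4f}",
                    fontsize=8, ha="center")

        ax.set_xlim(0.0, 1.0)
        ax.set_ylim(0.0, 1.0)
        ax.set_xlabel("risk quantile $q$ within stratum")
        ax.set_ylabel("predicted risk")
        ax.legend(loc="lower right", fontsize=8, frameon=False)
        fig.tight_layout()
    return _save(fig, config)
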