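"""Time-course analyses of perturbation experiments.

After a degradation factor is acutely depleted, total mRNA follows an
accumulation -> adaptation -> reversion trajectory: levels rise while
degradation is impaired, transcription then adapts downward, and levels
settle back. This module quantifies that response:

* per-transcript linear fits of the accumulation phase with
  Benjamini-Hochberg FDR selection,
* correlation (and expression-controlled partial correlation) of the
  accumulation slopes with pre-perturbation production rates,
* the global recently-transcribed trajectory (level x p_r, scaled to
  t = 0) and its response half-time, the first midpoint crossing between
  the initial value and the late plateau,
* the per-transcript Delta-new / Delta-max comparison between two
  depletion strains: difference in cumulative recently-transcribed
  change (trapezoid over t < 60 min) against difference in peak total
  mRNA change (t < 90 min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kinetics import smooth_trajectory

__all__ = [
    "Trajectory",
    "SlopeFit",
    "ACCUMULATION_WINDOW",
    "ADAPTATION_WINDOW",
    "fit_accumulation",
    "accumulation_fits",
    "slope_production_correlation",
    "recent_trajectory",
    "response_halftime",
    "delta_new_delta_max",
]

ACCUMULATION_WINDOW = (0.0, 55.0)
ADAPTATION_WINDOW = (55.0, 95.0)
FDR_LEVEL = 0.10


@dataclass
class Trajectory:
    """Per-transcript time series of total and recently-transcribed mRNA.

    ``total`` is the relative (spike-normalized) level; ``recent`` is
    total x p_r at each sampled time. Fold changes are defined only where
    numerator and denominator are positive.
    """

    transcript_id: str
    times: np.ndarray
    total: np.ndarray
    recent: np.ndarray | None = None
    p_r: np.ndarray | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.total.shape:
            raise ValueError("times and total must have matching shapes")
        if self.recent is None and self.p_r is not None:
            self.recent = self.total * np.asarray(self.p_r, dtype=float)
        if self.recent is not None:
            self.recent = np.asarray(self.recent, dtype=float)

    def fold_change(self, reference: "Trajectory | None" = None) -> np.ndarray:
        """Fold change vs a time-matched reference, else vs t = 0."""
        if reference is not None:
            if not np.array_equal(reference.times, self.times):
                raise ValueError("reference trajectory must share the time grid")
            denom = reference.total
        else:
            denom = np.full_like(self.total, self.total[0])
        out = np.full_like(self.total, np.nan)
        ok = (denom > 0) & (self.total > 0)
        out[ok] = self.total[ok] / denom[ok]
        return out


@dataclass
class SlopeFit:
    """Accumulation-phase linear fit for one transcript."""

    transcript_id: str
    slope: float
    intercept: float
    r2: float
    pvalue: float
    qvalue: float = math.nan
    selected: bool = False
    n_points: int = 0

    @property
    def fit_ok(self) -> bool:
        return self.n_points >= 3 and math.isfinite(self.slope)


def fit_accumulation(
    traj: Trajectory,
    window: tuple[float, float] = ACCUMULATION_WINDOW,
) -> SlopeFit:
    """OLS of total level against time over the accumulation window.

    The p-value is the F-test for a non-zero slope (equivalent to the
    two-sided t-test on the slope in simple regression). Fewer than three
    points in the window yields an unfit flag (NaN slope).
    """
    lo, hi = window
    sel = (traj.times >= lo) & (traj.times <= hi) & np.isfinite(traj.total)
    n = int(sel.sum())
    if n < 3:
        return SlopeFit(traj.transcript_id, math.nan, math.nan, math.nan, math.nan, n_points=n)
    t, y = traj.times[sel], traj.total[sel]
    res = stats.linregress(t, y)
    r2 = res.rvalue**2 if math.isfinite(res.rvalue) else 0.0
    p = res.pvalue if math.isfinite(res.pvalue) else 1.0
    return SlopeFit(traj.transcript_id, res.slope, res.intercept, r2, p, n_points=n)


def accumulation_fits(
    trajectories: list[Trajectory],
    window: tuple[float, float] = ACCUMULATION_WINDOW,
    fdr: float = FDR_LEVEL,
) -> list[SlopeFit]:
    """Fit every transcript and select at the given FDR.

    q-values are Benjamini-Hochberg over all transcripts with a defined
    fit; ``selected`` means q <= fdr.
    """
    fits = [fit_accumulation(tr, window) for tr in trajectories]
    fitted = [f for f in fits if f.fit_ok]
    if fitted:
        pvals = np.array([f.pvalue for f in fitted])
        _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for f, q in zip(fitted, qvals):
            f.qvalue = float(q)
            f.selected = bool(q <= fdr)
    return fits


def slope_production_correlation(
    slopes: np.ndarray,
    pis: np.ndarray,
    expression: np.ndarray,
) -> tuple[float, float]:
    """Pearson and expression-controlled partial correlation.

    Returns (r, partial r): the plain Pearson correlation between
    accumulation slopes and production rates, and the correlation of the
    residuals of each after regressing out log expression.
    """
    slopes = np.asarray(slopes, dtype=float)
    pis = np.asarray(pis, dtype=float)
    expression = np.asarray(expression, dtype=float)
    ok = np.isfinite(slopes) & np.isfinite(pis) & np.isfinite(expression) & (expression > 0)
    if ok.sum() < 10:
        raise ValueError("need at least 10 transcripts with defined values")
    s, p, e = slopes[ok], pis[ok], np.log(expression[ok])
    if np.std(s) == 0 or np.std(p) == 0 or np.std(e) == 0:
        raise ValueError("degenerate variance; correlation undefined")
    r = float(stats.pearsonr(s, p).statistic)
    design = np.column_stack([np.ones_like(e), e])
    res_s = s - design @ np.linalg.lstsq(design, s, rcond=None)[0]
    res_p = p - design @ np.linalg.lstsq(design, p, rcond=None)[0]
    partial = float(stats.pearsonr(res_s, res_p).statistic)
    return r, partial


def recent_trajectory(
    trajectories: list[Trajectory],
    smooth_window: float = 120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Global recently-transcribed series relative to t = 0.

    Each replicate trajectory's recent level (total x p_r) is scaled to
    its t = 0 value and smoothed; replicates are averaged after
    smoothing. All inputs must share the time grid and include t = 0.
    Returns (times, mean series).
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    times = trajectories[0].times
    if times[0] != 0.0:
        raise ValueError("trajectories must start at t = 0")
    series = []
    for tr in trajectories:
        if tr.recent is None:
            raise ValueError(f"{tr.transcript_id}: no recently-transcribed levels")
        if not np.array_equal(tr.times, times):
            raise ValueError("all trajectories must share the time grid")
        if tr.recent[0] <= 0:
            raise ValueError(f"{tr.transcript_id}: non-positive t = 0 level")
        scaled = tr.recent / tr.recent[0]
        series.append(smooth_trajectory(times, scaled, window=smooth_window))
    return times, np.mean(series, axis=0)


def response_halftime(times: np.ndarray, series: np.ndarray) -> float:
    """First midpoint crossing of a declining response series.

    The plateau is the mean of the last two samples; the half-time is the
    first time the series crosses (initial + plateau)/2, linearly
    interpolated between samples. A non-declining series raises.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 time points")
    initial = series[0]
    plateau = float(np.mean(series[-2:]))
    if plateau >= initial:
        raise ValueError("series does not decline; half-time undefined")
    mid = 0.5 * (initial + plateau)
    below = np.nonzero(series <= mid)[0]
    below = below[below > 0]
    if below.size == 0:
        raise ValueError("series never crosses the midpoint")
    i = int(below[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = series[i - 1], series[i]
    if y0 == y1:
        return float(t1)
    return float(t0 + (mid - y0) / (y1 - y0) * (t1 - t0))


def _cumulative_recent_change(traj: Trajectory, t_max: float) -> float:
    """Trapezoid integral of (recent(t) - recent(0)) over t < t_max."""
    if traj.recent is None:
        raise ValueError(f"{traj.transcript_id}: no recently-transcribed levels")
    sel = traj.times <= t_max
    t = traj.times[sel]
    y = traj.recent[sel] - traj.recent[0]
    if t.size < 2:
        raise ValueError("insufficient time coverage")
    return float(np.trapezoid(y, t))


def _max_total_change(traj: Trajectory, t_max: float) -> float:
    sel = traj.times <= t_max
    if sel.sum() < 2:
        raise ValueError("insufficient time coverage")
    return float(np.max(traj.total[sel] - traj.total[0]))


def delta_new_delta_max(
    trajs_a: dict[str, Trajectory],
    trajs_b: dict[str, Trajectory],
    t_new: float = 60.0,
    t_max: float = 90.0,
) -> tuple[pd.DataFrame, float, int]:
    """Per-transcript Delta-new vs Delta-max between two depletion strains.

    For each transcript present in both strains, Delta-new is the
    difference (B minus A) of the cumulative recently-transcribed change
    integrated over t < ``t_new`` min, and Delta-max the difference of
    the per-transcript maxima of total mRNA change over t < ``t_max``
    min. Returns (per-transcript frame, Pearson r, transcripts dropped
    for missing coverage).
    """
    shared = sorted(set(trajs_a) & set(trajs_b))
    rows = []
    dropped = 0
    for tid in shared:
        try:
            dnew = _cumulative_recent_change(trajs_b[tid], t_new) - _cumulative_recent_change(
                trajs_a[tid], t_new
            )
            dmax = _max_total_change(trajs_b[tid], t_max) - _max_total_change(trajs_a[tid], t_max)
        except ValueError:
            dropped += 1
            continue
        rows.append((tid, dnew, dmax))
    df = pd.DataFrame(rows, columns=["transcript_id", "delta_new", "delta_max"])
    if len(df) >= 3 and df["delta_new"].std() > 0 and df["delta_max"].std() > 0:
        r = float(stats.pearsonr(df["delta_new"], df["delta_max"]).statistic)
    else:
        r = math.nan
    return df, r, dropped
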