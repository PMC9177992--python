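"""First-order mRNA kinetics: half-lives, production rates, normalization.

The steady-state model is dR/dt = pi - (delta + gamma) R for the
per-cell mRNA level R, with gene-specific production rate pi, degradation
rate delta, and growth (dilution) rate gamma. During a 4tU pulse of
duration t the recent fraction evolves as

    p_r(t) = 1 - exp(-(t - t0) (delta + gamma))

with a short conversion lag t0 before label becomes detectable. Inverting
gives delta = -ln(1 - p_r)/(t - t0) - gamma and the half-life ln(2)/delta.
Estimates outside the dynamic range of the pulse are censored rather than
clipped: half-life > 180 min is 'too_stable', < 1 min 'too_volatile', and
delta <= 0 'negative_delta' (apparent production-free stability).

Relative mRNA levels are spike-in- and biomass-normalized: host TTS reads
divided by (OD x spike-genome reads). Time courses are smoothed with a
third-order Savitzky-Golay filter spanning a 120-minute window, realized
as a local polynomial regression so irregular sampling grids are handled
exactly the same way as uniform ones. The culture growth rate comes from
sliding-window log-linear fits of the OD series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticRates",
    "SampleQuant",
    "GrowthFit",
    "HALF_LIFE_STABLE_MIN",
    "HALF_LIFE_VOLATILE_MIN",
    "pr_expected",
    "pr_to_delta",
    "fit_delta_timecourse",
    "production_rate",
    "relative_mrna",
    "smooth_trajectory",
    "growth_rate",
]

HALF_LIFE_STABLE_MIN = 180.0  # > 3 h: beyond the labeling dynamic range
HALF_LIFE_VOLATILE_MIN = 1.0
LN2 = math.log(2.0)


@dataclass
class KineticRates:
    """Per-transcript kinetic estimate with explicit censoring.

    delta in 1/min; half_life in min; pi in the (arbitrary) units of the
    relative mRNA level per minute. ``censoring`` is one of ``ok``,
    ``too_stable``, ``too_volatile``, ``negative_delta``.
    """

    delta: float
    half_life: float
    pi: float = math.nan
    censoring: str = "ok"

    @property
    def ok(self) -> bool:
        return self.censoring == "ok"


@dataclass
class SampleQuant:
    """Per-sample quantities entering spike-in normalization."""

    sample_id: str
    host_reads: int
    spike_reads: int
    od: float
    t_label: float = math.nan
    relative_level: float = math.nan


def pr_expected(t: float, delta: float, gamma: float, t0: float = 0.0) -> float:
    """Expected recent fraction after a pulse of duration ``t``.

    p_r = 1 - exp(-max(t - t0, 0) * (delta + gamma)).
    """
    if t < 0:
        raise ValueError("labeling time must be >= 0")
    if delta + gamma < 0:
        raise ValueError("delta + gamma must be >= 0")
    eff = max(t - t0, 0.0)
    return -math.expm1(-eff * (delta + gamma))


def _censor(delta: float) -> str:
    if delta <= 0:
        return "negative_delta"
    half_life = LN2 / delta
    if half_life > HALF_LIFE_STABLE_MIN:
        return "too_stable"
    if half_life < HALF_LIFE_VOLATILE_MIN:
        return "too_volatile"
    return "ok"


def pr_to_delta(p_r: float, t: float, gamma: float = 0.0, t0: float = 0.0) -> KineticRates:
    """Invert the labeling curve: recent fraction -> degradation rate.

    delta = -ln(1 - p_r)/(t - t0) - gamma, half-life = ln(2)/delta.
    Requires effective labeling time t - t0 > 0. p_r = 1 maps to an
    infinite rate (censored ``too_volatile``); estimates with delta <= 0
    are reported as ``negative_delta`` with an undefined half-life, not
    silently clipped.
    """
    if not (0.0 <= p_r <= 1.0):
        raise ValueError("p_r must be in [0, 1]")
    eff = t - t0
    if eff <= 0:
        raise ValueError("effective labeling time t - t0 must be > 0")
    if p_r >= 1.0:
        return KineticRates(math.inf, 0.0, censoring="too_volatile")
    delta = -math.log1p(-p_r) / eff - gamma
    # round-off guard: a delta within machine noise of the cancellation
    # -log(1-p_r)/eff - gamma is the no-degradation boundary
    if delta <= 1e-12 * (gamma + 1.0 / eff):
        return KineticRates(delta, math.inf, censoring="negative_delta")
    return KineticRates(delta, LN2 / delta, censoring=_censor(delta))


def fit_delta_timecourse(
    times: np.ndarray,
    prs: np.ndarray,
    gamma: float = 0.0,
    t0: float = 0.0,
) -> KineticRates:
    """One degradation rate from p_r measured at several pulse durations.

    Minimizes the squared error of the expected labeling curve over all
    time points jointly (one parameter per gene), which pools information
    across a time course instead of inverting each sample separately.
    """
    times = np.asarray(times, dtype=float)
    prs = np.asarray(prs, dtype=float)
    mask = np.isfinite(prs) & (times - t0 > 0)
    if mask.sum() < 1:
        raise ValueError("no usable time points")
    tt, pp = times[mask], prs[mask]

    def sse(delta):
        pred = 1.0 - np.exp(-np.maximum(tt - t0, 0.0) * (delta + gamma))
        return float(np.sum((pred - pp) ** 2))

    # the objective plateaus once delta >> 1/t; bracket on a log grid
    # before the local search so the plateau cannot trap it
    grid = np.concatenate([[0.0], np.geomspace(1e-6, 60.0, 400)])
    vals = [sse(d) for d in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    delta = float(res.x)
    if delta <= 0:
        return KineticRates(delta, math.inf, censoring="negative_delta")
    return KineticRates(delta, LN2 / delta, censoring=_censor(delta))


def production_rate(r_ss: float, delta: float, gamma: float = 0.0,
                    censoring: str = "ok") -> tuple[float, str]:
    """Steady-state production rate pi = (delta + gamma) * R_ss.

    A censored degradation estimate propagates to a censored pi.
    """
    if censoring != "ok":
        return math.nan, censoring
    if delta + gamma <= 0:
        raise ValueError("delta + gamma must be > 0 at steady state")
    return (delta + gamma) * r_ss, "ok"


def relative_mrna(sample: SampleQuant) -> float:
    """Spike-in/biomass-normalized mRNA level for one sample.

    host TTS reads / (OD x spike-genome reads). Zero spike reads or OD is
    an error (no internal standard), not an infinite level.
    """
    if sample.spike_reads <= 0:
        raise ValueError(f"sample {sample.sample_id}: no spike-in reads")
    if sample.od <= 0:
        raise ValueError(f"sample {sample.sample_id}: OD must be > 0")
    level = sample.host_reads / (sample.od * sample.spike_reads)
    sample.relative_level = level
    return level


def smooth_trajectory(
    times: np.ndarray,
    values: np.ndarray,
    window: float = 120.0,
    order: int = 3,
) -> np.ndarray:
    """Savitzky-Golay-style smoothing on a possibly irregular grid.

    At each time point a polynomial of the given order is least-squares
    fitted to all samples within ``window``/2 minutes and evaluated at
    that point; on a uniform grid this reproduces the classical
    Savitzky-Golay filter. Windows holding fewer than order+1 points pass
    the value through unchanged with a warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times.size < order + 1:
        warnings.warn("too few points to smooth; returning input unchanged")
        return values.copy()
    half = window / 2.0
    out = np.empty_like(values)
    warned = False
    for i, t in enumerate(times):
        sel = np.abs(times - t) <= half
        if sel.sum() < order + 1:
            if not warned:
                warnings.warn("window with fewer than order+1 points; passing through")
                warned = True
            out[i] = values[i]
            continue
        # centering keeps the Vandermonde well-conditioned
        coef = np.polynomial.polynomial.polyfit(times[sel] - t, values[sel], order)
        out[i] = coef[0]
    return out


@dataclass
class GrowthFit:
    """Growth rate from sliding-window log-linear OD fits."""

    gamma: float
    doubling_time: float
    window_start: float
    n_windows: int
    n_passing: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.gamma)


def growth_rate(
    times: np.ndarray,
    od: np.ndarray,
    window: int = 10,
    alpha: float = 0.05,
) -> GrowthFit:
    """Maximal growth rate from log-linear fits of consecutive OD points.

    Ordinary least squares of log(OD) against time is applied to every
    run of ``window`` consecutive points; the slope significance test is
    Bonferroni-corrected across windows at level ``alpha``, and the
    highest passing slope is returned as gamma with doubling time
    ln(2)/gamma. If no window passes, the fit is undefined (NaN fields).
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if times.size != od.size:
        raise ValueError("times and od must have equal length")
    if times.size < window:
        raise ValueError(f"need at least {window} points")
    if np.any(od <= 0):
        raise ValueError("OD values must be > 0")
    log_od = np.log(od)
    n_windows = times.size - window + 1
    best_slope = -math.inf
    best_start = math.nan
    n_passing = 0
    for i in range(n_windows):
        t = times[i : i + window]
        y = log_od[i : i + window]
        res = stats.linregress(t, y)
        if res.pvalue * n_windows < alpha:
            n_passing += 1
            if res.slope > best_slope:
                best_slope = res.slope
                best_start = t[0]
    if n_passing == 0 or best_slope <= 0:
        return GrowthFit(math.nan, math.nan, math.nan, n_windows, n_passing)
    return GrowthFit(best_slope, LN2 / best_slope, best_start, n_windows, n_passing)
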