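"""Two-component binomial mixture model for T->C conversion counts.

Each read summarizes to (X, Y): X genomic Ts in its aligned span and Y of
them read as C. Reads come from a mixture of *old* molecules (transcribed
before the 4tU pulse), which convert at a background error rate epsilon,
and *recent* molecules, which convert at the 4tU incorporation rate xi:

    Pr(Y | X) = p_r * Bin(Y; X, xi) + (1 - p_r) * Bin(Y; X, epsilon)

With epsilon and xi global (shared across transcripts in a batch), the
per-transcript likelihood is a function of the single recent-fraction
parameter p_r in [0, 1]; it is log-concave in p_r, so a bounded scalar
search finds the maximum. A 95% confidence interval comes from the
profile likelihood (drop of 1.92 log units).

Conversion counts are aggregated into a :class:`ConversionTable`, a
histogram over (X, Y) that can be pooled per transcript, per transcript
group, or over the whole transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

__all__ = [
    "ConversionTable",
    "GlobalParams",
    "PrEstimate",
    "build_table",
    "loglik",
    "fit_pr",
    "estimate_epsilon",
    "estimate_xi",
    "check_mixture_fit",
]

MAX_X = 30
_CI_DROP = 1.92  # chi2(1) 95% / 2


@dataclass
class GlobalParams:
    """Batch-level model parameters.

    epsilon: conversion probability of old molecules (sequencing /
    alkylation background); xi: conversion probability of recently
    transcribed molecules (4tU incorporation x conversion efficiency);
    t0: lag (min) before incorporated label becomes detectable;
    gamma: growth (dilution) rate in 1/min.
    """

    epsilon: float
    xi: float
    t0: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must be in [0, 1)")
        if not (self.epsilon < self.xi <= 1.0):
            raise ValueError("xi must be in (epsilon, 1]")
        if self.t0 < 0 or self.gamma < 0:
            raise ValueError("t0 and gamma must be >= 0")
        for v in (self.epsilon, self.xi, self.t0, self.gamma):
            if not np.isfinite(v):
                raise ValueError("parameters must be finite")


@dataclass
class ConversionTable:
    """Histogram of reads over (genomic Ts, conversions).

    ``counts[x, y]`` is the number of reads with X=x and Y=y; the array is
    lower-triangular since Y <= X.
    """

    counts: np.ndarray
    scope: str = "transcriptome"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square (X, Y) matrix")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if np.triu(self.counts, k=1).any():
            raise ValueError("counts with Y > X are invalid")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def max_x(self) -> int:
        return self.counts.shape[0] - 1

    def cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Non-empty (X, Y, count) triplets."""
        xs, ys = np.nonzero(self.counts)
        return xs, ys, self.counts[xs, ys]

    @classmethod
    def empty(cls, scope: str = "transcriptome", max_x: int = MAX_X) -> "ConversionTable":
        return cls(np.zeros((max_x + 1, max_x + 1), dtype=np.int64), scope)

    @classmethod
    def from_pairs(cls, xs, ys, scope: str = "transcriptome", max_x: int = MAX_X) -> "ConversionTable":
        xs = np.asarray(xs, dtype=np.int64)
        ys = np.asarray(ys, dtype=np.int64)
        if (ys > xs).any() or (ys < 0).any() or (xs < 0).any():
            raise ValueError("need 0 <= Y <= X")
        if xs.size and xs.max() > max_x:
            raise ValueError(f"X exceeds max_x={max_x}")
        counts = np.zeros((max_x + 1, max_x + 1), dtype=np.int64)
        np.add.at(counts, (xs, ys), 1)
        return cls(counts, scope)

    def __add__(self, other: "ConversionTable") -> "ConversionTable":
        return ConversionTable(self.counts + other.counts, self.scope)

    def to_frame(self) -> pd.DataFrame:
        xs, ys, ns = self.cells()
        return pd.DataFrame({"scope": self.scope, "X": xs, "Y": ys, "count": ns})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scope: str | None = None, max_x: int = MAX_X) -> "ConversionTable":
        if scope is not None:
            df = df[df["scope"] == scope]
        counts = np.zeros((max_x + 1, max_x + 1), dtype=np.int64)
        counts[df["X"].to_numpy(), df["Y"].to_numpy()] = df["count"].to_numpy()
        return cls(counts, scope or "transcriptome")


def build_table(assigned, scope: str = "transcriptome", max_x: int = MAX_X) -> ConversionTable:
    """Exact (X, Y) histogram of assigned read records."""
    xs = [r.X for r in assigned]
    ys = [r.Y for r in assigned]
    return ConversionTable.from_pairs(xs, ys, scope=scope, max_x=max_x)


def build_tables_by_transcript(assigned_pairs, max_x: int = MAX_X) -> dict[str, ConversionTable]:
    """One table per transcript from (transcript id, record) pairs."""
    groups: dict[str, list] = {}
    for tid, rec in assigned_pairs:
        groups.setdefault(tid, []).append(rec)
    return {tid: build_table(recs, scope=tid, max_x=max_x) for tid, recs in groups.items()}


def _log_binom_pmf(y: np.ndarray, x: np.ndarray, p: float) -> np.ndarray:
    """log Bin(y; x, p) with exact handling of p in {0, 1}."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if p <= 0.0:
        return np.where(y == 0, 0.0, -np.inf)
    if p >= 1.0:
        return np.where(y == x, 0.0, -np.inf)
    return (
        gammaln(x + 1) - gammaln(y + 1) - gammaln(x - y + 1)
        + y * np.log(p) + (x - y) * np.log1p(-p)
    )


def _mixture_logpmf(xs, ys, p_r: float, params: GlobalParams) -> np.ndarray:
    log_old = _log_binom_pmf(ys, xs, params.epsilon)
    log_new = _log_binom_pmf(ys, xs, params.xi)
    if p_r <= 0.0:
        return log_old
    if p_r >= 1.0:
        return log_new
    return np.logaddexp(np.log(p_r) + log_new, np.log1p(-p_r) + log_old)


def loglik(table: ConversionTable, p_r: float, params: GlobalParams) -> float:
    """Mixture log-likelihood of the table at recent fraction ``p_r``."""
    if not (0.0 <= p_r <= 1.0):
        raise ValueError("p_r must be in [0, 1]")
    xs, ys, ns = table.cells()
    if xs.size == 0:
        return 0.0
    return float(np.sum(ns * _mixture_logpmf(xs, ys, p_r, params)))


def loglik_grid(table: ConversionTable, grid: np.ndarray, params: GlobalParams) -> np.ndarray:
    """Vectorized log-likelihood over a grid of p_r values."""
    xs, ys, ns = table.cells()
    grid = np.asarray(grid, dtype=float)
    if xs.size == 0:
        return np.zeros_like(grid)
    log_old = _log_binom_pmf(ys, xs, params.epsilon)[None, :]
    log_new = _log_binom_pmf(ys, xs, params.xi)[None, :]
    with np.errstate(divide="ignore"):
        lp = np.log(grid)[:, None]
        lq = np.log1p(-grid)[:, None]
    per_cell = np.logaddexp(lp + log_new, lq + log_old)
    # endpoints of the grid collapse to a single component
    per_cell[grid <= 0.0] = np.broadcast_to(log_old, per_cell[grid <= 0.0].shape)
    per_cell[grid >= 1.0] = np.broadcast_to(log_new, per_cell[grid >= 1.0].shape)
    return per_cell @ ns.astype(float)


@dataclass
class PrEstimate:
    """Maximum-likelihood recent fraction with a profile-likelihood CI."""

    p_r: float
    loglik: float
    ci_low: float
    ci_high: float
    n_reads: int
    converged: bool = True
    defined: bool = True


def fit_pr(table: ConversionTable, params: GlobalParams, xtol: float = 1e-8) -> PrEstimate:
    """Maximize the mixture likelihood over p_r in [0, 1].

    The log-likelihood is a sum of logs of functions affine in p_r, hence
    concave: bounded Brent search converges to the global optimum. Reads
    with X = 0 carry no information; a table with only such reads (or no
    reads) yields a flat likelihood, flagged ``defined=False``.
    """
    xs, ys, ns = table.cells()
    informative = xs > 0
    if table.total == 0 or not informative.any():
        return PrEstimate(np.nan, 0.0, 0.0, 1.0, table.total, converged=True, defined=False)

    def neg(p):
        return -float(np.sum(ns * _mixture_logpmf(xs, ys, float(p), params)))

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": xtol})
    # the bounded method can stall short of a boundary optimum
    p_hat, ll_hat = float(res.x), -float(res.fun)
    for edge in (0.0, 1.0):
        if -neg(edge) > ll_hat:
            p_hat, ll_hat = edge, -neg(edge)

    lo, hi = _profile_ci(neg, p_hat, ll_hat)
    return PrEstimate(p_hat, ll_hat, lo, hi, table.total, converged=bool(res.success))


def _profile_ci(neg, p_hat: float, ll_hat: float, drop: float = _CI_DROP) -> tuple[float, float]:
    target = ll_hat - drop

    def g(p):
        return -neg(p) - target

    lo = 0.0
    if p_hat > 0.0 and g(0.0) < 0:
        lo = optimize.brentq(g, 0.0, p_hat, xtol=1e-9)
    hi = 1.0
    if p_hat < 1.0 and g(1.0) < 0:
        hi = optimize.brentq(g, p_hat, 1.0, xtol=1e-9)
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def estimate_epsilon(tables: list[ConversionTable]) -> float:
    """Pooled binomial MLE of the background conversion rate.

    Intended for unlabeled (no-4tU or t=0) samples, where every molecule
    is 'old': epsilon-hat = sum(Y) / sum(X) over all reads.
    """
    tot_x = 0.0
    tot_y = 0.0
    for t in tables:
        xs, ys, ns = t.cells()
        tot_x += float(np.sum(ns * xs))
        tot_y += float(np.sum(ns * ys))
    if tot_x == 0:
        raise ValueError("no genomic Ts observed; epsilon is undefined")
    return tot_y / tot_x


def estimate_xi(
    tables: list[ConversionTable],
    epsilon: float,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[float, list[float], bool]:
    """Estimate the incorporation rate jointly with per-table p_r.

    Alternates (i) fitting p_r per table at the current xi with (ii) a
    bounded 1-D maximization of the summed likelihood over xi at the
    current p_r values, until xi moves by less than ``tol``. Returns
    (xi_hat, per-table p_r, identifiable flag); the fit is flagged
    non-identifiable when every table lands near p_r = 0 (no labeled
    reads constrain xi).
    """
    cells = [t.cells() for t in tables]
    xi = min(max(10 * epsilon, 0.02), 0.5)
    prs = [0.5] * len(tables)

    def neg_xi(x):
        par = GlobalParams(epsilon, x)
        tot = 0.0
        for (xs, ys, ns), p in zip(cells, prs):
            if xs.size:
                tot -= float(np.sum(ns * _mixture_logpmf(xs, ys, p, par)))
        return tot

    for _ in range(max_iter):
        par = GlobalParams(epsilon, xi)
        prs = [fit_pr(t, par).p_r if t.total else 0.0 for t in tables]
        prs = [0.0 if not np.isfinite(p) else p for p in prs]
        res = optimize.minimize_scalar(
            neg_xi, bounds=(min(epsilon * 1.001 + 1e-9, 1.0), 1.0),
            method="bounded", options={"xatol": tol * 0.1},
        )
        xi_new = float(res.x)
        if abs(xi_new - xi) < tol:
            xi = xi_new
            break
        xi = xi_new
    identifiable = any(p > 0.01 for p in prs)
    return xi, prs, identifiable


def check_mixture_fit(table: ConversionTable, p_r: float, params: GlobalParams) -> pd.DataFrame:
    """Expected vs observed read counts per (X, Y) cell under the fit.

    Expected count = total * Pr(X) * Pr(Y|X), with Pr(X) the observed
    genomic-T marginal. The returned frame carries one row per cell with
    X > 0 and expected or observed reads, plus a Pearson chi-square-style
    contribution per cell.
    """
    total = table.total
    row_tot = table.counts.sum(axis=1)
    rows = []
    for x in range(1, table.max_x + 1):
        if row_tot[x] == 0:
            continue
        ys = np.arange(x + 1)
        pyx = np.exp(_mixture_logpmf(np.full(x + 1, x), ys, p_r, params))
        exp = row_tot[x] * pyx
        obs = table.counts[x, : x + 1]
        for y in ys:
            if exp[y] > 0 or obs[y] > 0:
                chi = (obs[y] - exp[y]) ** 2 / exp[y] if exp[y] > 0 else np.inf
                rows.append((x, int(y), float(exp[y]), int(obs[y]), float(chi)))
    df = pd.DataFrame(rows, columns=["X", "Y", "expected", "observed", "chi2"])
    df.attrs["total"] = total
    df.attrs["chi2_sum"] = float(df.loc[np.isfinite(df["chi2"]) & (df["expected"] >= 5), "chi2"].sum())
    return df
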