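"""Cosinor (single-harmonic sinusoid) fitting of laboratory seasonality.

Each stratum — a unique combination of laboratory test (name + specimen),
unit, lab ID, sex and 10-year age group — is normalized to mean 0 / sd 1 and
its weekly means are fit to

    y(week) = beta0 + beta1 * cos(2*pi*(week - theta) / 52)

by bounded non-linear least squares (beta0, beta1 in [-1, 1]; theta in
[0, 52]).  Strata whose fitted parameters survive a per-parameter
Benjamini-Hochberg FDR correction are declared seasonally significant, and
their standard reference interval is translated week-by-week by the
de-normalized fitted deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

N_WEEKS = 52
PARAM_NAMES = ("beta0", "beta1", "theta")

#: significance rules: which parameter q-values must all fall below alpha
SIGNIFICANCE_RULES = {
    "all": ("beta0", "beta1", "theta"),
    "beta1_theta": ("beta1", "theta"),
    "beta1": ("beta1",),
}


def cosinor_value(beta0: float, beta1: float, theta: float, week) -> np.ndarray | float:
    """Seasonal deviation (normalized units) at ``week``.

    Periodic with period 52; ``week`` may be scalar or array, real-valued.
    """
    w = np.asarray(week, dtype=float)
    out = beta0 + beta1 * np.cos(2.0 * np.pi * (w - theta) / N_WEEKS)
    return out if out.ndim else float(out)


def angular_distance_weeks(a: float, b: float) -> float:
    """Distance between two phases on the 52-week circle."""
    d = abs(a - b) % N_WEEKS
    return min(d, N_WEEKS - d)


class StratumUnfittableError(ValueError):
    """Raised when a stratum cannot be normalized/fitted (e.g. zero variance)."""


@dataclass
class SeasonalFit:
    """Fitted cosinor parameters and inference for one stratum."""

    stratum: Hashable
    beta0: float
    beta1: float
    theta: float
    se: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    q: dict[str, float] = field(default_factory=dict)
    significant: bool = False
    n_points: int = 0
    converged: bool = False

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.beta0, self.beta1, self.theta)

    def predict(self, week) -> np.ndarray | float:
        return cosinor_value(self.beta0, self.beta1, self.theta, week)


@dataclass(frozen=True)
class StandardRI:
    """Standard (health-authority) reference interval for one stratum."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"standard RI requires lower < upper, got ({self.lower}, {self.upper})")


@dataclass
class AdjustedRI:
    """Week-indexed reference interval derived from a standard RI and a fit.

    The whole interval is translated by the de-normalized seasonal deviation
    ``stratum_sd * cosinor_value(fit, week)``; a non-significant fit leaves
    the standard interval untouched, so the adjustment is the identity when
    no seasonality was detected.  Interval width is week-invariant.
    """

    base: StandardRI
    fit: SeasonalFit
    stratum_mean: float
    stratum_sd: float

    def shift(self, week) -> np.ndarray | float:
        if not self.fit.significant:
            return np.zeros_like(np.asarray(week, dtype=float)) if np.ndim(week) else 0.0
        return self.stratum_sd * self.fit.predict(week)

    def bounds(self, week) -> tuple:
        s = self.shift(week)
        return (self.base.lower + s, self.base.upper + s)


def normalize_stratum(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Center and scale one stratum's values to mean 0, sd 1.

    Returns ``(normalized, stratum_mean, stratum_sd)``; the mean/sd are
    computed over the supplied (fitting-subset) values and retained so the
    fitted deviation can later be mapped back to measurement units.

    Raises
    ------
    StratumUnfittableError
        fewer than 2 values or zero variance.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise StratumUnfittableError(f"need >= 2 values to normalize, got {v.size}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        raise StratumUnfittableError("zero variance: stratum is unfittable")
    return (v - mean) / sd, mean, sd


def weekly_aggregate(weeks: Sequence[int], values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Mean of (normalized) values per week-of-year 1..52, pooled across years.

    Returns ``(means, counts)`` as length-52 arrays indexed by week-1; weeks
    with no observations have count 0 and mean NaN.
    """
    w = np.asarray(weeks, dtype=int)
    if w.size and (w.min() < 1 or w.max() > N_WEEKS):
        raise ValueError("weeks must be in 1..52 (fold week 53 into 52 upstream)")
    v = np.asarray(values, dtype=float)
    counts = np.bincount(w - 1, minlength=N_WEEKS).astype(float)
    sums = np.bincount(w - 1, weights=v, minlength=N_WEEKS)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    return means, counts


def _canonical(beta0: float, beta1: float, theta: float) -> tuple[float, float, float]:
    """Unique parameterization: amplitude >= 0, phase reported mod 52.

    (-beta1, theta) describes the same curve as (beta1, theta + 26); the
    non-negative-amplitude form is reported.
    """
    beta0, beta1, theta = float(beta0), float(beta1), float(theta)
    if beta1 < 0:
        beta1, theta = -beta1, theta + 26.0
    return beta0, beta1, theta % N_WEEKS


def _start_points(y: np.ndarray) -> list[list[float]]:
    b0 = float(np.clip(np.nanmean(y), -0.9, 0.9))
    amp = float(np.clip((np.nanmax(y) - np.nanmin(y)) / 2.0, 0.05, 0.9))
    return [[b0, amp, th] for th in (0.0, 13.0, 26.0, 39.0)]


def fit_sinusoid(
    weekly_means: Sequence[float],
    counts: Sequence[float],
    stratum: Hashable = None,
    min_weeks: int = 26,
) -> SeasonalFit:
    """Bounded NLS cosinor fit to 52 count-weighted weekly means.

    Multi-start over theta in {0, 13, 26, 39} to escape local minima in the
    periodic phase; the lowest-SSE solution is kept.  Wald p-values come from
    the asymptotic covariance of the weighted least-squares problem
    (parameter / SE against a t distribution with n - 3 dof), mirroring
    standard NLS summary output.
    """
    y_all = np.asarray(weekly_means, dtype=float)
    n_all = np.asarray(counts, dtype=float)
    if y_all.shape != (N_WEEKS,) or n_all.shape != (N_WEEKS,):
        raise ValueError("weekly_means and counts must be length-52 vectors")
    mask = (n_all > 0) & np.isfinite(y_all)
    n_points = int(mask.sum())
    if n_points < min_weeks:
        return SeasonalFit(stratum, np.nan, np.nan, np.nan, n_points=n_points, converged=False)

    weeks = np.arange(1, N_WEEKS + 1, dtype=float)[mask]
    y = y_all[mask]
    sw = np.sqrt(n_all[mask])

    def residuals(p):
        return sw * (cosinor_value(p[0], p[1], p[2], weeks) - y)

    lb, ub = [-1.0, -1.0, 0.0], [1.0, 1.0, 52.0]
    best = None
    for p0 in _start_points(y):
        try:
            res = optimize.least_squares(residuals, p0, bounds=(lb, ub), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return SeasonalFit(stratum, np.nan, np.nan, np.nan, n_points=n_points, converged=False)

    beta0, beta1, theta = _canonical(*best.x)

    dof = max(n_points - 3, 1)
    # floor the residual variance so noiseless/interpolating fits do not
    # produce zero SEs and spuriously significant ~0 amplitudes
    s2 = max(2.0 * best.cost / dof, (1e-9 * max(1.0, float(np.abs(y).max()))) ** 2)
    J = best.jac
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(3, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.array([beta0, beta1, theta]) / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    return SeasonalFit(
        stratum=stratum,
        beta0=beta0,
        beta1=beta1,
        theta=theta,
        se=dict(zip(PARAM_NAMES, (float(x) for x in se))),
        p=dict(zip(PARAM_NAMES, (float(x) for x in pvals))),
        n_points=n_points,
        converged=True,
    )


def fit_stratum_records(
    weeks: Sequence[int],
    values: Sequence[float],
    stratum: Hashable = None,
    min_weeks: int = 26,
    aggregate: bool = True,
) -> tuple[SeasonalFit, float, float]:
    """Normalize one stratum and fit the cosinor.

    ``aggregate=True`` (default) fits the 52 count-weighted weekly means;
    ``aggregate=False`` fits the raw normalized records (each with unit
    weight), offered because per-record fitting is an equally defensible
    reading of the model.  Returns ``(fit, stratum_mean, stratum_sd)``.
    """
    normalized, mean, sd = normalize_stratum(values)
    if aggregate:
        means, counts = weekly_aggregate(weeks, normalized)
        fit = fit_sinusoid(means, counts, stratum=stratum, min_weeks=min_weeks)
    else:
        w = np.asarray(weeks, dtype=int)
        distinct = np.unique(w).size
        if distinct < min_weeks:
            fit = SeasonalFit(stratum, np.nan, np.nan, np.nan, n_points=distinct, converged=False)
        else:
            fit = _fit_raw(w, normalized, stratum, distinct)
    return fit, mean, sd


def _fit_raw(weeks: np.ndarray, values: np.ndarray, stratum, n_distinct) -> SeasonalFit:
    wk = weeks.astype(float)
    y = values.astype(float)

    def residuals(p):
        return cosinor_value(p[0], p[1], p[2], wk) - y

    lb, ub = [-1.0, -1.0, 0.0], [1.0, 1.0, 52.0]
    best = None
    for p0 in _start_points(y):
        res = optimize.least_squares(residuals, p0, bounds=(lb, ub), method="trf")
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return SeasonalFit(stratum, np.nan, np.nan, np.nan, n_points=n_distinct, converged=False)
    beta0, beta1, theta = _canonical(*best.x)
    dof = max(y.size - 3, 1)
    s2 = max(2.0 * best.cost / dof, (1e-9 * max(1.0, float(np.abs(y).max()))) ** 2)
    cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.array([beta0, beta1, theta]) / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    return SeasonalFit(
        stratum=stratum,
        beta0=beta0,
        beta1=beta1,
        theta=theta,
        se=dict(zip(PARAM_NAMES, map(float, se))),
        p=dict(zip(PARAM_NAMES, map(float, pvals))),
        n_points=n_distinct,
        converged=True,
    )


def fdr_correct(
    fits: Iterable[SeasonalFit],
    alpha: float = 0.05,
    rule: str = "beta1_theta",
) -> list[SeasonalFit]:
    """Benjamini-Hochberg correction applied separately per parameter family.

    All beta0 p-values are corrected together across strata, likewise beta1
    and theta.  A stratum is significant iff q < alpha for every parameter
    named by ``rule`` (see :data:`SIGNIFICANCE_RULES`) and the fit converged.
    Non-converged fits receive no q-values and are never significant.
    Mutates and returns the fits.
    """
    if rule not in SIGNIFICANCE_RULES:
        raise ValueError(f"unknown significance rule {rule!r}; options: {sorted(SIGNIFICANCE_RULES)}")
    fits = list(fits)
    converged = [f for f in fits if f.converged]
    if not converged:
        return fits
    for name in PARAM_NAMES:
        pvec = np.array([f.p[name] for f in converged])
        _, qvec, _, _ = multipletests(pvec, alpha=alpha, method="fdr_bh")
        for f, q in zip(converged, qvec):
            f.q[name] = float(q)
    required = SIGNIFICANCE_RULES[rule]
    for f in converged:
        f.significant = all(f.q[name] < alpha for name in required)
    return fits


def fits_to_frame(fits: Iterable[SeasonalFit]) -> pd.DataFrame:
    """One row per stratum: parameters, SEs, p, q, significance, n."""
    rows = []
    for f in fits:
        row = {"stratum": f.stratum, "beta0": f.beta0, "beta1": f.beta1, "theta": f.theta,
               "n_points": f.n_points, "converged": f.converged, "significant": f.significant}
        for name in PARAM_NAMES:
            row[f"se_{name}"] = f.se.get(name, np.nan)
            row[f"p_{name}"] = f.p.get(name, np.nan)
            row[f"q_{name}"] = f.q.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
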