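"""Cohort-level statistics and the sampling-day accuracy evaluation.

This module is the results engine of the analysis.  For a cohort of solved
subjects it tabulates the composite RID coefficient FaS by day (geometric
mean, SD, CV%), applies the super-subject prediction — each day's cohort
geometric-mean FaS combined with every individual's own plasma specific
activity SAp — and scores the predictions against assigned stores with
regressions, rank correlations, within-threshold percentages, and best-day
frequencies.

A useful exact property drives the group-level results: because each
subject's FaS/SAp equals their own TBS, the geometric mean of the
super-subject predictions at any day equals the geometric mean of the
assigned TBS — GM(FaS_i)·GM(1/SAp_i) = GM(FaS_i/SAp_i).  Group means are
therefore recovered exactly at every sampling day; individual accuracy is
what varies with day, and is what this module quantifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .rid import RIDTrajectory, SubjectSpec, predict_tbs

__all__ = [
    "CohortDaySummary",
    "AccuracyReport",
    "geometric_mean",
    "geometric_sd",
    "summarize_fas",
    "evaluate_sampling_days",
    "fit_biexponential",
]

logger = logging.getLogger(__name__)

DEFAULT_DAYS = tuple(range(1, 31))
DEFAULT_SELECTED_DAYS = (4, 7, 10, 14, 21, 28)
DEFAULT_THRESHOLDS = (10, 25, 50)


def geometric_mean(values) -> float:
    """Geometric mean: exp of the mean of logs. All values must be > 0."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if np.any(~(x > 0)):
        raise ValueError("geometric mean requires strictly positive values")
    return float(stats.gmean(x))


def geometric_sd(values) -> float:
    """Geometric SD: exp of the sample SD (ddof=1) of logs. Dimensionless
    multiplicative spread; 1.0 means no dispersion."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(~(x > 0)):
        raise ValueError("geometric SD requires strictly positive values")
    return float(stats.gstd(x))


@dataclass(frozen=True)
class CohortDaySummary:
    """Dispersion of the composite coefficient FaS across a cohort on one day."""

    day: float
    gm_fas: float
    sd_fas: float
    cv_pct: float


def _fas_matrix(trajectories: Sequence[RIDTrajectory], days: Sequence[float]) -> pd.DataFrame:
    """FaS values as a (subject × day) frame; raises if undefined anywhere."""
    days = list(days)
    rows = {}
    for tr in trajectories:
        idx = []
        for d in days:
            k = np.flatnonzero(np.isclose(tr.times, d))
            if k.size != 1:
                raise ValueError(f"day {d} not on trajectory grid of subject {tr.subject_id}")
            k = int(k[0])
            if not tr.defined[k]:
                raise ValueError(
                    f"FaS undefined for subject {tr.subject_id} at day {d} (no tracer in stores)")
            idx.append(k)
        rows[tr.subject_id] = tr.FaS[idx]
    return pd.DataFrame.from_dict(rows, orient="index", columns=days)


def summarize_fas(
    trajectories: Sequence[RIDTrajectory],
    days: Sequence[float] = DEFAULT_DAYS,
    cv_convention: str = "arithmetic",
) -> list[CohortDaySummary]:
    """Per-day geometric mean, SD and CV% of FaS across the cohort.

    ``cv_convention`` selects the dispersion pairing: ``"arithmetic"``
    (default) reports the arithmetic SD of FaS and CV% = 100·SD/mean;
    ``"geometric"`` reports the geometric SD and the log-scale CV%
    = 100·sqrt(exp(σ²) − 1) with σ the SD of log FaS.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 subjects")
    if cv_convention not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown cv_convention {cv_convention!r}")
    fas = _fas_matrix(trajectories, days)
    out = []
    for d in fas.columns:
        col = fas[d].to_numpy()
        gm = geometric_mean(col)
        if cv_convention == "arithmetic":
            sd = float(np.std(col, ddof=1))
            cv = 100.0 * sd / float(np.mean(col))
        else:
            sd = geometric_sd(col)
            sigma = float(np.std(np.log(col), ddof=1))
            cv = 100.0 * float(np.sqrt(np.exp(sigma**2) - 1.0))
        out.append(CohortDaySummary(day=float(d), gm_fas=gm, sd_fas=sd, cv_pct=cv))
    return out


@dataclass(frozen=True)
class AccuracyReport:
    """Sampling-day accuracy of super-subject RID predictions for one cohort.

    Attributes
    ----------
    assigned
        Assigned (true) TBS per subject, μmol.
    predictions
        Predicted TBS, subjects × days, μmol.
    regressions
        Per-day OLS of predicted (y) on assigned (x): slope, intercept,
        r_squared (squared Pearson), p (two-sided, zero slope), and
        rank_r_squared (squared Pearson of average ranks).
    pct_within
        Percentage of subjects with |predicted − assigned|/assigned within
        each threshold, days × thresholds.
    best_day_frequency
        Among the selected days, how many subjects had their minimum
        absolute relative error on each day (earliest day wins ties).
    ties
        Subject ids whose best day was tied (also logged as warnings).
    """

    assigned: pd.Series
    predictions: pd.DataFrame
    regressions: pd.DataFrame
    pct_within: pd.DataFrame
    best_day_frequency: dict[float, int]
    ties: tuple[str, ...]


def evaluate_sampling_days(
    subjects: Sequence[SubjectSpec],
    trajectories: Sequence[RIDTrajectory],
    days: Sequence[float] = DEFAULT_DAYS,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    selected_days: Sequence[float] = DEFAULT_SELECTED_DAYS,
) -> AccuracyReport:
    """Score super-subject RID predictions against assigned TBS by day.

    For each day the prediction for subject *i* is GM_cohort(FaS at day) /
    SAp_i(day).  Regressions are ordinary least squares of predicted on
    assigned; ``pct_within`` uses |pred − assigned| / assigned ≤ t/100.
    """
    if len(subjects) != len(trajectories):
        raise ValueError("subjects and trajectories must align")
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for regression")
    ids = [s.id for s in subjects]
    if ids != [tr.subject_id for tr in trajectories]:
        raise ValueError("subject ids do not match trajectory ids")
    days = [float(d) for d in days]
    selected_days = [float(d) for d in selected_days]
    if not set(selected_days) <= set(days):
        raise ValueError("selected_days must be a subset of days")

    assigned = pd.Series({s.id: s.assigned_tbs for s in subjects}, name="assigned_tbs")
    fas = _fas_matrix(trajectories, days)
    sap = pd.DataFrame(
        {d: [tr.SAp[int(np.flatnonzero(np.isclose(tr.times, d))[0])] for tr in trajectories]
         for d in days},
        index=ids,
    )
    gm_fas = fas.apply(geometric_mean, axis=0)
    predictions = pd.DataFrame(
        {d: predict_tbs(gm_fas[d], sap[d].to_numpy()) for d in days}, index=ids)

    x = assigned.to_numpy()
    reg_rows = {}
    for d in days:
        y = predictions[d].to_numpy()
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        ranks_x = stats.rankdata(x)
        ranks_y = stats.rankdata(y)
        rank_r = float(np.corrcoef(ranks_x, ranks_y)[0, 1])
        reg_rows[d] = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "r_squared": float(np.corrcoef(x, y)[0, 1] ** 2),
            "p": float(fit.pvalues[1]),
            "rank_r_squared": rank_r**2,
        }
    regressions = pd.DataFrame.from_dict(reg_rows, orient="index")
    regressions.index.name = "day"

    rel_err = (predictions.sub(assigned, axis=0)).div(assigned, axis=0).abs()
    pct_within = pd.DataFrame(
        {t: 100.0 * (rel_err[days] <= t / 100.0).mean(axis=0) for t in thresholds})
    pct_within.index.name = "day"

    sel = rel_err[selected_days]
    best_day_frequency = {d: 0 for d in selected_days}
    ties: list[str] = []
    for sid, row in sel.iterrows():
        errs = row.to_numpy()
        best = float(selected_days[int(np.argmin(errs))])  # argmin → earliest on ties
        if np.sum(np.isclose(errs, errs.min(), rtol=1e-12, atol=0.0)) > 1:
            ties.append(str(sid))
            logger.warning("best-day tie for subject %s at error %.6g", sid, errs.min())
        best_day_frequency[best] += 1
    return AccuracyReport(
        assigned=assigned,
        predictions=predictions,
        regressions=regressions,
        pct_within=pct_within,
        best_day_frequency=best_day_frequency,
        ties=tuple(ties),
    )


def _biexp(t, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _peel_initializer(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Curve-peeling initial values: fit the slow tail log-linearly, subtract
    it, then fit the fast residual log-linearly."""
    n_tail = max(3, t.size // 2)
    ct, cy = t[-n_tail:], y[-n_tail:]
    k2, loga2 = np.polyfit(ct, np.log(cy), 1)
    k2, a2 = max(-k2, 0.0), float(np.exp(loga2))
    resid = y - a2 * np.exp(-k2 * t)
    pos = resid > 0
    if pos.sum() >= 2:
        k1, loga1 = np.polyfit(t[pos], np.log(resid[pos]), 1)
        k1, a1 = max(-k1, 1e-6), float(np.exp(loga1))
    else:  # tail fit already explains everything; seed a fast minor phase
        a1, k1 = 0.1 * a2, 10.0 * max(k2, 0.1)
    return a1, k1, a2, k2


def fit_biexponential(t, y) -> dict[str, float]:
    """Fit ``A1·exp(−k1·t) + A2·exp(−k2·t)`` by nonlinear least squares.

    Initialized by classical curve peeling (log-linear fit of the tail,
    subtraction, log-linear fit of the residual fast phase).  The returned
    parameters satisfy ``k1 > k2 >= 0`` (phases swapped if needed).  Returns
    a dict with ``A1, k1, A2, k2, r_squared``.

    Raises
    ------
    RuntimeError
        On non-convergence; the message includes the initializer values.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be equal-length 1-D arrays")
    if t.size < 5:
        raise ValueError("need at least 5 points")
    if np.any(~(y > 0)):
        raise ValueError("values must be positive")
    order = np.argsort(t)
    t, y = t[order], y[order]
    p0 = _peel_initializer(t, y)
    try:
        popt, _ = optimize.curve_fit(
            _biexp, t, y, p0=p0, bounds=(0.0, np.inf), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"biexponential fit did not converge (initializer A1={p0[0]:.4g}, "
            f"k1={p0[1]:.4g}, A2={p0[2]:.4g}, k2={p0[3]:.4g}): {exc}") from exc
    a1, k1, a2, k2 = popt
    if k1 < k2:  # enforce fast phase first
        a1, k1, a2, k2 = a2, k2, a1, k1
    yhat = _biexp(t, a1, k1, a2, k2)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"A1": float(a1), "k1": float(k1), "A2": float(a2), "k2": float(k2),
            "r_squared": r2}
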