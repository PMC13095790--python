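"""Cohort-level clinical statistics for radiation-induced lymphopenia.

Grading follows CTCAE v5.0 for lymphocyte count decrease: grade 1 for ALC
in [800, 1000)/uL, grade 2 in [500, 800), grade 3 in [200, 500), grade 4
below 200, and grade 0 at or above 1000.  Severe radiation-induced
lymphopenia (SRIL) is grade >= 3, i.e. ALC < 500/uL during the course.

Also provides exponential ALC-decay fitting on weekly group means,
univariate/multivariate logistic regression with odds ratios and Wald
intervals, median dichotomization, Bonferroni adjustment, and one-way
ANOVA of mean blood dose across lymphopenia grades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .bloodsim import DeliverySchedule
from .dvh import DifferentialDVH
from .errors import ValidationError

__all__ = [
    "PatientRecord",
    "ALCDecayFit",
    "LogisticResult",
    "grade_ril",
    "cohort_summary",
    "fit_alc_decay",
    "logistic_fit",
    "dichotomize",
    "bonferroni",
    "anova_by_grade",
]

_GRADE_EDGES = (200.0, 500.0, 800.0, 1000.0)  # grade 4/3/2/1 upper bounds
ALC_EXCLUSION_THRESHOLD = 500.0  # pre-treatment ALC <= this excludes the patient


def grade_ril(alc) -> int | np.ndarray:
    """CTCAE v5.0 lymphopenia grade for an ALC in cells/uL.

    Boundaries are lower-inclusive: 1000 is grade 0, 500 is grade 2,
    200 is grade 3.
    """
    arr = np.asarray(alc, float)
    if np.any(arr < 0):
        raise ValidationError("ALC must be >= 0")
    grade = 4 - np.searchsorted(_GRADE_EDGES, arr, side="right")
    return int(grade) if np.isscalar(alc) else grade


@dataclass
class PatientRecord:
    """One patient's dosimetry, lymphocyte history, outcome and covariates."""

    id: str
    modality: str                       # "photon" or "proton"
    sril: int
    ril_grade: int
    pre_rt_alc: float                   # cells/uL, before radiotherapy
    schedule: Optional[DeliverySchedule] = None
    blood_dvh: Optional[DifferentialDVH] = None
    organ_dvhs: Optional[Mapping[str, DifferentialDVH]] = None
    alc_series: Optional[np.ndarray] = None  # (k, 2) columns: day, cells/uL
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.modality not in ("photon", "proton"):
            raise ValidationError(f"{self.id}: modality must be photon or proton")
        if self.sril not in (0, 1):
            raise ValidationError(f"{self.id}: sril must be 0 or 1")
        if self.ril_grade not in range(5):
            raise ValidationError(f"{self.id}: ril_grade must be 0..4")
        if bool(self.sril) != (self.ril_grade >= 3):
            raise ValidationError(
                f"{self.id}: sril={self.sril} inconsistent with grade {self.ril_grade}"
            )
        if not self.pre_rt_alc > ALC_EXCLUSION_THRESHOLD:
            raise ValidationError(
                f"{self.id}: pre-treatment ALC must exceed "
                f"{ALC_EXCLUSION_THRESHOLD}/uL (exclusion criterion)"
            )
        if self.alc_series is not None:
            arr = np.asarray(self.alc_series, float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValidationError(f"{self.id}: alc_series must be (k, 2)")
            if np.any(arr[:, 1] < 0):
                raise ValidationError(f"{self.id}: ALC values must be >= 0")
            self.alc_series = arr


def cohort_summary(records: Sequence[PatientRecord],
                   continuous_covariates: Sequence[str] = ()) -> dict:
    """Event counts, SRIL incidence and the lymphopenia grade table."""
    if not records:
        raise ValidationError("empty cohort")
    n = len(records)
    events = sum(r.sril for r in records)
    grades = {g: sum(r.ril_grade == g for r in records) for g in range(5)}
    summary = {
        "n": n,
        "events": events,
        "sril_incidence_percent": 100.0 * events / n,
        "grade_table": grades,
        "covariates": {},
    }
    for name in continuous_covariates:
        vals = np.array([r.covariates[name] for r in records
                         if name in r.covariates], float)
        if vals.size:
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            summary["covariates"][name] = {"median": q50, "iqr": (q25, q75)}
    return summary


@dataclass(frozen=True)
class ALCDecayFit:
    lambda_per_day: float
    half_time_days: float
    fit_rmse: float
    n_points_used: int


def fit_alc_decay(trajectories: Sequence[np.ndarray],
                  window: Optional[tuple] = None,
                  bin_days: float = 7.0) -> ALCDecayFit:
    """Exponential decay rate of the cohort-average ALC.

    Pools all (day, ALC) measurements, averages ALC within ``bin_days``-wide
    time bins (weekly by default, mirroring weekly blood draws), and fits
    log(mean ALC) against the mean day of each bin by least squares.  The
    decay rate is minus the slope; half-time is ln 2 over the rate.
    Non-positive ALC values cannot enter the log fit and are dropped with a
    warning.
    """
    pts = [np.asarray(t, float) for t in trajectories if len(t)]
    if not pts:
        raise ValidationError("no ALC trajectories supplied")
    data = np.vstack(pts)
    if window is not None:
        lo, hi = window
        data = data[(data[:, 0] >= lo) & (data[:, 0] <= hi)]
    bad = data[:, 1] <= 0
    if np.any(bad):
        warnings.warn(f"dropping {bad.sum()} non-positive ALC values from the "
                      "log fit", stacklevel=2)
        data = data[~bad]
    if data.shape[0] < 2:
        raise ValidationError("need at least two positive ALC measurements")
    bins = np.floor(data[:, 0] / bin_days).astype(int)
    frame = pd.DataFrame({"bin": bins, "day": data[:, 0], "alc": data[:, 1]})
    grouped = frame.groupby("bin").agg(day=("day", "mean"), alc=("alc", "mean"))
    if len(grouped) < 2:
        raise ValidationError("need measurements in at least two time bins")
    slope, intercept = np.polyfit(grouped["day"], np.log(grouped["alc"]), 1)
    lam = -float(slope)
    resid = np.log(grouped["alc"]) - (slope * grouped["day"] + intercept)
    return ALCDecayFit(
        lambda_per_day=lam,
        half_time_days=float(np.log(2) / lam) if lam > 0 else np.inf,
        fit_rmse=float(np.sqrt(np.mean(resid ** 2))),
        n_points_used=int(data.shape[0]),
    )


@dataclass
class LogisticResult:
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    or_ci: np.ndarray            # (k, 2) Wald 95% intervals on the OR scale
    converged: bool
    separation: bool
    names: list


def logistic_fit(design, outcomes, names: Optional[Sequence[str]] = None,
                 add_constant: bool = True, max_iter: int = 100,
                 tol: float = 1e-8) -> LogisticResult:
    """Binary logistic regression with Wald inference.

    Fits by iteratively reweighted least squares (Newton); odds ratios are
    exp(coef) with symmetric Wald 95% intervals.  Complete separation is
    flagged (no usable estimates) rather than silently returning divergent
    coefficients.
    """
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcomes, int)
    if y.min() == y.max():
        raise ValidationError("outcomes are single-class")
    if add_constant:
        X = sm.add_constant(X, has_constant="add")
        names = ["intercept"] + list(names or [f"x{i}" for i in range(X.shape[1] - 1)])
    else:
        names = list(names or [f"x{i}" for i in range(X.shape[1])])

    separation = False
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=max_iter, tol=tol)
        converged = bool(res.mle_retvals.get("converged", False))
        coef = np.asarray(res.params, float)
        se = np.asarray(res.bse, float)
        # enormous coefficients with blown-up SEs indicate (quasi-)separation
        if np.any(np.abs(coef) > 30) or np.any(~np.isfinite(se)):
            separation = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
        coef = np.full(X.shape[1], np.nan)
        se = np.full(X.shape[1], np.nan)

    if separation:
        nan = np.full(X.shape[1], np.nan)
        return LogisticResult(coef=nan, se=nan, p_values=nan, odds_ratios=nan,
                              or_ci=np.full((X.shape[1], 2), np.nan),
                              converged=False, separation=True, names=names)
    z = stats.norm.ppf(0.975)
    p_values = 2 * stats.norm.sf(np.abs(coef / se))
    return LogisticResult(
        coef=coef, se=se, p_values=p_values,
        odds_ratios=np.exp(coef),
        or_ci=np.column_stack([np.exp(coef - z * se), np.exp(coef + z * se)]),
        converged=converged, separation=False, names=names,
    )


def dichotomize(values, threshold: Optional[float] = None) -> np.ndarray:
    """Split a continuous variable at a threshold (cohort median by default).

    Values at or above the threshold map to 1, matching the ">= median"
    grouping convention for high-dose strata.
    """
    arr = np.asarray(values, float)
    if np.unique(arr).size < 2:
        raise ValidationError("cannot dichotomize a constant variable")
    if threshold is None:
        threshold = float(np.median(arr))
    return (arr >= threshold).astype(int)


def bonferroni(p_values, k: Optional[int] = None):
    """Bonferroni adjustment: min(1, k * p)."""
    arr = np.asarray(p_values, float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if k is None:
        k = arr.size
    out = np.minimum(1.0, k * arr)
    return float(out) if np.isscalar(p_values) else out


def anova_by_grade(groups: Mapping | Sequence) -> dict:
    """One-way ANOVA of mean blood dose across lymphopenia-grade groups."""
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, float) for v in groups]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two non-empty groups")
    if all(a.size < 2 for a in arrays):
        raise ValidationError("ANOVA needs at least one group with >= 2 members")
    f_stat, p = stats.f_oneway(*arrays)
    return {"F": float(f_stat), "p": float(p)}
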