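"""Validation and calibration of fitted NTCP models.

Covers discrimination (ROC AUC, Brier score), parameter uncertainty
(patient-level percentile bootstrap), internal validation (stratified
k-fold cross-validation), dose-binned chi-square goodness of fit, and
calibration analysis (decile observed/predicted rates with Wilson score
intervals, a LOWESS smoothed curve, and the logistic calibration slope and
intercept), including transfer of a frozen model to an external cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .errors import FitError, ValidationError
from .lkb import CohortOutcomes, FitResult, LKBParams, fit_lkb, predict_ntcp

__all__ = [
    "roc_auc",
    "brier_score",
    "wilson_interval",
    "lowess",
    "bootstrap_ci",
    "stratified_kfold_cv",
    "chisq_gof",
    "calibration_report",
    "external_validate",
    "CalibrationReport",
]


def _check_two_classes(outcomes: np.ndarray):
    if outcomes.min() == outcomes.max():
        raise ValidationError("need at least one event and one non-event")


def roc_auc(scores, outcomes) -> float:
    """ROC AUC in the Mann-Whitney form: P(score_event > score_nonevent),
    ties counted half."""
    y = np.asarray(outcomes, int)
    s = np.asarray(scores, float)
    _check_two_classes(y)
    return float(roc_auc_score(y, s))


def brier_score(probs, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probs, float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    y = np.asarray(outcomes, float)
    return float(np.mean((p - y) ** 2))


def wilson_interval(events: int, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion (exact normal quantile)."""
    if n <= 0 or not 0 <= events <= n:
        raise ValidationError("need 0 <= events <= n with n > 0")
    lo, hi = proportion_confint(events, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def lowess(x, y, frac: float = 2.0 / 3.0, robust_iters: int = 3):
    """Locally weighted scatterplot smoothing (tricube kernel, bisquare
    robustness), evaluated at the sorted input abscissae.

    Local linear fits over the ``ceil(frac*n)`` nearest neighbours of each
    point; ``robust_iters`` bisquare reweighting passes downweight
    outliers.  Returns ``(x_sorted, y_smoothed)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValidationError("lowess needs >= 5 (x, y) pairs")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = xs.size
    k = max(2, min(n, int(frac * n)))

    # nearest-neighbour windows on sorted x (two-pointer)
    lefts = np.empty(n, int)
    left = 0
    for i in range(n):
        right = left + k - 1
        while right + 1 < n and (xs[right + 1] - xs[i]) < (xs[i] - xs[left]):
            left += 1
            right += 1
        lefts[i] = left
    robust_w = np.ones(n)
    fitted = ys.copy()
    for it in range(robust_iters + 1):
        for i in range(n):
            lo = lefts[i]
            xi = xs[lo:lo + k]
            yi = ys[lo:lo + k]
            h = max(xs[i] - xi[0], xi[-1] - xs[i])
            if h <= 0:
                w = robust_w[lo:lo + k].copy()
            else:
                d = np.abs(xi - xs[i]) / h
                w = np.clip(1 - d ** 3, 0, None) ** 3 * robust_w[lo:lo + k]
            sw = w.sum()
            if sw <= 0:
                fitted[i] = ys[i]
                continue
            xm = np.dot(w, xi) / sw
            ym = np.dot(w, yi) / sw
            sxx = np.dot(w, (xi - xm) ** 2)
            if sxx > 1e-12 * (h * h if h > 0 else 1.0):
                beta = np.dot(w, (xi - xm) * (yi - ym)) / sxx
                fitted[i] = ym + beta * (xs[i] - xm)
            else:
                fitted[i] = ym
        if it == robust_iters:
            break
        resid = ys - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        robust_w = np.clip(1 - (resid / (6.0 * s)) ** 2, 0, None) ** 2
    return xs, fitted


# --- resampling ------------------------------------------------------------

@dataclass
class BootstrapCI:
    intervals: dict            # param name -> (lo, hi)
    samples: pd.DataFrame      # one row per bootstrap fit
    n_degenerate_redrawn: int
    level: float
    seed: int


def bootstrap_ci(cohort: CohortOutcomes,
                 fit_fn: Optional[Callable[[CohortOutcomes], FitResult]] = None,
                 n_boot: int = 1000, level: float = 0.95, seed: int = 0) -> BootstrapCI:
    """Patient-level bootstrap percentile confidence intervals.

    Resamples patients with replacement, refits with ``fit_fn`` (default:
    the free LKB fit) and takes the (1-level)/2 percentile interval of each
    parameter.  Single-class resamples are redrawn and counted; more than
    50% degenerate draws aborts, since the percentile interval would then
    describe a conditioned distribution.
    """
    cohort.require_fittable()
    if fit_fn is None:
        fit_fn = fit_lkb
    rng = np.random.default_rng(seed)
    rows = []
    n_degenerate = 0
    attempts = 0
    for _ in range(n_boot):
        while True:
            attempts += 1
            idx = rng.integers(0, cohort.n, size=cohort.n)
            y = cohort.outcomes[idx]
            if 0 < y.sum() < cohort.n:
                break
            n_degenerate += 1
            if attempts >= 100 and n_degenerate > attempts / 2:
                raise FitError("more than half of bootstrap resamples were single-class")
        fit = fit_fn(cohort.resample(idx))
        p = fit.params if isinstance(fit, FitResult) else fit
        rows.append({"d50": p.d50, "m": p.m, "a": p.a})
    samples = pd.DataFrame(rows)
    alpha = (1 - level) / 2
    intervals = {
        name: (float(np.percentile(samples[name], 100 * alpha)),
               float(np.percentile(samples[name], 100 * (1 - alpha))))
        for name in samples.columns
    }
    return BootstrapCI(intervals=intervals, samples=samples,
                       n_degenerate_redrawn=n_degenerate, level=level, seed=seed)


def stratified_kfold_cv(cohort: CohortOutcomes,
                        fit_fn: Optional[Callable[[CohortOutcomes], FitResult]] = None,
                        k: int = 5, seed: int = 0) -> dict:
    """Stratified k-fold cross-validation of held-out discrimination.

    Folds preserve the event proportion; the model (all parameters) is
    refit on each training split and AUC is computed on the held-out
    split.
    """
    cohort.require_fittable()
    y = cohort.outcomes
    if min(y.sum(), cohort.n - y.sum()) < k:
        raise ValidationError(f"each class needs at least k={k} members")
    if fit_fn is None:
        fit_fn = fit_lkb
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_auc = []
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(cohort.n), y):
        fit = fit_fn(cohort.resample(train_idx))
        params = fit.params if isinstance(fit, FitResult) else fit
        probs = predict_ntcp(params, cohort.resample(test_idx))
        fold_auc.append(roc_auc(probs, y[test_idx]))
        folds.append({"test_idx": test_idx, "n_events": int(y[test_idx].sum())})
    return {"fold_auc": fold_auc, "mean_auc": float(np.mean(fold_auc)), "folds": folds}


# --- goodness of fit -------------------------------------------------------

def chisq_gof(cohort: CohortOutcomes, params: LKBParams, n_bins: int = 5,
              df: Optional[int] = None) -> dict:
    """Chi-square goodness of fit on mean-blood-dose-sorted bins.

    Patients are sorted by mean blood dose and split into ``n_bins``
    near-equal bins; the statistic sums (O_k - E_k)^2 / (E_k (1 - E_k/n_k))
    over bins, where E_k is the summed predicted NTCP.  The p-value refers
    the statistic to a chi-square with ``n_bins - 1`` degrees of freedom
    by default (the multinomial binning convention); pass ``df`` to use a
    parameter-corrected reference instead.  A value near zero indicates
    close agreement between observed and predicted event counts; the raw
    binned table is always returned so other statistics can be recomputed.
    """
    if cohort.n < 2 * n_bins:
        raise ValidationError(f"need at least {2 * n_bins} patients for {n_bins} bins")
    order = np.argsort(cohort.mean_doses, kind="stable")
    probs = predict_ntcp(params, cohort)
    chunks = np.array_split(order, n_bins)
    rows = []
    chi2_val = 0.0
    for k, idx in enumerate(chunks):
        n_k = idx.size
        o_k = float(cohort.outcomes[idx].sum())
        e_k = float(probs[idx].sum())
        e_used = e_k
        if e_k <= 0 or e_k >= n_k:
            warnings.warn(f"bin {k}: expected count {e_k:.3g} clipped for the "
                          "variance term", stacklevel=2)
            e_used = min(max(e_k, 0.5), n_k - 0.5)
        chi2_val += (o_k - e_used) ** 2 / (e_used * (1 - e_used / n_k))
        rows.append({"bin": k, "n": n_k, "observed": o_k, "expected": e_k,
                     "mean_dose_lo": float(cohort.mean_doses[idx].min()),
                     "mean_dose_hi": float(cohort.mean_doses[idx].max())})
    if df is None:
        df = n_bins - 1
    df = max(df, 1)
    return {
        "chi2": float(chi2_val),
        "p": float(stats.chi2.sf(chi2_val, df)),
        "df": df,
        "binning": pd.DataFrame(rows),
    }


# --- calibration -----------------------------------------------------------

@dataclass
class CalibrationReport:
    bins: pd.DataFrame          # n, observed_rate, wilson_lo/hi, mean_predicted
    lowess_x: np.ndarray
    lowess_y: np.ndarray
    slope: float
    intercept: float
    brier: float
    auc: float
    prevalence: float

    def __post_init__(self):
        assert int(self.bins["n"].sum()) >= 0


def _probability_bins(probs: np.ndarray, outcomes: np.ndarray, n_bins: int,
                      level: float) -> pd.DataFrame:
    order = np.argsort(probs, kind="stable")
    chunks = [c for c in np.array_split(order, min(n_bins, probs.size)) if c.size]
    # merge bins that contain fewer than two distinct predictions (heavy
    # ties in small cohorts) into their lower neighbour
    merged = []
    for c in chunks:
        if merged and np.unique(probs[c]).size < 2:
            merged[-1] = np.concatenate([merged[-1], c])
        else:
            merged.append(c)
    rows = []
    for idx in merged:
        n_k = idx.size
        events = int(outcomes[idx].sum())
        lo, hi = wilson_interval(events, n_k, level)
        rows.append({"n": n_k, "events": events, "observed_rate": events / n_k,
                     "wilson_lo": lo, "wilson_hi": hi,
                     "mean_predicted": float(probs[idx].mean())})
    return pd.DataFrame(rows)


def calibration_report(probs, outcomes, n_bins: int = 10,
                       lowess_frac: float = 2.0 / 3.0,
                       level: float = 0.95) -> CalibrationReport:
    """Full calibration analysis of predicted probabilities.

    The slope and intercept come from a logistic regression of the
    outcomes on the logit of the predictions (clipped to (1e-6, 1-1e-6)):
    slope 1 / intercept 0 is perfect calibration; slope < 1 indicates
    predictions more extreme than the outcomes warrant.
    """
    p = np.asarray(probs, float)
    y = np.asarray(outcomes, int)
    if p.size != y.size or p.size == 0:
        raise ValidationError("probs and outcomes must be equal-length and non-empty")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    _check_two_classes(y)

    bins = _probability_bins(p, y, n_bins, level)
    lx, ly = lowess(p, y.astype(float), frac=lowess_frac)

    p_clip = np.clip(p, 1e-6, 1 - 1e-6)
    logit_p = np.log(p_clip / (1 - p_clip))
    design = sm.add_constant(logit_p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    intercept, slope = float(glm.params[0]), float(glm.params[1])

    return CalibrationReport(
        bins=bins,
        lowess_x=lx,
        lowess_y=ly,
        slope=slope,
        intercept=intercept,
        brier=brier_score(p, y),
        auc=roc_auc(p, y),
        prevalence=float(y.mean()),
    )


def external_validate(fit: FitResult, target_cohort: CohortOutcomes,
                      n_bins: int = 10, lowess_frac: float = 2.0 / 3.0) -> CalibrationReport:
    """Apply a frozen fitted model (all parameters, including ``a``) to an
    independent cohort and report its calibration and discrimination."""
    probs = predict_ntcp(fit.params, target_cohort)
    return calibration_report(probs, target_cohort.outcomes,
                              n_bins=n_bins, lowess_frac=lowess_frac)
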