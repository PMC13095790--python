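"""Lyman-Kutcher-Burman probit NTCP model on blood gEUD.

The complication probability for a patient whose blood DVH reduces to a
generalized equivalent uniform dose ``g`` at volume-effect exponent ``a`` is

    NTCP = Phi(x),   x = (g - D50) / (m * D50)

with ``Phi`` the standard normal CDF, ``D50`` the dose giving 50% risk and
``m`` the (dimensionless) slope of the dose-response curve.  Parameters are
estimated by maximising the Bernoulli likelihood of the observed binary
severe-lymphopenia outcomes (Nelder-Mead on the negative log-likelihood in
log-parameter space, multi-start because the (D50, m, a) surface is
multi-modal).

For speed the cohort container pre-tabulates each patient's log-gEUD on a
dense log-spaced grid of ``a`` values and interpolates; gEUD is smooth and
monotone in ``a`` so the interpolation error is far below the sampling
noise of any realistic cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .dvh import DifferentialDVH, geud, mean_dose
from .errors import FitError, ValidationError

__all__ = [
    "A_BOUNDS",
    "LKBParams",
    "CohortOutcomes",
    "FitResult",
    "ntcp_probit",
    "negative_log_likelihood",
    "predict_ntcp",
    "fit_lkb",
    "fit_lkb_fixed_a",
]

#: allowed range for the volume-effect exponent during fitting
A_BOUNDS = (0.1, 50.0)

_P_CLIP = 1e-12
_DEFAULT_A_GRID_SIZE = 256


@dataclass(frozen=True)
class LKBParams:
    """LKB parameter triple (D50 in Gy, slope m, volume exponent a)."""

    d50: float
    m: float
    a: float

    def __post_init__(self):
        if not self.d50 > 0:
            raise ValidationError("D50 must be > 0")
        if not self.m > 0:
            raise ValidationError("m must be > 0")
        if not A_BOUNDS[0] <= self.a <= A_BOUNDS[1]:
            raise ValidationError(f"a must lie in [{A_BOUNDS[0]}, {A_BOUNDS[1]}]")


def ntcp_probit(geud_gy, params: LKBParams):
    """Probit dose-response: standard normal CDF of (gEUD - D50)/(m D50).

    Accepts a scalar or array of gEUD values; NTCP(D50) = 0.5 for any m.
    """
    g = np.asarray(geud_gy, dtype=float)
    x = (g - params.d50) / (params.m * params.d50)
    out = ndtr(x)
    return float(out) if np.isscalar(geud_gy) else out


class CohortOutcomes:
    """Per-patient blood gEUD curves over ``a`` plus binary outcomes.

    Stores log gEUD tabulated on a log-spaced ``a`` grid; ``geud_at``
    interpolates bilinearly in (log a, log gEUD).  ``mean_doses`` (gEUD at
    a=1) is kept exactly for dose-sorted goodness-of-fit binning.
    """

    def __init__(self, log_a_grid, log_geud_table, outcomes, mean_doses=None,
                 dvhs: Optional[Sequence[DifferentialDVH]] = None):
        self.log_a_grid = np.asarray(log_a_grid, float)
        self.log_geud_table = np.asarray(log_geud_table, float)  # (n, grid)
        self.outcomes = np.asarray(outcomes, int)
        if self.outcomes.size == 0:
            raise ValidationError("empty cohort")
        if self.log_geud_table.shape != (self.outcomes.size, self.log_a_grid.size):
            raise ValidationError("gEUD table shape does not match outcomes/grid")
        if not np.all(np.isin(self.outcomes, (0, 1))):
            raise ValidationError("outcomes must be binary 0/1")
        if mean_doses is not None:
            self.mean_doses = np.asarray(mean_doses, float)
        else:
            self.mean_doses = self.geud_at(1.0)
        self.dvhs = list(dvhs) if dvhs is not None else None

    @classmethod
    def from_dvhs(cls, dvhs: Sequence[DifferentialDVH], outcomes,
                  a_grid: Optional[np.ndarray] = None) -> "CohortOutcomes":
        if a_grid is None:
            a_grid = np.geomspace(A_BOUNDS[0], A_BOUNDS[1], _DEFAULT_A_GRID_SIZE)
        a_grid = np.asarray(a_grid, float)
        if np.any(a_grid <= 0):
            raise ValidationError("a grid must be positive")
        # pad the cohort's DVHs into (n, max_bins) matrices; masked bins and
        # zero-dose bins carry -inf log-weight so they drop out of the
        # log-sum-exp power mean
        n, width = len(dvhs), max(d.doses.size for d in dvhs)
        log_v = np.full((n, width), -np.inf)
        log_d = np.zeros((n, width))
        for i, dvh in enumerate(dvhs):
            k = dvh.doses.size
            with np.errstate(divide="ignore"):
                lv = np.log(dvh.fractions)
                ld = np.where(dvh.doses > 0, np.log(np.maximum(dvh.doses, 1e-300)), 0.0)
            lv = np.where(dvh.doses > 0, lv, -np.inf)  # zero-dose bins: no mass
            log_v[i, :k] = lv
            log_d[i, :k] = ld
        table = np.empty((n, a_grid.size))
        for j, a in enumerate(a_grid):
            s = log_v + a * log_d
            mx = s.max(axis=1)
            with np.errstate(invalid="ignore"):
                lse = mx + np.log(np.exp(s - mx[:, None]).sum(axis=1))
            lse = np.where(np.isfinite(mx), lse, -np.inf)  # all-zero-dose DVH
            table[:, j] = np.maximum(lse / a, np.log(_P_CLIP))
        means = np.array([mean_dose(d) for d in dvhs])
        return cls(np.log(a_grid), table, outcomes, mean_doses=means, dvhs=dvhs)

    @property
    def n(self) -> int:
        return self.outcomes.size

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())

    def require_fittable(self):
        if self.n == 0:
            raise ValidationError("empty cohort")
        if self.n_events == 0 or self.n_events == self.n:
            raise ValidationError("fitting requires at least one event and one non-event")

    def geud_at(self, a: float) -> np.ndarray:
        """Per-patient gEUD at exponent ``a`` (log-log interpolation)."""
        la = np.log(np.clip(a, A_BOUNDS[0], A_BOUNDS[1]))
        grid = self.log_a_grid
        j = np.searchsorted(grid, la)
        if j <= 0:
            return np.exp(self.log_geud_table[:, 0])
        if j >= grid.size:
            return np.exp(self.log_geud_table[:, -1])
        w = (la - grid[j - 1]) / (grid[j] - grid[j - 1])
        col = (1 - w) * self.log_geud_table[:, j - 1] + w * self.log_geud_table[:, j]
        return np.exp(col)

    def resample(self, indices) -> "CohortOutcomes":
        idx = np.asarray(indices, int)
        return CohortOutcomes(
            self.log_a_grid,
            self.log_geud_table[idx],
            self.outcomes[idx],
            mean_doses=self.mean_doses[idx],
            dvhs=[self.dvhs[i] for i in idx] if self.dvhs is not None else None,
        )


@dataclass
class FitResult:
    params: LKBParams
    nll: float
    converged: bool
    n_restarts_used: int
    seed: int
    identifiable: bool = True
    fixed_a: Optional[float] = None
    bootstrap_ci: Optional[dict] = None  # {"d50": (lo, hi), ...}
    restart_table: list = field(default_factory=list)

    def with_bootstrap_ci(self, ci: dict) -> "FitResult":
        return replace(self, bootstrap_ci=ci)


def _clipped_nll(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def negative_log_likelihood(params: LKBParams, cohort: CohortOutcomes) -> float:
    """Bernoulli NLL of the outcomes under the probit model (>= 0)."""
    if cohort.n == 0:
        raise ValidationError("empty cohort")
    p = ntcp_probit(cohort.geud_at(params.a), params)
    return _clipped_nll(p, cohort.outcomes)


def predict_ntcp(params: LKBParams, cohort: CohortOutcomes) -> np.ndarray:
    """Per-patient NTCP under ``params`` (gEUD taken at params.a)."""
    return ntcp_probit(cohort.geud_at(params.a), params)


# --- maximum likelihood ----------------------------------------------------

_RESTART_A = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
_RESTART_M = (0.2, 0.5)
_D50_PERCENTILES = (20, 50, 80)
_LOG_A_LO, _LOG_A_HI = np.log(A_BOUNDS[0]), np.log(A_BOUNDS[1])


def _objective_free(cohort: CohortOutcomes) -> Callable[[np.ndarray], float]:
    y = cohort.outcomes

    def nll(theta: np.ndarray) -> float:
        ld50, lm, la = theta
        # soft box on a: evaluate at the clipped value, penalize the excess
        la_c = min(max(la, _LOG_A_LO), _LOG_A_HI)
        penalty = 1e3 * (la - la_c) ** 2
        d50, m, a = np.exp(ld50), np.exp(lm), np.exp(la_c)
        g = cohort.geud_at(a)
        p = ndtr((g - d50) / (m * d50))
        return _clipped_nll(p, y) + penalty

    return nll


def _objective_fixed_a(cohort: CohortOutcomes, a: float) -> Callable[[np.ndarray], float]:
    y = cohort.outcomes
    g = cohort.geud_at(a)

    def nll(theta: np.ndarray) -> float:
        d50, m = np.exp(theta[0]), np.exp(theta[1])
        p = ndtr((g - d50) / (m * d50))
        return _clipped_nll(p, y)

    return nll


def _d50_starts(cohort: CohortOutcomes, a: float) -> np.ndarray:
    g = cohort.geud_at(a)
    return np.maximum(np.percentile(g, _D50_PERCENTILES), 1e-6)


def _is_flat_in_dose(cohort: CohortOutcomes) -> bool:
    """True when every patient has the same gEUD curve (nothing to fit on)."""
    for a in (0.5, 1.0, 8.0):
        g = cohort.geud_at(a)
        if np.ptp(g) > 1e-9 * max(abs(g).max(), 1.0):
            return False
    return True


def _run_restarts(objective, starts, fatol, max_iter):
    best = None
    table = []
    n_converged = 0
    for x0 in starts:
        res = minimize(
            objective,
            np.asarray(x0, float),
            method="Nelder-Mead",
            options={"fatol": fatol, "xatol": 1e-8, "maxiter": max_iter,
                     "maxfev": 2 * max_iter},
        )
        table.append({"x0": list(map(float, x0)), "nll": float(res.fun),
                      "converged": bool(res.success)})
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, table, n_converged


def fit_lkb(cohort: CohortOutcomes, starts: Optional[list] = None, seed: int = 0,
            fatol: float = 1e-8, max_iter: int = 2000) -> FitResult:
    """Maximum-likelihood LKB fit over (D50, m, a).

    Nelder-Mead in log-parameter space from a multi-start grid: a over
    octaves in [0.5, 32], D50 at the 20/50/80th gEUD percentiles for each
    trial a, and m in {0.2, 0.5}.  Deterministic given the cohort; ``seed``
    is recorded for provenance.  A cohort whose patients all share one
    gEUD curve is returned flagged non-identifiable rather than raising.
    """
    cohort.require_fittable()
    if _is_flat_in_dose(cohort):
        g0 = float(cohort.geud_at(1.0)[0])
        return FitResult(
            params=LKBParams(max(g0, 1e-6), 1.0, 1.0),
            nll=negative_log_likelihood(LKBParams(max(g0, 1e-6), 1.0, 1.0), cohort),
            converged=False, n_restarts_used=0, seed=seed, identifiable=False,
        )

    if starts is None:
        starts = []
        for a0 in _RESTART_A:
            for d0 in _d50_starts(cohort, a0):
                for m0 in _RESTART_M:
                    starts.append([np.log(d0), np.log(m0), np.log(a0)])

    best, table, n_conv = _run_restarts(_objective_free(cohort), starts, fatol, max_iter)
    ld50, lm, la = best.x
    la = min(max(la, _LOG_A_LO), _LOG_A_HI)
    params = LKBParams(float(np.exp(ld50)), float(np.exp(lm)), float(np.exp(la)))
    return FitResult(
        params=params,
        nll=negative_log_likelihood(params, cohort),
        converged=n_conv > 0,
        n_restarts_used=len(starts),
        seed=seed,
        restart_table=table,
    )


def warm_fit_fn(init: LKBParams, fixed_a: Optional[float] = None):
    """Single-start fit function seeded at ``init``.

    The standard choice for bootstrap refits: each resample's likelihood
    surface is a small perturbation of the original, so restarting the
    whole multi-start grid per resample buys nothing.
    """
    if fixed_a is None:
        starts = [[np.log(init.d50), np.log(init.m), np.log(init.a)]]
        return lambda cohort: fit_lkb(cohort, starts=starts)
    starts = [[np.log(init.d50), np.log(init.m)]]
    return lambda cohort: fit_lkb_fixed_a(cohort, fixed_a, starts=starts)


def fit_lkb_fixed_a(cohort: CohortOutcomes, a_fixed: float,
                    starts: Optional[list] = None, seed: int = 0,
                    fatol: float = 1e-8, max_iter: int = 2000) -> FitResult:
    """LKB fit with the volume exponent held fixed; optimizes (D50, m) only.

    Used for constrained cross-modality analyses, e.g. refitting a proton
    cohort under the photon-derived volume exponent.
    """
    cohort.require_fittable()
    if not A_BOUNDS[0] <= a_fixed <= A_BOUNDS[1]:
        raise ValidationError(f"a_fixed must lie in [{A_BOUNDS[0]}, {A_BOUNDS[1]}]")
    if _is_flat_in_dose(cohort):
        g0 = float(cohort.geud_at(a_fixed)[0])
        p = LKBParams(max(g0, 1e-6), 1.0, a_fixed)
        return FitResult(params=p, nll=negative_log_likelihood(p, cohort),
                         converged=False, n_restarts_used=0, seed=seed,
                         identifiable=False, fixed_a=a_fixed)
    if starts is None:
        starts = [[np.log(d0), np.log(m0)]
                  for d0 in _d50_starts(cohort, a_fixed) for m0 in _RESTART_M]
    best, table, n_conv = _run_restarts(
        _objective_fixed_a(cohort, a_fixed), starts, fatol, max_iter
    )
    params = LKBParams(float(np.exp(best.x[0])), float(np.exp(best.x[1])), a_fixed)
    return FitResult(
        params=params,
        nll=negative_log_likelihood(params, cohort),
        converged=n_conv > 0,
        n_restarts_used=len(starts),
        seed=seed,
        fixed_a=a_fixed,
        restart_table=table,
    )
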