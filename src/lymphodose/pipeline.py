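"""End-to-end reproducible pipeline: synthesize -> fit -> evaluate.

All randomness derives from one root seed; each stage gets a child seed
computed deterministically from (root seed, stage name) and recorded in
the outputs, so re-running an identical configuration reproduces identical
JSON byte for byte (timestamps excluded by construction — none are
written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import evaluate as ev
from .errors import ValidationError
from .io import config_hash, json_sanitize, write_cohort
from .lkb import CohortOutcomes, fit_lkb, fit_lkb_fixed_a, predict_ntcp
from .synth import (PHOTON_PROFILE, PHOTON_TRUTH, PROTON_PROFILE, PROTON_TRUTH,
                    cohort_outcomes, generate_cohort)

logger = logging.getLogger("lymphodose")

__all__ = ["RunConfig", "run_pipeline", "child_seed"]

_PROFILES = {"photon-like": (PHOTON_PROFILE, PHOTON_TRUTH),
             "proton-like": (PROTON_PROFILE, PROTON_TRUTH)}


def child_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    modality: str = "photon-like"
    n: int = 200
    n_boot: int = 200
    k_folds: int = 5
    gof_bins: int = 5
    calib_bins: int = 10
    lowess_frac: float = 2.0 / 3.0
    fix_a: Optional[float] = None

    def __post_init__(self):
        if self.modality not in _PROFILES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not (self.n >= 10 and self.n_boot >= 0 and self.k_folds >= 2):
            raise ValidationError("n >= 10, n_boot >= 0 and k_folds >= 2 required")
        if not 0 < self.lowess_frac <= 1:
            raise ValidationError("lowess_frac must lie in (0, 1]")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _dump(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(json_sanitize(payload), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run synth -> fit (free and, if requested, fixed-a) -> evaluate.

    Writes ``cohort.csv``, ``alc.csv``, ``fit.json`` and ``report.json``
    under ``config.out_dir``; every JSON embeds the config hash and the
    stage seeds.  Returns the report bundle as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.as_dict())
    seeds = {stage: child_seed(config.seed, stage)
             for stage in ("synth", "bootstrap", "cv")}
    logger.info("run %s: stage seeds %s", chash, seeds)

    profile, truth = _PROFILES[config.modality]
    records = generate_cohort(config.n, profile, truth, seed=seeds["synth"])
    write_cohort(records, out / "cohort.csv", alc_path=out / "alc.csv")
    cohort = cohort_outcomes(records)

    fit = fit_lkb(cohort, seed=seeds["synth"])
    fit_payload = {
        "config_hash": chash, "seeds": seeds,
        "free": _fit_to_dict(fit),
    }
    if config.n_boot > 0:
        boot = ev.bootstrap_ci(cohort, n_boot=config.n_boot, seed=seeds["bootstrap"])
        fit_payload["free"]["bootstrap_ci"] = boot.intervals
        fit_payload["free"]["n_degenerate_redrawn"] = boot.n_degenerate_redrawn
    if config.fix_a is not None:
        fit_payload["fixed_a"] = _fit_to_dict(
            fit_lkb_fixed_a(cohort, config.fix_a, seed=seeds["synth"])
        )
    _dump(out / "fit.json", fit_payload)

    probs = predict_ntcp(fit.params, cohort)
    report = {
        "config_hash": chash,
        "seeds": seeds,
        "n": cohort.n,
        "events": cohort.n_events,
        "auc": ev.roc_auc(probs, cohort.outcomes),
        "brier": ev.brier_score(probs, cohort.outcomes),
        "cv": _strip(ev.stratified_kfold_cv(cohort, k=config.k_folds,
                                            seed=seeds["cv"])),
        "gof": _gof_to_dict(ev.chisq_gof(cohort, fit.params,
                                         n_bins=config.gof_bins)),
        "calibration": _calib_to_dict(
            ev.calibration_report(probs, cohort.outcomes,
                                  n_bins=config.calib_bins,
                                  lowess_frac=config.lowess_frac)
        ),
        "fit": fit_payload["free"],
    }
    _dump(out / "report.json", report)
    return report


def _fit_to_dict(fit) -> dict:
    return {
        "d50": fit.params.d50, "m": fit.params.m, "a": fit.params.a,
        "nll": fit.nll, "converged": fit.converged,
        "identifiable": fit.identifiable,
        "n_restarts_used": fit.n_restarts_used, "seed": fit.seed,
        "fixed_a": fit.fixed_a,
    }


def _strip(cv: dict) -> dict:
    return {"fold_auc": cv["fold_auc"], "mean_auc": cv["mean_auc"]}


def _gof_to_dict(gof: dict) -> dict:
    return {"chi2": gof["chi2"], "p": gof["p"], "df": gof["df"],
            "binning": gof["binning"]}


def _calib_to_dict(rep: ev.CalibrationReport) -> dict:
    return {
        "slope": rep.slope, "intercept": rep.intercept,
        "brier": rep.brier, "auc": rep.auc, "prevalence": rep.prevalence,
        "bins": rep.bins,
        "lowess": {"x": rep.lowess_x, "y": rep.lowess_y},
    }
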