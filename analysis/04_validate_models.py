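#!/usr/bin/env python
"""Validate the fitted NTCP models and test cross-modality transfer.

Per modality: apparent AUC and Brier score, stratified 5-fold
cross-validated AUC, the dose-binned chi-square goodness of fit, and the
decile calibration report.  Then the photon-derived model is applied
frozen to the proton cohort to quantify transfer miscalibration
(calibration slope/intercept).  Requires 02 and 03.
"""

import json
from pathlib import Path

import lymphodose as ld
from lymphodose.evaluate import (calibration_report, chisq_gof,
                                 external_validate, stratified_kfold_cv)
from lymphodose.io import json_sanitize, read_cohort
from lymphodose.lkb import predict_ntcp

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SEED = 20260924


def load(modality):
    base = OUT / "cohorts" / modality
    records = read_cohort(base / "cohort.csv", dvh_dir=base / "dvh")
    return ld.cohort_outcomes(records)


def main():
    fits = json.loads((OUT / "fits.json").read_text())
    payload = {}
    for modality in ("photon", "proton"):
        cohort = load(modality)
        f = fits[modality]
        params = ld.LKBParams(f["d50"], f["m"], f["a"])
        probs = predict_ntcp(params, cohort)
        cv = stratified_kfold_cv(cohort, k=5,
                                 seed=ld.child_seed(SEED, f"cv-{modality}"))
        gof = chisq_gof(cohort, params)
        calib = calibration_report(probs, cohort.outcomes)
        payload[modality] = {
            "auc": ld.roc_auc(probs, cohort.outcomes),
            "brier": ld.brier_score(probs, cohort.outcomes),
            "cv_mean_auc": cv["mean_auc"], "fold_auc": cv["fold_auc"],
            "gof_chi2": gof["chi2"], "gof_p": gof["p"],
            "calibration_slope": calib.slope,
            "calibration_intercept": calib.intercept,
        }
        print(f"{modality}: AUC {payload[modality]['auc']:.2f}, Brier "
              f"{payload[modality]['brier']:.2f}, CV AUC "
              f"{cv['mean_auc']:.2f}, chi2 {gof['chi2']:.2f} (p={gof['p']:.2f})")

    # cross-modality: frozen photon model on the proton cohort
    f = fits["photon"]
    frozen = ld.FitResult(params=ld.LKBParams(f["d50"], f["m"], f["a"]),
                          nll=f["nll"], converged=True, n_restarts_used=0,
                          seed=SEED)
    proton = load("proton")
    transfer = external_validate(frozen, proton)
    payload["photon_model_on_proton"] = {
        "slope": transfer.slope, "intercept": transfer.intercept,
        "auc": transfer.auc, "brier": transfer.brier,
        "prevalence": transfer.prevalence,
        "bins": transfer.bins,
    }
    print(f"photon model on proton cohort: calibration slope "
          f"{transfer.slope:.2f}, intercept {transfer.intercept:.2f}, AUC "
          f"{transfer.auc:.2f}, Brier {transfer.brier:.2f} — slope below 1 "
          "means the transferred model is overconfident for this cohort")

    (OUT / "validation.json").write_text(
        json.dumps(json_sanitize(payload), indent=2) + "\n")
    print(f"wrote {OUT / 'validation.json'}")


if __name__ == "__main__":
    main()
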