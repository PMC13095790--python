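"""Discrimination, resampling, goodness of fit and calibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import lymphodose as ld
from lymphodose.errors import FitError, ValidationError
from lymphodose.evaluate import bootstrap_ci, chisq_gof, stratified_kfold_cv
from lymphodose.lkb import CohortOutcomes, warm_fit_fn


def brute_force_auc(scores, outcomes):
    """All event/non-event pairs; ties get half credit."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        assert ld.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert ld.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_matches_all_pairs_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(10, 200)
            scores = np.round(rng.random(n), 2)  # force some ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assert ld.roc_auc(scores, y) == pytest.approx(
                brute_force_auc(scores, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(60)
        y = rng.integers(0, 2, 60)
        assert ld.roc_auc(scores, y) == pytest.approx(
            ld.roc_auc(np.exp(3 * scores), y))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ld.roc_auc([0.1, 0.2], [1, 1])


class TestBrier:
    def test_exact_predictions(self):
        assert ld.brier_score([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_coin_flip(self):
        assert ld.brier_score([0.5] * 10, [1] * 5 + [0] * 5) == pytest.approx(0.25)

    def test_bounded_by_one(self):
        assert ld.brier_score([1.0, 0.0], [0, 1]) == 1.0


class TestWilson:
    def test_closed_form(self):
        # z = 1.95996...; 5/10 at 95%
        lo, hi = ld.wilson_interval(5, 10)
        assert (lo, hi) == pytest.approx((0.2366, 0.7634), abs=2e-4)

    def test_zero_events_lower_bound(self):
        lo, _ = ld.wilson_interval(0, 20)
        assert lo == 0.0

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            lo, hi = ld.wilson_interval(k, n)
            assert lo - 1e-12 <= k / n <= hi + 1e-12
            assert 0 <= lo <= hi <= 1

    def test_against_closed_form_formula(self):
        from scipy.stats import norm
        z = norm.ppf(0.975)
        for k, n in [(3, 17), (12, 40), (1, 5)]:
            p = k / n
            center = (p + z * z / (2 * n)) / (1 + z * z / n)
            half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
            lo, hi = ld.wilson_interval(k, n)
            assert lo == pytest.approx(center - half, abs=1e-10)
            assert hi == pytest.approx(center + half, abs=1e-10)


class TestLowess:
    def test_reproduces_exact_line(self):
        x = np.linspace(0, 5, 40)
        xs, ys = ld.lowess(x, 2 * x, frac=0.5)
        np.testing.assert_allclose(ys, 2 * xs, atol=1e-8)

    def test_constant_stays_constant(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 30)
        xs, ys = ld.lowess(x, np.full(30, 0.7))
        np.testing.assert_allclose(ys, 0.7, atol=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 80)
        y = np.sin(x) + rng.normal(0, 0.3, 80)
        xs, ys = ld.lowess(x, y, frac=2 / 3, robust_iters=3)
        ref = sm.nonparametric.lowess(y, x, frac=2 / 3, it=3)
        np.testing.assert_allclose(ys, ref[:, 1], atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            ld.lowess([1, 2, 3], [1, 2, 3])


def _toy_cohort(geuds, outcomes):
    dvhs = [ld.DifferentialDVH([g], [1.0]) for g in geuds]
    return CohortOutcomes.from_dvhs(dvhs, outcomes)


class TestBootstrap:
    def test_identical_records_zero_width(self):
        # two distinct patients repeated: resample always refits the same
        # data up to multiplicity weighting, still yields finite spread;
        # the fully-degenerate analogue is identical fit inputs
        cohort = _toy_cohort([4.0] * 10 + [9.0] * 10, [0] * 10 + [1] * 10)
        fixed = ld.LKBParams(6.0, 0.3, 2.0)
        ci = bootstrap_ci(cohort, fit_fn=lambda c: fixed, n_boot=20, seed=0)
        for lo, hi in ci.intervals.values():
            assert hi - lo == 0.0

    def test_percentile_endpoints_are_order_statistics(self):
        cohort = _toy_cohort([4.0, 5.0, 8.0, 9.0] * 5, [0, 0, 1, 1] * 5)
        calls = []

        def fake_fit(c):
            calls.append(1)
            return ld.LKBParams(4.0 + len(calls) * 0.1, 0.3, 2.0)

        ci = bootstrap_ci(cohort, fit_fn=fake_fit, n_boot=40, seed=1)
        d50s = ci.samples["d50"].to_numpy()
        lo, hi = ci.intervals["d50"]
        assert lo == pytest.approx(np.percentile(d50s, 2.5))
        assert hi == pytest.approx(np.percentile(d50s, 97.5))

    def test_reproducible_under_seed(self, photon_cohort, photon_fit):
        fn = warm_fit_fn(photon_fit.params)
        c1 = bootstrap_ci(photon_cohort, fit_fn=fn, n_boot=25, seed=5)
        c2 = bootstrap_ci(photon_cohort, fit_fn=fn, n_boot=25, seed=5)
        assert c1.intervals == c2.intervals

    def test_mostly_degenerate_resampling_errors(self):
        # a two-patient cohort resamples single-class half the time, the
        # worst case possible; the guard trips once the running degenerate
        # fraction exceeds one half
        cohort = _toy_cohort([4.0, 9.0], [0, 1])
        with pytest.raises(FitError):
            bootstrap_ci(cohort, fit_fn=lambda c: ld.LKBParams(5, 0.3, 2),
                         n_boot=200, seed=0)


class TestStratifiedCV:
    def test_exact_stratification(self):
        rng = np.random.default_rng(4)
        cohort = _toy_cohort(rng.uniform(2, 12, 100),
                             [1] * 40 + [0] * 60)
        out = stratified_kfold_cv(cohort, fit_fn=lambda c: ld.LKBParams(7, 0.4, 2),
                                  k=5, seed=0)
        for fold in out["folds"]:
            assert fold["n_events"] == 8
            assert fold["test_idx"].size == 20

    def test_folds_partition_cohort(self):
        rng = np.random.default_rng(5)
        cohort = _toy_cohort(rng.uniform(2, 12, 60), rng.integers(0, 2, 60))
        out = stratified_kfold_cv(cohort, fit_fn=lambda c: ld.LKBParams(7, 0.4, 2),
                                  k=5, seed=1)
        all_idx = np.concatenate([f["test_idx"] for f in out["folds"]])
        assert sorted(all_idx) == list(range(60))

    def test_small_class_rejected(self):
        cohort = _toy_cohort([2, 3, 4, 5, 6, 7, 8, 9], [1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValidationError):
            stratified_kfold_cv(cohort, k=5)


class TestChisqGof:
    def test_bin_sizes_for_94_patients(self):
        rng = np.random.default_rng(6)
        cohort = _toy_cohort(rng.uniform(2, 12, 94), rng.integers(0, 2, 94))
        out = chisq_gof(cohort, ld.LKBParams(7.44, 0.42, 2.0))
        assert list(out["binning"]["n"]) == [19, 19, 19, 19, 18]

    def test_perfect_per_bin_match_gives_zero(self):
        # construct outcomes whose per-bin counts equal summed predictions
        geuds = np.repeat([3.0, 5.0, 7.44, 9.5, 12.0], 10)
        params = ld.LKBParams(7.44, 0.42, 2.0)
        probs = ld.ntcp_probit(geuds, params)
        outcomes = np.zeros(50, int)
        for b in range(5):
            sel = slice(10 * b, 10 * (b + 1))
            k = int(round(probs[sel].sum()))
            outcomes[10 * b:10 * b + k] = 1
        cohort = _toy_cohort(geuds, outcomes)
        out = chisq_gof(cohort, params)
        # bins differ from round() by at most the rounding residual
        assert out["chi2"] < 0.6
        assert out["p"] > 0.7

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        geuds = rng.uniform(2, 12, 60)
        y = rng.integers(0, 2, 60)
        cohort = _toy_cohort(geuds, y)
        perm = rng.permutation(60)
        shuffled = cohort.resample(perm)
        params = ld.LKBParams(7.0, 0.4, 2.0)
        assert chisq_gof(cohort, params)["chi2"] == pytest.approx(
            chisq_gof(shuffled, params)["chi2"], abs=1e-9)

    def test_too_small_cohort_rejected(self):
        cohort = _toy_cohort([2, 3, 4, 5], [1, 0, 1, 0])
        with pytest.raises(ValidationError):
            chisq_gof(cohort, ld.LKBParams(5, 0.4, 2))


class TestCalibration:
    def test_self_consistent_probabilities(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, 2000)
        y = (rng.random(2000) < p).astype(int)
        rep = ld.calibration_report(p, y)
        assert rep.slope == pytest.approx(1.0, abs=0.15)
        assert rep.intercept == pytest.approx(0.0, abs=0.15)
        assert rep.prevalence == pytest.approx(y.mean())
        assert int(rep.bins["n"].sum()) == 2000

    def test_logit_shift_recovered_in_intercept(self):
        rng = np.random.default_rng(9)
        true_p = rng.uniform(0.1, 0.9, 3000)
        y = (rng.random(3000) < true_p).astype(int)
        c = 0.8
        shifted = 1 / (1 + np.exp(-(np.log(true_p / (1 - true_p)) + c)))
        rep = ld.calibration_report(shifted, y)
        assert rep.slope == pytest.approx(1.0, abs=0.15)
        assert rep.intercept == pytest.approx(-c, abs=0.2)

    def test_wilson_bins_and_invariants(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 300)
        y = (rng.random(300) < p).astype(int)
        rep = ld.calibration_report(p, y, n_bins=10)
        assert ((rep.bins["wilson_lo"] >= 0) & (rep.bins["wilson_hi"] <= 1)).all()
        assert 0 <= rep.brier <= 1 and 0 <= rep.auc <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ld.calibration_report([0.2, 0.4], [0, 0])


class TestExternalValidation:
    def test_identity_transfer_reproduces_apparent_metrics(self, photon_cohort,
                                                           photon_fit):
        rep = ld.external_validate(photon_fit, photon_cohort)
        probs = ld.predict_ntcp(photon_fit.params, photon_cohort)
        assert rep.auc == pytest.approx(ld.roc_auc(probs, photon_cohort.outcomes))
        assert rep.brier == pytest.approx(ld.brier_score(probs, photon_cohort.outcomes))
        assert rep.prevalence == pytest.approx(photon_cohort.outcomes.mean())

    def test_shifted_target_detected_as_miscalibrated(self):
        import dataclasses
        rng_truth = ld.PHOTON_TRUTH.lkb
        shifted = dataclasses.replace(
            ld.PHOTON_TRUTH, lkb=ld.LKBParams(rng_truth.d50 * 1.6, rng_truth.m,
                                              rng_truth.a))
        target = ld.cohort_outcomes(
            ld.generate_cohort(500, ld.PHOTON_PROFILE, shifted, seed=31))
        frozen = ld.FitResult(params=rng_truth, nll=0.0, converged=True,
                              n_restarts_used=0, seed=0)
        rep = ld.external_validate(frozen, target)
        assert abs(rep.slope - 1) > 0.2 or abs(rep.intercept) > 0.2
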