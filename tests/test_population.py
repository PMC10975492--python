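"""Virtual trials, post hoc individualization, fold-difference statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from mfpbpk.drug import BUPRENORPHINE, TABLET
from mfpbpk.population import (
    Dyad,
    ObservationRecord,
    PosthocFit,
    TrialConfig,
    fold_difference_stats,
    po_ratio,
    posthoc_optimize_absorption,
    predict_dyad_concentrations,
    run_virtual_trial,
    sample_dyads,
    simulate_dyad,
)
from mfpbpk.simulator import PKMetrics, Regimen


@pytest.fixture(scope="module")
def template():
    return Dyad(
        dyad_id="t",
        maternal_age=30.0,
        ga_weeks=33.0,
        regimen=Regimen(dose_mg=8.0, interval_h=12.0, n_doses=16),
    )


class TestDyadSampling:
    def test_zero_cv_gives_unit_multipliers(self, template, tablet):
        import dataclasses

        absorption = dataclasses.replace(tablet, dose_cv=0.0)
        cohort = sample_dyads(TrialConfig(seed=1), template, absorption)
        assert all(d.dose_multiplier == 1.0 for d in cohort)
        assert len(cohort) == 100

    def test_sample_cv_matches_lognormal_moments(self, template, tablet):
        # sigma^2 = ln(1 + CV^2): at n = 10^4 the sample CV should land
        # within 2 percentage points of the nominal 33.9%
        cfg = TrialConfig(n_subjects_per_trial=100, n_trials=100, seed=3)
        cohort = sample_dyads(cfg, template, tablet)
        mults = np.array([d.dose_multiplier for d in cohort])
        assert abs(mults.std(ddof=1) / mults.mean() - 0.339) < 0.02
        assert mults.mean() == pytest.approx(1.0, abs=0.02)

    def test_same_seed_reproduces_cohort(self, template, tablet):
        a = sample_dyads(TrialConfig(seed=11), template, tablet)
        b = sample_dyads(TrialConfig(seed=11), template, tablet)
        assert a == b

    def test_age_range_enforced(self, template, tablet):
        import dataclasses

        young = dataclasses.replace(template, maternal_age=16.0)
        with pytest.raises(ValueError):
            sample_dyads(TrialConfig(), young, tablet)


@pytest.fixture(scope="module")
def small_trial(template, tablet, physiology):
    cfg = TrialConfig(n_subjects_per_trial=5, n_trials=2, duration_h=192.0, seed=5)
    cohort = sample_dyads(cfg, template, tablet)
    summary = run_virtual_trial(
        cohort, BUPRENORPHINE, tablet, physiology,
        duration_h=192.0, grid_step_h=0.5,
    )
    return cohort, summary


class TestVirtualTrial:

    def test_percentiles_bracket_geomean(self, small_trial):
        _, summary = small_trial
        late = summary.times > 1.0  # after absorption onset, all conc > 0
        assert np.all(summary.maternal_p5[late] <= summary.maternal_geomean[late] + 1e-12)
        assert np.all(summary.maternal_geomean[late] <= summary.maternal_p95[late] + 1e-12)
        assert np.all(summary.fetal_p5[late] <= summary.fetal_p95[late] + 1e-12)

    def test_band_brackets_most_trajectories(self, template, tablet, physiology):
        # at n = 100 the pooled 5th-95th band covers ~90% of individual
        # values at each time point
        cfg = TrialConfig(n_subjects_per_trial=10, n_trials=10,
                          duration_h=96.0, seed=17)
        cohort = sample_dyads(cfg, template, tablet)
        summary = run_virtual_trial(
            cohort, BUPRENORPHINE, tablet, physiology,
            duration_h=96.0, grid_step_h=1.0,
        )
        profiles = np.vstack([
            simulate_dyad(d, BUPRENORPHINE, tablet, physiology,
                          duration_h=96.0, grid_step_h=1.0).profile.maternal_plasma
            for d in cohort
        ])
        inside = (profiles >= summary.maternal_p5 - 1e-12) & (
            profiles <= summary.maternal_p95 + 1e-12
        )
        assert inside.mean() >= 0.9

    def test_identical_dyads_collapse_band(self, template, tablet, physiology):
        import dataclasses

        cohort = [
            dataclasses.replace(template, dyad_id=f"c{i}") for i in range(4)
        ]
        summary = run_virtual_trial(
            cohort, BUPRENORPHINE, tablet, physiology,
            duration_h=48.0, grid_step_h=0.5,
        )
        np.testing.assert_allclose(summary.maternal_p5, summary.maternal_geomean, rtol=1e-9)
        np.testing.assert_allclose(summary.maternal_p95, summary.maternal_geomean, rtol=1e-9)

    def test_determinism_bit_identical(self, template, tablet, physiology):
        def run():
            cfg = TrialConfig(n_subjects_per_trial=3, n_trials=2,
                              duration_h=48.0, seed=9)
            cohort = sample_dyads(cfg, template, tablet)
            return run_virtual_trial(cohort, BUPRENORPHINE, tablet, physiology,
                                     duration_h=48.0, grid_step_h=0.5)

        a, b = run(), run()
        assert np.array_equal(a.maternal_geomean, b.maternal_geomean)
        assert np.array_equal(a.fetal_p95, b.fetal_p95)
        assert a.pk_geomean == b.pk_geomean

    def test_two_point_geomean(self):
        from mfpbpk.population import _geomean_cols

        assert _geomean_cols(np.array([[1.0], [100.0]]))[0] == pytest.approx(10.0)


@pytest.fixture(scope="module")
def delivery_dyad():
    return Dyad(
        dyad_id="d",
        maternal_age=28.0,
        ga_weeks=39.0,
        regimen=Regimen(dose_mg=12.0, interval_h=24.0, n_doses=14),
    )


class TestPosthoc:

    def test_noise_free_recovery(self, delivery_dyad, tablet, physiology):
        # simulator-generated observation with a known fraction must be
        # recovered within the search tolerance
        true_f = 0.30
        import dataclasses

        truth_dyad = dataclasses.replace(
            delivery_dyad, absorbed_fraction_override=true_f
        )
        t_obs = 24.0 * 13 + 6.0
        res = simulate_dyad(
            truth_dyad, BUPRENORPHINE, tablet, physiology,
            duration_h=t_obs, grid_step_h=None, extra_times=[t_obs],
        )
        record = ObservationRecord(
            dyad_id="d", time_since_last_dose_h=6.0,
            maternal_conc=float(res.profile.maternal_plasma[-1]),
        )
        fit = posthoc_optimize_absorption(
            delivery_dyad, record, BUPRENORPHINE, tablet, physiology
        )
        assert fit.converged and not fit.hit_bound
        assert fit.absorbed_fraction_hat == pytest.approx(true_f, abs=0.005)

    def test_unattainable_observation_hits_upper_bound(
        self, delivery_dyad, tablet, physiology
    ):
        record = ObservationRecord(
            dyad_id="d", time_since_last_dose_h=6.0, maternal_conc=1e6
        )
        fit = posthoc_optimize_absorption(
            delivery_dyad, record, BUPRENORPHINE, tablet, physiology
        )
        assert fit.hit_bound
        assert fit.absorbed_fraction_hat == 0.999

    def test_two_noisy_observations_recover_truth(
        self, delivery_dyad, tablet, physiology
    ):
        # two observations from the same dyad with 10% noise: each estimate
        # matches the affine-propagation oracle (the predicted concentration
        # is affine in the fraction, so the noise maps linearly onto the
        # estimate) and stays close to the truth
        import dataclasses

        true_f = 0.45
        truth_dyad = dataclasses.replace(
            delivery_dyad, absorbed_fraction_override=true_f
        )
        rng = np.random.default_rng(42)
        sigma = math.sqrt(math.log1p(0.10 ** 2))
        for t_since in (4.0, 18.0):
            t_obs = 24.0 * 13 + t_since
            res = simulate_dyad(
                truth_dyad, BUPRENORPHINE, tablet, physiology,
                duration_h=t_obs, grid_step_h=None, extra_times=[t_obs],
            )
            noisy = float(res.profile.maternal_plasma[-1]) * math.exp(
                rng.standard_normal() * sigma - 0.5 * sigma**2
            )
            record = ObservationRecord(
                dyad_id="d", time_since_last_dose_h=t_since, maternal_conc=noisy
            )
            fit = posthoc_optimize_absorption(
                delivery_dyad, record, BUPRENORPHINE, tablet, physiology
            )
            m0, _ = predict_dyad_concentrations(
                delivery_dyad, record, 0.0, BUPRENORPHINE, tablet, physiology
            )
            m1, _ = predict_dyad_concentrations(
                delivery_dyad, record, 1.0, BUPRENORPHINE, tablet, physiology
            )
            oracle = (noisy - m0) / (m1 - m0)
            assert fit.absorbed_fraction_hat == pytest.approx(oracle, abs=1e-3)
            # 10% noise maps to ~|e^eps - 1| * (f + oral share) in the
            # estimate: within 0.07 for these realized draws
            assert abs(fit.absorbed_fraction_hat - true_f) < 0.07

    def test_nonpositive_observation_rejected(self, delivery_dyad, tablet):
        record = ObservationRecord(
            dyad_id="d", time_since_last_dose_h=6.0, maternal_conc=0.0
        )
        with pytest.raises(ValueError):
            posthoc_optimize_absorption(delivery_dyad, record, BUPRENORPHINE, tablet)

    def test_fetal_prediction_scales_with_fraction(
        self, delivery_dyad, tablet, physiology
    ):
        record = ObservationRecord(
            dyad_id="d", time_since_last_dose_h=6.0, maternal_conc=1.0
        )
        _, f_low = predict_dyad_concentrations(
            delivery_dyad, record, 0.2, BUPRENORPHINE, tablet, physiology
        )
        _, f_high = predict_dyad_concentrations(
            delivery_dyad, record, 0.6, BUPRENORPHINE, tablet, physiology
        )
        assert f_high > f_low > 0


class TestFoldDifferenceStats:
    def test_identity_pairs(self):
        stats_ = fold_difference_stats([(2.0, 2.0), (3.0, 3.0), (4.0, 4.0)])
        assert stats_.geometric_mean_ratio == pytest.approx(1.0)
        assert stats_.prop_within_2fold == 1.0
        assert stats_.prop_within_1p25fold == 1.0

    def test_constant_twofold_ratio_inclusive_boundary(self):
        stats_ = fold_difference_stats([(2.0, 1.0)] * 3)
        assert stats_.geometric_mean_ratio == pytest.approx(2.0)
        assert stats_.prop_within_2fold == 1.0  # boundary counts as inside
        assert stats_.prop_within_1p25fold == 0.0

    def test_swap_gives_reciprocal_gmr(self):
        rng = np.random.default_rng(0)
        pred = rng.lognormal(0.0, 0.4, 12)
        obs = rng.lognormal(0.0, 0.4, 12)
        fwd = fold_difference_stats(list(zip(pred, obs)))
        rev = fold_difference_stats(list(zip(obs, pred)))
        assert fwd.geometric_mean_ratio * rev.geometric_mean_ratio == pytest.approx(
            1.0, rel=1e-12
        )
        assert fwd.ci95_low == pytest.approx(1.0 / rev.ci95_high, rel=1e-12)

    def test_t_interval_matches_bootstrap_oracle(self):
        # 21 synthetic pairs, log-ratios ~ N(log 1.15, 0.3^2): the analytic
        # GMR must sit inside a 10^4-resample bootstrap CI of the mean
        rng = np.random.default_rng(123)
        logs = rng.normal(math.log(1.15), 0.3, 21)
        pairs = [(math.exp(l), 1.0) for l in logs]
        stats_ = fold_difference_stats(pairs)
        boots = np.exp(
            np.mean(rng.choice(logs, size=(10_000, 21), replace=True), axis=1)
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo < stats_.geometric_mean_ratio < hi
        # and the t-based CI agrees with the bootstrap CI to ~a few percent
        assert stats_.ci95_low == pytest.approx(lo, rel=0.05)
        assert stats_.ci95_high == pytest.approx(hi, rel=0.05)

    def test_ci_brackets_gmr_and_shapiro_on_log_scale(self):
        rng = np.random.default_rng(7)
        pairs = [(x, 1.0) for x in rng.lognormal(0.1, 0.25, 15)]
        s = fold_difference_stats(pairs)
        assert s.ci95_low <= s.geometric_mean_ratio <= s.ci95_high
        logs = np.log([p / o for p, o in pairs])
        assert s.shapiro_p == pytest.approx(stats.shapiro(logs).pvalue)

    def test_nonpositive_pairs_rejected(self):
        with pytest.raises(ValueError):
            fold_difference_stats([(1.0, 0.0), (1.0, 1.0), (1.0, 1.0)])


class TestPORatio:
    def _metrics(self, auc=10.0, clf=100.0, cmax=3.0, tmax=2.0):
        return PKMetrics(auc=auc, cl_over_f=clf, cmax=cmax, tmax=tmax)

    def test_identical_metrics(self):
        ratios = po_ratio(self._metrics(), self._metrics())
        assert all(r.ratio == 1.0 and r.within_1p25fold for r in ratios)

    def test_tmax_outside_error_range(self):
        # predicted Tmax 2.0 vs observed 2.74 -> ratio 0.73, outside 1.25-fold
        ratios = po_ratio(self._metrics(tmax=2.0), self._metrics(tmax=2.74))
        tmax = next(r for r in ratios if r.metric == "tmax")
        assert tmax.ratio == pytest.approx(0.73, abs=0.005)
        assert not tmax.within_1p25fold

    def test_boundary_ratio_inclusive(self):
        ratios = po_ratio(self._metrics(auc=12.5), self._metrics(auc=10.0))
        auc = next(r for r in ratios if r.metric == "auc")
        assert auc.ratio == pytest.approx(1.25)
        assert auc.within_1p25fold

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            po_ratio(self._metrics(), self._metrics(tmax=0.0))
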