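"""Statistical chain: normalization, percent change, detrend, smoothing, CI,
tSNR, detectability, response characterization, Fourier localizer."""

import numpy as np
import pytest
from scipy import stats

from dianasim.acquisition import diana_schedule, run_duration_s, simulate_acquisition, spgre_schedule
from dianasim.analysis import (
    boxcar_attenuation,
    ci_across_runs,
    detrend_linear,
    estimate_response,
    fourier_localizer,
    gaussian_kernel,
    group_average,
    localizer_threshold,
    min_detectable_pct,
    normalize_trials,
    percent_change,
    percent_change_pipeline,
    roi_aggregate,
    roi_timecourse_tsnr,
    roi_tsnr,
    smooth_gaussian,
    tsnr,
)
from dianasim.phantom import DriftModel, ResponseModel
from dianasim.recon import reconstruct


class TestPercentChange:
    def test_constant_series_is_zero(self):
        assert np.all(percent_change(np.full((10, 3), 7.0)) == 0)

    def test_elevated_boxcar_closed_form(self):
        # b*(1+5e-4) on 30 of 140 points: baseline includes the elevation,
        # so the net plateau is 100*5e-4*(1 - 30/140)/(1 + 5e-4*30/140)
        s = np.full(140, 2.5)
        s[15:45] *= 1.0005
        pct = percent_change(s)
        eps = 5e-4
        expected = 100 * eps * (1 - 30 / 140) / (1 + eps * 30 / 140)
        assert pct[20] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0393, abs=2e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        s = 1.0 + 0.01 * rng.standard_normal((50, 4))
        np.testing.assert_allclose(percent_change(s), percent_change(3.7 * s))

    def test_zero_baseline_maps_to_zero(self):
        s = np.zeros((10, 2))
        assert np.all(percent_change(s) == 0)


class TestDetrend:
    def test_ramp_becomes_constant(self):
        ramp = np.arange(50.0)
        out = detrend_linear(ramp)
        np.testing.assert_allclose(out, ramp.mean(), atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal((80, 5)) + np.linspace(0, 3, 80)[:, None]
        once = detrend_linear(s)
        np.testing.assert_allclose(detrend_linear(once), once, atol=1e-10)

    def test_line_plus_boxcar_matches_projection_oracle(self):
        # independent oracle: explicit least-squares fit with numpy.polyfit
        t = np.arange(140.0)
        box = np.zeros(140)
        box[15:45] = 0.05
        s = 2.0 + 0.01 * t + box
        out = detrend_linear(s)
        coef = np.polyfit(t, s, 1)
        oracle = s - np.polyval(coef, t) + s.mean()
        np.testing.assert_allclose(out, oracle, atol=1e-10)


class TestSmoothing:
    def test_kernel_sums_to_one(self):
        assert gaussian_kernel(3, 0.6).sum() == pytest.approx(1.0)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_gaussian(np.full(30, 2.2)), 2.2)

    def test_impulse_response_is_kernel(self):
        x = np.zeros(31)
        x[15] = 1.0
        out = smooth_gaussian(x)
        w = gaussian_kernel(3, 0.6)
        np.testing.assert_allclose(out[14:17], w)
        assert np.all(out[:14] == 0) and np.all(out[17:] == 0)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200_000)
        w = gaussian_kernel(3, 0.6)
        ratio = smooth_gaussian(x).var() / x.var()
        assert ratio == pytest.approx(np.sum(w**2), rel=0.02)


class TestConfidenceIntervals:
    def test_identical_runs_zero_width(self):
        runs = np.tile(np.linspace(0, 1, 20), (5, 1))
        resp = ci_across_runs(runs)
        np.testing.assert_allclose(resp.ci_half, 0.0, atol=1e-12)
        np.testing.assert_allclose(resp.mean, runs[0])

    def test_null_pointwise_calibration(self):
        # ~5% of time points should exclude zero across many null draws
        rng = np.random.default_rng(3)
        excl = []
        for _ in range(400):
            runs = rng.standard_normal((12, 40))
            resp = ci_across_runs(runs)
            excl.append((np.abs(resp.mean) > resp.ci_half).mean())
        assert np.mean(excl) == pytest.approx(0.05, abs=0.01)

    def test_pooling_shrinks_ci_sqrt_k(self):
        rng = np.random.default_rng(4)
        runs = rng.standard_normal((30, 25))
        one = ci_across_runs(runs)
        k = 4
        pooled = group_average([runs] * k)
        # pooling k copies multiplies n by k without changing the spread,
        # shrinking the half-width by ~sqrt(k) (up to t-quantile/ddof terms)
        ratio = one.ci_half.mean() / pooled.ci_half.mean()
        assert ratio == pytest.approx(np.sqrt(k), rel=0.06)

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            ci_across_runs(np.ones((1, 10)))


class TestTSNR:
    def test_definition(self):
        rng = np.random.default_rng(5)
        series = 1000.0 + rng.standard_normal((4000, 6, 6))
        m = tsnr(series)
        assert np.nanmean(m.map) == pytest.approx(1000.0, rel=0.05)

    def test_constant_voxel_flagged_not_infinite(self):
        series = np.ones((20, 3, 3))
        m = tsnr(series)
        assert not m.valid.any()
        assert np.isnan(m.map).all()

    def test_roi_scaling_sqrt_v(self):
        # ROI-average time course gains sqrt(V) in tSNR for i.i.d. noise
        rng = np.random.default_rng(6)
        v = 25
        series = 1000.0 + rng.standard_normal((3000, v))
        mask = np.ones(v, dtype=bool)
        voxel = tsnr(series).summary(mask)["mean_voxel_tsnr"]
        course = roi_timecourse_tsnr(series, mask)
        assert course / voxel == pytest.approx(np.sqrt(v), rel=0.10)

    def test_expected_roi_tsnr_field(self):
        rng = np.random.default_rng(7)
        series = 500.0 + rng.standard_normal((1000, 4, 4))
        s = roi_tsnr(tsnr(series), np.ones((4, 4), bool))
        assert s["expected_roi_tsnr"] == pytest.approx(
            s["mean_voxel_tsnr"] * 4.0, rel=1e-12
        )


class TestMinDetectable:
    def test_limits_and_scaling(self):
        base = min_detectable_pct(1000, 25, 30)
        assert min_detectable_pct(1e9, 25, 30) < 1e-6
        assert min_detectable_pct(1000, 25, 120) == pytest.approx(base / 2)

    def test_matches_monte_carlo_power_oracle(self):
        # bisect the amplitude giving 80% power in a simulated t-test
        ana = min_detectable_pct(1000, 25, 30)
        rng = np.random.default_rng(8)
        sroi = 100.0 / (1000 * np.sqrt(25))
        crit = stats.t.ppf(0.975, 29)

        def power(amp):
            x = rng.normal(amp, sroi, size=(30, 3000))
            tt = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(30))
            return (np.abs(tt) > crit).mean()

        lo, hi = ana * 0.4, ana * 2.5
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if power(mid) < 0.8 else (lo, mid)
        assert ana == pytest.approx(0.5 * (lo + hi), rel=0.15)

    def test_validation(self):
        with pytest.raises(ValueError):
            min_detectable_pct(0, 25, 30)


class TestNormalizeTrials:
    def test_driftfree_data_essentially_unchanged(self, brain32, seq):
        resp = ResponseModel(onset_ms=75, duration_ms=150, amplitude_pct=0.05)
        runs = [
            simulate_acquisition(
                brain32, seq, diana_schedule(32, 140, start_time_s=r * 22.4),
                response=resp,
            )
            for r in range(2)
        ]
        norm = normalize_trials(runs)
        for raw, nk in zip(runs, norm):
            a = percent_change_pipeline(reconstruct(raw), brain32.rois["target_v1"])
            b = percent_change_pipeline(reconstruct(nk), brain32.rois["target_v1"])
            assert np.abs(a - b).max() < 1e-6

    def test_two_run_drift_step_removed(self, tubes32, seq):
        drift = DriftModel(rate_pct_per_min=1.0)
        rd = run_duration_s(32, 40, 5.0)
        runs = [
            simulate_acquisition(
                tubes32, seq, diana_schedule(32, 40, start_time_s=r * rd), drift=drift
            )
            for r in range(2)
        ]
        raw_means = [np.abs(reconstruct(k).data).mean() for k in runs]
        step_pct = (raw_means[1] - raw_means[0]) / raw_means[0] * 100
        assert step_pct == pytest.approx(1.0 / 60 * rd, rel=0.01)
        norm = normalize_trials(runs)
        norm_means = [np.abs(reconstruct(k).data).mean() for k in norm]
        assert abs(norm_means[1] - norm_means[0]) / norm_means[0] * 100 < 1e-3

    def test_zero_energy_line_rejected(self, tubes32, seq):
        ks = simulate_acquisition(tubes32, seq, diana_schedule(32, 4))
        ks.data[:, 5, :] = 0
        with pytest.raises(ValueError, match="zero-energy"):
            normalize_trials(ks)

    def test_spgre_mode_rejected(self, tubes32, seq):
        ks = simulate_acquisition(tubes32, seq, spgre_schedule(32, 4))
        with pytest.raises(ValueError, match="loop-swapped"):
            normalize_trials(ks)


class TestPipelineOrder:
    def test_pipeline_is_the_declared_composition(self, brain32, seq):
        resp = ResponseModel(onset_ms=75, duration_ms=150, amplitude_pct=0.5)
        ks = simulate_acquisition(
            brain32, seq, diana_schedule(32, 140), response=resp
        )
        img = reconstruct(ks).data
        mask = brain32.rois["target_v1"]
        canonical = roi_aggregate(
            smooth_gaussian(detrend_linear(percent_change(img))), mask
        )
        np.testing.assert_array_equal(canonical, percent_change_pipeline(img, mask))

    def test_roi_averaging_last_matters(self, brain32, seq):
        # voxelwise percent change before ROI averaging weights every voxel
        # equally in relative units; averaging raw signal first weights by
        # absolute baseline, which differs across mixed tissue — the order
        # is therefore observable, guarding against silent reordering
        resp = ResponseModel(onset_ms=75, duration_ms=150, amplitude_pct=0.5)
        ks = simulate_acquisition(
            brain32, seq, diana_schedule(32, 140), response=resp
        )
        img = reconstruct(ks).data
        mask = brain32.rois["target_v1"] | brain32.rois["control_wm"]
        canonical = percent_change_pipeline(img, mask)
        aggregated_first = smooth_gaussian(
            detrend_linear(percent_change(roi_aggregate(img, mask)))
        )
        assert not np.allclose(canonical, aggregated_first)


class TestEstimateResponse:
    def _noise_free_response(self, brain32, seq, amp=0.05):
        resp = ResponseModel(onset_ms=75, duration_ms=150, amplitude_pct=amp)
        ks = simulate_acquisition(brain32, seq, diana_schedule(32, 140), response=resp)
        course = percent_change_pipeline(reconstruct(ks), brain32.rois["target_v1"])
        return ci_across_runs(np.stack([course, course]), tr_ms=5.0)

    def test_noise_free_recovery(self, brain32, seq):
        est = estimate_response(self._noise_free_response(brain32, seq))
        assert est.significant
        # onset recovered up to smoothing bias (one sample)
        assert est.onset_ms == pytest.approx(75.0, abs=5.0)
        assert est.amplitude_pct == pytest.approx(0.05, rel=0.10)

    def test_amplitude_linear_in_injection(self, brain32, seq):
        e1 = estimate_response(self._noise_free_response(brain32, seq, 0.05))
        e2 = estimate_response(self._noise_free_response(brain32, seq, 0.10))
        assert e2.amplitude_pct == pytest.approx(2 * e1.amplitude_pct, rel=0.02)

    def test_boxcar_attenuation_bounds(self):
        att = boxcar_attenuation(140, 15, 30)
        assert 0.5 < att < 0.8

    def test_null_specific(self):
        rng = np.random.default_rng(10)
        n_sig = 0
        for _ in range(20):
            runs = rng.standard_normal((30, 140)) * 0.01
            runs = smooth_gaussian(runs, axis=1)
            est = estimate_response(ci_across_runs(runs, tr_ms=5.0))
            n_sig += est.significant
        assert n_sig <= 2  # >= 90% of null seeds stay non-significant


class TestFourierLocalizer:
    def test_constant_series_scores_zero(self):
        assert np.all(fourier_localizer(np.ones((360, 3))) == 0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="cycles"):
            fourier_localizer(np.ones((20, 2)), period_s=12.0)

    def test_fundamental_sinusoid_detected(self):
        rng = np.random.default_rng(11)
        t = np.arange(360.0)
        series = np.sin(2 * np.pi * t / 12.0)[:, None] + 0.5 * rng.standard_normal(
            (360, 32)
        )
        thr = localizer_threshold(360, seed=12)
        assert np.all(fourier_localizer(series) > thr)

    def test_white_noise_calibration(self):
        thr = localizer_threshold(360, alpha=0.05, n_sim=2000, seed=13)
        rng = np.random.default_rng(14)
        stats_null = fourier_localizer(rng.standard_normal((360, 3000)))
        frac_below = (stats_null <= thr).mean()
        assert frac_below == pytest.approx(0.95, abs=0.02)
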