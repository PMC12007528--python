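"""Acquisition schedules, protocol timing arithmetic and k-space sampling."""

import numpy as np
import pytest

from dianasim.acquisition import (
    PARADIGM_PRESETS,
    diana_schedule,
    get_paradigm,
    run_duration_s,
    scan_duration_s,
    simulate_acquisition,
    spgre_discard_count,
    spgre_schedule,
    trial_timepoints,
)
from dianasim.phantom import DriftModel, ResponseModel


class TestTiming:
    @pytest.mark.parametrize(
        "stim,isi,tr,m", [(100, 600, 5, 140), (50, 550, 5, 120), (5, 0, 5, 1)]
    )
    def test_trial_timepoints(self, stim, isi, tr, m):
        assert trial_timepoints(stim, isi, tr) == m

    def test_trial_timepoints_requires_divisibility(self):
        with pytest.raises(ValueError):
            trial_timepoints(101, 600, 5)

    @pytest.mark.parametrize(
        "n,m,tr,dur", [(96, 140, 5, 67.2), (1, 1, 5, 0.005), (96, 120, 5, 57.6)]
    )
    def test_run_duration(self, n, m, tr, dur):
        assert run_duration_s(n, m, tr) == pytest.approx(dur)

    def test_scan_duration_protocol(self):
        # 2000 dummies + 11 runs of 96x140x5 ms = 749.2 s (~12.5 min)
        assert scan_duration_s(11, 2000, 96, 140, 5) == pytest.approx(749.2)
        assert scan_duration_s(0, 2000, 96, 140, 5) == pytest.approx(10.0)
        assert scan_duration_s(1, 0, 96, 140, 5) == pytest.approx(
            run_duration_s(96, 140, 5)
        )

    @pytest.mark.parametrize("trs,n,count", [(2000, 96, 21), (96, 96, 1), (97, 96, 2)])
    def test_spgre_discard_count(self, trs, n, count):
        assert spgre_discard_count(trs, n) == count


class TestParadigmPresets:
    def test_table_values(self):
        rows = {
            "paradigm_I": (50, 550, 11, 3, 96, "2x2x5mm", 120),
            "paradigm_II": (200, 500, 10, 3, 96, "2x2x5mm", 140),
            "paradigm_III": (100, 600, 11, 3, 96, "2x2x5mm", 140),
            "paradigm_IV": (100, 600, 11, 4, 96, "2x2x5mm", 140),
            "paradigm_V": (100, 600, 11, 4, 192, "1x1x5mm", 140),
        }
        assert set(PARADIGM_PRESETS) == set(rows)
        for name, (stim, isi, runs, scans, n, res, m) in rows.items():
            p = get_paradigm(name)
            assert (p.stim_ms, p.isi_ms) == (stim, isi)
            assert (p.n_runs_per_scan, p.n_scans) == (runs, scans)
            assert (p.matrix_n, p.resolution) == (n, res)
            assert p.trial_timepoints_m == m

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="paradigm"):
            get_paradigm("paradigm_X")


class TestSchedules:
    def test_diana_event_count(self):
        assert diana_schedule(96, 140).n_events == 13440
        assert diana_schedule(1, 1).n_events == 1

    def test_diana_center_line_within_one_trial(self):
        sched = diana_schedule(16, 10)
        centre_trials = sched.trial_index[sched.phase_line == 8]
        assert len(set(centre_trials)) == 1

    def test_diana_center_revisit_interval_is_run_duration(self):
        n, m, tr = 16, 10, 5.0
        runs = [
            diana_schedule(n, m, tr_ms=tr, start_time_s=r * run_duration_s(n, m, tr))
            for r in range(3)
        ]
        firsts = [s.center_line_times()[0] for s in runs]
        np.testing.assert_allclose(np.diff(firsts), run_duration_s(n, m, tr))

    def test_spgre_center_interval_n_tr(self):
        sched = spgre_schedule(16, 8, tr_ms=5.0)
        times = sched.center_line_times()
        np.testing.assert_allclose(np.diff(times), 16 * 5.0 / 1000.0)

    def test_spgre_single_line_always_center(self):
        sched = spgre_schedule(1, 5)
        assert np.all(sched.phase_line == 0)
        assert sched.center_line_times().size == sched.n_events

    def test_spgre_phantom_protocol_split(self):
        # 1024 sequential images collected in 2 runs -> 512 images per run
        n_total, n_runs = 1024, 2
        per_run = n_total // n_runs
        assert per_run == 512
        sched = spgre_schedule(96, per_run)
        assert sched.n_events == 96 * 512

    def test_times_increase_by_tr(self):
        for sched in (diana_schedule(8, 6, n_dummy=10), spgre_schedule(8, 6)):
            np.testing.assert_allclose(
                np.diff(sched.absolute_time_s), sched.tr_ms / 1000.0
            )

    def test_no_duplicate_line_timepoint_pairs(self):
        for sched in (diana_schedule(12, 7), spgre_schedule(12, 7)):
            pairs = set(zip(sched.phase_line.tolist(), sched.time_point.tolist()))
            assert len(pairs) == sched.n_events

    def test_dummy_offset_shifts_first_event(self):
        sched = diana_schedule(8, 6, n_dummy=100, tr_ms=5.0)
        assert sched.absolute_time_s[0] == pytest.approx(0.5)

    def test_centric_order_starts_at_center(self):
        sched = diana_schedule(8, 2, line_order="centric")
        assert sched.phase_line[0] == 4
        assert sorted(set(sched.phase_line.tolist())) == list(range(8))


class TestSimulateAcquisition:
    def test_static_phantom_all_timepoints_identical(self, tubes32, seq):
        ks = simulate_acquisition(tubes32, seq, diana_schedule(32, 6))
        for t in range(1, 6):
            np.testing.assert_array_equal(ks.data[t], ks.data[0])

    def test_drift_constant_within_trial_scaled_across_trials(self, tubes32, seq):
        drift = DriftModel(rate_pct_per_min=6.0)
        sched = diana_schedule(32, 6, tr_ms=5.0)
        ks = simulate_acquisition(tubes32, seq, sched, drift=drift)
        ks0 = simulate_acquisition(tubes32, seq, sched)
        mag = np.abs(ks.data)
        mag0 = np.abs(ks0.data)
        nz = mag0 > 1e-9
        # within one trial (line) the drift factor varies by < 6%/min * M*TR
        for line in (0, 16, 31):
            ratios = mag[:, line, :][nz[:, line, :]] / mag0[:, line, :][nz[:, line, :]]
            assert np.ptp(ratios) < 6.0 / 100 / 60 * 6 * 0.005 * 1.01
        # across trials the line scale follows the drift factor at the trial time
        trial_mid = np.array(
            [sched.absolute_time_s[sched.trial_index == k].mean() for k in range(32)]
        )
        measured = np.array(
            [
                (mag[:, k, :][nz[:, k, :]] / mag0[:, k, :][nz[:, k, :]]).mean()
                for k in range(32)
            ]
        )
        np.testing.assert_allclose(measured, drift.factor(trial_mid), rtol=1e-6)

    def test_response_locality_in_time(self, brain32, seq):
        resp = ResponseModel(onset_ms=75.0, duration_ms=150.0, amplitude_pct=0.5)
        ks = simulate_acquisition(brain32, seq, diana_schedule(32, 140), response=resp)
        ks0 = simulate_acquisition(brain32, seq, diana_schedule(32, 140))
        diff = np.abs(ks.data - ks0.data).max(axis=(1, 2))
        active = np.zeros(140, dtype=bool)
        active[15:45] = True  # [75, 225) ms at TR 5 ms
        assert np.all(diff[active] > 0)
        assert np.all(diff[~active] == 0)

    def test_matrix_mismatch_rejected(self, tubes32, seq):
        with pytest.raises(ValueError, match="lines"):
            simulate_acquisition(tubes32, seq, diana_schedule(16, 4))

    def test_fully_sampled_flag(self, tubes32, seq):
        ks = simulate_acquisition(tubes32, seq, diana_schedule(32, 3))
        assert ks.fully_sampled
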