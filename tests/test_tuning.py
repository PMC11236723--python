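"""Spike-triggered tuning, selectivity, nulls, RF mapping, latencies."""

import numpy as np
import pytest

from collikinetics.synth import (
    PlantedEvent,
    PlantedUnitSpec,
    irregular_event_times,
    make_schedule,
    simulate_head_trace,
    simulate_motor_unit,
    simulate_visual_unit,
)
from collikinetics.tuning import (
    EmptyWindowError,
    HeadTrace,
    RecordingRejectedError,
    SpikeTrain,
    classify_motion_tuning,
    classify_visual_tuning,
    compute_sta,
    detect_saccades,
    displacement_vector,
    epsp_latency,
    eye_movement_tuning,
    map_ssrf,
    null_rank,
    pupil_to_degrees,
    selectivity,
    shuffle_null,
    split_by_running,
    sta_displacement_null,
    visual_onset_latency,
)


@pytest.fixture(scope="module")
def planted_yaw_session():
    """Head trace with alternating +/-20 deg yaw movements and a tuned unit."""
    rng = np.random.default_rng(0)
    times = irregular_event_times(rng, 120.0, 58)
    events = [
        PlantedEvent(t=float(t), yaw=20.0 * s)
        for t, s in zip(times, np.resize([1.0, -1.0], 58))
    ]
    head = simulate_head_trace(120.0, seed=2, events=events)
    spec = PlantedUnitSpec(kind="motor", baseline_rate=2.0, gain=15.0, motor_yaw=20.0)
    spikes = simulate_motor_unit(head, events, spec, seed=3)
    return head, events, spikes


class TestComputeSta:
    def test_planted_yaw_ramp_recovered(self, planted_yaw_session):
        head, events, spikes = planted_yaw_session
        sta = compute_sta(spikes, head)
        v = sta.displacement_vectors
        assert v[0] > 5.0                      # yaw displacement dominates
        assert abs(v[1]) < 3.0 and abs(v[2]) < 3.0

    def test_zero_at_spike_bin(self, planted_yaw_session):
        head, _, spikes = planted_yaw_session
        sta = compute_sta(spikes, head)
        assert np.allclose(sta.mean[:, 25], 0.0)
        assert np.allclose(sta.offsets[25], 0.0)

    def test_constant_orientation_gives_zero_curves(self):
        head = simulate_head_trace(60.0, seed=0, ou_sigma=0.0)
        sta = compute_sta(np.arange(5.0, 50.0, 1.0), head)
        assert np.allclose(sta.mean, 0.0)

    def test_no_complete_window_raises(self):
        head = simulate_head_trace(2.0, seed=0)
        with pytest.raises(EmptyWindowError):
            compute_sta(np.array([0.1]), head)

    def test_independent_spikes_average_out(self):
        # white-noise velocity: many spikes drive the STA toward zero
        rng = np.random.default_rng(5)
        head = simulate_head_trace(400.0, seed=1, ou_sigma=8.0, ou_tau=0.5)
        spikes = np.sort(rng.uniform(1.0, 399.0, 8000))
        sta = compute_sta(spikes, head)
        assert np.all(np.abs(sta.displacement_vectors) < 1.5)


class TestDisplacementVector:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            (np.linspace(0, 20, 50), 20.0),
            (np.linspace(0, -20, 50), -20.0),
        ],
    )
    def test_monotone(self, curve, expected):
        assert displacement_vector(curve) == pytest.approx(expected)

    def test_dip_then_peak(self):
        curve = np.zeros(76)
        curve[10] = -5.0
        curve[60] = 15.0
        assert displacement_vector(curve) == pytest.approx(20.0)

    def test_peak_then_dip_is_negative(self):
        curve = np.zeros(76)
        curve[10] = 15.0
        curve[60] = -5.0
        assert displacement_vector(curve) == pytest.approx(-20.0)


class TestShuffleNull:
    def test_preserves_count_and_circular_isis(self):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, 300.0, 200))
        duration = 300.0
        seen = {}

        def stat(s):
            seen["last"] = s
            return float(s.size)

        null = shuffle_null(spikes, duration, stat, n=20, seed=1)
        assert np.all(null.samples == 200)
        s = seen["last"]
        isi = lambda x: np.sort(np.diff(np.concatenate([x, [x[0] + duration]])))
        assert np.allclose(isi(s), isi(spikes), atol=1e-9)

    def test_shift_range_respected(self):
        spikes = np.arange(0.0, 100.0, 1.0)
        null = shuffle_null(spikes, 100.0, lambda s: 0.0, n=50, seed=0)
        assert np.all(null.shifts >= 2.0) and np.all(null.shifts <= 98.0)

    def test_short_trial_raises(self):
        with pytest.raises(ValueError):
            shuffle_null(np.array([0.5]), 3.0, lambda s: 0.0, n=5)

    def test_fft_null_matches_direct_shuffle_statistics(self, planted_yaw_session):
        """The FFT-based displacement null has the same scale as a direct one."""
        head, _, spikes = planted_yaw_session
        fast = sta_displacement_null(spikes, head, 120.0, n=400, seed=9)

        def stat(s):
            return compute_sta(s, head).displacement_vectors

        direct = shuffle_null(spikes, 120.0, stat, n=100, seed=9).samples
        for ax in range(3):
            q_fast = np.percentile(np.abs(fast[:, ax]), 90)
            q_dir = np.percentile(np.abs(direct[:, ax]), 90)
            assert q_fast == pytest.approx(q_dir, rel=0.5)


class TestClassifyMotionTuning:
    def _session(self, tuned_trials, seed0=0):
        rng = np.random.default_rng(seed0)
        stas, nulls = {}, {}
        for i, name in enumerate(("light1", "light2", "dark1", "dark2")):
            times = irregular_event_times(rng, 100.0, 48)
            events = [
                PlantedEvent(t=float(t), yaw=20.0 * s)
                for t, s in zip(times, np.resize([1.0, -1.0], 48))
            ]
            head = simulate_head_trace(100.0, seed=seed0 * 10 + i, events=events)
            spec = PlantedUnitSpec(
                kind="motor",
                baseline_rate=2.0,
                gain=15.0 if name in tuned_trials else 0.0,
                motor_yaw=20.0,
            )
            spikes = simulate_motor_unit(head, events, spec, seed=seed0 * 100 + i)
            stas[name] = compute_sta(spikes, head)
            nulls[name] = sta_displacement_null(spikes, head, 100.0, n=200, seed=i)
        return stas, nulls

    def test_motor_unit_tuned_in_both(self):
        stas, nulls = self._session(("light1", "light2", "dark1", "dark2"))
        assert classify_motion_tuning(stas, nulls) == "both"

    def test_visual_only_unit_is_light_only(self):
        stas, nulls = self._session(("light1", "light2"))
        assert classify_motion_tuning(stas, nulls) == "light"

    def test_untuned_unit_is_none(self):
        stas, nulls = self._session(())
        assert classify_motion_tuning(stas, nulls) == "none"

    def test_missing_trial_raises(self):
        stas, nulls = self._session(())
        del stas["dark2"]
        with pytest.raises(ValueError):
            classify_motion_tuning(stas, nulls)


class TestSelectivity:
    def test_single_direction_response(self):
        angles = np.arange(12) * 30.0
        r = np.zeros(12)
        r[5] = 1.0
        res = selectivity(r, angles, "direction")
        assert res.si == pytest.approx(1.0)
        assert res.preferred_angle == pytest.approx(150.0)

    def test_uniform_responses(self):
        angles = np.arange(12) * 30.0
        res = selectivity(np.ones(12), angles, "direction")
        assert res.si == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_matches_direct_sum(self):
        angles = np.arange(12) * 30.0
        r = np.exp(2.0 * (np.cos(np.deg2rad(angles - 150.0)) - 1.0))
        res = selectivity(r, angles, "direction")
        z = np.sum(r * np.exp(1j * np.deg2rad(angles))) / r.sum()
        assert res.si == pytest.approx(abs(z), abs=1e-12)
        assert res.preferred_angle == pytest.approx(150.0, abs=1.0)

    def test_orientation_space_period(self):
        angles = np.arange(12) * 30.0
        r = np.exp(2.0 * (np.cos(2 * np.deg2rad(angles - 60.0)) - 1.0))
        res = selectivity(r, angles, "orientation")
        assert 0.0 <= res.preferred_angle < 180.0
        assert res.preferred_angle == pytest.approx(60.0, abs=1.0)

    def test_scale_invariance_and_offset_shrinks(self):
        angles = np.arange(12) * 30.0
        r = np.exp(2.0 * (np.cos(np.deg2rad(angles - 90.0)) - 1.0))
        si = selectivity(r, angles).si
        assert selectivity(5.0 * r, angles).si == pytest.approx(si, abs=1e-12)
        assert selectivity(r + 1.0, angles).si < si

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            selectivity(np.zeros(12), np.arange(12) * 30.0)


class TestClassifyVisualTuning:
    angles = np.arange(12) * 30.0

    def _responses(self, kind, seed, pref=150.0):
        sch = make_schedule("gratings", seed)
        spec = PlantedUnitSpec(
            kind=kind, baseline_rate=5.0, gain=3.0, preferred_angle=pref, kappa=2.0
        )
        spikes = simulate_visual_unit(sch, spec, seed=seed + 1)
        from collikinetics.session import _grating_si_null, grating_trial_responses

        resp, angles, base = grating_trial_responses(spikes, sch)
        nulls = _grating_si_null(spikes, sch, base, 200, seed + 2)
        return resp, angles, nulls

    def test_planted_ds_unit(self):
        resp, angles, nulls = self._responses("visual_DS", 10)
        d = classify_visual_tuning(resp, angles, nulls)
        assert d.tuned and d.klass == "DS"
        assert abs(d.direction.preferred_angle - 150.0) < 15.0

    def test_planted_os_unit(self):
        resp, angles, nulls = self._responses("visual_OS", 20, pref=60.0)
        d = classify_visual_tuning(resp, angles, nulls)
        assert d.tuned and d.klass == "OS"

    def test_zero_of_three_criteria_untuned(self):
        rng = np.random.default_rng(0)
        resp = 1.0 + 0.01 * rng.random((3, 12))
        nulls = {"direction": np.ones(100), "orientation": np.ones(100)}
        d = classify_visual_tuning(resp, self.angles, nulls)
        assert not d.tuned and d.klass == "untuned"

    def test_single_trial_raises(self):
        with pytest.raises(ValueError):
            classify_visual_tuning(np.ones((1, 12)), self.angles)


class TestMapSsrf:
    def _unit(self, kind, seed, centre=(7.0, 5.0)):
        sch = make_schedule("squares", seed)
        spec = PlantedUnitSpec(
            kind=kind, baseline_rate=5.0, gain=5.0, rf_centre=centre, rf_sigma=1.5
        )
        spikes = simulate_visual_unit(sch, spec, seed=seed + 1)
        ev = sch.events
        black = ev[ev["colour"] == "black"]
        return map_ssrf(
            spikes,
            sch.duration,
            black["onset"].to_numpy(),
            black["offset"].to_numpy(),
            black["col"].to_numpy(),
            black["row"].to_numpy(),
            baseline_rate=5.0,
            n_shuffles=200,
            seed=seed,
        )

    def test_planted_gaussian_rf_recovered(self):
        rf = self._unit("ssRF", 30)
        assert rf.significant
        assert rf.fit_converged
        assert abs(rf.centre[0] - 7.0) <= 1.0
        assert abs(rf.centre[1] - 5.0) <= 1.0

    def test_zmap_standardized(self):
        rf = self._unit("ssRF", 31)
        assert rf.zmap.mean() == pytest.approx(0.0, abs=1e-9)
        assert rf.zmap.std() == pytest.approx(1.0, abs=1e-9)

    def test_silent_unit_not_significant(self):
        sch = make_schedule("squares", 1)
        ev = sch.events[sch.events["colour"] == "black"]
        rf = map_ssrf(
            np.array([100.0, 200.0, 300.0]),
            sch.duration,
            ev["onset"].to_numpy(),
            ev["offset"].to_numpy(),
            ev["col"].to_numpy(),
            ev["row"].to_numpy(),
            baseline_rate=5.0,
            n_shuffles=100,
            seed=0,
        )
        assert not rf.significant
        assert rf.centre is None


class TestSplitByRunning:
    def test_constant_speeds(self):
        t = np.arange(0, 100, 0.02)
        windows = np.array([[10.0, 14.0], [50.0, 54.0]])
        assert not split_by_running(windows, t, np.zeros_like(t)).any()
        assert split_by_running(windows, t, np.full_like(t, 30.0)).all()

    def test_alternating_square_wave(self):
        t = np.arange(0, 80, 0.02)
        v = np.where((t // 4).astype(int) % 2 == 0, 0.0, 40.0)
        windows = np.array([[i * 4.0 + 0.5, i * 4.0 + 3.5] for i in range(2, 18)])
        labels = split_by_running(windows, t, v)
        assert np.array_equal(labels, np.arange(2, 18) % 2 == 1)

    def test_coverage_gap_raises(self):
        t = np.arange(0, 10, 0.02)
        with pytest.raises(ValueError):
            split_by_running(np.array([[8.0, 12.0]]), t, np.zeros_like(t))


class TestEyeMovements:
    def test_pupil_angle_conversion(self):
        assert pupil_to_degrees(np.array([1.7]), 1.7)[0] == pytest.approx(45.0)

    def test_saccade_locked_unit_is_tuned(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 120, 0.02)
        x = np.zeros_like(t)
        sac_times = np.sort(rng.uniform(5, 115, 20))
        sac_times = sac_times[np.concatenate([[True], np.diff(sac_times) > 2.0])]
        r = 1.7
        for ts in sac_times:
            x[t >= ts] += r * np.tan(np.deg2rad(5.0)) * (1 if ts % 2 < 1 else -1)
        nasal = [ts for i, ts in enumerate(sac_times) if ts % 2 < 1]
        spikes = np.sort(
            np.concatenate(
                [rng.uniform(0, 120, 60)]
                + [rng.uniform(ts - 0.25, ts - 0.05, 8) for ts in nasal]
            )
        )
        res = eye_movement_tuning(
            spikes, t, np.vstack([x, np.zeros_like(x)]), r, 120.0,
            n_shuffles=200, seed=1,
        )
        assert res.tuned
        assert abs(res.sta.displacement_vectors[0]) > 1.0

    def test_binocular_saccade_detection(self):
        t = np.arange(0, 60, 0.02)
        vl = np.zeros_like(t)
        vr = np.zeros_like(t)
        for ts in (10.0, 25.0, 40.0):
            i = int(ts / 0.02)
            vl[i : i + 2] = 500.0
            vr[i : i + 2] = 500.0
        assert detect_saccades(t, vl, vr).size == 3
        # monocular event is rejected
        vr2 = np.zeros_like(t)
        assert detect_saccades(t, vl, vr2).size == 0


class TestEpspLatency:
    def test_linear_rise_latency(self):
        t = np.arange(0, 60, 0.01)        # ms
        vm = np.full_like(t, -70.0)
        onset = 10.0
        start = onset + 5.0
        rise = (t >= start) & (t < start + 10.0)
        vm[rise] = -70.0 + (t[rise] - start) * 0.5
        vm[t >= start + 10.0] = -65.0
        lat = epsp_latency(t, vm, onset)
        assert lat == pytest.approx(5.0, abs=0.1)

    def test_flat_trace_no_response(self):
        t = np.arange(0, 60, 0.01)
        assert epsp_latency(t, np.full_like(t, -70.0), 10.0) is None

    def test_sigmoid_matches_tangent_crossing(self):
        t = np.arange(0, 80, 0.005)
        onset, t0, k, amp = 10.0, 30.0, 1.5, 6.0
        vm = -70.0 + amp / (1.0 + np.exp(-(t - t0) / k))
        vm[t < onset] = vm[t < onset] * 0 - 70.0 + amp / (1.0 + np.exp(-(t[t < onset] - t0) / k))
        lat = epsp_latency(t, vm, onset)
        # mid-band line of the logistic crosses rest near t0 - 2k (by direct
        # evaluation of the chord through the 27.5% and 72.5% points)
        f = lambda x: 1.0 / (1.0 + np.exp(-x))
        x1 = -np.log(1 / 0.275 - 1)
        x2 = -np.log(1 / 0.725 - 1)
        slope = (f(x2) - f(x1)) / (k * (x2 - x1))
        t_cross = (t0 + k * x1) - 0.275 / slope
        assert lat == pytest.approx(t_cross - onset, abs=0.3)


class TestVisualOnsetLatency:
    def test_planted_ramp_onset(self):
        t = np.arange(-200, 300, 1.0)     # ms
        rng = np.random.default_rng(0)
        vm = np.cumsum(rng.normal(0, 0.05, t.size))
        vm = vm - vm.mean()
        rep = vm.copy()
        rep[t >= 40.0] += (t[t >= 40.0] - 40.0) * 1.0
        lats = visual_onset_latency(t, rep[None, :], (-200.0, 0.0))
        assert lats[0] == pytest.approx(40.0, abs=2.0)

    def test_no_event_gives_nan(self):
        t = np.arange(-200, 300, 1.0)
        vm = np.zeros_like(t)
        lats = visual_onset_latency(t, vm[None, :], (-200.0, 0.0))
        assert np.isnan(lats[0])

    def test_noisy_baseline_rejected(self):
        t = np.arange(-200, 300, 1.0)
        rng = np.random.default_rng(1)
        vm = rng.normal(0, 5.0, t.size)
        with pytest.raises(RecordingRejectedError):
            visual_onset_latency(t, vm[None, :], (-200.0, 0.0))


class TestSpikeTrainValidation:
    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            SpikeTrain("u", {"a": np.array([1.0, 0.5])}, {"a": 10.0})

    def test_rejects_beyond_duration(self):
        with pytest.raises(ValueError):
            SpikeTrain("u", {"a": np.array([1.0, 11.0])}, {"a": 10.0})

    def test_null_rank(self):
        assert null_rank(5.0, np.arange(100.0)) == pytest.approx(0.05)
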