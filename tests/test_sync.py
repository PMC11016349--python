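"""Log synchronization, segmentation, averaging, and lag estimation."""

import numpy as np
import pytest

from sgrt_dynqa import (
    AlignedSession,
    BeamOnInterval,
    SurfaceLog,
    SynchronizationError,
    average_over_beam_on,
    detect_motion_onset,
    estimate_time_lag,
    resample_surface_log,
    segment_beam_on,
    segment_dwells,
    synchronize_logs,
)
from sgrt_dynqa.log_io import SURF_COLUMNS

from helpers import make_surf, make_traj


def make_session(t, couch, surface, dt=None):
    t = np.asarray(t, dtype=float)
    couch = np.asarray(couch, dtype=float)
    surface = np.asarray(surface, dtype=float)
    return AlignedSession(
        t=t, sample_interval_s=dt if dt is not None else float(t[1] - t[0]),
        couch_expected=couch, couch_actual=couch, surface=surface,
        onset_traj_s=float(t[0]), onset_surf_s=float(t[0]), shift_s=0.0)


class TestResample:
    def test_linear_interpolation_midpoint(self):
        surf = make_surf([0.0, 1.0], lat_mm=[0.0, 10.0])
        out = resample_surface_log(surf, [0.5])
        assert out[0, 0] == pytest.approx(5.0)

    def test_query_at_sample_time_returns_sample(self):
        surf = make_surf([0.0, 0.3, 1.0], lat_mm=[0.0, 7.0, 10.0])
        out = resample_surface_log(surf, [0.3])
        assert out[0, 0] == 7.0

    def test_clamping_outside_span(self):
        surf = make_surf([1.0, 2.0], lng_mm=[3.0, 5.0])
        out = resample_surface_log(surf, [0.0, 3.0])
        assert out[0, 1] == 3.0 and out[1, 1] == 5.0

    def test_single_sample_log_cannot_interpolate(self):
        with pytest.raises(SynchronizationError):
            resample_surface_log(make_surf([0.0]), [0.0])

    def test_matches_bruteforce_interpolation_oracle(self):
        """15 Hz piecewise-linear truth queried at 50 Hz vs a scalar oracle."""
        rng = np.random.default_rng(7)
        ts = np.arange(0, 4, 1 / 15.0)
        vals = {ax: rng.uniform(-20, 20, len(ts)) for ax in SURF_COLUMNS}
        surf = make_surf(ts, **vals)
        grid = np.arange(0, 4, 0.02)
        out = resample_surface_log(surf, grid)

        def oracle(q, ax):  # plain scalar linear interpolation with clamping
            v = vals[ax]
            if q <= ts[0]:
                return v[0]
            if q >= ts[-1]:
                return v[-1]
            j = int(np.searchsorted(ts, q, side="right")) - 1
            a = (q - ts[j]) / (ts[j + 1] - ts[j])
            return (1 - a) * v[j] + a * v[j + 1]

        for k, ax in enumerate(SURF_COLUMNS):
            expected = np.array([oracle(q, ax) for q in grid])
            np.testing.assert_allclose(out[:, k], expected, rtol=0, atol=1e-12)


def onset_scan_oracle(t, x, threshold, baseline_window_s=1.0):
    """Exhaustive scan: first sample exceeding baseline by > threshold."""
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    base = x[t <= t[0] + baseline_window_s].mean(axis=0)
    for i in range(len(t)):
        if np.any(np.abs(x[i] - base) > threshold):
            return t[i]
    return None


class TestMotionOnset:
    def test_constant_series_has_no_onset(self):
        t = np.arange(100) * 0.02
        assert detect_motion_onset(t, np.full((100, 6), 2.0), 0.1) is None

    def test_step_detected_at_exact_sample(self):
        t = np.arange(200) * 0.02
        x = np.zeros((200, 1))
        x[140:] = 10.0
        assert detect_motion_onset(t, x, 0.5) == pytest.approx(t[140])

    def test_noisy_step_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 5, 0.02)
        x = np.where(t >= 2.0, 10.0, 0.0) + rng.normal(0, 0.02, len(t))
        found = detect_motion_onset(t, x, 0.1)
        assert abs(found - 2.0) <= 0.02 + 1e-12
        assert abs(found - onset_scan_oracle(t, x, 0.1)) <= 0.02 + 1e-12

    def test_isolated_noise_spike_is_not_an_onset(self):
        t = np.arange(0, 5, 0.02)
        x = np.zeros(len(t))
        x[30] = 1.0  # single-sample glitch
        x[t >= 3.0] = 10.0
        assert detect_motion_onset(t, x, 0.5) == pytest.approx(3.0)

    def test_raising_threshold_never_gives_earlier_onset(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 6, 0.02)
        x = np.clip(t - 2.0, 0, None) * 5.0 + rng.normal(0, 0.02, len(t))
        onsets = []
        for thr in (0.1, 0.3, 0.5, 1.0, 2.0):
            found = detect_motion_onset(t, x, thr)
            assert found is not None
            onsets.append(found)
        assert onsets == sorted(onsets)

    def test_empty_series_is_an_error(self):
        with pytest.raises(Exception):
            detect_motion_onset(np.array([]), np.empty((0, 6)), 0.1)


class TestSynchronize:
    def _delayed_pair(self, delay):
        """Trajectory with a ramp, surface = same actual trace delayed."""
        traj = make_traj(600, dt=0.02)
        t = traj.t
        ramp = np.clip((t - 3.0) * 10.0, 0, 20.0)
        traj.data["lat_mm_expected"] = ramp
        traj.data["lat_mm_actual"] = ramp
        surf = make_surf(t, lat_mm=np.interp(t - delay, t, ramp))
        return traj, surf

    def test_constructed_delay_is_removed(self):
        traj, surf = self._delayed_pair(0.30)
        sess = synchronize_logs(traj, surf)
        core = (sess.t > 3.5) & (sess.t < 7.0)
        assert np.max(np.abs(sess.surface[core, 0] - sess.couch_actual[core, 0])) < 1e-6

    def test_identical_logs_zero_shift(self):
        traj, surf = self._delayed_pair(0.0)
        sess = synchronize_logs(traj, surf)
        assert sess.shift_s == pytest.approx(0.0, abs=1e-12)

    def test_motionless_source_named_in_error(self):
        traj = make_traj(300, dt=0.02)
        surf = make_surf(np.arange(0, 6, 1 / 15.0))
        with pytest.raises(SynchronizationError, match="trajectory"):
            synchronize_logs(traj, surf)

    def test_simulator_lag_recovered_by_onset_to_surface_resolution(self, noisy_session):
        """Onset alignment recovers injected lag only to the surface sampling
        period (~67 ms), which is why latency QA uses cross-correlation."""
        sess = synchronize_logs(noisy_session["traj"], noisy_session["surf"])
        lag = noisy_session["truth"].surface_latency_s
        assert abs(sess.onset_lag_s - lag) <= 1 / 15.0 + 1e-9


class TestBeamSegmentation:
    def test_constant_mu_gives_no_intervals(self):
        assert segment_beam_on(make_traj(100, mu=np.full(100, 10.0))) == []

    def test_ramp_spans_exactly_its_samples(self):
        mu = np.zeros(400)
        mu[100:200] = np.linspace(0.5, 50.0, 100)
        mu[200:] = 50.0
        traj = make_traj(400, mu=mu)
        (iv,) = segment_beam_on(traj)
        assert iv.start_s == pytest.approx(traj.t[100])
        assert iv.end_s == pytest.approx(traj.t[199])

    def test_simulated_session_has_one_interval_per_translation(self, zero_noise_session):
        traj, plan = zero_noise_session["traj"], zero_noise_session["plan"]
        intervals = segment_beam_on(traj, plan=plan)
        assert len(intervals) == 12
        mu, t = traj.mu, traj.t
        for iv in intervals:
            i0, i1 = np.searchsorted(t, [iv.start_s, iv.end_s])
            delivered = mu[i1] - mu[i0 - 1]
            assert delivered == pytest.approx(50.0, abs=1e-6)

    def test_total_mu_conserved_across_intervals(self, zero_noise_session):
        traj = zero_noise_session["traj"]
        intervals = segment_beam_on(traj)
        mu, t = traj.mu, traj.t
        total = sum(mu[np.searchsorted(t, iv.end_s)]
                    - mu[np.searchsorted(t, iv.start_s) - 1] for iv in intervals)
        assert total == pytest.approx(mu[-1] - mu[0], abs=1e-3 * len(t))


class TestAveraging:
    def test_constant_interval_mean(self):
        t = np.arange(10) * 0.1
        couch = np.full((10, 6), 10.0)
        sess = make_session(t, couch, couch)
        (s,) = average_over_beam_on(sess, [BeamOnInterval(0.0, 0.9, 4)])
        assert s.couch_mean.lat_mm == pytest.approx(10.0)
        assert s.step_index == 4 and s.n_samples == 10

    def test_two_sample_mean(self):
        t = np.array([0.0, 0.1])
        vals = np.zeros((2, 6))
        vals[:, 0] = [9.0, 11.0]
        sess = make_session(t, vals, vals)
        (s,) = average_over_beam_on(sess, [BeamOnInterval(0.0, 0.1, 0)])
        assert s.couch_mean.lat_mm == pytest.approx(10.0)

    def test_empty_interval_is_an_error(self):
        t = np.arange(10) * 0.1
        sess = make_session(t, np.zeros((10, 6)), np.zeros((10, 6)))
        with pytest.raises(SynchronizationError, match="step 3"):
            average_over_beam_on(sess, [BeamOnInterval(5.0, 6.0, 3)])

    def test_matches_bruteforce_masked_mean(self, noisy_session):
        """Summary means equal a plain masked mean to 1e-12 on every axis."""
        traj, surf, plan = (noisy_session["traj"], noisy_session["surf"],
                            noisy_session["plan"])
        sess = synchronize_logs(traj, surf)
        intervals = segment_dwells(traj, plan)
        summaries = average_over_beam_on(sess, intervals)
        for iv, s in zip(intervals, summaries):
            mask = (sess.t >= iv.start_s) & (sess.t <= iv.end_s)
            np.testing.assert_allclose(
                s.couch_mean.as_array(), sess.couch_actual[mask].mean(axis=0),
                rtol=0, atol=1e-12)
            np.testing.assert_allclose(
                s.surface_mean.as_array(), sess.surface[mask].mean(axis=0),
                rtol=0, atol=1e-12)

    def test_zero_noise_closure_surface_equals_couch(self, zero_noise_session):
        """With no noise and no latency, per-position surface means match
        couch means to 1e-6 on every axis."""
        traj, surf, plan = (zero_noise_session["traj"], zero_noise_session["surf"],
                            zero_noise_session["plan"])
        sess = synchronize_logs(traj, surf)
        summaries = average_over_beam_on(sess, segment_dwells(traj, plan))
        for s in summaries:
            np.testing.assert_allclose(
                s.surface_mean.as_array(), s.couch_mean.as_array(),
                rtol=0, atol=1e-6)


class TestDwellSegmentation:
    def test_one_dwell_per_plan_step(self, zero_noise_session):
        traj, plan = zero_noise_session["traj"], zero_noise_session["plan"]
        dwells = segment_dwells(traj, plan)
        assert [iv.step_index for iv in dwells] == [s.index for s in plan.steps]
        starts = [iv.start_s for iv in dwells]
        assert starts == sorted(starts)

    def test_dwells_cover_truth_windows(self, zero_noise_session):
        """Each found dwell contains the simulator's stationary window (the
        found interval may start earlier, e.g. during the pre-roll)."""
        truth = zero_noise_session["truth"]
        dwells = segment_dwells(zero_noise_session["traj"], zero_noise_session["plan"])
        for iv in dwells:
            lo, hi = truth.dwell_windows[iv.step_index]
            assert iv.start_s <= lo + 0.15 and hi - 0.15 <= iv.end_s


def lag_scan_oracle(session, max_lag_s):
    """Independent exhaustive scan over integer lags (plain python loops)."""
    x = session.couch_actual[:, :3] - session.couch_actual[:, :3].mean(axis=0)
    y = session.surface[:, :3] - session.surface[:, :3].mean(axis=0)
    dt = session.sample_interval_s
    kmax = int(round(max_lag_s / dt))
    n = len(x)
    best = (None, -np.inf)
    for k in range(-kmax, kmax + 1):
        xa = x[: n - k] if k >= 0 else x[-k:]
        ya = y[k:] if k >= 0 else y[: n + k]
        num = float((xa * ya).sum())
        den = float(np.sqrt((xa ** 2).sum() * (ya ** 2).sum()))
        if den > 0 and num / den > best[1]:
            best = (k * dt, num / den)
    return best[0]


class TestTimeLag:
    def test_identical_traces_zero_lag(self):
        t = np.arange(0, 10, 0.02)
        x = np.zeros((len(t), 6))
        x[:, 0] = np.clip(t - 3, 0, 2) * 10
        sess = make_session(t, x, x)
        assert estimate_time_lag(sess) == 0.0

    def test_constructed_shift_recovered(self):
        t = np.arange(0, 20, 0.02)
        x = np.zeros((len(t), 6))
        x[:, 1] = np.interp(t, [0, 5, 6, 10, 11, 20], [0, 0, 20, 20, 0, 0])
        y = np.zeros_like(x)
        y[:, 1] = np.interp(t - 0.24, [0, 5, 6, 10, 11, 20], [0, 0, 20, 20, 0, 0])
        sess = make_session(t, x, y)
        assert estimate_time_lag(sess) == pytest.approx(0.24, abs=0.02 + 1e-12)

    def test_motionless_session_is_an_error(self):
        t = np.arange(0, 5, 0.02)
        z = np.zeros((len(t), 6))
        with pytest.raises(SynchronizationError):
            estimate_time_lag(make_session(t, z, z))

    def test_simulator_lag_matches_exhaustive_scan(self, default_plan):
        from sgrt_dynqa import SimulationConfig, simulate_session
        cfg = SimulationConfig(seed=21, surf_latency_s=0.10, render_images=False)
        traj, surf, _, _ = simulate_session(default_plan, cfg)
        sess = synchronize_logs(traj, surf, mode="clock")
        lag = estimate_time_lag(sess)
        assert abs(lag - 0.10) <= 0.02 + 1e-12
        assert lag == lag_scan_oracle(sess, 1.0)
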