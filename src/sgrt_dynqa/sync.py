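"""Temporal alignment of surface and trajectory logs and per-position reduction.

The analysis pipeline interpolates the surface log onto the trajectory log's
uniform time grid, aligns the two streams in time, segments the session into
per-position intervals, and averages every series over each interval.  Two
alignment modes are provided:

``"onset"``
    The procedure used clinically when the surface log carries no beam-on
    flag: the first instance of motion in each log defines its start time.
    Note that onset alignment *absorbs* any true system latency — the lag
    remaining afterwards reflects alignment error, not hardware latency —
    so lag estimates on onset-aligned sessions are informational only.

``"clock"``
    Both logs are assumed to share a clock (as the simulator's do); the
    surface series is resampled without shifting.  Cross-correlation lag on
    a clock-aligned session is a genuine latency measurement.

Motion onset is the first sample whose deviation from the initial-window
baseline exceeds a per-axis threshold *and stays above it* for a short
persistence window; the persistence requirement rejects isolated noise
excursions without biasing the onset time (a real motion ramp keeps rising).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SynchronizationError, ValidationError
from .log_io import SurfaceLog, TrajectoryLog
from .motion_plan import MotionPlan, Pose6DoF

__all__ = [
    "AlignedSession",
    "BeamOnInterval",
    "PositionSummary",
    "resample_surface_log",
    "detect_motion_onset",
    "synchronize_logs",
    "segment_beam_on",
    "segment_dwells",
    "average_over_beam_on",
    "estimate_time_lag",
    "interval_mean_weights",
]

#: default onset thresholds: above simulated sensor noise (sigma ~0.05),
#: well below the smallest planned motion (10 mm / 0.5 deg)
DEFAULT_ONSET_THRESHOLD_MM = 0.1
DEFAULT_ONSET_THRESHOLD_DEG = 0.1
DEFAULT_BASELINE_WINDOW_S = 1.0
# Long enough that several consecutive samples of the slower (surface) stream
# must all exceed threshold: isolated noise excursions are correlated through
# the shared baseline estimate, so a short window is not safe at 2-sigma
# thresholds.  A real motion ramp exceeds threshold for its whole duration,
# so the window does not bias the onset time.
DEFAULT_PERSIST_S = 0.4
DEFAULT_MU_EPSILON = 1e-3


@dataclass
class BeamOnInterval:
    """A closed time interval associated with one motion step."""

    start_s: float
    end_s: float
    step_index: int

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"interval for step {self.step_index}: start {self.start_s} "
                f"must precede end {self.end_s}")


@dataclass
class PositionSummary:
    """Interval-averaged couch and surface pose for one motion step."""

    step_index: int
    couch_mean: Pose6DoF
    surface_mean: Pose6DoF
    n_samples: int

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError(
                f"summary for step {self.step_index}: needs >= 1 sample")


@dataclass
class AlignedSession:
    """Surface and couch series on a common uniform time base.

    ``shift_s`` is the constant added to the surface log's timestamps before
    resampling (``onset_traj_s - onset_surf_s`` in onset mode, 0 in clock
    mode).  When both logs share a session clock, ``onset_surf_s -
    onset_traj_s`` estimates the surface system's reporting latency.
    """

    t: np.ndarray
    sample_interval_s: float
    couch_expected: np.ndarray  # (n, 6)
    couch_actual: np.ndarray    # (n, 6)
    surface: np.ndarray         # (n, 6)
    onset_traj_s: float
    onset_surf_s: float
    shift_s: float

    def __post_init__(self):
        n = len(self.t)
        for name in ("couch_expected", "couch_actual", "surface"):
            if getattr(self, name).shape != (n, 6):
                raise ValidationError(f"{name} must have shape ({n}, 6)")

    @property
    def onset_lag_s(self) -> float:
        """Surface onset minus trajectory onset (latency if clocks shared)."""
        return self.onset_surf_s - self.onset_traj_s


def _axis_thresholds(threshold_mm: float, threshold_deg: float) -> np.ndarray:
    return np.array([threshold_mm] * 3 + [threshold_deg] * 3)


def resample_surface_log(surf: SurfaceLog, t_grid, *, shift_s: float = 0.0) -> np.ndarray:
    """Linearly interpolate the surface offsets onto ``t_grid``.

    Surface timestamps are first shifted by ``shift_s``.  Grid points outside
    the (shifted) log span take the nearest-edge value (clamping).  Returns
    an (n, 6) array.
    """
    if len(surf) < 2:
        raise SynchronizationError(
            "surface log has fewer than 2 samples; cannot interpolate")
    t_grid = np.asarray(t_grid, dtype=float)
    ts = surf.t + shift_s
    offsets = surf.offsets()
    out = np.empty((len(t_grid), 6))
    for k in range(6):
        out[:, k] = np.interp(t_grid, ts, offsets[:, k])
    return out


def detect_motion_onset(
    t,
    series,
    threshold,
    *,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    persist_s: float = DEFAULT_PERSIST_S,
) -> float | None:
    """Return the time of the first sustained departure from baseline.

    ``series`` is (n,) or (n, k); ``threshold`` is a positive scalar or
    per-axis vector (mm for translations, deg for rotations).  The baseline
    is the per-axis mean of the first ``baseline_window_s`` of samples.  The
    onset is the earliest sample at which some axis exceeds its threshold
    and continues to exceed it for ``persist_s``; returns None if no axis
    ever does.
    """
    t = np.asarray(t, dtype=float)
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if len(t) == 0 or series.shape[0] != len(t):
        raise ValidationError("series must be non-empty and match timestamps")
    threshold = np.broadcast_to(np.asarray(threshold, dtype=float), (series.shape[1],))
    if np.any(threshold <= 0):
        raise ValidationError("onset threshold must be > 0")

    baseline_mask = t <= t[0] + baseline_window_s
    baseline = series[baseline_mask].mean(axis=0)
    exceeds = np.abs(series - baseline) > threshold  # (n, k)

    n = len(t)
    for i in np.flatnonzero(exceeds.any(axis=1)):
        window = (t >= t[i]) & (t <= t[i] + persist_s)
        # sustained on at least one axis that is on at sample i
        for ax in np.flatnonzero(exceeds[i]):
            if exceeds[window, ax].all():
                return float(t[i])
        # otherwise an isolated excursion; keep scanning
        if i == n - 1:
            break
    return None


def synchronize_logs(
    traj: TrajectoryLog,
    surf: SurfaceLog,
    *,
    threshold_mm: float = DEFAULT_ONSET_THRESHOLD_MM,
    threshold_deg: float = DEFAULT_ONSET_THRESHOLD_DEG,
    mode: str = "onset",
) -> AlignedSession:
    """Align the surface log to the trajectory log's time grid.

    In ``"onset"`` mode the surface timestamps are shifted by
    ``onset_traj - onset_surf`` so the first instances of motion coincide;
    in ``"clock"`` mode no shift is applied.  Either way the surface series
    is then linearly resampled onto the trajectory grid.
    """
    if mode not in ("onset", "clock"):
        raise ValueError(f"unknown synchronization mode {mode!r}")
    thresholds = _axis_thresholds(threshold_mm, threshold_deg)
    onset_traj = detect_motion_onset(traj.t, traj.actual(), thresholds)
    if onset_traj is None:
        raise SynchronizationError("no motion onset found in trajectory log")
    onset_surf = detect_motion_onset(surf.t, surf.offsets(), thresholds)
    if onset_surf is None:
        raise SynchronizationError("no motion onset found in surface log")

    shift = (onset_traj - onset_surf) if mode == "onset" else 0.0
    surface = resample_surface_log(surf, traj.t, shift_s=shift)
    return AlignedSession(
        t=traj.t,
        sample_interval_s=traj.sample_interval_s,
        couch_expected=traj.expected(),
        couch_actual=traj.actual(),
        surface=surface,
        onset_traj_s=onset_traj,
        onset_surf_s=onset_surf,
        shift_s=shift,
    )


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop inclusive)."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    yield from zip(starts, stops)


def segment_beam_on(
    traj: TrajectoryLog,
    mu_epsilon: float = DEFAULT_MU_EPSILON,
    plan: MotionPlan | None = None,
) -> list[BeamOnInterval]:
    """Find maximal intervals where MU is being delivered.

    A sample is beam-on when the MU increment from the previous sample
    exceeds ``mu_epsilon``.  Intervals are returned in time order; when a
    ``plan`` is given they are mapped to its beam-delivering steps by order
    of occurrence, otherwise ``step_index`` is the interval ordinal.
    """
    mu = traj.mu
    t = traj.t
    if len(mu) < 2:
        return []
    on = np.concatenate([[False], np.diff(mu) > mu_epsilon])
    intervals = [(float(t[i0]), float(t[i1])) for i0, i1 in _runs(on) if i1 > i0]
    if plan is not None:
        beam_steps = plan.beam_steps
        if len(beam_steps) != len(intervals):
            raise SynchronizationError(
                f"found {len(intervals)} beam-on intervals but plan has "
                f"{len(beam_steps)} beam-delivering steps")
        indices = [s.index for s in beam_steps]
    else:
        indices = list(range(len(intervals)))
    return [BeamOnInterval(start_s=a, end_s=b, step_index=i)
            for (a, b), i in zip(intervals, indices)]


def segment_dwells(
    traj: TrajectoryLog,
    plan: MotionPlan,
    *,
    pose_tol: float = 1e-4,
    min_samples: int = 3,
    margin_s: float = 0.1,
) -> list[BeamOnInterval]:
    """Find each step's stationary dwell interval from the expected series.

    Rotation steps deliver no beam, so their per-position averages cannot
    come from MU segmentation; instead the expected (commanded) series is
    scanned sequentially for the maximal run where the couch sits at each
    step's target pose and the gantry at its target angle.  ``margin_s`` is
    trimmed from both ends to stay clear of ramp edges in interpolated
    surface data.
    """
    t = traj.t
    expected = traj.expected()
    gantry = traj.gantry_expected()
    ref = plan.reference.as_array()

    intervals: list[BeamOnInterval] = []
    cursor = 0
    for step in plan.steps:
        target = ref + step.delta.as_array()
        match = (np.abs(expected - target).max(axis=1) <= pose_tol) \
            & (np.abs(gantry - step.gantry_deg) <= pose_tol)
        match[:cursor] = False
        found = None
        for i0, i1 in _runs(match):
            if i1 - i0 + 1 >= min_samples:
                found = (i0, i1)
                break
        if found is None:
            raise SynchronizationError(
                f"no dwell found for step {step.index} "
                f"(axis {step.moved_axis}, target {target.tolist()})")
        i0, i1 = found
        start, end = float(t[i0]) + margin_s, float(t[i1]) - margin_s
        if end <= start:  # dwell shorter than the margins; keep it whole
            start, end = float(t[i0]), float(t[i1])
        intervals.append(BeamOnInterval(start_s=start, end_s=end,
                                        step_index=step.index))
        cursor = i1 + 1
    return intervals


def _unwrapped_mean(values: np.ndarray) -> np.ndarray:
    """Mean of a (n, 6) pose block; rotation axes unwrapped defensively."""
    out = values.mean(axis=0)
    for k in range(3, 6):
        unwrapped = np.degrees(np.unwrap(np.radians(values[:, k])))
        m = unwrapped.mean()
        # renormalize to (-180, 180]
        m = (m + 180.0) % 360.0 - 180.0
        out[k] = -m if m == -180.0 else m
    return out


def average_over_beam_on(
    session: AlignedSession,
    intervals: list[BeamOnInterval],
) -> list[PositionSummary]:
    """Average couch-actual and surface series over each interval.

    Plain arithmetic means; rotations are unwrapped before averaging, which
    is a no-op for the planned +/-3 degree sweeps but keeps the reduction
    wrap-safe for arbitrary data.
    """
    summaries = []
    for iv in intervals:
        mask = (session.t >= iv.start_s) & (session.t <= iv.end_s)
        n = int(mask.sum())
        if n == 0:
            raise SynchronizationError(
                f"interval [{iv.start_s}, {iv.end_s}] for step {iv.step_index} "
                "contains no session samples")
        summaries.append(PositionSummary(
            step_index=iv.step_index,
            couch_mean=Pose6DoF.from_array(_unwrapped_mean(session.couch_actual[mask])),
            surface_mean=Pose6DoF.from_array(_unwrapped_mean(session.surface[mask])),
            n_samples=n,
        ))
    return summaries


def estimate_time_lag(session: AlignedSession, *, max_lag_s: float = 1.0) -> float:
    """Lag maximizing normalized cross-correlation of couch vs surface motion.

    Translation axes are mean-centered, stacked and correlated over integer
    shifts within ``+/-max_lag_s``; the sign convention is positive when the
    surface trace lags the couch trace.  On an onset-aligned session this
    measures residual alignment error rather than true latency (see module
    docstring); on a clock-aligned session it measures the injected/actual
    reporting latency.
    """
    x = session.couch_actual[:, :3].copy()
    y = session.surface[:, :3].copy()
    x -= x.mean(axis=0)
    y -= y.mean(axis=0)
    if float(np.abs(x).max(initial=0.0)) < 1e-9:
        raise SynchronizationError("session contains no couch motion")

    dt = session.sample_interval_s
    kmax = int(round(max_lag_s / dt))
    n = len(session.t)
    if kmax >= n:
        raise ValueError("max_lag_s exceeds session duration")

    best_k, best_c = 0, -np.inf
    for k in range(-kmax, kmax + 1):
        if k >= 0:
            xa, ya = x[: n - k], y[k:]
        else:
            xa, ya = x[-k:], y[: n + k]
        num = float((xa * ya).sum())
        den = float(np.sqrt((xa * xa).sum() * (ya * ya).sum()))
        if den == 0:
            continue
        c = num / den
        if c > best_c:
            best_c, best_k = c, k
    return best_k * dt


def interval_mean_weights(
    surf: SurfaceLog,
    t_grid,
    interval: BeamOnInterval,
    *,
    shift_s: float = 0.0,
) -> np.ndarray:
    """Weights of each raw surface sample in an interval-averaged mean.

    Resampling then averaging is a linear map from the raw surface samples
    to each position mean; this returns that map's weight vector (length =
    number of surface samples, summing to 1).  With i.i.d. per-sample noise
    of standard deviation sigma, the exact standard error of the position
    mean is ``sigma * sqrt(sum(w**2))`` — equivalently an effective sample
    count of ``1 / sum(w**2)``, which is what "sigma over root n" means once
    interpolation has correlated the grid samples.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    ts = surf.t + shift_s
    q = t_grid[(t_grid >= interval.start_s) & (t_grid <= interval.end_s)]
    if len(q) == 0:
        raise SynchronizationError("interval contains no grid samples")
    w = np.zeros(len(ts))
    j = np.searchsorted(ts, q, side="right") - 1
    for t, jj in zip(q, j):
        if jj < 0:
            w[0] += 1.0  # clamped below the log span
        elif jj >= len(ts) - 1:
            w[-1] += 1.0  # clamped above
        else:
            alpha = (t - ts[jj]) / (ts[jj + 1] - ts[jj])
            w[jj] += 1.0 - alpha
            w[jj + 1] += alpha
    return w / len(q)
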