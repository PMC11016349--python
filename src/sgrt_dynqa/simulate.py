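"""Synthetic QA sessions with known ground truth.

Generates everything a real session produces — trajectory log, surface log,
MV images — from a motion plan, so the whole analysis pipeline is testable
without a linac.  The forward model:

* **Couch/gantry motion**: constant-speed linear ramps between consecutive
  step targets (all axes finish together, the slowest axis setting the
  segment duration), followed by a stationary dwell at each target.  The
  expected and actual series coincide; the simulator models an ideally
  performing machine, and miscalibration for negative-control tests is
  injected through the per-axis surface scale factors instead.
* **Beam**: during the dwell of each beam-delivering step, cumulative MU
  ramps linearly by the step's MU between two margins inside the dwell, so
  beam-on time is strictly stationary.
* **Surface**: the phantom is rigidly jigged to the couch, so the true
  surface offset equals the couch offset from reference (optionally scaled
  per axis), delayed by the configured reporting latency, sampled on the
  camera's own rate, with i.i.d. Gaussian noise per axis per sample.  Both
  logs share the session clock, so injected latency is recoverable.
* **MV images**: the bb is projected through the divergent-beam geometry
  onto the detector as a disc whose edge is blurred by a Gaussian detector
  PSF (erf radial profile).  The profile is radially symmetric and
  effectively band-limited, so the sampled image's intensity-weighted
  centroid coincides with the projected center to well below 0.01 px.  The
  disc is darker than background by a configurable contrast; optional
  Gaussian pixel noise is added.  One image per imaging step, including the
  zero-delta reference steps at gantry 0 and gantry 90.

A single seeded generator drives every stochastic draw: identical
(seed, plan, config) triples give bit-identical sessions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import ConfigurationError, DynQAError
from .log_io import SurfaceLog, TrajectoryLog
from .motion_plan import AXES, MotionPlan, Pose6DoF, TRANSLATION_AXES
from .mv_analysis import (
    DEFAULT_BB_DIAMETER_MM,
    DEFAULT_PIXEL_PITCH_MM,
    DEFAULT_SAD_MM,
    DEFAULT_SID_MM,
    MVImage,
    detector_axes,
)

__all__ = ["SimulationConfig", "SessionTruth", "simulate_session", "render_mv_image"]


@dataclass
class SimulationConfig:
    """All knobs of the session forward model.

    Sampling rates and noise magnitudes for the surface system are stand-ins
    (vendor log rates and noise spectra are not published); the defaults —
    15 Hz, sigma 0.05 mm / 0.05 deg — are of the order clinical optical
    systems achieve and are safely below the smallest planned motion.
    """

    seed: int = 0
    traj_rate_hz: float = 50.0
    surf_rate_hz: float = 15.0
    surf_noise_mm: float = 0.05
    surf_noise_deg: float = 0.05
    surf_latency_s: float = 0.0
    surf_scale: tuple[float, ...] = (1.0,) * 6  # per-axis miscalibration
    couch_speed_mm_s: float = 20.0
    couch_speed_deg_s: float = 3.0
    gantry_speed_deg_s: float = 6.0
    dwell_s: float = 2.0
    beam_margin_s: float = 0.2
    pre_roll_s: float = 2.0
    post_roll_s: float = 1.0
    bb_diameter_mm: float = DEFAULT_BB_DIAMETER_MM
    bb_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bb_contrast: float = 0.5
    edge_sigma_px: float = 0.7  # detector PSF blur of the disc edge
    background_level: float = 0.8
    image_noise_sigma: float = 0.0
    image_shape: tuple[int, int] = (512, 512)
    sad_mm: float = DEFAULT_SAD_MM
    sid_mm: float = DEFAULT_SID_MM
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    render_images: bool = True

    def validate(self) -> None:
        if self.traj_rate_hz <= 0 or self.surf_rate_hz <= 0:
            raise ConfigurationError("sampling rates must be > 0")
        if min(self.surf_noise_mm, self.surf_noise_deg, self.image_noise_sigma) < 0:
            raise ConfigurationError("noise sigmas must be >= 0")
        if min(self.couch_speed_mm_s, self.couch_speed_deg_s,
               self.gantry_speed_deg_s) <= 0:
            raise ConfigurationError("speeds must be > 0")
        if self.dwell_s < 2.0 / self.traj_rate_hz:
            raise ConfigurationError(
                "dwell shorter than 2 trajectory samples cannot be averaged")
        if not 0 < 2 * self.beam_margin_s < self.dwell_s:
            raise ConfigurationError("beam margins must fit inside the dwell")
        if len(self.surf_scale) != 6:
            raise ConfigurationError("surf_scale needs one factor per axis")

    @property
    def noise_sigmas(self) -> np.ndarray:
        return np.array([self.surf_noise_mm] * 3 + [self.surf_noise_deg] * 3)


@dataclass
class SessionTruth:
    """Ground truth of a simulated session, exactly consistent with the plan."""

    step_deltas: dict[int, Pose6DoF]
    surface_latency_s: float
    bb_px: dict[int, tuple[float, float]]  # step index -> (row, col)
    dwell_windows: dict[int, tuple[float, float]]  # step index -> (start, end)
    plan_label: str = ""

    def to_json(self) -> str:
        payload = {
            "surface_latency_s": self.surface_latency_s,
            "plan_label": self.plan_label,
            "step_deltas": {str(i): list(p.as_array()) for i, p in self.step_deltas.items()},
            "bb_px": {str(i): list(rc) for i, rc in self.bb_px.items()},
            "dwell_windows": {str(i): list(w) for i, w in self.dwell_windows.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "SessionTruth":
        p = json.loads(text)
        return cls(
            step_deltas={int(i): Pose6DoF.from_array(v)
                         for i, v in p["step_deltas"].items()},
            surface_latency_s=p["surface_latency_s"],
            bb_px={int(i): tuple(v) for i, v in p["bb_px"].items()},
            dwell_windows={int(i): tuple(v) for i, v in p["dwell_windows"].items()},
            plan_label=p.get("plan_label", ""),
        )


def _build_profile(plan: MotionPlan, config: SimulationConfig):
    """Piecewise-linear knots (t, couch pose abs, gantry, cumulative MU)."""
    ref = plan.reference.as_array()
    speeds = np.array([config.couch_speed_mm_s] * 3 + [config.couch_speed_deg_s] * 3)

    times = [0.0]
    poses = [ref.copy()]
    gantries = [0.0]
    mus = [0.0]
    t = config.pre_roll_s
    dwell_windows: dict[int, tuple[float, float]] = {}

    def knot(time, pose, gantry, mu):
        times.append(float(time))
        poses.append(np.asarray(pose, dtype=float).copy())
        gantries.append(float(gantry))
        mus.append(float(mu))

    pose, gantry, mu = ref.copy(), 0.0, 0.0
    knot(t, pose, gantry, mu)  # end of pre-roll
    for step in plan.steps:
        target = ref + step.delta.as_array()
        g_target = step.gantry_deg
        durations = np.abs(target - pose) / speeds
        move_t = float(max(durations.max(initial=0.0),
                           abs(g_target - gantry) / config.gantry_speed_deg_s))
        if move_t > 0:
            t += move_t
            knot(t, target, g_target, mu)
        dwell_start = t
        t += config.dwell_s
        if step.mu > 0:
            b0 = dwell_start + config.beam_margin_s
            b1 = t - config.beam_margin_s
            knot(b0, target, g_target, mu)
            mu += step.mu
            knot(b1, target, g_target, mu)
        knot(t, target, g_target, mu)
        dwell_windows[step.index] = (dwell_start, t)
        pose, gantry = target, g_target
    t += config.post_roll_s
    knot(t, pose, gantry, mu)

    return (np.array(times), np.vstack(poses), np.array(gantries),
            np.array(mus), dwell_windows)


def render_mv_image(
    bb_pos_mm,
    gantry_deg: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    step_index: int | None = None,
) -> tuple[MVImage, tuple[float, float]]:
    """Project the bb onto the detector and render the image.

    ``bb_pos_mm`` is the bb's (lat, lng, vrt) position relative to isocenter.
    Returns the image and the true projected (row, col) center.  Raises if
    the projected disc does not fit fully inside the detector.
    """
    rng = rng or np.random.default_rng(config.seed)
    lat, lng, vrt = (float(v) for v in bb_pos_mm)
    pos = {"lat_mm": lat, "lng_mm": lng, "vrt_mm": vrt}
    col_axis, row_axis, beam_axis = detector_axes(gantry_deg)
    axial = pos[beam_axis]
    if axial >= config.sad_mm:
        raise DynQAError("bb at or beyond the source; cannot project")
    mag = config.sid_mm / (config.sad_mm - axial)

    rows, cols = config.image_shape
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    row_px = center[0] + pos[row_axis] * mag / config.pixel_pitch_mm
    col_px = center[1] + pos[col_axis] * mag / config.pixel_pitch_mm
    radius_px = 0.5 * config.bb_diameter_mm * mag / config.pixel_pitch_mm

    pad = radius_px + 1.0
    if not (pad <= row_px <= rows - 1 - pad and pad <= col_px <= cols - 1 - pad):
        raise DynQAError(
            f"bb projection ({row_px:.1f}, {col_px:.1f}) px falls outside the "
            f"{rows}x{cols} detector")

    rr = np.arange(rows, dtype=float)[:, None] - row_px
    cc = np.arange(cols, dtype=float)[None, :] - col_px
    d = np.hypot(rr, cc)
    if config.edge_sigma_px > 0:
        # erf edge: the detector PSF blurs the disc boundary; the profile is
        # radially symmetric and band-limited, so the sampled image's
        # intensity-weighted centroid coincides with the projected center
        coverage = 0.5 * (1.0 + erf((radius_px - d) /
                                    (config.edge_sigma_px * np.sqrt(2.0))))
    else:
        coverage = np.clip(radius_px + 0.5 - d, 0.0, 1.0)
    pixels = config.background_level - config.bb_contrast * coverage
    if config.image_noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, config.image_noise_sigma, pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    img = MVImage(
        pixels=pixels,
        pixel_pitch_mm=config.pixel_pitch_mm,
        sid_mm=config.sid_mm,
        sad_mm=config.sad_mm,
        gantry_deg=gantry_deg,
        step_index=step_index,
    )
    return img, (row_px, col_px)


def simulate_session(
    plan: MotionPlan,
    config: SimulationConfig | None = None,
) -> tuple[TrajectoryLog, SurfaceLog, list[MVImage], SessionTruth]:
    """Generate a complete synthetic QA session for ``plan``."""
    config = config or SimulationConfig()
    plan.validate()
    config.validate()
    if not plan.steps:
        raise ConfigurationError("cannot simulate an empty plan")
    rng = np.random.default_rng(config.seed)

    knot_t, knot_pose, knot_gantry, knot_mu, dwell_windows = _build_profile(plan, config)
    t_end = knot_t[-1]

    # trajectory log: expected == actual (ideal machine)
    dt = 1.0 / config.traj_rate_hz
    n = int(np.floor(t_end / dt)) + 1
    t = np.arange(n) * dt
    couch = np.column_stack([np.interp(t, knot_t, knot_pose[:, k]) for k in range(6)])
    gantry = np.interp(t, knot_t, knot_gantry)
    mu = np.interp(t, knot_t, knot_mu)
    columns: dict[str, np.ndarray] = {"t": t}
    for k, ax in enumerate(AXES):
        columns[f"{ax}_expected"] = couch[:, k]
        columns[f"{ax}_actual"] = couch[:, k]
    columns["gantry_deg_expected"] = gantry
    columns["gantry_deg_actual"] = gantry
    columns["mu"] = mu
    traj = TrajectoryLog(sample_interval_s=dt, data=pd.DataFrame(columns),
                         meta={"label": plan.metadata.get("label", "")})
    traj.validate()

    # surface log: rigid phantom response, delayed, scaled, noisy
    dts = 1.0 / config.surf_rate_hz
    ns = int(np.floor(t_end / dts)) + 1
    ts = np.arange(ns) * dts
    ref = plan.reference.as_array()
    scale = np.asarray(config.surf_scale, dtype=float)
    query = np.clip(ts - config.surf_latency_s, 0.0, None)
    offsets = np.column_stack([
        (np.interp(query, knot_t, knot_pose[:, k]) - ref[k]) * scale[k]
        for k in range(6)
    ])
    offsets = offsets + rng.normal(0.0, 1.0, offsets.shape) * config.noise_sigmas
    surf_cols: dict[str, np.ndarray] = {"t": ts}
    for k, ax in enumerate(AXES):
        surf_cols[ax] = offsets[:, k]
    surf = SurfaceLog(data=pd.DataFrame(surf_cols),
                      meta={"label": plan.metadata.get("label", "")})
    surf.validate()

    # MV images: one per imaging step (references included)
    images: list[MVImage] = []
    bb_px: dict[int, tuple[float, float]] = {}
    if config.render_images:
        bb_ref = np.asarray(config.bb_offset_mm, dtype=float)
        for step in plan.imaging_steps:
            delta_t = np.array([getattr(step.delta, ax) for ax in TRANSLATION_AXES])
            img, center = render_mv_image(
                bb_ref + delta_t, step.gantry_deg, config, rng,
                step_index=step.index)
            images.append(img)
            bb_px[step.index] = center

    truth = SessionTruth(
        step_deltas={s.index: s.delta for s in plan.steps},
        surface_latency_s=config.surf_latency_s,
        bb_px=bb_px,
        dwell_windows=dwell_windows,
        plan_label=plan.metadata.get("label", ""),
    )
    return traj, surf, images, truth


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config (for YAML/JSON serialization)."""
    return asdict(config)


def config_from_dict(data: dict) -> SimulationConfig:
    cfg = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in (data or {}).items()})
    cfg.validate()
    return cfg
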