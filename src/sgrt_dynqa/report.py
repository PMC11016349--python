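"""Deviation computation, tolerance evaluation, and QA report generation.

Each moved-axis step yields one :class:`DeviationRecord` comparing the
commanded delta against up to three independent measurements: the trajectory
log (machine's own report), the surface-imaging log, and — for translations
only — MV imaging of the implanted bb.  Deviations are signed, measured
minus expected.  Verdicts apply stereotactic (SABR) tolerances of 1 mm and
1 degree per axis; a deviation exactly equal to the tolerance passes (the
comparison is <=), which is stated here prominently because the boundary
rule changes borderline monthly results.

"Maximum deviation" throughout means the signed deviation of largest
magnitude, so a report echoes values like -0.94 mm rather than 0.94 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import ConsistencyError, DynQAError, ValidationError
from .motion_plan import MotionPlan, ROTATION_AXES, TRANSLATION_AXES
from .mv_analysis import ImageOffset
from .sync import PositionSummary

__all__ = [
    "DeviationRecord",
    "ToleranceSet",
    "QAReport",
    "compute_deviations",
    "evaluate_tolerances",
    "generate_report",
    "load_report_json",
    "analyze_session",
]

REPORT_SCHEMA_VERSION = "1"
SOURCES = ("traj", "surf", "mv")


@dataclass
class ToleranceSet:
    """Per-axis action thresholds; defaults are the SABR values (1 mm, 1 deg)."""

    translation_tol_mm: float = 1.0
    rotation_tol_deg: float = 1.0

    def __post_init__(self):
        if self.translation_tol_mm <= 0 or self.rotation_tol_deg <= 0:
            raise ValidationError("tolerances must be > 0")

    def for_axis(self, axis: str) -> float:
        return self.translation_tol_mm if axis in TRANSLATION_AXES else self.rotation_tol_deg


@dataclass
class DeviationRecord:
    """Expected vs measured delta on one axis of one step, per source.

    ``measured_mv``/``dev_mv`` are structurally absent (None) for rotation
    axes: a single-bb phantom cannot constrain rotations radiographically.
    """

    step_index: int
    axis: str
    expected: float
    measured_traj: float | None = None
    measured_surf: float | None = None
    measured_mv: float | None = None

    def __post_init__(self):
        if self.axis in ROTATION_AXES and self.measured_mv is not None:
            raise ValidationError(
                f"step {self.step_index}: rotation axis {self.axis} cannot "
                "carry an MV measurement")

    def deviation(self, source: str) -> float | None:
        measured = getattr(self, f"measured_{source}")
        return None if measured is None else measured - self.expected

    @property
    def dev_traj(self):
        return self.deviation("traj")

    @property
    def dev_surf(self):
        return self.deviation("surf")

    @property
    def dev_mv(self):
        return self.deviation("mv")

    @property
    def is_translation(self) -> bool:
        return self.axis in TRANSLATION_AXES


@dataclass
class QAReport:
    """Tolerance verdicts and signed extreme deviations per source."""

    records: list[DeviationRecord]
    tolerances: ToleranceSet
    max_dev: dict  # {source: {"translation": signed-or-None, "rotation": ...}}
    verdicts: dict[str, bool]  # per source: True = pass
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return all(self.verdicts.values())


def _signed_extreme(values: list[float]) -> float | None:
    """Signed value of largest magnitude, or None for an empty list."""
    return max(values, key=abs) if values else None


def compute_deviations(
    plan: MotionPlan,
    summaries: list[PositionSummary],
    offsets: list[ImageOffset] | None = None,
) -> list[DeviationRecord]:
    """Build one record per (step, moved axis) from all measurement sources.

    Trajectory/surface measurements come from the per-position summaries
    (couch means are absolute, so the plan reference is subtracted; surface
    offsets are already relative to the reference capture).  MV measurements
    are attached where an image offset exists for the step and covers the
    moved axis.  Zero-delta home/reference steps produce no record.
    """
    by_step = {}
    for s in summaries:
        if s.step_index in by_step:
            raise ConsistencyError(f"duplicate summary for step {s.step_index}")
        by_step[s.step_index] = s
    mv_by_step = {}
    for off in offsets or []:
        if off.step_index in mv_by_step:
            raise ConsistencyError(f"duplicate image offset for step {off.step_index}")
        mv_by_step[off.step_index] = off

    records = []
    for step in plan.steps:
        axis = step.moved_axis
        if axis is None:
            continue
        summary = by_step.get(step.index)
        if summary is None:
            raise ConsistencyError(f"no position summary for step {step.index}")
        expected = getattr(step.delta, axis)
        measured_traj = getattr(summary.couch_mean, axis) - getattr(plan.reference, axis)
        measured_surf = getattr(summary.surface_mean, axis)
        measured_mv = None
        if axis in TRANSLATION_AXES:
            off = mv_by_step.get(step.index)
            if off is not None and axis in off.axes:
                measured_mv = off.axes[axis]
        records.append(DeviationRecord(
            step_index=step.index, axis=axis, expected=expected,
            measured_traj=measured_traj, measured_surf=measured_surf,
            measured_mv=measured_mv,
        ))
    return records


def evaluate_tolerances(
    records: list[DeviationRecord],
    tol: ToleranceSet | None = None,
) -> QAReport:
    """Apply per-axis tolerances and assemble the report.

    A source passes iff every one of its applicable |deviation| values is
    <= its tolerance (boundary passes).  Extremes are reported separately
    for translations and rotations, keeping their sign.
    """
    if not records:
        raise DynQAError("cannot evaluate tolerances on an empty record list")
    tol = tol or ToleranceSet()

    max_dev: dict = {}
    verdicts: dict[str, bool] = {}
    for source in SOURCES:
        devs_t = [r.deviation(source) for r in records
                  if r.is_translation and r.deviation(source) is not None]
        devs_r = [r.deviation(source) for r in records
                  if not r.is_translation and r.deviation(source) is not None]
        max_dev[source] = {
            "translation": _signed_extreme(devs_t),
            "rotation": _signed_extreme(devs_r),
        }
        verdicts[source] = (
            all(abs(d) <= tol.translation_tol_mm for d in devs_t)
            and all(abs(d) <= tol.rotation_tol_deg for d in devs_r)
        )
    return QAReport(records=records, tolerances=tol, max_dev=max_dev,
                    verdicts=verdicts)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def generate_report(report: QAReport, format: str = "json") -> str:
    """Render the report as machine-readable JSON or a markdown table."""
    if not report.records:
        raise DynQAError("refusing to render a report with no records")
    if format == "json":
        return _to_json(report)
    if format in ("md", "markdown"):
        return _to_markdown(report)
    raise DynQAError(f"unknown report format {format!r}")


def _to_json(report: QAReport) -> str:
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tolerances": {
            "translation_tol_mm": report.tolerances.translation_tol_mm,
            "rotation_tol_deg": report.tolerances.rotation_tol_deg,
        },
        "metadata": report.metadata,
        "max_dev": report.max_dev,
        "verdicts": report.verdicts,
        "records": [
            {
                "step_index": r.step_index,
                "axis": r.axis,
                "expected": r.expected,
                "measured_traj": r.measured_traj,
                "measured_surf": r.measured_surf,
                "measured_mv": r.measured_mv,
            }
            for r in report.records
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True) + "\n"


def load_report_json(text: str) -> QAReport:
    """Inverse of ``generate_report(..., "json")``."""
    payload = json.loads(text)
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise DynQAError(
            f"unsupported report schema {payload.get('schema_version')!r}")
    records = [DeviationRecord(**rec) for rec in payload["records"]]
    tol = ToleranceSet(**payload["tolerances"])
    return QAReport(
        records=records,
        tolerances=tol,
        max_dev=payload["max_dev"],
        verdicts=payload["verdicts"],
        metadata=payload.get("metadata", {}),
    )


def _fmt_val(v: float | None) -> str:
    return "--" if v is None else f"{v:+.3f}"


def _to_markdown(report: QAReport) -> str:
    tol = report.tolerances
    lines = [
        "# SGRT dynamic localization QA report",
        "",
        f"Tolerances (SABR): {tol.translation_tol_mm} mm translation, "
        f"{tol.rotation_tol_deg} deg rotation (boundary passes).",
        "",
        "| source | max trans dev (mm) | max rot dev (deg) | verdict |",
        "|---|---|---|---|",
    ]
    names = {"traj": "trajectory log", "surf": "surface log", "mv": "MV imaging"}
    for source in SOURCES:
        md = report.max_dev[source]
        verdict = "PASS" if report.verdicts[source] else "FAIL"
        lines.append(
            f"| {names[source]} | {_fmt_val(md['translation'])} | "
            f"{_fmt_val(md['rotation'])} | {verdict} |")
    lines += [
        "",
        "| step | axis | expected | traj dev | surf dev | MV dev |",
        "|---|---|---|---|---|---|",
    ]
    for r in report.records:
        lines.append(
            f"| {r.step_index} | {r.axis} | {r.expected:+.3f} | "
            f"{_fmt_val(r.dev_traj)} | {_fmt_val(r.dev_surf)} | "
            f"{_fmt_val(r.dev_mv)} |")
    overall = "PASS" if report.overall_pass else "FAIL"
    lines += ["", f"Overall: {overall}", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# end-to-end analysis
# ---------------------------------------------------------------------------

def analyze_session(
    plan,
    traj,
    surf,
    images=(),
    *,
    tolerances: ToleranceSet | None = None,
    bb_diameter_mm: float | None = None,
    sync_mode: str = "onset",
    metadata: dict | None = None,
) -> QAReport:
    """Run the full analysis pipeline on one session and return the report.

    Steps: synchronize the surface log to the trajectory grid, segment the
    session into per-position intervals (beam-on intervals for
    beam-delivering steps, stationary dwells found from the expected series
    for the rest), average both streams over each interval, detect the bb in
    every MV image, convert bb displacements into couch-axis millimetres,
    and evaluate SABR tolerances.  ``images`` may be empty, in which case MV
    columns are absent from the report.
    """
    from .mv_analysis import DEFAULT_BB_DIAMETER_MM, compute_image_offsets, detect_bb_center
    from .sync import average_over_beam_on, segment_beam_on, segment_dwells, synchronize_logs

    plan.validate()
    session = synchronize_logs(traj, surf, mode=sync_mode)
    dwells = segment_dwells(traj, plan)
    beam = {iv.step_index: iv for iv in segment_beam_on(traj, plan=plan)}
    intervals = [beam.get(iv.step_index, iv) for iv in dwells]
    summaries = average_over_beam_on(session, intervals)

    offsets = None
    if images:
        bb_d = bb_diameter_mm if bb_diameter_mm is not None else DEFAULT_BB_DIAMETER_MM
        steps = {s.index: s for s in plan.steps}
        references, measurements = [], []
        for img in images:
            det = detect_bb_center(img, bb_d)
            step = steps.get(img.step_index)
            if step is not None and step.acquire_mv and step.delta.is_zero():
                references.append((img, det))
            else:
                measurements.append((img, det))
        offsets = compute_image_offsets(references, measurements)

    records = compute_deviations(plan, summaries, offsets)
    qa = evaluate_tolerances(records, tolerances)
    qa.metadata = dict(metadata or {})
    qa.metadata.setdefault("plan_label", plan.metadata.get("label", ""))
    qa.metadata.setdefault("sync_mode", sync_mode)
    return qa
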