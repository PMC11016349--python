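"""Couch/gantry motion plans for dynamic-localization QA.

The monthly QA procedure drives the treatment couch through a fixed sequence
of single-axis moves while the surface-imaging system watches a rigid
phantom: lateral and longitudinal translations of +/-1 cm and +/-5 cm at
gantry 0, the same vertical shifts at gantry 90, and yaw/pitch/roll sweeps of
+/-3 degrees in 0.5-degree increments.  An MV image is acquired and 50 MU
delivered after each translation; rotations are not imaged because a single
implanted bb cannot constrain them.

Plans are rendered to a small, versioned XML control script (one
``<controlPoint>`` per step, absolute axis values) and parsed back
losslessly.  Couch coordinates follow IEC 61217: lat = X (+toward couch
left), lng = Y (+toward gantry), vrt = Z (+up); yaw/pitch/roll are rotations
about Z/X/Y in degrees, normalized to (-180, 180].
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "AXES",
    "TRANSLATION_AXES",
    "ROTATION_AXES",
    "Pose6DoF",
    "MotionStep",
    "MotionPlan",
    "PlanConfig",
    "build_motion_plan",
    "render_developer_xml",
    "parse_developer_xml",
]

#: Canonical axis order used throughout the package.
AXES = ("lat_mm", "lng_mm", "vrt_mm", "yaw_deg", "pitch_deg", "roll_deg")
TRANSLATION_AXES = AXES[:3]
ROTATION_AXES = AXES[3:]

SCHEMA_VERSION = "1"
_GANTRY_TOL_DEG = 1e-6


def _normalize_angle(a: float) -> float:
    """Map an angle in degrees to the half-open interval (-180, 180]."""
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class Pose6DoF:
    """One 6-degree-of-freedom couch (or surface) state.

    Translations in millimetres, rotations in degrees.  Rotations are
    normalized to (-180, 180] on construction; all values must be finite.
    """

    lat_mm: float = 0.0
    lng_mm: float = 0.0
    vrt_mm: float = 0.0
    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0

    def __post_init__(self):
        for ax in AXES:
            v = getattr(self, ax)
            if not math.isfinite(v):
                raise ValidationError(f"Pose6DoF.{ax} must be finite, got {v!r}")
            object.__setattr__(self, ax, float(v))
        for ax in ROTATION_AXES:
            object.__setattr__(self, ax, _normalize_angle(getattr(self, ax)))

    def as_array(self) -> np.ndarray:
        """Return the pose as a length-6 float array in canonical axis order."""
        return np.array([getattr(self, ax) for ax in AXES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "Pose6DoF":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValidationError(f"expected 6 axis values, got shape {values.shape}")
        return cls(**dict(zip(AXES, values)))

    def __add__(self, other: "Pose6DoF") -> "Pose6DoF":
        return Pose6DoF.from_array(self.as_array() + other.as_array())

    def __sub__(self, other: "Pose6DoF") -> "Pose6DoF":
        return Pose6DoF.from_array(self.as_array() - other.as_array())

    def is_zero(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.as_array()) <= tol))

    def nonzero_axes(self, tol: float = 0.0) -> tuple[str, ...]:
        return tuple(ax for ax in AXES if abs(getattr(self, ax)) > tol)


@dataclass(frozen=True)
class MotionStep:
    """A single control point: a couch offset from reference plus delivery.

    ``delta`` is the absolute offset from the plan reference (the couch
    returns to zero between axes, so offsets never accumulate).  ``mu`` is
    the monitor units delivered while dwelling at this position and
    ``acquire_mv`` requests an MV image there.
    """

    index: int
    delta: Pose6DoF
    gantry_deg: float = 0.0
    acquire_mv: bool = False
    mu: float = 0.0

    def __post_init__(self):
        if self.mu < 0:
            raise ValidationError(f"step {self.index}: mu must be >= 0, got {self.mu}")
        if not math.isfinite(self.gantry_deg):
            raise ValidationError(f"step {self.index}: gantry angle must be finite")
        if len(self.delta.nonzero_axes()) > 1:
            raise ValidationError(
                f"step {self.index}: moves more than one axis at a time "
                f"({', '.join(self.delta.nonzero_axes())})"
            )

    @property
    def moved_axis(self) -> str | None:
        """Name of the single moved axis, or None for a zero-delta step."""
        axes = self.delta.nonzero_axes()
        return axes[0] if axes else None


@dataclass
class MotionPlan:
    """Ordered sequence of motion steps starting and ending at reference."""

    reference: Pose6DoF = field(default_factory=Pose6DoF)
    steps: list[MotionStep] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every offending step."""
        problems: list[str] = []
        seen: set[int] = set()
        for step in self.steps:
            if step.index in seen:
                problems.append(f"step {step.index}: duplicate index")
            seen.add(step.index)
            ax = step.moved_axis
            if ax in ("lat_mm", "lng_mm") and abs(step.gantry_deg) > _GANTRY_TOL_DEG:
                problems.append(
                    f"step {step.index}: {ax} move requires gantry 0, "
                    f"got {step.gantry_deg}"
                )
            if ax == "vrt_mm" and abs(step.gantry_deg - 90.0) > _GANTRY_TOL_DEG:
                problems.append(
                    f"step {step.index}: vertical move requires gantry 90, "
                    f"got {step.gantry_deg}"
                )
            if ax in ROTATION_AXES and abs(step.gantry_deg) > _GANTRY_TOL_DEG:
                problems.append(
                    f"step {step.index}: rotation requires gantry 0, "
                    f"got {step.gantry_deg}"
                )
        if self.steps:
            if not self.steps[0].delta.is_zero():
                problems.append("first step must start at the reference pose")
            if not self.steps[-1].delta.is_zero():
                problems.append("last step must return to the reference pose")
        if problems:
            raise ValidationError("invalid motion plan: " + "; ".join(problems))

    @property
    def imaging_steps(self) -> list[MotionStep]:
        return [s for s in self.steps if s.acquire_mv]

    @property
    def beam_steps(self) -> list[MotionStep]:
        """Steps that deliver beam (mu > 0), in plan order."""
        return [s for s in self.steps if s.mu > 0]

    def equals(self, other: "MotionPlan", tol: float = 1e-9) -> bool:
        """Field-wise equality within ``tol`` (metadata compared exactly)."""
        if len(self.steps) != len(other.steps) or self.metadata != other.metadata:
            return False
        if np.max(np.abs(self.reference.as_array() - other.reference.as_array()), initial=0.0) > tol:
            return False
        for a, b in zip(self.steps, other.steps):
            if a.index != b.index or a.acquire_mv != b.acquire_mv:
                return False
            if abs(a.gantry_deg - b.gantry_deg) > tol or abs(a.mu - b.mu) > tol:
                return False
            if np.max(np.abs(a.delta.as_array() - b.delta.as_array()), initial=0.0) > tol:
                return False
        return True


@dataclass(frozen=True)
class PlanConfig:
    """Parameters of the QA motion sequence.

    Defaults reproduce the standard monthly test: +/-10 and +/-50 mm
    translations on each translation axis and +/-3 degree sweeps in
    0.5-degree increments on each rotation axis, 50 MU per imaging point.
    """

    translation_offsets_mm: tuple[float, ...] = (-50.0, -10.0, 10.0, 50.0)
    rotation_range_deg: float = 3.0
    rotation_increment_deg: float = 0.5
    mu_per_image: float = 50.0
    label: str = "sgrt-dynqa monthly"

    def validate(self) -> None:
        for off in self.translation_offsets_mm:
            if not math.isfinite(off) or off == 0.0:
                raise ConfigurationError(
                    f"translation offsets must be nonzero and finite, got {off!r}"
                )
        if self.rotation_range_deg < 0 or not math.isfinite(self.rotation_range_deg):
            raise ConfigurationError("rotation range must be finite and >= 0")
        if self.rotation_range_deg > 0:
            if self.rotation_increment_deg <= 0:
                raise ConfigurationError("rotation increment must be > 0")
            n = self.rotation_range_deg / self.rotation_increment_deg
            if abs(n - round(n)) > 1e-9:
                raise ConfigurationError(
                    "rotation range must be an integer multiple of the increment "
                    f"({self.rotation_range_deg} / {self.rotation_increment_deg})"
                )
        if self.mu_per_image < 0:
            raise ConfigurationError("mu_per_image must be >= 0")

    def rotation_offsets_deg(self) -> tuple[float, ...]:
        """Monotone sweep -range .. +range in increments, skipping zero."""
        if self.rotation_range_deg == 0:
            return ()
        n = int(round(self.rotation_range_deg / self.rotation_increment_deg))
        neg = [-self.rotation_range_deg + k * self.rotation_increment_deg for k in range(n)]
        pos = [self.rotation_increment_deg * (k + 1) for k in range(n)]
        return tuple(neg + pos)


def build_motion_plan(config: PlanConfig | None = None) -> MotionPlan:
    """Construct the QA motion sequence from ``config``.

    Structure of the default plan (53 steps):

    * reference MV image at gantry 0 (zero delta, no MU),
    * lateral then longitudinal offsets at gantry 0, each imaged with 50 MU,
    * return home; reference MV image at gantry 90; vertical offsets at
      gantry 90, each imaged with 50 MU; return home (gantry back to 0),
    * yaw, pitch, roll sweeps at gantry 0 (no imaging, no beam),
    * final zero-delta step so the plan ends at reference.

    Each step's delta is an absolute offset from reference: the couch
    returns to zero between axes and the sweep within an axis is monotone.
    Zero-delta "home" steps carry no beam; reference-image steps acquire an
    MV image without logged MU (beam intervals therefore correspond
    one-to-one to translation steps).
    """
    config = config or PlanConfig()
    config.validate()

    steps: list[MotionStep] = []

    def add(delta=Pose6DoF(), gantry=0.0, acquire=False, mu=0.0):
        steps.append(
            MotionStep(index=len(steps), delta=delta, gantry_deg=gantry,
                       acquire_mv=acquire, mu=mu)
        )

    has_translations = bool(config.translation_offsets_mm)
    rotations = config.rotation_offsets_deg()

    if has_translations:
        add(acquire=True)  # reference image, gantry 0
        for axis in ("lat_mm", "lng_mm"):
            for off in config.translation_offsets_mm:
                add(Pose6DoF(**{axis: off}), gantry=0.0, acquire=True,
                    mu=config.mu_per_image)
        add()  # home before gantry rotates
        add(gantry=90.0, acquire=True)  # reference image, gantry 90
        for off in config.translation_offsets_mm:
            add(Pose6DoF(vrt_mm=off), gantry=90.0, acquire=True,
                mu=config.mu_per_image)
        add()  # home, gantry back to 0

    if rotations:
        if not steps:
            add()  # rotation-only plan still starts at reference
        for axis in ROTATION_AXES:
            for off in rotations:
                add(Pose6DoF(**{axis: off}))
        add()  # final home

    plan = MotionPlan(
        reference=Pose6DoF(),
        steps=steps,
        metadata={
            "label": config.label,
            "rotation_sequencing": "absolute-offsets;return-to-zero-between-axes;monotone-sweep",
            "coordinate_system": "IEC61217",
        },
    )
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# XML rendering / parsing (schema v1)
# ---------------------------------------------------------------------------
#
# <dynqaPlan schemaVersion="1">
#   <meta key="..." value="..."/>            (sorted by key)
#   <reference lat_mm="..." ... roll_deg="..."/>
#   <sequence>
#     <controlPoint index="0" gantry_deg="0.0" acquireMv="true" mu="50.0">
#       <couch lat_mm="..." ... roll_deg="..."/>   (absolute = reference+delta)
#     </controlPoint>
#   </sequence>
# </dynqaPlan>
#
# Floats are serialized with repr() (shortest round-trip form), so
# render -> parse -> render is byte-identical.

_XML_DECL = "<?xml version='1.0' encoding='utf-8'?>\n"


def _fmt(v: float) -> str:
    return repr(float(v))


def render_developer_xml(plan: MotionPlan) -> str:
    """Render ``plan`` as a schema-v1 XML control script (UTF-8 text)."""
    plan.validate()
    root = ET.Element("dynqaPlan", {"schemaVersion": SCHEMA_VERSION})
    for key in sorted(plan.metadata):
        ET.SubElement(root, "meta", {"key": key, "value": plan.metadata[key]})
    ET.SubElement(root, "reference",
                  {ax: _fmt(getattr(plan.reference, ax)) for ax in AXES})
    seq = ET.SubElement(root, "sequence")
    for step in plan.steps:
        cp = ET.SubElement(seq, "controlPoint", {
            "index": str(step.index),
            "gantry_deg": _fmt(step.gantry_deg),
            "acquireMv": "true" if step.acquire_mv else "false",
            "mu": _fmt(step.mu),
        })
        absolute = plan.reference + step.delta
        ET.SubElement(cp, "couch", {ax: _fmt(getattr(absolute, ax)) for ax in AXES})
    ET.indent(root)
    return _XML_DECL + ET.tostring(root, encoding="unicode") + "\n"


def _require(cond: bool, message: str, location: str | None = None) -> None:
    if not cond:
        raise ParseError(message, location)


def parse_developer_xml(doc: str) -> MotionPlan:
    """Parse a schema-v1 XML control script back into a :class:`MotionPlan`."""
    try:
        root = ET.fromstring(doc)
    except ET.ParseError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    _require(root.tag == "dynqaPlan", f"unknown root element <{root.tag}>", root.tag)
    _require(root.get("schemaVersion") == SCHEMA_VERSION,
             f"unsupported schema version {root.get('schemaVersion')!r}")

    metadata: dict[str, str] = {}
    reference: Pose6DoF | None = None
    raw_steps: list[tuple[int, Pose6DoF, float, bool, float]] = []

    for child in root:
        if child.tag == "meta":
            metadata[child.get("key", "")] = child.get("value", "")
        elif child.tag == "reference":
            reference = _parse_pose(child)
        elif child.tag == "sequence":
            for cp in child:
                _require(cp.tag == "controlPoint",
                         f"unknown element <{cp.tag}> in <sequence>", cp.tag)
                raw_steps.append(_parse_control_point(cp))
        else:
            raise ParseError(f"unknown element <{child.tag}>", child.tag)

    _require(reference is not None, "missing <reference> element")
    # control points carry absolute axis values; recover deltas
    try:
        steps = [
            MotionStep(index=idx, delta=absolute - reference, gantry_deg=gantry,
                       acquire_mv=acquire, mu=mu)
            for idx, absolute, gantry, acquire, mu in raw_steps
        ]
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc
    plan = MotionPlan(reference=reference, steps=steps, metadata=metadata)
    plan.validate()
    return plan


def _parse_pose(elem: ET.Element) -> Pose6DoF:
    values = {}
    for name, raw in elem.attrib.items():
        _require(name in AXES, f"unknown axis name {name!r}", elem.tag)
        values[name] = float(raw)
    _require(set(values) == set(AXES),
             f"<{elem.tag}> must carry all six axes, got {sorted(values)}", elem.tag)
    return Pose6DoF(**values)


def _parse_control_point(cp: ET.Element) -> tuple[int, Pose6DoF, float, bool, float]:
    couch = None
    for sub in cp:
        _require(sub.tag == "couch",
                 f"unknown element <{sub.tag}> in <controlPoint>", sub.tag)
        couch = _parse_pose(sub)
    _require(couch is not None, "controlPoint missing <couch>", cp.get("index"))
    try:
        return (
            int(cp.get("index")),
            couch,
            float(cp.get("gantry_deg")),
            {"true": True, "false": False}[cp.get("acquireMv")],
            float(cp.get("mu")),
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise ParseError(f"invalid controlPoint attributes: {exc}",
                         cp.get("index")) from exc
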