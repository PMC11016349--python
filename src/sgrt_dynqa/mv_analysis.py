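"""Ball-bearing detection in MV portal images and conversion to couch mm.

A single radio-opaque bb implanted in the phantom projects as a dark disc on
the portal imager.  Its center is located by matched filtering against a
projected-disc template followed by an intensity-weighted sub-pixel
centroid, and pixel displacements between each post-move image and the
reference image at the same gantry angle are scaled to millimetres at the
isocenter plane by the inverse magnification ``pixel_pitch * SAD / SID``.

Detector-orientation convention (validated end-to-end against the session
simulator; pixel (0, 0) is the top-left corner, row-major):

* gantry 0 (beam vertical): +column = +lateral, +row = +longitudinal;
  the vertical axis is along the beam and invisible.
* gantry 90 (beam horizontal): +column = +vertical, +row = +longitudinal;
  the lateral axis is along the beam and invisible.

Rotations are never estimated from images: one bb cannot constrain them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .errors import DetectionFailedError, UnsupportedGeometryError, ValidationError

__all__ = [
    "MVImage",
    "BBDetection",
    "ImageOffset",
    "detect_bb_center",
    "pixel_to_isocenter_mm",
    "compute_image_offsets",
    "detector_axes",
    "read_mv_image",
    "write_mv_image",
]

DEFAULT_SAD_MM = 1000.0
DEFAULT_SID_MM = 1500.0
DEFAULT_PIXEL_PITCH_MM = 0.336
DEFAULT_BB_DIAMETER_MM = 5.0

_GANTRY_MATCH_TOL_DEG = 1.0
_CORRELATION_FLOOR = 0.3


@dataclass
class MVImage:
    """An MV image plus the acquisition geometry needed to reach isocenter mm."""

    pixels: np.ndarray
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    sid_mm: float = DEFAULT_SID_MM
    sad_mm: float = DEFAULT_SAD_MM
    gantry_deg: float = 0.0
    step_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D array")
        if not (self.sid_mm >= self.sad_mm > 0):
            raise ValidationError(
                f"require SID >= SAD > 0, got SID={self.sid_mm}, SAD={self.sad_mm}")
        if self.pixel_pitch_mm <= 0:
            raise ValidationError("pixel_pitch_mm must be > 0")

    @property
    def magnification(self) -> float:
        """Projective magnification at the isocenter plane (SID / SAD)."""
        return self.sid_mm / self.sad_mm


@dataclass
class BBDetection:
    """Sub-pixel bb center in continuous pixel units plus a confidence score."""

    row_px: float
    col_px: float
    score: float

    def validate_in(self, img: MVImage) -> None:
        rows, cols = img.pixels.shape
        if not (0 <= self.row_px <= rows - 1 and 0 <= self.col_px <= cols - 1):
            raise ValidationError(
                f"detection ({self.row_px:.2f}, {self.col_px:.2f}) outside image")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1]")


@dataclass
class ImageOffset:
    """Measured couch-axis deltas (mm at isocenter) from one MV image.

    Exactly the two couch axes visible at the image's gantry angle are
    populated; the beam-axis component is unobservable in projection.
    """

    step_index: int
    axes: dict[str, float]

    def __post_init__(self):
        if len(self.axes) != 2:
            raise ValidationError(
                f"image offset for step {self.step_index} must populate exactly "
                f"two axes, got {sorted(self.axes)}")


def detector_axes(gantry_deg: float) -> tuple[str, str, str]:
    """Return (column axis, row axis, beam axis) couch-axis names for a gantry angle."""
    if abs(gantry_deg) <= _GANTRY_MATCH_TOL_DEG:
        return "lat_mm", "lng_mm", "vrt_mm"
    if abs(gantry_deg - 90.0) <= _GANTRY_MATCH_TOL_DEG:
        return "vrt_mm", "lng_mm", "lat_mm"
    raise UnsupportedGeometryError(
        f"gantry {gantry_deg} deg not supported (expected 0 or 90)")


def projected_disc_template(radius_px: float, *, depth: float = 1.0) -> np.ndarray:
    """Anti-aliased disc template: intensity falls linearly across a 1 px edge.

    The radial profile ``clip(r + 0.5 - d, 0, 1)`` is symmetric about the
    disc center, so the template's intensity-weighted centroid sits exactly
    at its geometric center.
    """
    half = int(math.ceil(radius_px)) + 2
    yy, xx = np.mgrid[-half: half + 1, -half: half + 1].astype(float)
    d = np.hypot(yy, xx)
    return depth * np.clip(radius_px + 0.5 - d, 0.0, 1.0)


def _normalized_correlation(signal: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation map of ``template`` over ``signal``.

    Computed with FFT convolutions.  The denominator (local signal spread
    times template spread) is floored at a small fraction of its maximum:
    in exactly-constant image regions both numerator and denominator cancel
    to rounding noise and an unfloored ratio produces spurious peaks.
    """
    t0 = template - template.mean()
    ss_t = float((t0 * t0).sum())
    ones = np.ones_like(template)
    cross = fftconvolve(signal, t0[::-1, ::-1], mode="same")
    s1 = fftconvolve(signal, ones, mode="same")
    s2 = fftconvolve(signal * signal, ones, mode="same")
    var = np.clip(s2 - s1 * s1 / template.size, 0.0, None)
    den = np.sqrt(var * ss_t)
    floor = 1e-6 * float(den.max())
    if floor <= 0:
        return np.zeros_like(signal)
    return cross / np.maximum(den, floor)


def detect_bb_center(
    img: MVImage,
    bb_diameter_mm: float = DEFAULT_BB_DIAMETER_MM,
    *,
    correlation_floor: float = _CORRELATION_FLOOR,
) -> BBDetection:
    """Locate the bb center to sub-pixel precision.

    The image is background-subtracted (median) and sign-flipped so the bb
    is a bright blob, matched against a projected-disc template (expected
    projected diameter ``bb_diameter_mm * SID / SAD``), and the best peak is
    refined by an intensity-weighted centroid over a window just larger than
    the disc.  Weights below 20% of the window peak are clipped to zero so
    background noise outside the disc cannot bias the centroid.

    Raises :class:`DetectionFailedError` when no candidate reaches
    ``correlation_floor`` — a QA run must flag a missing bb, never guess.
    """
    signal = np.median(img.pixels) - img.pixels.astype(float)
    if float(signal.std()) < 1e-12:
        raise DetectionFailedError("image is uniform; no bb candidate")

    radius_px = 0.5 * bb_diameter_mm * img.magnification / img.pixel_pitch_mm
    template = projected_disc_template(radius_px)
    if template.shape[0] > min(img.pixels.shape):
        raise DetectionFailedError(
            "expected bb projection larger than the image itself")

    ncc = _normalized_correlation(signal, template)
    peak = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    score = float(ncc[peak])
    if score < correlation_floor:
        raise DetectionFailedError(
            f"best template correlation {score:.3f} below floor "
            f"{correlation_floor:.3f}; no bb found")

    # sub-pixel refinement: clipped intensity-weighted centroid
    win = int(math.ceil(radius_px)) + 3
    r0, r1 = max(peak[0] - win, 0), min(peak[0] + win + 1, signal.shape[0])
    c0, c1 = max(peak[1] - win, 0), min(peak[1] + win + 1, signal.shape[1])
    window = signal[r0:r1, c0:c1]
    weights = np.clip(window - 0.2 * float(window.max()), 0.0, None)
    total = float(weights.sum())
    if total <= 0:
        raise DetectionFailedError("empty centroid window; no bb found")
    rows = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    row_px = float((weights.sum(axis=1) * rows).sum() / total)
    col_px = float((weights.sum(axis=0) * cols).sum() / total)

    det = BBDetection(row_px=row_px, col_px=col_px, score=min(max(score, 0.0), 1.0))
    det.validate_in(img)
    return det


def detect_bb_center_threshold(
    img: MVImage,
    bb_diameter_mm: float = DEFAULT_BB_DIAMETER_MM,
    *,
    fraction: float = 0.5,
) -> BBDetection:
    """Plain threshold-centroid fallback detector (no matched filter).

    Thresholds the background-subtracted signal at ``fraction`` of its peak
    and takes the intensity-weighted centroid of everything above it.  Used
    as an independent cross-check of :func:`detect_bb_center`; less robust
    to structured background.
    """
    signal = np.median(img.pixels) - img.pixels.astype(float)
    peak = float(signal.max())
    if peak <= 0 or float(signal.std()) < 1e-12:
        raise DetectionFailedError("image is uniform; no bb candidate")
    weights = np.clip(signal - fraction * peak, 0.0, None)
    total = float(weights.sum())
    rows = np.arange(signal.shape[0], dtype=float)
    cols = np.arange(signal.shape[1], dtype=float)
    return BBDetection(
        row_px=float((weights.sum(axis=1) * rows).sum() / total),
        col_px=float((weights.sum(axis=0) * cols).sum() / total),
        score=1.0,
    )


def pixel_to_isocenter_mm(delta_px, img: MVImage):
    """Scale a detector-plane pixel displacement to mm at the isocenter plane.

    ``delta_px * pixel_pitch_mm * SAD / SID`` — the inverse of the divergent
    beam's magnification.  When SID equals SAD the scale is exactly the
    pixel pitch.
    """
    return np.multiply(delta_px, img.pixel_pitch_mm * img.sad_mm / img.sid_mm)


def compute_image_offsets(
    references: list[tuple[MVImage, BBDetection]],
    measurements: list[tuple[MVImage, BBDetection]],
) -> list[ImageOffset]:
    """Convert bb displacements from reference into couch-axis mm.

    ``references`` holds one (image, detection) pair per gantry angle used;
    each measurement is compared against the reference acquired at the same
    gantry angle (within 1 degree).  Displacement is measurement minus
    reference, scaled by the inverse magnification and mapped onto the two
    couch axes visible at that gantry angle.
    """
    by_gantry: dict[str, tuple[MVImage, BBDetection]] = {}
    for img, det in references:
        key = detector_axes(img.gantry_deg)[0]
        by_gantry[key] = (img, det)

    offsets = []
    for img, det in measurements:
        col_axis, row_axis, _ = detector_axes(img.gantry_deg)
        if col_axis not in by_gantry:
            raise UnsupportedGeometryError(
                f"no reference image for gantry {img.gantry_deg} deg")
        ref_img, ref_det = by_gantry[col_axis]
        d_col = pixel_to_isocenter_mm(det.col_px - ref_det.col_px, img)
        d_row = pixel_to_isocenter_mm(det.row_px - ref_det.row_px, img)
        offsets.append(ImageOffset(
            step_index=img.step_index if img.step_index is not None else -1,
            axes={col_axis: float(d_col), row_axis: float(d_row)},
        ))
    return offsets


# ---------------------------------------------------------------------------
# image I/O: DICOM, and 16-bit PNG/TIFF with a geometry sidecar
# ---------------------------------------------------------------------------

_SIDECAR_FIELDS = ("pixel_pitch_mm", "sid_mm", "sad_mm", "gantry_deg", "step_index")


def read_mv_image(path, *, geometry: dict | None = None) -> MVImage:
    """Read an MV image from DICOM or 16-bit PNG/TIFF.

    For DICOM, RT-image geometry tags (RTImageSID, RadiationMachineSAD,
    ImagePlanePixelSpacing, GantryAngle) take precedence over defaults.  For
    PNG/TIFF a JSON sidecar ``<stem>.json`` next to the file (or an explicit
    ``geometry`` dict) supplies the geometry.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path), force=True)
        pixels = ds.pixel_array
        geo = dict(geometry or {})
        if "RTImageSID" in ds:
            geo.setdefault("sid_mm", float(ds.RTImageSID))
        if "RadiationMachineSAD" in ds:
            geo.setdefault("sad_mm", float(ds.RadiationMachineSAD))
        if "ImagePlanePixelSpacing" in ds:
            geo.setdefault("pixel_pitch_mm", float(ds.ImagePlanePixelSpacing[0]))
        if "GantryAngle" in ds:
            geo.setdefault("gantry_deg", float(ds.GantryAngle))
    else:
        import imageio.v3 as iio

        pixels = iio.imread(str(path))
        geo = dict(geometry or {})
        sidecar = path.with_suffix(".json")
        if not geo and sidecar.exists():
            geo = json.loads(sidecar.read_text())
    kwargs = {k: geo[k] for k in _SIDECAR_FIELDS if k in geo and geo[k] is not None}
    return MVImage(pixels=pixels, **kwargs)


def write_mv_image(img: MVImage, path) -> None:
    """Write a 16-bit PNG (pixels scaled to uint16) plus a geometry sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    pixels = np.asarray(img.pixels, dtype=float)
    scaled = np.clip(pixels, 0.0, 1.0) if pixels.max() <= 1.0 else pixels / pixels.max()
    iio.imwrite(str(path), (scaled * 65535.0 + 0.5).astype(np.uint16))
    sidecar = {
        "pixel_pitch_mm": img.pixel_pitch_mm,
        "sid_mm": img.sid_mm,
        "sad_mm": img.sad_mm,
        "gantry_deg": img.gantry_deg,
        "step_index": img.step_index,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")
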