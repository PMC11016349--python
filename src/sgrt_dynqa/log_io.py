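"""Readers and writers for trajectory and surface-imaging log dialects.

Machine trajectory logs record the expected and actual state of every linac
axis (6-DoF couch, gantry) plus cumulative monitor units on a uniform time
grid.  Surface-imaging logs record the monitored ROI's 6-DoF offset from the
reference capture, on the camera system's own (possibly irregular) clock,
and carry no beam-on flag.

Vendor trajectory logs are proprietary binary; this package defines an open
CSV interchange dialect instead (converters from binary formats are out of
scope).  Both dialects share the same layout::

    # dialect: sgrt-dynqa-trajlog      (or sgrt-dynqa-surflog)
    # version: 1
    # sample_interval_s: 0.02          (trajectory only)
    # <extra-key>: <value>             (free-form, preserved on round-trip)
    t,<column>,...
    0.000000,...

Values are written with six decimal places; round-trips are therefore exact
to 1e-6.  Unknown extra columns are preserved and written back verbatim.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .motion_plan import AXES, Pose6DoF

__all__ = [
    "TrajectoryLog",
    "SurfaceLog",
    "parse_trajectory_log",
    "write_trajectory_log",
    "parse_surface_log",
    "write_surface_log",
]

logger = logging.getLogger(__name__)

TRAJ_DIALECT = "sgrt-dynqa-trajlog"
SURF_DIALECT = "sgrt-dynqa-surflog"
DIALECT_VERSION = "1"

#: machine axes logged as expected/actual pairs
MACHINE_AXES = AXES + ("gantry_deg",)
TRAJ_COLUMNS = tuple(
    f"{ax}_{kind}" for ax in MACHINE_AXES for kind in ("expected", "actual")
) + ("mu",)
SURF_COLUMNS = AXES

_GRID_TOL_S = 5e-6  # written timestamps are only good to 1e-6


def _pose_series(df: pd.DataFrame, columns) -> np.ndarray:
    return df.loc[:, list(columns)].to_numpy(dtype=float)


@dataclass
class TrajectoryLog:
    """Uniformly sampled expected/actual linac axis series plus cumulative MU."""

    sample_interval_s: float
    data: pd.DataFrame  # columns: t + TRAJ_COLUMNS (+ extras)
    meta: dict[str, str] = field(default_factory=dict)
    extra_columns: tuple[str, ...] = ()

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(dtype=float)

    @property
    def mu(self) -> np.ndarray:
        return self.data["mu"].to_numpy(dtype=float)

    def expected(self) -> np.ndarray:
        """(n, 6) couch expected series in canonical axis order."""
        return _pose_series(self.data, (f"{ax}_expected" for ax in AXES))

    def actual(self) -> np.ndarray:
        """(n, 6) couch actual series in canonical axis order."""
        return _pose_series(self.data, (f"{ax}_actual" for ax in AXES))

    def gantry_expected(self) -> np.ndarray:
        return self.data["gantry_deg_expected"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        for col in ("t",) + TRAJ_COLUMNS:
            if col not in self.data.columns:
                raise ValidationError(f"trajectory log missing mandatory column {col!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"NaN sample at row {i}, column {self.data.columns[j]!r}"
            )
        if not math.isfinite(self.sample_interval_s) or self.sample_interval_s <= 0:
            raise ValidationError("sample_interval_s must be finite and > 0")
        t = self.t
        if len(t) > 1:
            if np.any(np.diff(t) <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            grid = t[0] + np.arange(len(t)) * self.sample_interval_s
            if np.max(np.abs(t - grid)) > _GRID_TOL_S:
                raise ValidationError(
                    "timestamps must be uniform at the declared sample interval"
                )
            if np.any(np.diff(self.mu) < 0):
                raise ValidationError("cumulative mu must be non-decreasing")


@dataclass
class SurfaceLog:
    """Surface 6-DoF offsets from the reference capture, possibly non-uniform."""

    data: pd.DataFrame  # columns: t + SURF_COLUMNS (+ extras)
    meta: dict[str, str] = field(default_factory=dict)
    extra_columns: tuple[str, ...] = ()

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(dtype=float)

    def offsets(self) -> np.ndarray:
        """(n, 6) surface offset series in canonical axis order."""
        return _pose_series(self.data, SURF_COLUMNS)

    def offset_at(self, i: int) -> Pose6DoF:
        return Pose6DoF.from_array(self.offsets()[i])

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        for col in ("t",) + SURF_COLUMNS:
            if col not in self.data.columns:
                raise ValidationError(f"surface log missing mandatory column {col!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"NaN sample at row {i}, column {self.data.columns[j]!r}"
            )
        if len(self.data) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")


# ---------------------------------------------------------------------------
# dialect plumbing
# ---------------------------------------------------------------------------

def _read_header(stream) -> tuple[dict[str, str], str]:
    """Consume ``# key: value`` lines; return (header, first non-header line)."""
    header: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                raise ParseError("header line is not 'key: value'", f"line {lineno}")
            key, _, value = body.partition(":")
            header[key.strip()] = value.strip()
        else:
            return header, line
    return header, ""


def _as_stream(stream) -> io.StringIO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def _parse_csv_body(columns_line: str, stream, mandatory, what: str):
    if not columns_line:
        raise ParseError(f"{what}: missing column header line")
    columns = [c.strip() for c in columns_line.split(",")]
    missing = [c for c in ("t",) + tuple(mandatory) if c not in columns]
    if missing:
        raise ParseError(f"{what}: missing mandatory axis column(s) {missing}")
    body = stream.read()
    if body.strip():
        df = pd.read_csv(io.StringIO(columns_line + "\n" + body),
                         dtype=float, skip_blank_lines=True)
    else:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in columns})
    return df, columns


def _check_dialect(header: dict[str, str], dialect: str, what: str) -> None:
    if header.get("dialect") != dialect:
        raise ParseError(
            f"{what}: expected dialect {dialect!r}, got {header.get('dialect')!r}"
        )
    if header.get("version") != DIALECT_VERSION:
        raise ParseError(
            f"{what}: unsupported dialect version {header.get('version')!r}"
        )


def parse_trajectory_log(stream) -> TrajectoryLog:
    """Parse the trajectory-log CSV dialect from a string or text stream."""
    stream = _as_stream(stream)
    header, columns_line = _read_header(stream)
    _check_dialect(header, TRAJ_DIALECT, "trajectory log")
    if "sample_interval_s" not in header:
        raise ParseError("trajectory log: header missing sample_interval_s")
    interval = float(header["sample_interval_s"])
    df, columns = _parse_csv_body(columns_line, stream, TRAJ_COLUMNS, "trajectory log")
    extras = tuple(c for c in columns if c != "t" and c not in TRAJ_COLUMNS)
    meta = {k: v for k, v in header.items()
            if k not in ("dialect", "version", "sample_interval_s")}
    log = TrajectoryLog(sample_interval_s=interval, data=df, meta=meta,
                        extra_columns=extras)
    log.validate()
    if len(df) > 1:
        # snap written (6-decimal) timestamps back onto the exact grid
        df["t"] = df["t"].iloc[0] + np.arange(len(df)) * interval
    return log


def parse_surface_log(stream) -> SurfaceLog:
    """Parse the surface-log CSV dialect.

    Beam-state columns are not part of the dialect (surface systems predating
    beam-flag support cannot produce them); if one is present it is dropped
    with a warning rather than rejected.
    """
    stream = _as_stream(stream)
    header, columns_line = _read_header(stream)
    _check_dialect(header, SURF_DIALECT, "surface log")
    df, columns = _parse_csv_body(columns_line, stream, SURF_COLUMNS, "surface log")
    beamish = [c for c in columns if "beam" in c.lower()]
    if beamish:
        logger.warning(
            "surface log contains beam-state column(s) %s; "
            "the dialect has no beam-on flag, ignoring them", beamish)
        df = df.drop(columns=beamish)
        columns = [c for c in columns if c not in beamish]
    extras = tuple(c for c in columns if c != "t" and c not in SURF_COLUMNS)
    meta = {k: v for k, v in header.items() if k not in ("dialect", "version")}
    log = SurfaceLog(data=df, meta=meta, extra_columns=extras)
    log.validate()
    return log


def _write_common(header_pairs, df: pd.DataFrame, columns) -> str:
    lines = [f"# {k}: {v}" for k, v in header_pairs]
    lines.append(",".join(columns))
    if len(df):
        body = df.loc[:, list(columns)].to_csv(
            index=False, header=False, float_format="%.6f")
        lines.append(body.rstrip("\n"))
    return "\n".join(lines) + "\n"


def write_trajectory_log(log: TrajectoryLog) -> str:
    """Serialize a valid :class:`TrajectoryLog` to canonical dialect-v1 text."""
    log.validate()
    header = [("dialect", TRAJ_DIALECT), ("version", DIALECT_VERSION),
              ("sample_interval_s", repr(float(log.sample_interval_s)))]
    header += sorted(log.meta.items())
    columns = ("t",) + TRAJ_COLUMNS + tuple(log.extra_columns)
    return _write_common(header, log.data, columns)


def write_surface_log(log: SurfaceLog) -> str:
    """Serialize a valid :class:`SurfaceLog` to canonical dialect-v1 text."""
    log.validate()
    header = [("dialect", SURF_DIALECT), ("version", DIALECT_VERSION)]
    header += sorted(log.meta.items())
    columns = ("t",) + SURF_COLUMNS + tuple(log.extra_columns)
    return _write_common(header, log.data, columns)
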