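"""Gaze-table and geometry I/O.

Gaze recordings are plain delimited text (tab by default, comma accepted)
with one row per eye-tracker sample.  Screen coordinates are converted to
degrees of visual angle per axis via the arctangent of the physical offset
from screen centre over the viewing distance; the screen centre is the
angular origin, x positive rightward and y positive downward, matching the
screen-pixel convention.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class GazeFormatError(ValueError):
    """Input table does not have the expected columns or shape."""


class GazeDataError(ValueError):
    """Input table is structurally fine but the data violate a contract."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used for pixel <-> degree conversion.

    All distances in millimetres, resolution in pixels.  The pixel and
    physical aspect ratios must agree within 5% (square pixels).
    """

    width_px: int
    height_px: int
    width_mm: float
    height_mm: float
    viewing_distance_mm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm",
                     "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        aspect_px = self.width_px / self.height_px
        aspect_mm = self.width_mm / self.height_mm
        if abs(aspect_px / aspect_mm - 1.0) > 0.05:
            raise ValueError(
                "pixel and physical aspect ratios differ by more than 5%")

    @property
    def mm_per_px_x(self) -> float:
        return self.width_mm / self.width_px

    @property
    def mm_per_px_y(self) -> float:
        return self.height_mm / self.height_px

    def px_to_deg(self, x_px, y_px):
        """Convert pixel coordinates to degrees of visual angle.

        The screen centre maps to (0, 0); conversion is exact (per-axis
        arctangent), not the small-angle approximation.
        """
        dx_mm = (np.asarray(x_px, dtype=float) - self.width_px / 2.0) * self.mm_per_px_x
        dy_mm = (np.asarray(y_px, dtype=float) - self.height_px / 2.0) * self.mm_per_px_y
        x_deg = np.degrees(np.arctan2(dx_mm, self.viewing_distance_mm))
        y_deg = np.degrees(np.arctan2(dy_mm, self.viewing_distance_mm))
        return x_deg, y_deg

    def deg_to_px(self, x_deg, y_deg):
        """Inverse of :meth:`px_to_deg` (exact)."""
        dx_mm = np.tan(np.radians(np.asarray(x_deg, dtype=float))) * self.viewing_distance_mm
        dy_mm = np.tan(np.radians(np.asarray(y_deg, dtype=float))) * self.viewing_distance_mm
        x_px = dx_mm / self.mm_per_px_x + self.width_px / 2.0
        y_px = dy_mm / self.mm_per_px_y + self.height_px / 2.0
        return x_px, y_px


#: A plausible desktop eye-tracking setup.  The original study reports no
#: screen geometry, so this is a fixture, not a reconstruction.
DEFAULT_SCREEN = ScreenGeometry(
    width_px=1920, height_px=1080,
    width_mm=510.0, height_mm=287.0,
    viewing_distance_mm=600.0,
)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in degrees; containment is boundary-inclusive."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("rectangle must be non-empty")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x <= self.x_max) & \
               (y >= self.y_min) & (y <= self.y_max)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0,
                (self.y_min + self.y_max) / 2.0)

    def overlaps(self, other: "Rect") -> bool:
        return not (self.x_max < other.x_min or other.x_max < self.x_min or
                    self.y_max < other.y_min or other.y_max < self.y_min)


@dataclass(frozen=True)
class AOISet:
    """The two cued facial regions, as abstract rectangles in degrees."""

    eyes: Rect
    mouth: Rect

    def __post_init__(self) -> None:
        if self.eyes.overlaps(self.mouth):
            raise ValueError("eyes and mouth AOIs must not overlap")


@dataclass
class GazeRecording:
    """A monocular (or eye-averaged) gaze sample stream in degrees.

    ``t`` is seconds from recording start and must be strictly increasing;
    invalid samples carry NaN coordinates.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise GazeDataError("t, x, y, valid must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise GazeDataError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def slice_time(self, t0: float, t1: float) -> "GazeRecording":
        """Samples with t0 <= t < t1, timestamps kept on the original clock."""
        m = (self.t >= t0) & (self.t < t1)
        return GazeRecording(self.t[m], self.x[m], self.y[m], self.valid[m],
                             self.rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x_deg": self.x, "y_deg": self.y,
                             "valid": self.valid.astype(int)})


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    import csv
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise GazeFormatError(f"{path}: empty or malformed file") from exc
    if df.empty:
        raise GazeFormatError(f"{path}: no data rows")
    return df


def read_gaze_table(path, geometry: ScreenGeometry | None = None,
                    sampling_rate: float = 120.0) -> GazeRecording:
    """Read a delimited gaze sample table.

    The table must contain ``t`` and ``valid`` plus either pixel columns
    (``x_px``, ``y_px``; requires *geometry*) or degree columns (``x_deg``,
    ``y_deg``).  Pixel coordinates are converted to degrees relative to the
    screen centre.
    """
    if sampling_rate not in (60, 120, 1200):
        raise ValueError(f"unsupported sampling rate: {sampling_rate}")
    df = _read_delimited(path)
    cols = set(df.columns)
    if not {"t", "valid"} <= cols:
        raise GazeFormatError(f"{path}: missing required columns t, valid")
    if {"x_deg", "y_deg"} <= cols:
        x, y = df["x_deg"].to_numpy(float), df["y_deg"].to_numpy(float)
    elif {"x_px", "y_px"} <= cols:
        if geometry is None:
            raise GazeFormatError(
                f"{path}: pixel coordinates require a screen geometry")
        x, y = geometry.px_to_deg(df["x_px"].to_numpy(float),
                                  df["y_px"].to_numpy(float))
    else:
        raise GazeFormatError(
            f"{path}: need x_deg/y_deg or x_px/y_px columns")
    t = df["t"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise GazeDataError(f"{path}: non-monotone timestamps")
    valid = df["valid"].to_numpy().astype(bool)
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeRecording(t, x, y, valid, float(sampling_rate))


def write_gaze_table(recording: GazeRecording, path, sep: str = "\t") -> None:
    recording.to_frame().to_csv(path, sep=sep, index=False)


_EVENT_COLUMNS = ["kind", "onset", "offset", "amplitude", "peak_velocity"]


def write_events(events, path, precision: int = 9) -> None:
    """Write detected oculomotor events as a CSV table.

    Round-trips losslessly with :func:`read_events` at the declared
    precision.  An empty event list yields a header-only file.
    """
    rows = [{"kind": e.kind, "onset": e.onset, "offset": e.offset,
             "amplitude": e.amplitude, "peak_velocity": e.peak_velocity}
            for e in events]
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df.to_csv(path, index=False, float_format=f"%.{precision}g")


def read_events(path):
    from .ivt import OculomotorEvent  # local import to avoid a cycle
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise GazeFormatError(f"{path}: missing event columns {sorted(missing)}")
    return [OculomotorEvent(kind=r.kind, onset=r.onset, offset=r.offset,
                            amplitude=r.amplitude,
                            peak_velocity=r.peak_velocity)
            for r in df.itertuples()]


def load_aoi_config(path) -> tuple[AOISet, ScreenGeometry | None]:
    """Load AOI rectangles (degrees) and optional screen geometry from JSON."""
    with open(path) as fh:
        cfg = json.load(fh)
    try:
        aois = AOISet(eyes=Rect(**cfg["eyes"]), mouth=Rect(**cfg["mouth"]))
    except KeyError as exc:
        raise GazeFormatError(f"{path}: missing AOI key {exc}") from exc
    screen = ScreenGeometry(**cfg["screen"]) if "screen" in cfg else None
    return aois, screen


def save_aoi_config(aois: AOISet, path,
                    screen: ScreenGeometry | None = None) -> None:
    cfg = {"eyes": vars(aois.eyes), "mouth": vars(aois.mouth)}
    if screen is not None:
        cfg["screen"] = vars(screen)
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2)
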