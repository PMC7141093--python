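"""Gaze-data domain model.

Types and operations for one subject's gaze recording in video pixel
coordinates: parsing delimited text with a configurable column layout,
aligning sample times to video frames, and dispersion-threshold (I-DT)
fixation/saccade classification.

Conventions
-----------
* Coordinates are video pixels, origin top-left, x rightward, y downward,
  0-based, in the same space as the video resolution.
* Time is seconds as float, relative to video start.  Frame display
  intervals are half-open ``[start, end)`` so every instant belongs to
  exactly one frame.
"""

from __future__ import annotations

import configparser
import csv
import io
import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional, Sequence

__all__ = [
    "GazeSample",
    "GazeTrajectory",
    "ObjectAnnotation",
    "VideoMeta",
    "ColumnSpec",
    "GazeParseError",
    "parse_gaze",
    "write_gaze",
    "frame_index",
    "frame_interval",
    "classify_events",
    "write_config",
    "read_config",
]

FIXATION = "fixation"
SACCADE = "saccade"

TIME_UNITS = ("seconds", "milliseconds", "microseconds", "sample_index")


class GazeParseError(ValueError):
    """Raised for malformed gaze text input; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class GazeSample:
    """One gaze measurement.

    ``t`` is seconds relative to video start; ``x``/``y`` the point of
    regard in video pixels; ``pupil`` an optional relative pupil size in
    arbitrary units; ``label`` an optional event tag (``"fixation"``,
    ``"saccade"`` or ``None``).
    """

    t: float
    x: float
    y: float
    pupil: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self):
        if self.t < 0:
            raise ValueError(f"sample time must be >= 0, got {self.t}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"sample coordinates must be finite, got ({self.x}, {self.y})")

    def is_offscreen(self, video: "VideoMeta") -> bool:
        """Whether the sample lies outside the video frame (kept, but flagged)."""
        return not (0 <= self.x < video.width and 0 <= self.y < video.height)


@dataclass
class GazeTrajectory:
    """Time-ordered gaze samples of one subject."""

    subject_id: str
    samples: list[GazeSample]
    sampling_rate: float

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        for i in range(1, len(self.samples)):
            if self.samples[i].t <= self.samples[i - 1].t:
                raise ValueError(
                    "sample times must be strictly increasing; "
                    f"t[{i - 1}]={self.samples[i - 1].t} >= t[{i}]={self.samples[i].t}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.samples[-1].t - self.samples[0].t if self.samples else 0.0

    def offscreen_mask(self, video: "VideoMeta") -> list[bool]:
        return [s.is_offscreen(video) for s in self.samples]


Geometry = tuple  # rectangle: (x, y, w, h); polygon: tuple of (x, y) vertices


@dataclass
class ObjectAnnotation:
    """A named object with timed geometry intervals.

    Each interval is ``(t_start, t_end, geometry)`` where geometry is either
    a rectangle ``(x, y, width, height)`` or a polygon (sequence of >= 3
    ``(x, y)`` vertices), in video pixels.  Geometry is constant within an
    interval; motion is expressed as a sequence of intervals.
    """

    object_id: str
    intervals: list[tuple[float, float, Geometry]]

    def __post_init__(self):
        for t0, t1, geom in self.intervals:
            if not t0 < t1:
                raise ValueError(f"annotation interval must have t_start < t_end, got [{t0}, {t1})")
            if geometry_kind(geom) == "polygon" and len(geom) < 3:
                raise ValueError("polygon needs >= 3 vertices")


def geometry_kind(geom: Geometry) -> str:
    """Classify an annotation geometry as ``"rectangle"`` or ``"polygon"``."""
    if len(geom) == 4 and all(isinstance(v, (int, float)) for v in geom):
        return "rectangle"
    return "polygon"


@dataclass(frozen=True)
class VideoMeta:
    """Resolution and frame rate of the stimulus video."""

    width: int
    height: int
    fps: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0 or self.fps <= 0:
            raise ValueError("width, height and fps must all be > 0")


@dataclass(frozen=True)
class ColumnSpec:
    """Layout of a delimited gaze text file.

    Eye trackers disagree on header length, delimiter, column order and
    timestamp unit, so all of it is declared here rather than guessed.
    ``time_unit`` is one of ``seconds``, ``milliseconds``, ``microseconds``
    or ``sample_index`` (timestamp column holds the running sample number,
    converted to seconds by dividing by the sampling rate).
    """

    header_lines: int = 0
    delimiter: str = ","
    t_col: int = 0
    x_col: int = 1
    y_col: int = 2
    pupil_col: Optional[int] = None
    label_col: Optional[int] = None
    time_unit: str = "seconds"

    def __post_init__(self):
        if self.header_lines < 0:
            raise ValueError("header_lines must be >= 0")
        cols = [self.t_col, self.x_col, self.y_col]
        cols += [c for c in (self.pupil_col, self.label_col) if c is not None]
        if len(set(cols)) != len(cols):
            raise ValueError(f"column indices must be distinct, got {cols}")
        if any(c < 0 for c in cols):
            raise ValueError("column indices must be >= 0")
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"time_unit must be one of {TIME_UNITS}, got {self.time_unit!r}")


_TIME_SCALE = {"seconds": 1.0, "milliseconds": 1e-3, "microseconds": 1e-6}


def parse_gaze(
    stream: IO[str] | str,
    spec: ColumnSpec,
    sampling_rate: float,
    subject_id: str = "subject",
) -> GazeTrajectory:
    """Parse delimited gaze text into a :class:`GazeTrajectory`.

    ``stream`` is a text stream or a string.  Header lines are skipped per
    ``spec.header_lines``; empty lines are ignored.  Timestamps are converted
    to seconds according to ``spec.time_unit``.  Malformed rows raise
    :class:`GazeParseError` naming the 1-based line number; non-monotonic
    timestamps raise an error listing the first offending pair.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream, delimiter=spec.delimiter)
    samples: list[GazeSample] = []
    needed = max(
        c for c in (spec.t_col, spec.x_col, spec.y_col, spec.pupil_col, spec.label_col)
        if c is not None
    )
    for lineno, row in enumerate(reader, start=1):
        if lineno <= spec.header_lines:
            continue
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) <= needed:
            raise GazeParseError(
                f"expected at least {needed + 1} columns, got {len(row)}", lineno
            )
        try:
            raw_t = float(row[spec.t_col])
            x = float(row[spec.x_col])
            y = float(row[spec.y_col])
        except ValueError as exc:
            raise GazeParseError(f"non-numeric field ({exc})", lineno) from None
        if spec.time_unit == "sample_index":
            t = raw_t / sampling_rate
        else:
            t = raw_t * _TIME_SCALE[spec.time_unit]
        pupil = None
        if spec.pupil_col is not None:
            try:
                pupil = float(row[spec.pupil_col])
            except ValueError:
                raise GazeParseError("non-numeric pupil field", lineno) from None
        label = None
        if spec.label_col is not None:
            raw = row[spec.label_col].strip().lower()
            if raw in (FIXATION, SACCADE):
                label = raw
            elif raw not in ("", "none"):
                raise GazeParseError(f"unknown event label {raw!r}", lineno)
        try:
            samples.append(GazeSample(t=t, x=x, y=y, pupil=pupil, label=label))
        except ValueError as exc:
            raise GazeParseError(str(exc), lineno) from None
        if len(samples) >= 2 and samples[-1].t <= samples[-2].t:
            raise GazeParseError(
                "timestamps not strictly increasing: "
                f"t={samples[-2].t} followed by t={samples[-1].t}",
                lineno,
            )
    return GazeTrajectory(subject_id=subject_id, samples=samples, sampling_rate=sampling_rate)


def write_gaze(traj: GazeTrajectory, stream: IO[str], precision: int = 6) -> None:
    """Write a trajectory as canonical CSV: header ``t,x,y[,pupil][,label]``.

    Times are in seconds.  ``parse_gaze`` of the output (header_lines=1,
    matching optional columns) reproduces sample values to ``precision``
    decimals.
    """
    has_pupil = any(s.pupil is not None for s in traj.samples)
    has_label = any(s.label is not None for s in traj.samples)
    cols = ["t", "x", "y"] + (["pupil"] if has_pupil else []) + (["label"] if has_label else [])
    stream.write(",".join(cols) + "\n")
    fmt = f"%.{precision}f"
    for s in traj.samples:
        row = [fmt % s.t, fmt % s.x, fmt % s.y]
        if has_pupil:
            row.append(fmt % s.pupil if s.pupil is not None else "")
        if has_label:
            row.append(s.label or "none")
        stream.write(",".join(row) + "\n")


def canonical_spec(has_pupil: bool = False, has_label: bool = False) -> ColumnSpec:
    """ColumnSpec matching :func:`write_gaze` output."""
    return ColumnSpec(
        header_lines=1,
        delimiter=",",
        t_col=0,
        x_col=1,
        y_col=2,
        pupil_col=3 if has_pupil else None,
        label_col=(4 if has_pupil else 3) if has_label else None,
        time_unit="seconds",
    )


def frame_index(t: float, video: VideoMeta) -> int:
    """Index n of the frame whose half-open display interval contains t.

    Guarantees ``n/fps <= t < (n+1)/fps`` under float comparison, so the
    frame intervals tile ``[0, inf)`` exactly.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    n = int(math.floor(t * video.fps))
    # repair float rounding so the half-open invariant holds exactly
    while n > 0 and t < n / video.fps:
        n -= 1
    while t >= (n + 1) / video.fps:
        n += 1
    return n


def frame_interval(t: float, video: VideoMeta) -> tuple[float, float]:
    """Half-open display interval ``[n/fps, (n+1)/fps)`` containing t."""
    n = frame_index(t, video)
    return (n / video.fps, (n + 1) / video.fps)


def _dispersion(xs: Sequence[float], ys: Sequence[float]) -> float:
    return (max(xs) - min(xs)) + (max(ys) - min(ys))


def classify_events(
    traj: GazeTrajectory,
    dispersion_px: float,
    min_duration_s: float,
    overwrite: bool = True,
) -> GazeTrajectory:
    """Label samples fixation/saccade with the I-DT dispersion algorithm.

    Maximal windows whose dispersion ``(max x - min x) + (max y - min y)``
    stays within ``dispersion_px`` and that last at least ``min_duration_s``
    are labeled ``"fixation"``; all remaining samples ``"saccade"``.
    Pre-existing labels are kept unless ``overwrite`` is true.

    Recommended artifact defaults: ``dispersion_px = 0.02 * max(width,
    height)`` of the stimulus and ``min_duration_s = 0.1``.
    """
    if not traj.samples:
        raise ValueError("trajectory is empty")
    if dispersion_px <= 0 or min_duration_s <= 0:
        raise ValueError("dispersion_px and min_duration_s must be > 0")

    n = len(traj.samples)
    ts = [s.t for s in traj.samples]
    xs = [s.x for s in traj.samples]
    ys = [s.y for s in traj.samples]
    labels = [SACCADE] * n

    start = 0
    while start < n:
        # grow the candidate window to minimum duration
        end = start  # inclusive
        while end + 1 < n and ts[end] - ts[start] < min_duration_s:
            end += 1
        if ts[end] - ts[start] < min_duration_s:
            break  # tail too short for any further fixation
        if _dispersion(xs[start : end + 1], ys[start : end + 1]) <= dispersion_px:
            while end + 1 < n and _dispersion(xs[start : end + 2], ys[start : end + 2]) <= dispersion_px:
                end += 1
            for i in range(start, end + 1):
                labels[i] = FIXATION
            start = end + 1
        else:
            start += 1

    new_samples = []
    for s, lab in zip(traj.samples, labels):
        if overwrite or s.label is None:
            new_samples.append(replace(s, label=lab))
        else:
            new_samples.append(s)
    return GazeTrajectory(traj.subject_id, new_samples, traj.sampling_rate)


# ---------------------------------------------------------------------------
# key-value config (ColumnSpec + VideoMeta)

def write_config(path, spec: ColumnSpec, video: VideoMeta) -> None:
    cp = configparser.ConfigParser()
    cp["columns"] = {
        "header_lines": str(spec.header_lines),
        # escaped so whitespace delimiters (tab) survive configparser stripping
        "delimiter": spec.delimiter.encode("unicode_escape").decode("ascii"),
        "t_col": str(spec.t_col),
        "x_col": str(spec.x_col),
        "y_col": str(spec.y_col),
        "pupil_col": "" if spec.pupil_col is None else str(spec.pupil_col),
        "label_col": "" if spec.label_col is None else str(spec.label_col),
        "time_unit": spec.time_unit,
    }
    cp["video"] = {"width": str(video.width), "height": str(video.height), "fps": repr(video.fps)}
    with open(path, "w", encoding="utf-8") as fh:
        cp.write(fh)


def read_config(path) -> tuple[ColumnSpec, VideoMeta]:
    cp = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        cp.read_file(fh)
    c = cp["columns"]
    spec = ColumnSpec(
        header_lines=c.getint("header_lines"),
        delimiter=c.get("delimiter").encode("ascii").decode("unicode_escape"),
        t_col=c.getint("t_col"),
        x_col=c.getint("x_col"),
        y_col=c.getint("y_col"),
        pupil_col=c.getint("pupil_col") if c.get("pupil_col") else None,
        label_col=c.getint("label_col") if c.get("label_col") else None,
        time_unit=c.get("time_unit"),
    )
    v = cp["video"]
    video = VideoMeta(width=v.getint("width"), height=v.getint("height"), fps=v.getfloat("fps"))
    return spec, video
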