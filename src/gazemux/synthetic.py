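"""Seeded generators for every input the toolchain consumes.

Tests and demos run without downloads: gaze trajectories with known
fixation/saccade structure, moving object annotations, EEG with a
controlled alpha-burst schedule, and a procedural stimulus video.  Every
generator is fully deterministic under its seed and returns its ground
truth so recovery tests can score against it.

Realism is limited to what the exchange format and detection code need:
fixations are Gaussian jitter around a fixed point, saccades are linear
interpolation between fixation centers (no main-sequence velocity
profile), pupil size is a smooth reflected random walk.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import GazeSample, GazeTrajectory, ObjectAnnotation, VideoMeta
from .sonification import EEGTrace

__all__ = [
    "GazeGenSpec",
    "GroundTruthSegment",
    "gen_gaze",
    "gen_annotations",
    "gen_eeg",
    "gen_video",
]


@dataclass
class GazeGenSpec:
    """Parameters of one synthetic gaze recording.

    Defaults emulate a 250 Hz eye tracker watching a standard-definition
    stimulus: 5 fixations of 0.2–0.4 s with 1 px jitter SD (typical video
    pixel noise), separated by 20–80 ms saccades.
    """

    n_fixations: int = 5
    fixation_duration_s: tuple[float, float] = (0.2, 0.4)
    saccade_duration_s: tuple[float, float] = (0.02, 0.08)
    dispersion_px: float = 1.0  # within-fixation jitter SD
    sampling_rate: float = 250.0
    video: VideoMeta = field(default_factory=lambda: VideoMeta(640, 480, 25.0))
    with_pupil: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_fixations < 0 or self.sampling_rate <= 0 or self.dispersion_px <= 0:
            raise ValueError("generator parameters must be positive")


@dataclass(frozen=True)
class GroundTruthSegment:
    kind: str  # fixation | saccade
    t_start: float
    t_end: float
    center: Optional[tuple[float, float]] = None


def gen_gaze(spec: GazeGenSpec) -> tuple[GazeTrajectory, list[GroundTruthSegment]]:
    """Generate an alternating fixation/saccade trajectory plus ground truth.

    Samples sit on the uniform 1/rate clock; each segment contributes
    ``round(duration * rate)`` samples.  Fixation samples are the segment
    center plus isotropic Gaussian jitter; saccade samples interpolate
    linearly between consecutive centers.  Pupil size (arbitrary units
    around 1000) follows a smooth reflected random walk.
    """
    rng = np.random.default_rng(spec.seed)
    v = spec.video
    margin = 0.1
    centers = [
        (rng.uniform(margin * v.width, (1 - margin) * v.width),
         rng.uniform(margin * v.height, (1 - margin) * v.height))
        for _ in range(spec.n_fixations)
    ]
    dt = 1.0 / spec.sampling_rate
    samples: list[GazeSample] = []
    truth: list[GroundTruthSegment] = []
    k = 0  # global sample index
    pupil = 1000.0
    for i, center in enumerate(centers):
        if i > 0:
            dur = rng.uniform(*spec.saccade_duration_s)
            n = max(1, round(dur * spec.sampling_rate))
            t0 = k * dt
            prev = centers[i - 1]
            for j in range(n):
                u = (j + 1) / (n + 1)
                x = prev[0] + u * (center[0] - prev[0])
                y = prev[1] + u * (center[1] - prev[1])
                pupil = _walk_pupil(pupil, rng)
                samples.append(GazeSample(k * dt, x, y,
                                          pupil=pupil if spec.with_pupil else None))
                k += 1
            truth.append(GroundTruthSegment("saccade", t0, k * dt))
        dur = rng.uniform(*spec.fixation_duration_s)
        n = max(1, round(dur * spec.sampling_rate))
        t0 = k * dt
        jitter = rng.normal(0.0, spec.dispersion_px, size=(n, 2))
        for j in range(n):
            pupil = _walk_pupil(pupil, rng)
            samples.append(GazeSample(k * dt, center[0] + jitter[j, 0],
                                      center[1] + jitter[j, 1],
                                      pupil=pupil if spec.with_pupil else None))
            k += 1
        truth.append(GroundTruthSegment("fixation", t0, k * dt, center=center))
    traj = GazeTrajectory(f"sim{spec.seed}", samples, spec.sampling_rate)
    return traj, truth


def _walk_pupil(p: float, rng, sd: float = 1.5, lo: float = 600.0, hi: float = 1400.0) -> float:
    p = p + rng.normal(0.0, sd)
    if p < lo:
        p = lo + (lo - p)
    elif p > hi:
        p = hi - (p - hi)
    return p


def gen_annotations(
    video: VideoMeta,
    n_objects: int,
    seed: int,
    duration_s: float = 2.0,
) -> list[ObjectAnnotation]:
    """Moving bounding boxes and polygons, clipped to the frame.

    Each object moves piecewise-linearly between random waypoints; its
    geometry is sampled at each video frame midpoint, yielding one
    per-frame interval so the annotation aligns exactly with the frame
    grid.  Even-indexed objects are rectangles, odd ones triangles.
    """
    rng = np.random.default_rng(seed)
    n_frames = max(1, round(duration_s * video.fps))
    out = []
    for obj in range(n_objects):
        w = rng.uniform(0.05, 0.2) * video.width
        h = rng.uniform(0.05, 0.2) * video.height
        n_way = 4
        way = np.column_stack([
            rng.uniform(0, video.width - w, n_way),
            rng.uniform(0, video.height - h, n_way),
        ])
        way_t = np.linspace(0.0, duration_s, n_way)
        intervals = []
        for f in range(n_frames):
            t0, t1 = f / video.fps, (f + 1) / video.fps
            tm = min(0.5 * (t0 + t1), duration_s)
            x = float(np.interp(tm, way_t, way[:, 0]))
            y = float(np.interp(tm, way_t, way[:, 1]))
            if obj % 2 == 0:
                geom = (x, y, w, h)
            else:
                geom = ((x, y + h), (x + w / 2, y), (x + w, y + h))
            intervals.append((t0, t1, geom))
        out.append(ObjectAnnotation(f"object{obj}", intervals))
    return out


def gen_eeg(
    fs: float,
    duration_s: float,
    burst_schedule: Sequence[tuple[float, float]],
    alpha_freq: float = 10.0,
    alpha_amp: float = 20.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[EEGTrace, list[tuple[float, float]]]:
    """White noise plus an alpha sinusoid gated on during the burst intervals.

    Amplitudes are in microvolts; defaults (20 µV bursts over 2 µV noise)
    give the clear on/off alpha contrast the sonification is meant to make
    audible.  Returns the trace and the schedule as ground truth.
    """
    rng = np.random.default_rng(seed)
    n = round(fs * duration_s)
    t = np.arange(n) / fs
    x = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    gate = np.zeros(n)
    for (b0, b1) in burst_schedule:
        gate[(t >= b0) & (t < b1)] = 1.0
    x = x + alpha_amp * gate * np.sin(2.0 * np.pi * alpha_freq * t)
    return EEGTrace(x, fs), list(burst_schedule)


def gen_video(video: VideoMeta, duration_s: float, out_path) -> Path:
    """Procedural stimulus stand-in: an MKV of JPEG-coded frames.

    Each frame shows a solid background, a frame-index binary strip and a
    moving block, enough to verify muxing, seeking and frame counts.
    ``duration_s`` must be positive.
    """
    from PIL import Image, ImageDraw

    from . import mkv as mkvlib

    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    n_frames = max(1, round(duration_s * video.fps))
    frame_ms = 1000.0 / video.fps
    mkv = mkvlib.MKVFile()
    mkv.tracks.append(mkvlib.MKVTrack(
        number=1, type="video", codec_id="V_MJPEG", name="stimulus",
        width=video.width, height=video.height,
        default_duration_ns=round(1e9 / video.fps),
    ))
    for f in range(n_frames):
        img = Image.new("RGB", (video.width, video.height), (24, 24, 64))
        draw = ImageDraw.Draw(img)
        # binary frame-index strip along the top edge
        cell = max(2, video.width // 32)
        for bit in range(16):
            if (f >> bit) & 1:
                draw.rectangle([bit * cell, 0, (bit + 1) * cell - 1, cell - 1],
                               fill=(255, 255, 255))
        # moving block so consecutive frames differ visibly
        x = int((f / max(1, n_frames - 1)) * (video.width - 40)) if n_frames > 1 else 0
        draw.rectangle([x, video.height // 2 - 20, x + 39, video.height // 2 + 19],
                       fill=(255, 160, 0))
        buf = io.BytesIO()
        img.save(buf, format="JPEG", quality=70)
        mkv.blocks.append(mkvlib.MKVBlock(1, round(f * frame_ms), buf.getvalue()))
    mkv.duration_ms = n_frames * frame_ms
    mkvlib.write_mkv(mkv, out_path)
    return Path(out_path)
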