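# Methods

This note documents the conventions, models and numerical choices behind
`gazemux`, and what the synthetic-data based tests do and do not show.

## Coordinate and time conventions

Gaze coordinates live in video pixel space: origin top-left, x rightward,
y downward, 0-based, same resolution as the stimulus. Off-screen samples
are retained (the carrier must be lossless) and can be flagged via
`GazeTrajectory.offscreen_mask`. Time is seconds as float, relative to
video start. A sample at time `t` is displayed during the half-open frame
interval `[n/fps, (n+1)/fps)` with `n = floor(t·fps)`; `frame_index`
repairs floating-point rounding so the intervals tile `[0, ∞)` exactly
under float comparison (a boundary instant always belongs to the *next*
frame). Eye trackers commonly sample faster than the video frame rate, so
several samples map to one interval and are drawn simultaneously — this
is intended, not a collision.

Timestamp dialects vary by vendor; `ColumnSpec.time_unit` accepts
seconds, milliseconds, microseconds, or a running sample index (divided
by the sampling rate). Header length, delimiter and column order are
likewise declared, never guessed.

## Lossless USF carrier

The USF subtitle format sketches a `shape` attribute but its upstream
drawing grammar was never completed, so this package fixes its own
normative attribute set (documented in `usf.py`): `point` (center +
radius), `rectangle` (origin + size), `polygon` (vertex list), each with
outline color, optional fill and fill color. Everything that cannot be
drawn — the raw timestamp, pupil size, event label, original annotation
interval — is stored as ordered per-shape comment children rather than a
sidecar file, preserving the single-file property of the container.
Decoding prefers that payload over the frame-quantized display times,
making `usf_to_gaze ∘ gaze_to_usf` an exact inverse; a foreign document
without payload decodes in a declared degraded mode (times = frame-interval
starts) with a `LossyDecodeWarning`.

Numbers are serialized as fixed 6-decimal, `.`-separated, locale-free
text; round trips are exact to that precision, and serialization is
byte-for-byte idempotent.

Pupil-scaled drawing: circle radius = `base_radius · pupil /
reference_pupil`, with `base_radius = 8 px` and `reference_pupil` the
trajectory's median pupil value. Only relative pupil size is meaningful
across vendors, so the median — robust against blinks — anchors the scale.
Fixation-labeled samples are drawn as squares of side `2·radius` centred
on the gaze point; saccade and unlabeled samples as circles.

## Lossy ASS encoding

ASS carries only what can be drawn. The mapping is: rectangle → `m x y
l x+w y l x+w y+h l x y+h`; polygon → `m v0 l v1 …`; circle → four cubic
Bézier quadrants with control-point offset `k = 0.5523·r` (maximum radial
error of the ideal curve ≈ 0.027 % of r; with integer-rounded coordinates
the practical bound is half a pixel, which the tests check as < 0.03·r
for the radii drawn in practice). Only `m`, `l`, `b` are emitted —
Béziers render more widely than b-splines. Coordinates are rounded
half-up to integers because renderers disagree on fractional coordinates;
drawings are wrapped in `{\an7\pos(0,0)\p1}…{\p0}` so they are expressed
directly in PlayRes (video-resolution) space. Times round to the ASS
centisecond grain with a minimum duration of 1 cs so no event vanishes.

Track merging exists because players render a single subtitle track:
`merge_ass_tracks` concatenates per-subject tracks, re-sorts by (start
time, input index) — stable within each input — and restyles each input
with a distinct color from a fixed 8-color maximally-distinct palette
(overridable). Event counts are conserved by construction and asserted in
tests.

## Reference rasterizer

The rasterizer reproduces offline what a patched player draws at playback
time, so visualizations are testable without a media player: Bresenham's
integer line algorithm (8-connected, endpoints included), the midpoint
circle algorithm (8-way symmetric; r = 0 is the center pixel), and
even-odd scan-line polygon fill. Boundary convention: pixel (x, y) covers
the unit square with center (x+0.5, y+0.5) and is filled iff its center
is inside; edges use the half-open rule `(y0 ≤ yc) ≠ (y1 ≤ yc)` so shared
vertices count once. Self-intersecting polygons are legal (even-odd rule
decides). Filled circles use per-scan-line spans between the boundary's
x-extents. No anti-aliasing — binary pixel sets keep every primitive
comparable to a brute-force oracle (nearest-pixel line walk, per-octant
`round(sqrt(r²−y²))`, per-pixel crossing-number test). Overlap resolves
in painter's order: the later event in the list wins per pixel. On exact
half-pixel ties (lines with even axis deltas) Bresenham's integer error
accumulation decides; every chosen pixel still lies within half a pixel
of the ideal line, with exactly one pixel per driving-axis step. Clipping
simply discards out-of-frame pixels after rasterization; shapes are small
relative to the frame, so clip-then-rasterize buys nothing.

## Container layer

Muxing and demuxing go through one interface with three backends:
`mkvmerge` (preferred — mkvextract gives attachment-exact extraction),
`ffmpeg`, and `native`, a pure-Python Matroska subset writer/reader
(`mkv.py`) that is always available. `auto` picks them in that order. The
native subset: millisecond timestamp scale, MJPEG video (one JPEG per
block), `A_PCM/INT/LIT` 16-bit audio in ~100 ms chunks, `S_TEXT/ASS`
subtitles (script header as codec private, one block per event with
BlockDuration), attachments, no lacing, clusters cut at 30 s so int16
relative timestamps cannot overflow. ASS event times are centisecond-
precise and block timestamps millisecond-precise, so subtitle round trips
are lossless; attachments round-trip byte-identically.

`bundle` produces two containers per data set: an ASS variant that plays
out of the box and a USF variant that additionally attaches the lossless
carrier. USF travels as an attachment, not a subtitle track, because
released players do not recognize a USF codec; the ASS track is the
playable one.

The procedural stimulus (`gen_video`) writes JPEG frames (solid
background, binary frame-index strip, moving block) straight into a
native MKV — enough to verify track inventories, frame counts and
remuxing without shipping any media.

## Event detection (I-DT)

Dispersion-threshold identification: grow a window from the current
sample to the minimum duration; if its dispersion `(max x − min x) +
(max y − min y)` is within threshold, extend while it stays within, label
the window fixation and restart after it; otherwise advance one sample.
Everything unlabeled is a saccade. Defaults: dispersion `0.02·max(width,
height)` of the stimulus (≈ 12.8 px on 640×480) and 0.1 s minimum —
artifact defaults in stimulus-pixel terms, deliberately resolution-
relative because the package has no knowledge of viewing geometry
(degrees of visual angle). Velocity-based detection (I-VT) is out of
scope. Pre-existing labels (e.g. from the tracker) are only overwritten
on request.

## Sonification

Alpha band fixed to 8–13 Hz by default. The envelope pipeline: zero-phase
4th-order Butterworth band-pass (applied forward-backward via
`sosfiltfilt`), squared signal, moving average over `window_s` (default
0.25 s — long enough to smooth the 10 Hz carrier's power ripple, short
enough to keep burst edges within one window), linear resampling to the
audio rate, then normalization so the trace maximum maps to 1. The
pre-normalization peak is kept on the `PowerEnvelope` so absolute band
power (µV²) remains recoverable; if the band content is below 10⁻¹² of
the squared input peak (numerical residue, e.g. a pure-DC trace) the
envelope is exactly zero rather than noise amplified to full scale.

Synthesis, both on the 220 Hz carrier (note a): FM integrates phase,
`s[n] = sin(2π Σ_{k≤n} (f_c + Δf·e[k]) / f_s)`, with default deviation
Δf = 110 Hz (half the carrier: a clearly audible but not octave-breaking
pitch range; configurable). AM is `e[n]·sin(2π f_c n/f_s)`. Audio is
mono 44.1 kHz 16-bit PCM WAV at 0.9 full-scale gain. Nyquist violations
(envelope rate vs carrier + deviation) are errors, not warnings.

## Synthetic data: what it does and does not show

The generators produce exactly the structure the toolchain must preserve
and detect: alternating fixations (Gaussian jitter, default SD 1 px —
typical video-pixel noise of a remote tracker — around uniformly placed
centers, 0.2–0.4 s) and saccades (linear interpolation, 20–80 ms), pupil
size as a smooth reflected random walk around 1000 arbitrary units, EEG
as white noise (SD 2 µV) plus a gated 10 Hz, 20 µV sinusoid, annotations
as piecewise-linear motion sampled per frame. All are deterministic under
their seed and return ground truth.

They do **not** model oculomotor realism: no main-sequence saccade
velocity profiles, no drift or microsaccades within fixations, no blinks
or tracking dropouts, no 1/f EEG background or artifacts. Passing the
recovery tests therefore shows the formats are lossless and the detectors
consistent with their own definitions on clean, well-separated data — not
that the default I-DT thresholds are tuned for any particular real
tracker, which always requires per-study threshold choice.

Test and acceptance problem sizes (50 trajectories of ~400–500 samples,
100 random instances per rasterizer primitive, 1–4 s signals, 1 s of
320×240 video) are the package's chosen verification scale; every check
is seed-pinned and completes in seconds.

## Known limitations

* Full ASS is not parsed — only the subset this package emits (enough for
  merging and round trips).
* The native Matroska backend reads plainly-structured files (no lacing,
  no unknown-size elements); arbitrary third-party MKVs should be handled
  through the mkvmerge/ffmpeg backends.
* One subtitle stream per subject and single-channel EEG only; no MP4 or
  OGG output.
* Velocity-based or probabilistic event detection, calibration
  correction, and device drivers are out of scope.
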