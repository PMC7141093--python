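"""Lossless subtitle-track encoding of gaze data as USF-style XML.

USF (Universal Subtitle Format) is an XML subtitle format whose draft
specification sketches a ``shape`` attribute for drawing geometric
primitives, but the upstream grammar was never finished.  This module
therefore fixes a concrete, normative shape vocabulary (documented below)
and uses it as the lossless carrier for gaze samples and object
annotations: every sample becomes a timed shape placed on its video frame,
and every non-visual field (raw timestamp, pupil size, event label) is
preserved in per-shape comment children so the original recording can be
reconstructed exactly.

Normative shape element
-----------------------
::

    <subtitle start="0.000000" stop="0.040000">
      <shape type="point|rectangle|polygon"
             posx=".." posy=".." radius=".."        (point)
             posx=".." posy=".." width=".." height=".."  (rectangle)
             points="x0,y0 x1,y1 ..."               (polygon)
             outline-color="#RRGGBB" fill="yes|no" fill-color="#RRGGBB">
        <comment key=".." value=".."/> ...
      </shape>
    </subtitle>

Numbers are serialized in fixed 6-decimal notation with ``.`` as decimal
separator, locale-independent; decoding a serialized document reproduces
all shapes and comments to that precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

from lxml import etree

from .model import (
    FIXATION,
    GazeSample,
    GazeTrajectory,
    ObjectAnnotation,
    VideoMeta,
    frame_index,
    frame_interval,
    geometry_kind,
)

__all__ = [
    "ShapeStyle",
    "ShapeEvent",
    "USFDocument",
    "USFStream",
    "gaze_to_usf",
    "annotations_to_usf",
    "usf_to_gaze",
    "write_usf",
    "read_usf",
    "LossyDecodeWarning",
]

TOOL_NAME = "gazemux"
TOOL_VERSION = "0.1.0"

_FMT = "%.6f"


class LossyDecodeWarning(UserWarning):
    """Decoding a document without the lossless comment payload."""


def _rgb(color) -> str:
    r, g, b = color
    return f"#{r:02X}{g:02X}{b:02X}"


def _parse_rgb(s: str) -> tuple[int, int, int]:
    s = s.lstrip("#")
    return (int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16))


@dataclass(frozen=True)
class ShapeStyle:
    outline_color: tuple[int, int, int] = (255, 0, 0)
    fill: bool = False
    fill_color: Optional[tuple[int, int, int]] = None

    def resolved_fill_color(self) -> tuple[int, int, int]:
        return self.fill_color if self.fill_color is not None else self.outline_color


@dataclass
class ShapeEvent:
    """A timed geometric primitive — the unit of subtitle-track payload.

    ``geometry`` is ``(cx, cy, radius)`` for a point, ``(x, y, w, h)`` for a
    rectangle, or a tuple of ``(x, y)`` vertices for a polygon.  ``extra``
    is an ordered list of string key-value pairs carrying non-visual payload
    (raw timestamp, pupil size, event label, ...).
    """

    t_start: float
    t_end: float
    kind: str  # point | rectangle | polygon
    geometry: tuple
    style: ShapeStyle = ShapeStyle()
    source: str = ""
    extra: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError(f"need t_start < t_end, got [{self.t_start}, {self.t_end})")
        if self.kind == "point":
            if self.geometry[2] < 0:
                raise ValueError("point radius must be >= 0")
        elif self.kind == "rectangle":
            if self.geometry[2] < 0 or self.geometry[3] < 0:
                raise ValueError("rectangle width/height must be >= 0")
        elif self.kind == "polygon":
            if len(self.geometry) < 3:
                raise ValueError("polygon needs >= 3 vertices")
        else:
            raise ValueError(f"unknown shape kind {self.kind!r}")

    def extra_dict(self) -> dict[str, str]:
        return dict(self.extra)


@dataclass
class USFStream:
    """One per-source subtitle stream (one subject or one annotated object)."""

    source: str
    events: list[ShapeEvent]
    sampling_rate: Optional[float] = None


@dataclass
class USFDocument:
    title: str = "gaze metadata"
    author: str = TOOL_NAME
    tool: str = f"{TOOL_NAME}/{TOOL_VERSION}"
    video: Optional[VideoMeta] = None
    streams: list[USFStream] = field(default_factory=list)
    comments: list[tuple[str, str]] = field(default_factory=list)


def _style_for(sample: GazeSample, base_radius: float, ref_pupil: Optional[float],
               outline, fill: bool) -> tuple[str, tuple, ShapeStyle]:
    """Map one gaze sample to (kind, geometry, style)."""
    if sample.pupil is not None and ref_pupil:
        radius = base_radius * (sample.pupil / ref_pupil)
    else:
        radius = base_radius
    style = ShapeStyle(outline_color=outline, fill=fill)
    if sample.label == FIXATION:
        # fixations drawn as squares centred on the gaze point
        side = 2.0 * radius
        return "rectangle", (sample.x - radius, sample.y - radius, side, side), style
    return "point", (sample.x, sample.y, radius), style


def gaze_to_usf(
    traj: GazeTrajectory,
    video: VideoMeta,
    base_radius: float = 8.0,
    outline_color: tuple[int, int, int] = (255, 0, 0),
    fill: bool = False,
) -> USFDocument:
    """Encode a trajectory as one USF stream, losslessly.

    Each sample becomes a shape spanning the display interval of its frame;
    samples sharing a frame yield multiple co-timed shapes (eye trackers
    usually sample faster than the video frame rate).  Saccade/unlabeled
    samples become points whose radius scales with relative pupil size
    (``base_radius * pupil / median pupil``); fixation samples become
    squares.  Raw timestamp, pupil and label ride along as comment payload,
    so :func:`usf_to_gaze` is an exact inverse.
    """
    if video is None:
        raise ValueError("VideoMeta is required to align samples to frames")
    pupils = [s.pupil for s in traj.samples if s.pupil is not None]
    ref_pupil = _median(pupils) if pupils else None
    events = []
    for s in traj.samples:
        t0, t1 = frame_interval(s.t, video)
        kind, geom, style = _style_for(s, base_radius, ref_pupil, outline_color, fill)
        extra = [("t", _FMT % s.t)]
        if s.pupil is not None:
            extra.append(("pupil", _FMT % s.pupil))
        if s.label is not None:
            extra.append(("label", s.label))
        events.append(ShapeEvent(t0, t1, kind, geom, style, traj.subject_id, extra))
    doc = USFDocument(video=video)
    doc.streams.append(USFStream(traj.subject_id, events, traj.sampling_rate))
    return doc


def _median(vals):
    vals = sorted(vals)
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])


def annotations_to_usf(
    annotations: Sequence[ObjectAnnotation],
    video: VideoMeta,
    outline_color: tuple[int, int, int] = (0, 255, 0),
    fill: bool = False,
    granularity: str = "per_frame",
) -> USFDocument:
    """Encode object annotations as USF streams (one per object).

    ``granularity="per_frame"`` splits each interval at the video frame
    grid (one shape per overlapped frame); ``"per_interval"`` keeps one
    shape per interval.
    """
    if granularity not in ("per_frame", "per_interval"):
        raise ValueError("granularity must be 'per_frame' or 'per_interval'")
    doc = USFDocument(video=video)
    style = ShapeStyle(outline_color=outline_color, fill=fill)
    for ann in annotations:
        events = []
        for (t0, t1, geom) in ann.intervals:
            kind = geometry_kind(geom)
            geometry = tuple(geom) if kind == "rectangle" else tuple(tuple(v) for v in geom)
            if granularity == "per_interval":
                events.append(ShapeEvent(t0, t1, kind, geometry, style, ann.object_id,
                                         [("t_start", _FMT % t0), ("t_end", _FMT % t1)]))
            else:
                n0 = frame_index(t0, video)
                n = n0
                while n / video.fps < t1:
                    f0, f1 = n / video.fps, (n + 1) / video.fps
                    if f1 > t0:  # overlap is nonempty
                        events.append(
                            ShapeEvent(f0, f1, kind, geometry, style, ann.object_id,
                                       [("t_start", _FMT % t0), ("t_end", _FMT % t1)])
                        )
                    n += 1
        doc.streams.append(USFStream(ann.object_id, events))
    return doc


def usf_to_gaze(doc: USFDocument) -> list[GazeTrajectory]:
    """Recover gaze trajectories from a document written by this codec.

    Uses the comment payload (raw timestamp, pupil, label) rather than the
    frame-quantized display times, so the round trip through
    :func:`gaze_to_usf` is exact to the 6-decimal serialization precision.
    For a foreign document that lacks the payload, a degraded trajectory is
    returned whose times are the frame-interval starts, with a
    :class:`LossyDecodeWarning`.
    """
    import warnings

    out = []
    for stream in doc.streams:
        samples = []
        degraded = False
        last_t = -1.0
        for ev in stream.events:
            ex = ev.extra_dict()
            if ev.kind == "point":
                x, y = ev.geometry[0], ev.geometry[1]
            elif ev.kind == "rectangle":
                x = ev.geometry[0] + ev.geometry[2] / 2.0
                y = ev.geometry[1] + ev.geometry[3] / 2.0
            else:
                xs = [v[0] for v in ev.geometry]
                ys = [v[1] for v in ev.geometry]
                x, y = sum(xs) / len(xs), sum(ys) / len(ys)
            if "t" in ex:
                t = float(ex["t"])
            else:
                degraded = True
                t = ev.t_start
                if t <= last_t:  # multiple shapes in one frame, times quantized
                    t = last_t + 1e-6
            last_t = t
            pupil = float(ex["pupil"]) if "pupil" in ex else None
            label = ex.get("label")
            samples.append(GazeSample(t=t, x=x, y=y, pupil=pupil, label=label))
        if degraded:
            warnings.warn(
                f"stream {stream.source!r} lacks lossless payload; "
                "times quantized to frame intervals",
                LossyDecodeWarning,
            )
        rate = stream.sampling_rate
        if rate is None:
            dts = [b.t - a.t for a, b in zip(samples, samples[1:]) if b.t > a.t]
            rate = 1.0 / _median(dts) if dts else (doc.video.fps if doc.video else 1.0)
        out.append(GazeTrajectory(stream.source, samples, rate))
    return out


# ---------------------------------------------------------------------------
# XML serialization

def _shape_to_xml(ev: ShapeEvent) -> etree._Element:
    el = etree.Element("shape", type=ev.kind)
    if ev.kind == "point":
        el.set("posx", _FMT % ev.geometry[0])
        el.set("posy", _FMT % ev.geometry[1])
        el.set("radius", _FMT % ev.geometry[2])
    elif ev.kind == "rectangle":
        el.set("posx", _FMT % ev.geometry[0])
        el.set("posy", _FMT % ev.geometry[1])
        el.set("width", _FMT % ev.geometry[2])
        el.set("height", _FMT % ev.geometry[3])
    else:
        el.set("points", " ".join(f"{_FMT % x},{_FMT % y}" for x, y in ev.geometry))
    el.set("outline-color", _rgb(ev.style.outline_color))
    el.set("fill", "yes" if ev.style.fill else "no")
    if ev.style.fill:
        el.set("fill-color", _rgb(ev.style.resolved_fill_color()))
    for k, v in ev.extra:
        etree.SubElement(el, "comment", key=k, value=v)
    return el


def _shape_from_xml(el, t0: float, t1: float, source: str) -> ShapeEvent:
    kind = el.get("type")
    if kind == "point":
        geom = (float(el.get("posx")), float(el.get("posy")), float(el.get("radius")))
    elif kind == "rectangle":
        geom = (float(el.get("posx")), float(el.get("posy")),
                float(el.get("width")), float(el.get("height")))
    elif kind == "polygon":
        geom = tuple(
            tuple(float(c) for c in pair.split(","))
            for pair in el.get("points").split()
        )
    else:
        raise ValueError(f"unknown shape type {kind!r}")
    fill = el.get("fill") == "yes"
    style = ShapeStyle(
        outline_color=_parse_rgb(el.get("outline-color")),
        fill=fill,
        fill_color=_parse_rgb(el.get("fill-color")) if fill and el.get("fill-color") else None,
    )
    extra = [(c.get("key"), c.get("value")) for c in el.findall("comment")]
    return ShapeEvent(t0, t1, kind, geom, style, source, extra)


def write_usf(doc: USFDocument, path=None) -> bytes:
    """Serialize to UTF-8 XML bytes; also write to ``path`` if given.

    Serialization is deterministic: ``write(read(write(doc))) ==
    write(doc)`` byte-for-byte.
    """
    root = etree.Element("USFSubtitles", version="1.1")
    meta = etree.SubElement(root, "metadata")
    etree.SubElement(meta, "title").text = doc.title
    author = etree.SubElement(meta, "author")
    etree.SubElement(author, "name").text = doc.author
    etree.SubElement(meta, "tool").text = doc.tool
    if doc.video is not None:
        etree.SubElement(
            meta, "video",
            width=str(doc.video.width), height=str(doc.video.height),
            fps=_FMT % doc.video.fps,
        )
    for k, v in doc.comments:
        etree.SubElement(meta, "comment", key=k, value=v)
    for stream in doc.streams:
        sub = etree.SubElement(root, "subtitles", source=stream.source)
        if stream.sampling_rate is not None:
            sub.set("sampling-rate", _FMT % stream.sampling_rate)
        for ev in stream.events:
            entry = etree.SubElement(sub, "subtitle",
                                     start=_FMT % ev.t_start, stop=_FMT % ev.t_end)
            entry.append(_shape_to_xml(ev))
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(data)
    return data


def read_usf(source) -> USFDocument:
    """Parse USF XML from bytes, a file path, or a file object."""
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(source).getroot()
    if root.tag != "USFSubtitles":
        raise ValueError(f"not a USF document (root element {root.tag!r})")
    doc = USFDocument()
    meta = root.find("metadata")
    if meta is not None:
        title = meta.find("title")
        doc.title = title.text if title is not None and title.text else ""
        name = meta.find("author/name")
        doc.author = name.text if name is not None and name.text else ""
        tool = meta.find("tool")
        doc.tool = tool.text if tool is not None and tool.text else ""
        vid = meta.find("video")
        if vid is not None:
            doc.video = VideoMeta(int(vid.get("width")), int(vid.get("height")),
                                  float(vid.get("fps")))
        doc.comments = [(c.get("key"), c.get("value")) for c in meta.findall("comment")]
    for sub in root.findall("subtitles"):
        source_id = sub.get("source", "")
        rate = sub.get("sampling-rate")
        stream = USFStream(source_id, [], float(rate) if rate else None)
        for entry in sub.findall("subtitle"):
            t0, t1 = float(entry.get("start")), float(entry.get("stop"))
            shape = entry.find("shape")
            if shape is not None:
                stream.events.append(_shape_from_xml(shape, t0, t1, source_id))
        doc.streams.append(stream)
    return doc
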