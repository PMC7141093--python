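"""Lossy ASS (Advanced Sub Station Alpha) encoding of shape events.

ASS is the plain-text subtitle format that out-of-the-box media players
render, including its vector drawing mode (``{\\p1}m ... {\\p0}``).  It
cannot carry arbitrary payload, so conversion from the lossless shape
representation drops everything non-visual; geometry survives: rectangles
and polygons as move/line walks, circles as four cubic Bézier quadrants.
One track (document) is written per subject; tracks can be merged into a
single track with one distinct color per source, mirroring how multiple
subjects are compared side by side in a single player window.

Emitted subset grammar
----------------------
Sections ``[Script Info]`` (with mandatory PlayResX/PlayResY), ``[V4+
Styles]``, ``[Events]``; Dialogue lines with layer 0; drawing commands
``m``, ``l``, ``b`` only, integer coordinates, wrapped in
``{\\an7\\pos(0,0)\\p1}...{\\p0}`` so coordinates live in script (video
pixel) space.  Times have centisecond grain; a minimum duration of one
centisecond is enforced so no event vanishes in rounding.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import VideoMeta
from .usf import ShapeEvent

__all__ = [
    "ASSEvent",
    "ASSDocument",
    "ASSParseError",
    "shapes_to_ass",
    "parse_ass",
    "write_ass",
    "merge_ass_tracks",
    "DEFAULT_PALETTE",
    "bezier_circle_commands",
    "drawing_vertices",
]

# Kappa for approximating a quarter circle with one cubic Bezier segment.
BEZIER_K = 0.5523

# 8 maximally-distinct default track colors (RGB).
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (255, 0, 0), (0, 255, 0), (0, 128, 255), (255, 255, 0),
    (255, 0, 255), (0, 255, 255), (255, 128, 0), (128, 0, 255),
)


class ASSParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class ASSEvent:
    """One Dialogue line: centisecond times, style reference, drawing text."""

    start_cs: int
    end_cs: int
    style_name: str
    draw_text: str

    def __post_init__(self):
        if not self.start_cs < self.end_cs:
            raise ValueError(f"need start < end, got [{self.start_cs}, {self.end_cs}) cs")


@dataclass
class ASSStyle:
    name: str
    primary_color: tuple[int, int, int]
    outline_color: tuple[int, int, int] = (0, 0, 0)


@dataclass
class ASSDocument:
    play_res_x: int
    play_res_y: int
    title: str = "gaze metadata"
    styles: list[ASSStyle] = field(default_factory=list)
    events: list[ASSEvent] = field(default_factory=list)

    def style_names(self) -> set[str]:
        return {s.name for s in self.styles}


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def _fmt_time(cs: int) -> str:
    h, rem = divmod(cs, 360000)
    m, rem = divmod(rem, 6000)
    s, c = divmod(rem, 100)
    return f"{h}:{m:02d}:{s:02d}.{c:02d}"


_TIME_RE = re.compile(r"^(\d+):(\d{2}):(\d{2})\.(\d{2})$")


def _parse_time(text: str, lineno: int) -> int:
    m = _TIME_RE.match(text.strip())
    if not m:
        raise ASSParseError(f"bad timestamp {text!r}", lineno)
    h, mi, s, c = (int(g) for g in m.groups())
    return ((h * 60 + mi) * 60 + s) * 100 + c


def _ass_color(rgb: tuple[int, int, int]) -> str:
    r, g, b = rgb
    return f"&H00{b:02X}{g:02X}{r:02X}"  # &HAABBGGRR, opaque


_COLOR_RE = re.compile(r"^&H([0-9A-Fa-f]{8})$")


def _parse_color(text: str, lineno: int) -> tuple[int, int, int]:
    m = _COLOR_RE.match(text.strip())
    if not m:
        raise ASSParseError(f"bad colour {text!r}", lineno)
    v = int(m.group(1), 16)
    return (v & 0xFF, (v >> 8) & 0xFF, (v >> 16) & 0xFF)


def rectangle_commands(x: float, y: float, w: float, h: float) -> str:
    pts = [(x, y), (x + w, y), (x + w, y + h), (x, y + h)]
    pts = [(_round_half_up(px), _round_half_up(py)) for px, py in pts]
    return f"m {pts[0][0]} {pts[0][1]} " + " ".join(f"l {px} {py}" for px, py in pts[1:])


def polygon_commands(vertices: Sequence[tuple[float, float]]) -> str:
    pts = [(_round_half_up(px), _round_half_up(py)) for px, py in vertices]
    return f"m {pts[0][0]} {pts[0][1]} " + " ".join(f"l {px} {py}" for px, py in pts[1:])


def bezier_circle_commands(cx: float, cy: float, r: float) -> str:
    """Circle of radius r as four cubic Bézier quadrants (k = 0.5523·r).

    Radius 0 degenerates to a bare move at the center.
    """
    if r <= 0:
        return f"m {_round_half_up(cx)} {_round_half_up(cy)}"
    k = BEZIER_K * r
    # anchor points E, S, W, N (y grows downward; orientation is irrelevant)
    quads = [
        # from (cx+r, cy) to (cx, cy+r)
        ((cx + r, cy + k), (cx + k, cy + r), (cx, cy + r)),
        ((cx - k, cy + r), (cx - r, cy + k), (cx - r, cy)),
        ((cx - r, cy - k), (cx - k, cy - r), (cx, cy - r)),
        ((cx + k, cy - r), (cx + r, cy - k), (cx + r, cy)),
    ]
    parts = [f"m {_round_half_up(cx + r)} {_round_half_up(cy)}"]
    for (c1, c2, p) in quads:
        coords = [c1, c2, p]
        flat = " ".join(f"{_round_half_up(px)} {_round_half_up(py)}" for px, py in coords)
        parts.append(f"b {flat}")
    return " ".join(parts)


def _shape_drawing(ev: ShapeEvent) -> str:
    if ev.kind == "rectangle":
        return rectangle_commands(*ev.geometry)
    if ev.kind == "polygon":
        return polygon_commands(ev.geometry)
    cx, cy, r = ev.geometry
    return bezier_circle_commands(cx, cy, r)


def shapes_to_ass(
    events: Sequence[ShapeEvent],
    video: VideoMeta,
    color: tuple[int, int, int] = (255, 0, 0),
    style_name: str = "track",
    title: str = "gaze metadata",
) -> ASSDocument:
    """Convert shape events to one ASS track.

    Times are rounded to centiseconds with a 1 cs minimum duration; all
    non-visual payload is dropped (ASS is the lossy, widely-playable
    representation — the USF document remains the carrier of record).
    """
    doc = ASSDocument(play_res_x=video.width, play_res_y=video.height, title=title)
    doc.styles.append(ASSStyle(name=style_name, primary_color=color))
    for ev in events:
        start = _round_half_up(ev.t_start * 100.0)
        end = max(_round_half_up(ev.t_end * 100.0), start + 1)
        draw = "{\\an7\\pos(0,0)\\p1}" + _shape_drawing(ev) + "{\\p0}"
        doc.events.append(ASSEvent(start, end, style_name, draw))
    doc.events.sort(key=lambda e: e.start_cs)
    return doc


_STYLE_FORMAT = (
    "Name, Fontname, Fontsize, PrimaryColour, SecondaryColour, OutlineColour, "
    "BackColour, Bold, Italic, Underline, StrikeOut, ScaleX, ScaleY, Spacing, "
    "Angle, BorderStyle, Outline, Shadow, Alignment, MarginL, MarginR, MarginV, Encoding"
)
_EVENT_FORMAT = "Layer, Start, End, Style, Name, MarginL, MarginR, MarginV, Effect, Text"


def write_ass(doc: ASSDocument, path=None) -> str:
    """Serialize to ASS text (UTF-8 when written to ``path``)."""
    lines = [
        "[Script Info]",
        f"Title: {doc.title}",
        "ScriptType: v4.00+",
        f"PlayResX: {doc.play_res_x}",
        f"PlayResY: {doc.play_res_y}",
        "WrapStyle: 2",
        "",
        "[V4+ Styles]",
        f"Format: {_STYLE_FORMAT}",
    ]
    for st in doc.styles:
        lines.append(
            f"Style: {st.name},Arial,20,{_ass_color(st.primary_color)},"
            f"{_ass_color(st.primary_color)},{_ass_color(st.outline_color)},"
            "&H00000000,0,0,0,0,100,100,0,0,1,2,0,7,0,0,0,1"
        )
    lines += ["", "[Events]", f"Format: {_EVENT_FORMAT}"]
    for ev in doc.events:
        lines.append(
            f"Dialogue: 0,{_fmt_time(ev.start_cs)},{_fmt_time(ev.end_cs)},"
            f"{ev.style_name},,0,0,0,,{ev.draw_text}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    return text


def parse_ass(text: str) -> ASSDocument:
    """Parse the subset grammar emitted by :func:`write_ass`.

    Inverse of serialization on this module's own output.  Unknown sections
    or fields raise :class:`ASSParseError` with the line number; a missing
    PlayResX/PlayResY is an error (the drawing coordinate space would be
    undefined without it).
    """
    section = None
    title = ""
    resx = resy = None
    styles: list[ASSStyle] = []
    events: list[ASSEvent] = []
    known_info = ("Title", "ScriptType", "PlayResX", "PlayResY", "WrapStyle")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            if section not in ("Script Info", "V4+ Styles", "Events"):
                raise ASSParseError(f"unknown section [{section}]", lineno)
            continue
        if section is None:
            raise ASSParseError("content before any section header", lineno)
        key, sep, value = line.partition(":")
        if not sep:
            raise ASSParseError(f"expected 'Key: value', got {line!r}", lineno)
        key, value = key.strip(), value.strip()
        if section == "Script Info":
            if key not in known_info:
                raise ASSParseError(f"unknown Script Info field {key!r}", lineno)
            if key == "Title":
                title = value
            elif key == "PlayResX":
                resx = int(value)
            elif key == "PlayResY":
                resy = int(value)
        elif section == "V4+ Styles":
            if key == "Format":
                continue
            if key != "Style":
                raise ASSParseError(f"unknown styles field {key!r}", lineno)
            fields = value.split(",")
            if len(fields) < 6:
                raise ASSParseError("truncated Style line", lineno)
            styles.append(ASSStyle(
                name=fields[0].strip(),
                primary_color=_parse_color(fields[3], lineno),
                outline_color=_parse_color(fields[5], lineno),
            ))
        elif section == "Events":
            if key == "Format":
                continue
            if key != "Dialogue":
                raise ASSParseError(f"unknown events field {key!r}", lineno)
            fields = value.split(",", 9)
            if len(fields) != 10:
                raise ASSParseError("truncated Dialogue line", lineno)
            events.append(ASSEvent(
                start_cs=_parse_time(fields[1], lineno),
                end_cs=_parse_time(fields[2], lineno),
                style_name=fields[3].strip(),
                draw_text=fields[9],
            ))
    if resx is None or resy is None:
        raise ASSParseError("PlayResX/PlayResY missing — drawing space undefined")
    doc = ASSDocument(play_res_x=resx, play_res_y=resy, title=title,
                      styles=styles, events=events)
    names = doc.style_names()
    for ev in doc.events:
        if ev.style_name not in names:
            raise ASSParseError(f"event references undefined style {ev.style_name!r}")
    return doc


def merge_ass_tracks(
    docs: Sequence[ASSDocument],
    palette: Sequence[tuple[int, int, int]] = DEFAULT_PALETTE,
) -> ASSDocument:
    """Merge several per-subject tracks into a single track.

    Players typically render only one active subtitle track, so comparing
    subjects requires a merged track.  Every input keeps its events (count
    is conserved), restyled with a distinct palette color per input; the
    result is re-sorted by (start time, input index), stable within each
    input.  All inputs must share PlayRes.
    """
    if not docs:
        return ASSDocument(play_res_x=0, play_res_y=0, title="merged")
    resx, resy = docs[0].play_res_x, docs[0].play_res_y
    for i, d in enumerate(docs[1:], start=1):
        if (d.play_res_x, d.play_res_y) != (resx, resy):
            raise ValueError(
                f"PlayRes mismatch: track 0 is {resx}x{resy} but track {i} "
                f"is {d.play_res_x}x{d.play_res_y}"
            )
    merged = ASSDocument(play_res_x=resx, play_res_y=resy, title="merged")
    tagged = []
    for i, d in enumerate(docs):
        color = palette[i % len(palette)]
        name = f"track{i}"
        merged.styles.append(ASSStyle(name=name, primary_color=color))
        for j, ev in enumerate(d.events):
            tagged.append((ev.start_cs, i, j,
                           ASSEvent(ev.start_cs, ev.end_cs, name, ev.draw_text)))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    merged.events = [t[3] for t in tagged]
    return merged


# ---------------------------------------------------------------------------
# drawing-string geometry helpers (used by tests and the rasterizer bridge)

_DRAW_RE = re.compile(r"\{\\[^}]*\\p1\}(.*?)\{\\p0\}")


def drawing_commands(draw_text: str) -> list[tuple[str, list[tuple[float, float]]]]:
    """Tokenize a drawing string into (command, points) pairs."""
    m = _DRAW_RE.search(draw_text)
    body = m.group(1) if m else draw_text
    tokens = body.split()
    cmds: list[tuple[str, list[tuple[float, float]]]] = []
    i = 0
    while i < len(tokens):
        cmd = tokens[i]
        if cmd not in ("m", "l", "b"):
            raise ValueError(f"unsupported drawing command {cmd!r}")
        need = {"m": 2, "l": 2, "b": 6}[cmd]
        coords = [float(v) for v in tokens[i + 1 : i + 1 + need]]
        if len(coords) != need:
            raise ValueError(f"truncated coordinates after {cmd!r}")
        pts = [(coords[k], coords[k + 1]) for k in range(0, need, 2)]
        cmds.append((cmd, pts))
        i += 1 + need
    return cmds


def drawing_vertices(draw_text: str) -> list[tuple[float, float]]:
    """Vertices of an m/l walk (rectangles, polygons)."""
    return [pts[0] for cmd, pts in drawing_commands(draw_text) if cmd in ("m", "l")]


def sample_drawing_outline(draw_text: str, per_segment: int = 64) -> list[tuple[float, float]]:
    """Densely sample the outline (lines and cubic Béziers) of a drawing."""
    out: list[tuple[float, float]] = []
    cur: Optional[tuple[float, float]] = None
    for cmd, pts in drawing_commands(draw_text):
        if cmd == "m":
            cur = pts[0]
            out.append(cur)
        elif cmd == "l":
            assert cur is not None
            for k in range(1, per_segment + 1):
                u = k / per_segment
                out.append((cur[0] + u * (pts[0][0] - cur[0]),
                            cur[1] + u * (pts[0][1] - cur[1])))
            cur = pts[0]
        else:  # cubic Bezier: current point + 3 control/end points
            assert cur is not None
            p0, (p1, p2, p3) = cur, pts
            for k in range(1, per_segment + 1):
                u = k / per_segment
                w = 1 - u
                x = w**3 * p0[0] + 3 * w**2 * u * p1[0] + 3 * w * u**2 * p2[0] + u**3 * p3[0]
                y = w**3 * p0[1] + 3 * w**2 * u * p1[1] + 3 * w * u**2 * p2[1] + u**3 * p3[1]
                out.append((x, y))
            cur = p3
    return out
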