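"""Reference software rasterizer for shape overlays.

Replicates, offline and testably, the overlay drawing a patched media
player performs at playback time: Bresenham line and midpoint-circle
boundaries, even-odd scan-line polygon fill, composed into an RGBA frame
buffer.  No anti-aliasing — primitives are binary pixel sets, which keeps
them checkable against brute-force oracles.

Conventions: integer pixel grid; a pixel (x, y) covers the unit square
with center (x+0.5, y+0.5); fills include a pixel iff its center is inside
under the even-odd rule; overlapping shapes resolve in painter's order
(later event wins per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import VideoMeta
from .usf import ShapeEvent

__all__ = [
    "RasterOverlay",
    "raster_line",
    "raster_circle",
    "fill_polygon",
    "fill_circle",
    "render_overlay",
]

Pixel = tuple[int, int]


def raster_line(p0: Pixel, p1: Pixel) -> set[Pixel]:
    """8-connected Bresenham line including both endpoints."""
    x0, y0 = int(p0[0]), int(p0[1])
    x1, y1 = int(p1[0]), int(p1[1])
    dx = abs(x1 - x0)
    dy = -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    out = set()
    while True:
        out.add((x0, y0))
        if x0 == x1 and y0 == y1:
            break
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x0 += sx
        if e2 <= dx:
            err += dx
            y0 += sy
    return out


def raster_circle(center: Pixel, r: int) -> set[Pixel]:
    """Midpoint-circle boundary, 8-way symmetric about the center.

    r = 0 degenerates to the center pixel.
    """
    if r < 0:
        raise ValueError(f"radius must be >= 0, got {r}")
    cx, cy = int(center[0]), int(center[1])
    if r == 0:
        return {(cx, cy)}
    out = set()
    x, y = r, 0
    d = 1 - r
    while x >= y:
        for dx, dy in ((x, y), (y, x)):
            out.update({
                (cx + dx, cy + dy), (cx - dx, cy + dy),
                (cx + dx, cy - dy), (cx - dx, cy - dy),
            })
        y += 1
        if d < 0:
            d += 2 * y + 1
        else:
            x -= 1
            d += 2 * (y - x) + 1
    return out


def point_in_polygon(px: float, py: float, vertices: Sequence[tuple[float, float]]) -> bool:
    """Even-odd crossing test (used for fills smaller than a scanline and by tests)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        if (y0 <= py) != (y1 <= py):
            xc = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            if px < xc:
                inside = not inside
    return inside


def fill_polygon(vertices: Sequence[tuple[float, float]]) -> set[Pixel]:
    """Even-odd scan-line fill; a pixel is filled iff its center is inside.

    Self-intersecting polygons are allowed (even-odd rule decides);
    degenerate (zero-area) polygons yield the empty set.
    """
    if len(vertices) < 3:
        raise ValueError("polygon needs >= 3 vertices")
    ys = [v[1] for v in vertices]
    y_min = int(np.floor(min(ys)))
    y_max = int(np.ceil(max(ys)))
    n = len(vertices)
    out: set[Pixel] = set()
    for y in range(y_min - 1, y_max + 1):
        yc = y + 0.5
        xs: list[float] = []
        for i in range(n):
            x0, y0 = vertices[i]
            x1, y1 = vertices[(i + 1) % n]
            if (y0 <= yc) != (y1 <= yc):  # half-open edge rule: vertices count once
                xs.append(x0 + (yc - y0) * (x1 - x0) / (y1 - y0))
        xs.sort()
        for k in range(0, len(xs) - 1, 2):
            lo, hi = xs[k], xs[k + 1]
            # pixel centers x+0.5 in [lo, hi)
            first = int(np.ceil(lo - 0.5))
            last = int(np.ceil(hi - 0.5)) - 1
            for x in range(first, last + 1):
                out.add((x, y))
    return out


def fill_circle(center: Pixel, r: int) -> set[Pixel]:
    """Filled disc: per scan line, the span between the boundary x-extents."""
    boundary = raster_circle(center, r)
    rows: dict[int, list[int]] = {}
    for (x, y) in boundary:
        rows.setdefault(y, []).append(x)
    out: set[Pixel] = set()
    for y, xs in rows.items():
        for x in range(min(xs), max(xs) + 1):
            out.add((x, y))
    return out


@dataclass
class RasterOverlay:
    """RGBA frame buffer with transparent background."""

    width: int
    height: int
    buffer: np.ndarray  # (height, width, 4) uint8

    @classmethod
    def blank(cls, width: int, height: int) -> "RasterOverlay":
        return cls(width, height, np.zeros((height, width, 4), dtype=np.uint8))

    def paint(self, pixels: set[Pixel], color: tuple[int, int, int]) -> None:
        """Set pixels to an opaque color, clipping to the frame."""
        for (x, y) in pixels:
            if 0 <= x < self.width and 0 <= y < self.height:
                self.buffer[y, x] = (*color, 255)

    def drawn_pixels(self) -> set[Pixel]:
        ys, xs = np.nonzero(self.buffer[:, :, 3])
        return set(zip(xs.tolist(), ys.tolist()))

    def to_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.buffer, mode="RGBA").save(path, format="PNG")

    def composed_on(self, background_path, out_path) -> None:
        """Alpha-compose the overlay onto a frame image file."""
        from PIL import Image

        bg = Image.open(background_path).convert("RGBA")
        fg = Image.fromarray(self.buffer, mode="RGBA").resize(bg.size)
        Image.alpha_composite(bg, fg).save(out_path)


def _round(v: float) -> int:
    return int(np.floor(v + 0.5))


def _event_pixels(ev: ShapeEvent, fill: bool) -> tuple[set[Pixel], set[Pixel]]:
    """(outline, fill) pixel sets for one shape event."""
    if ev.kind == "point":
        cx, cy, r = ev.geometry
        center = (_round(cx), _round(cy))
        ri = _round(r)
        outline = raster_circle(center, ri)
        filled = fill_circle(center, ri) if fill else set()
        return outline, filled
    if ev.kind == "rectangle":
        x, y, w, h = ev.geometry
        verts = [(x, y), (x + w, y), (x + w, y + h), (x, y + h)]
    else:
        verts = list(ev.geometry)
    ipts = [(_round(vx), _round(vy)) for vx, vy in verts]
    outline: set[Pixel] = set()
    for i in range(len(ipts)):
        outline |= raster_line(ipts[i], ipts[(i + 1) % len(ipts)])
    filled = fill_polygon(verts) if fill else set()
    return outline, filled


def render_overlay(
    events: Sequence[ShapeEvent],
    t: float,
    video: VideoMeta,
    fill: bool = False,
) -> RasterOverlay:
    """Rasterize the events whose display interval [t_start, t_end) contains t.

    Outlines use the Bresenham primitives; ``fill`` additionally fills
    shapes (rectangles as 4-gons via scan-line fill, circles via per-row
    spans) in the event's fill color.  Everything is clipped to the frame;
    overlapping shapes resolve in painter's order.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    ov = RasterOverlay.blank(video.width, video.height)
    for ev in events:
        if not (ev.t_start <= t < ev.t_end):
            continue
        do_fill = fill or ev.style.fill
        outline, filled = _event_pixels(ev, do_fill)
        if filled:
            ov.paint(filled, ev.style.resolved_fill_color())
        ov.paint(outline, ev.style.outline_color)
    return ov
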