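"""Rasterizer primitives against brute-force oracles, and overlay composition."""

import math

import numpy as np
import pytest

from gazemux.model import VideoMeta
from gazemux.raster import (
    RasterOverlay,
    fill_circle,
    fill_polygon,
    raster_circle,
    raster_line,
    render_overlay,
)
from gazemux.usf import ShapeEvent, ShapeStyle


# --- independent oracles ----------------------------------------------------

def oracle_line(p0, p1):
    """Nearest-pixel walk along the parametric line."""
    (x0, y0), (x1, y1) = p0, p1
    steps = max(abs(x1 - x0), abs(y1 - y0))
    if steps == 0:
        return {(x0, y0)}
    out = set()
    for i in range(steps + 1):
        u = i / steps
        out.add((int(math.floor(x0 + u * (x1 - x0) + 0.5)),
                 int(math.floor(y0 + u * (y1 - y0) + 0.5))))
    return out


def oracle_circle(center, r):
    """Per-octant |distance - r| minimisation: x = round(sqrt(r^2 - y^2))."""
    cx, cy = center
    if r == 0:
        return {(cx, cy)}
    out = set()
    for y in range(0, r + 1):
        x = int(math.floor(math.sqrt(r * r - y * y) + 0.5))
        if x < y:  # past the octant diagonal
            break
        for dx, dy in ((x, y), (y, x)):
            out.update({(cx + dx, cy + dy), (cx - dx, cy + dy),
                        (cx + dx, cy - dy), (cx - dx, cy - dy)})
    return out


def oracle_point_in_polygon(px, py, vertices):
    """Even-odd crossing count, written independently of the scan-line fill."""
    crossings = 0
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        if (y0 > py) != (y1 > py):
            t = (py - y0) / (y1 - y0)
            if px < x0 + t * (x1 - x0):
                crossings += 1
    return crossings % 2 == 1


def oracle_fill(vertices):
    xs = [v[0] for v in vertices]
    ys = [v[1] for v in vertices]
    out = set()
    for y in range(int(min(ys)) - 2, int(max(ys)) + 2):
        for x in range(int(min(xs)) - 2, int(max(xs)) + 2):
            if oracle_point_in_polygon(x + 0.5, y + 0.5, vertices):
                out.add((x, y))
    return out


def shoelace(vertices):
    n = len(vertices)
    s = 0.0
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def perimeter(vertices):
    n = len(vertices)
    return sum(math.dist(vertices[i], vertices[(i + 1) % n]) for i in range(n))


# --- primitives -------------------------------------------------------------

class TestLine:
    def test_horizontal(self):
        assert raster_line((0, 0), (3, 0)) == {(0, 0), (1, 0), (2, 0), (3, 0)}

    def test_degenerate_point(self):
        assert raster_line((0, 0), (0, 0)) == {(0, 0)}

    def test_shallow_diagonal_matches_oracle(self):
        assert raster_line((0, 0), (5, 3)) == oracle_line((0, 0), (5, 3))

    def test_endpoints_always_included(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p0 = tuple(rng.integers(-30, 30, 2))
            p1 = tuple(rng.integers(-30, 30, 2))
            pixels = raster_line(p0, p1)
            assert p0 in pixels and p1 in pixels

    def test_random_lines_match_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p0 = tuple(int(v) for v in rng.integers(-30, 30, 2))
            p1 = tuple(int(v) for v in rng.integers(-30, 30, 2))
            got = raster_line(p0, p1)
            want = oracle_line(p0, p1)
            # 8-connected walks may disagree only on exact half-pixel ties;
            # every pixel must sit within half a pixel of the ideal line
            assert got == want or _line_distance_ok(got, p0, p1)


def _line_distance_ok(pixels, p0, p1, tol=0.5 + 1e-9):
    (x0, y0), (x1, y1) = p0, p1
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    steps = max(abs(dx), abs(dy))
    if norm == 0:
        return pixels == {p0}
    if len(pixels) != steps + 1:
        return False
    return all(abs(dy * (x - x0) - dx * (y - y0)) / norm <= tol for x, y in pixels)


class TestCircle:
    def test_zero_radius_is_center(self):
        assert raster_circle((4, 5), 0) == {(4, 5)}

    def test_radius_one(self):
        assert raster_circle((0, 0), 1) == {(1, 0), (-1, 0), (0, 1), (0, -1)}

    def test_eightfold_symmetry(self):
        pixels = raster_circle((0, 0), 10)
        for x, y in pixels:
            for rx, ry in ((x, -y), (-x, y), (-x, -y), (y, x), (-y, x), (y, -x), (-y, -x)):
                assert (rx, ry) in pixels

    def test_random_radii_match_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            r = int(rng.integers(0, 31))
            c = (int(rng.integers(-10, 10)), int(rng.integers(-10, 10)))
            assert raster_circle(c, r) == oracle_circle(c, r)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            raster_circle((0, 0), -1)


class TestFill:
    def test_axis_aligned_square_pixel_centers(self):
        pixels = fill_polygon([(0, 0), (4, 0), (4, 4), (0, 4)])
        assert pixels == {(x, y) for x in range(4) for y in range(4)}
        assert len(pixels) == 16

    def test_collinear_polygon_empty(self):
        assert fill_polygon([(0, 0), (5, 5), (10, 10)]) == set()

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            fill_polygon([(0, 0), (1, 1)])

    def test_random_heptagons_match_point_in_polygon_oracle(self):
        # simple (angularly sorted) heptagons: pixel count tracks shoelace area
        rng = np.random.default_rng(3)
        for _ in range(100):
            pts = rng.uniform(0, 64, size=(7, 2))
            center = pts.mean(axis=0)
            order = np.argsort(np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0]))
            verts = [tuple(map(float, p)) for p in pts[order]]
            got = fill_polygon(verts)
            assert got == oracle_fill(verts)
            assert abs(len(got) - shoelace(verts)) <= perimeter(verts)

    def test_random_self_intersecting_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            verts = [(float(rng.uniform(0, 64)), float(rng.uniform(0, 64)))
                     for _ in range(7)]
            assert fill_polygon(verts) == oracle_fill(verts)

    def test_self_intersecting_even_odd(self):
        # bow-tie: the crossing region cancels under the even-odd rule
        verts = [(0.0, 0.0), (10.0, 10.0), (10.0, 0.0), (0.0, 10.0)]
        assert fill_polygon(verts) == oracle_fill(verts)

    def test_filled_circle_spans_boundary_extents(self):
        filled = fill_circle((0, 0), 5)
        boundary = raster_circle((0, 0), 5)
        assert boundary <= filled
        for y in {p[1] for p in boundary}:
            row_b = [x for x, yy in boundary if yy == y]
            row_f = [x for x, yy in filled if yy == y]
            assert sorted(row_f) == list(range(min(row_b), max(row_b) + 1))


# --- overlays ---------------------------------------------------------------

def _pt(t0, t1, cx, cy, r, color=(255, 0, 0), fill=False):
    return ShapeEvent(t0, t1, "point", (cx, cy, r),
                      ShapeStyle(outline_color=color, fill=fill))


class TestRenderOverlay:
    def test_no_active_events_empty(self, small_video):
        ov = render_overlay([_pt(0.0, 0.04, 10, 10, 3)], t=1.0, video=small_video)
        assert ov.drawn_pixels() == set()

    def test_offscreen_shape_clipped_to_nothing(self, small_video):
        ov = render_overlay([_pt(0.0, 1.0, 1000, 1000, 5)], t=0.5, video=small_video)
        assert ov.drawn_pixels() == set()

    def test_half_open_interval_membership(self, small_video):
        ev = _pt(0.0, 0.04, 50, 50, 3)
        assert render_overlay([ev], 0.0, small_video).drawn_pixels()
        assert not render_overlay([ev], 0.04, small_video).drawn_pixels()

    def test_composite_equals_union_of_primitive_oracles(self, small_video):
        # a Fig-9-style frame: three gaze circles plus one fixation square
        events = [
            _pt(0.0, 0.04, 50, 50, 8),
            _pt(0.0, 0.04, 80, 60, 6),
            _pt(0.0, 0.04, 120, 90, 10),
            ShapeEvent(0.0, 0.04, "rectangle", (140.0, 100.0, 20.0, 20.0),
                       ShapeStyle(outline_color=(0, 255, 0))),
        ]
        ov = render_overlay(events, 0.02, small_video)
        expected = set()
        for (cx, cy, r) in [(50, 50, 8), (80, 60, 6), (120, 90, 10)]:
            expected |= oracle_circle((cx, cy), r)
        for a, b in [((140, 100), (160, 100)), ((160, 100), (160, 120)),
                     ((160, 120), (140, 120)), ((140, 120), (140, 100))]:
            expected |= oracle_line(a, b)
        assert ov.drawn_pixels() == expected

    def test_fill_flag_fills_rectangle_interior(self, small_video):
        ev = ShapeEvent(0.0, 1.0, "rectangle", (10.0, 10.0, 20.0, 10.0),
                        ShapeStyle(outline_color=(255, 0, 0), fill=True,
                                   fill_color=(0, 0, 255)))
        ov = render_overlay([ev], 0.5, small_video, fill=True)
        assert tuple(ov.buffer[15, 20]) == (0, 0, 255, 255)  # interior
        assert tuple(ov.buffer[10, 10]) == (255, 0, 0, 255)  # outline on top

    def test_painter_order_later_event_wins(self, small_video):
        a = _pt(0.0, 1.0, 50, 50, 5, color=(255, 0, 0))
        b = _pt(0.0, 1.0, 50, 50, 5, color=(0, 255, 0))
        ov = render_overlay([a, b], 0.5, small_video)
        assert tuple(ov.buffer[50, 55][:3]) == (0, 255, 0)

    def test_order_independent_for_disjoint_shapes(self, small_video):
        a = _pt(0.0, 1.0, 30, 30, 5)
        b = _pt(0.0, 1.0, 100, 100, 5, color=(0, 255, 0))
        ov1 = render_overlay([a, b], 0.5, small_video)
        ov2 = render_overlay([b, a], 0.5, small_video)
        assert np.array_equal(ov1.buffer, ov2.buffer)

    def test_clipping_keeps_pixels_in_bounds(self, small_video):
        ov = render_overlay([_pt(0.0, 1.0, 0, 0, 20, fill=True)], 0.5, small_video,
                            fill=True)
        for x, y in ov.drawn_pixels():
            assert 0 <= x < small_video.width and 0 <= y < small_video.height

    def test_png_export(self, small_video, tmp_path):
        from PIL import Image

        ov = render_overlay([_pt(0.0, 1.0, 50, 50, 5)], 0.5, small_video)
        path = tmp_path / "overlay.png"
        ov.to_png(path)
        img = Image.open(path)
        assert img.size == (small_video.width, small_video.height)
        assert img.mode == "RGBA"
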