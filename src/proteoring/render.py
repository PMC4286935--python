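"""Vector output: SVG (canonical backend) and PDF.

Both backends consume the same resolved :class:`~proteoring.layout.CircularDiagram`
scene; the PDF is drawn from the geometry, never converted from the SVG file,
so the two cannot drift apart.

Output is deterministic: floats are written with fixed precision, no
timestamps or random ids appear in the SVG, and the PDF's creation date is
pinned to a constant epoch with stream compression disabled, so re-rendering
identical input yields byte-identical files (usable as golden files).

White spacers are rendered as gaps by default (the page background shows
through, so diagrams composite cleanly onto slides); ``fill_spacers``
restores solid white sectors.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from typing import IO, Union

from proteoring.formats import RGB
from proteoring.layout import (
    ArcGeometry,
    CircularDiagram,
    Segment,
    _segment_sign,
    polar_point,
)

#: fixed PDF creation date so golden-file tests are byte-stable
PDF_EPOCH = datetime.datetime(2000, 1, 1, 0, 0, 0)

#: fraction of the inner radius a degenerate arc's stub extends toward center
STUB_FRACTION = 0.15

Point = tuple[float, float]


@dataclass(frozen=True)
class RenderOptions:
    """Styling knobs (canvas units are points)."""

    canvas_size: tuple[float, float] = (800.0, 800.0)
    arc_stroke: float = 1.2
    ring_stroke: bool = False
    label_font_size: float = 10.0
    draw_labels: bool = True
    background: RGB = (255, 255, 255)
    fill_spacers: bool = False
    arc_opacity: float = 0.8

    def __post_init__(self):
        if self.canvas_size[0] <= 0 or self.canvas_size[1] <= 0:
            raise ValueError("canvas_size must be positive")
        if self.arc_stroke <= 0:
            raise ValueError("arc_stroke must be > 0")


def polar_to_cartesian(angle_deg: float, radius: float, center: Point = (0.0, 0.0)) -> Point:
    """Standard polar conversion, mathematical convention (90 deg = top)."""
    return polar_point(angle_deg, radius, center)


def cartesian_to_polar(p: Point, center: Point = (0.0, 0.0)) -> tuple[float, float]:
    """Inverse of :func:`polar_to_cartesian`; returns (angle_deg in [0,360), radius)."""
    dx, dy = p[0] - center[0], p[1] - center[1]
    return math.degrees(math.atan2(dy, dx)) % 360.0, math.hypot(dx, dy)


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _css(color: RGB) -> str:
    return f"rgb({color[0]},{color[1]},{color[2]})"


class _Frame:
    """Shared canvas geometry for both backends (y up; SVG flips on emit)."""

    def __init__(self, diagram: CircularDiagram, opts: RenderOptions):
        w, h = opts.canvas_size
        self.cx, self.cy = w / 2.0, h / 2.0
        self.half = min(w, h) / 2.0
        lo = diagram.options
        self.r_in = lo.radius * self.half
        self.r_out = self.r_in * (1.0 + lo.ring_thickness)

    def point(self, angle_deg: float, radius: float) -> Point:
        return polar_to_cartesian(angle_deg, radius, (self.cx, self.cy))

    def scale(self, p: Point) -> Point:
        """Map a normalized layout point (half-extent 1) onto the canvas."""
        return (self.cx + p[0] * self.half, self.cy + p[1] * self.half)


def _drawn_segments(diagram: CircularDiagram, opts: RenderOptions) -> list[Segment]:
    out = []
    for seg in diagram.segments:
        if seg.width_deg == 0:
            continue
        if seg.kind == "spacer" and not opts.fill_spacers:
            continue
        out.append(seg)
    return out


def _arc_points(arc: ArcGeometry, frame: _Frame) -> tuple[Point, Point, Point]:
    p0 = frame.point(arc.from_angle, frame.r_in)
    p1 = frame.point(arc.to_angle, frame.r_in)
    c = frame.scale(arc.control_point)
    return p0, c, p1


def _label_plan(diagram: CircularDiagram, frame: _Frame, opts: RenderOptions):
    """Yield (text, x, y, rotation_ccw_deg, color) for every drawn label."""
    if not opts.draw_labels:
        return
    for seg in diagram.segments:
        if seg.width_deg == 0:
            continue
        mid = (seg.start_angle + _segment_sign(seg) * seg.width_deg / 2.0) % 360.0
        if seg.kind == "bait":
            x, y = frame.point(mid, (frame.r_in + frame.r_out) / 2.0)
            yield seg.label, x, y, _radial_rotation(mid), (255, 255, 255)
        elif seg.kind == "set":
            x, y = frame.point(mid, frame.r_out + 0.35 * opts.label_font_size)
            yield seg.label, x, y, _radial_rotation(mid), (0, 0, 0)


def _radial_rotation(angle_deg: float) -> float:
    """Tangential text rotation (CCW degrees), flipped to stay upright."""
    rot = angle_deg - 90.0
    if 90.0 < rot % 360.0 <= 270.0:
        rot += 180.0
    return rot % 360.0


# --------------------------------------------------------------------------
# SVG backend
# --------------------------------------------------------------------------

def _svg_sector_path(seg: Segment, frame: _Frame) -> str:
    sign = _segment_sign(seg)
    a0, a1 = seg.start_angle, seg.start_angle + sign * seg.width_deg
    sweep_out = 1 if sign < 0 else 0  # screen y points down: cw layout = sweep 1
    large = 1 if seg.width_deg > 180.0 else 0
    pts = [
        frame.point(a0, frame.r_out),
        frame.point(a1, frame.r_out),
        frame.point(a1, frame.r_in),
        frame.point(a0, frame.r_in),
    ]

    def spt(p: Point) -> str:  # flip y for SVG screen coordinates
        return f"{_fmt(p[0])},{_fmt(_svg_y(p[1], frame))}"

    ro, ri = _fmt(frame.r_out), _fmt(frame.r_in)
    return (
        f"M {spt(pts[0])} "
        f"A {ro},{ro} 0 {large} {sweep_out} {spt(pts[1])} "
        f"L {spt(pts[2])} "
        f"A {ri},{ri} 0 {large} {1 - sweep_out} {spt(pts[3])} Z"
    )


def _svg_y(y: float, frame: _Frame) -> float:
    return 2 * frame.cy - y


def svg_document(diagram: CircularDiagram, opts: RenderOptions = RenderOptions()) -> str:
    """Render the diagram to an SVG 1.1 document string."""
    w, h = opts.canvas_size
    frame = _Frame(diagram, opts)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
        f'<rect width="{_fmt(w)}" height="{_fmt(h)}" fill="{_css(opts.background)}"/>',
    ]

    lines.append('<g id="segments">')
    outline = ' stroke="rgb(0,0,0)" stroke-width="0.5"' if opts.ring_stroke else ""
    for seg in _drawn_segments(diagram, opts):
        d = _svg_sector_path(seg, frame)
        lines.append(f'<path d="{d}" fill="{_css(seg.color)}"{outline}/>')
    lines.append("</g>")

    lines.append('<g id="arcs">')
    for arc in diagram.arcs:
        p0, c, p1 = _arc_points(arc, frame)
        if arc.degenerate:
            stub = frame.point(arc.from_angle, frame.r_in * (1.0 - STUB_FRACTION))
            d = (
                f"M {_fmt(p0[0])},{_fmt(_svg_y(p0[1], frame))} "
                f"L {_fmt(stub[0])},{_fmt(_svg_y(stub[1], frame))}"
            )
        else:
            d = (
                f"M {_fmt(p0[0])},{_fmt(_svg_y(p0[1], frame))} "
                f"Q {_fmt(c[0])},{_fmt(_svg_y(c[1], frame))} "
                f"{_fmt(p1[0])},{_fmt(_svg_y(p1[1], frame))}"
            )
        lines.append(
            f'<path d="{d}" fill="none" stroke="{_css(arc.color)}" '
            f'stroke-width="{_fmt(opts.arc_stroke)}" '
            f'stroke-opacity="{opts.arc_opacity}" stroke-linecap="round"/>'
        )
    lines.append("</g>")

    lines.append('<g id="labels">')
    for text, x, y, rot, color in _label_plan(diagram, frame, opts):
        ysvg = _svg_y(y, frame)
        svg_rot = -rot  # SVG rotates clockwise in screen coordinates
        lines.append(
            f'<text x="{_fmt(x)}" y="{_fmt(ysvg)}" font-size="{_fmt(opts.label_font_size)}" '
            f'font-family="sans-serif" text-anchor="middle" dominant-baseline="middle" '
            f'fill="{_css(color)}" transform="rotate({_fmt(svg_rot)} {_fmt(x)} {_fmt(ysvg)})">'
            f"{_escape(text)}</text>"
        )
    lines.append("</g>")

    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def render_svg(
    diagram: CircularDiagram,
    opts: RenderOptions = RenderOptions(),
    out: Union[str, IO[str], None] = None,
) -> str:
    """Write the SVG rendering to ``out`` (path or stream) and return it."""
    doc = svg_document(diagram, opts)
    if isinstance(out, str):
        with open(out, "w", encoding="utf-8") as fh:
            fh.write(doc)
    elif out is not None:
        out.write(doc)
    return doc


# --------------------------------------------------------------------------
# PDF backend
# --------------------------------------------------------------------------

def _draw_on_figure(fig, diagram: CircularDiagram, opts: RenderOptions) -> None:
    """Draw the scene onto a matplotlib Figure (shared by PDF backends)."""
    from matplotlib.patches import PathPatch, Rectangle, Wedge
    from matplotlib.path import Path as MplPath

    w, h = opts.canvas_size
    frame = _Frame(diagram, opts)
    ax = fig.add_axes([0.0, 0.0, 1.0, 1.0])
    ax.set_axis_off()
    ax.set_xlim(0, w)
    ax.set_ylim(0, h)
    ax.set_aspect("equal")

    bg = tuple(v / 255.0 for v in opts.background)
    fig.patch.set_facecolor(bg)
    ax.add_patch(Rectangle((0, 0), w, h, facecolor=bg, edgecolor="none"))

    for seg in _drawn_segments(diagram, opts):
        sign = _segment_sign(seg)
        if sign > 0:
            t1, t2 = seg.start_angle, seg.start_angle + seg.width_deg
        else:
            t1, t2 = seg.start_angle - seg.width_deg, seg.start_angle
        ax.add_patch(
            Wedge(
                (frame.cx, frame.cy),
                frame.r_out,
                t1,
                t2,
                width=frame.r_out - frame.r_in,
                facecolor=tuple(v / 255.0 for v in seg.color),
                edgecolor=("black" if opts.ring_stroke else "none"),
                linewidth=0.5 if opts.ring_stroke else 0.0,
            )
        )

    for arc in diagram.arcs:
        p0, c, p1 = _arc_points(arc, frame)
        if arc.degenerate:
            stub = frame.point(arc.from_angle, frame.r_in * (1.0 - STUB_FRACTION))
            path = MplPath([p0, stub], [MplPath.MOVETO, MplPath.LINETO])
        else:
            path = MplPath([p0, c, p1], [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3])
        ax.add_patch(
            PathPatch(
                path,
                fill=False,
                edgecolor=tuple(v / 255.0 for v in arc.color),
                linewidth=opts.arc_stroke,
                alpha=opts.arc_opacity,
                capstyle="round",
            )
        )

    for text, x, y, rot, color in _label_plan(diagram, frame, opts):
        ax.text(
            x,
            y,
            text,
            rotation=rot,
            rotation_mode="anchor",
            ha="center",
            va="center",
            fontsize=opts.label_font_size,
            color=tuple(v / 255.0 for v in color),
        )



def render_pdf(
    diagram: CircularDiagram,
    opts: RenderOptions = RenderOptions(),
    out: Union[str, IO[bytes], None] = None,
) -> None:
    """Write a single-page vector PDF of the diagram.

    Drawn from the scene geometry with matplotlib; the page box equals
    ``canvas_size`` in points and the creation date is a fixed constant so
    output bytes are reproducible.
    """
    import matplotlib
    from matplotlib.figure import Figure

    w, h = opts.canvas_size
    with matplotlib.rc_context({"pdf.compression": 0, "pdf.fonttype": 3}):
        fig = Figure(figsize=(w / 72.0, h / 72.0))
        _draw_on_figure(fig, diagram, opts)
        fig.savefig(
            out,
            format="pdf",
            metadata={"CreationDate": PDF_EPOCH},
            facecolor=fig.patch.get_facecolor(),
        )
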