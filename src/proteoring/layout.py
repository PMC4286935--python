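"""Angular layout of the circular diagram, independent of any renderer.

The outer ring is tiled by segments, walked in the layout direction
(clockwise by default) starting from the bait segment:

    bait (black) -> spacer (white) -> set_0 -> ... -> set_{n-1} -> spacer

Widths are proportional to protein counts.  One protein occupies one *unit*;
the unit angle is ``360 / (sum of set sizes + bait_units + 2 * spacer_units)``.
The two white spacers flanking the bait double as a visual scale bar: with
the default ``spacer_units = 3`` each spacer is exactly three proteins wide.

Each interaction is a quadratic Bezier arc from the bait segment's midpoint
to the midpoint of the prey's one-unit slot inside its set, with the control
point at the circle center (``arc_tension = 0``) or displaced toward the
chord midpoint for higher tension.

All angles are degrees in the mathematical convention (counterclockwise
positive, 0 deg = +x axis), normalized to [0, 360); the clockwise option is
applied as a sign flip when walking the ring.  Geometry lives in normalized
canvas coordinates: center (0, 0), half-extent 1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import IO, Optional

from proteoring.formats import ColorScheme, Experiment, RGB, Reference
from proteoring.mapping import MappingResult, assign_set_colors, map_experiment

logger = logging.getLogger(__name__)

BLACK: RGB = (0, 0, 0)
WHITE: RGB = (255, 255, 255)

#: angular separation (degrees) below which an arc is flagged degenerate
DEGENERATE_ARC_EPS = 1e-3

Point = tuple[float, float]


@dataclass(frozen=True)
class LayoutOptions:
    """Geometry knobs.

    spacer_units
        Protein-width units per white spacer (default 3, the scale-bar rule).
    bait_units
        Units of the black bait segment (default 3, visually comparable to a
        spacer).
    radius
        Ring inner radius as a fraction of the canvas half-extent.
    ring_thickness
        Radial thickness of the ring, as a fraction of ``radius``.
    bait_center_angle
        Where the bait segment is centered, degrees (default 90 = top).
    clockwise
        Layout direction around the ring.
    arc_tension
        0 places every arc's control point at the circle center; 1 at the
        chord midpoint.  Intermediate values flatten dense diagrams.
    """

    spacer_units: float = 3.0
    bait_units: float = 3.0
    radius: float = 0.85
    ring_thickness: float = 0.06
    bait_center_angle: float = 90.0
    clockwise: bool = True
    arc_tension: float = 0.0

    def __post_init__(self):
        if self.spacer_units <= 0 or self.bait_units <= 0:
            raise ValueError("spacer_units and bait_units must be > 0")
        if not 0 < self.radius <= 1:
            raise ValueError("radius must be in (0, 1]")
        if not 0 <= self.arc_tension <= 1:
            raise ValueError("arc_tension must be in [0, 1]")
        if self.ring_thickness <= 0:
            raise ValueError("ring_thickness must be > 0")


@dataclass(frozen=True)
class Segment:
    """One sector of the outer ring."""

    kind: str  # 'set' | 'bait' | 'spacer'
    label: str
    set_index: Optional[int]
    start_angle: float  # where the segment begins, in layout direction
    end_angle: float
    width_deg: float  # n_units * unit_angle, >= 0
    n_units: float
    color: RGB


@dataclass(frozen=True)
class ArcGeometry:
    """A quadratic Bezier from the bait anchor to a prey anchor."""

    from_angle: float
    to_angle: float
    control_point: Point
    color: RGB
    stroke_width: float
    arc_class: str
    degenerate: bool = False


@dataclass
class CircularDiagram:
    """Fully resolved geometry: ring segments, arcs, legend."""

    segments: list[Segment]
    arcs: list[ArcGeometry]
    options: LayoutOptions
    legend: list[tuple[str, RGB]]
    bait_label: str
    unmatched: list[tuple[int, str]] = field(default_factory=list)
    mapping: Optional[MappingResult] = None

    # -- scene serialization -------------------------------------------------

    def to_scene_dict(self) -> dict:
        return {
            "format": "proteoring-scene",
            "version": 1,
            "options": asdict(self.options),
            "bait_label": self.bait_label,
            "segments": [asdict(s) for s in self.segments],
            "arcs": [asdict(a) for a in self.arcs],
            "legend": [[name, list(color)] for name, color in self.legend],
            "unmatched": [[i, prey] for i, prey in self.unmatched],
        }

    def to_scene_json(self, stream: IO[str] | None = None) -> str:
        text = json.dumps(self.to_scene_dict(), indent=1) + "\n"
        if stream is not None:
            stream.write(text)
        return text

    @classmethod
    def from_scene_dict(cls, d: dict) -> "CircularDiagram":
        if d.get("format") != "proteoring-scene":
            raise ValueError("not a proteoring scene document")
        opts = LayoutOptions(**d["options"])
        segments = [
            Segment(
                kind=s["kind"], label=s["label"], set_index=s["set_index"],
                start_angle=s["start_angle"], end_angle=s["end_angle"],
                width_deg=s["width_deg"], n_units=s["n_units"],
                color=tuple(s["color"]),
            )
            for s in d["segments"]
        ]
        arcs = [
            ArcGeometry(
                from_angle=a["from_angle"], to_angle=a["to_angle"],
                control_point=tuple(a["control_point"]), color=tuple(a["color"]),
                stroke_width=a["stroke_width"], arc_class=a["arc_class"],
                degenerate=a.get("degenerate", False),
            )
            for a in d["arcs"]
        ]
        return cls(
            segments=segments, arcs=arcs, options=opts,
            legend=[(name, tuple(color)) for name, color in d["legend"]],
            bait_label=d["bait_label"],
            unmatched=[(i, prey) for i, prey in d.get("unmatched", [])],
        )

    @classmethod
    def from_scene_json(cls, text: str) -> "CircularDiagram":
        return cls.from_scene_dict(json.loads(text))


def normalize_angle(a: float) -> float:
    """Map an angle to [0, 360)."""
    return a % 360.0


def unit_angle(reference: Reference, opts: LayoutOptions = LayoutOptions()) -> float:
    """Degrees per protein-width unit.

    ``360 / (total set entries + bait_units + 2 * spacer_units)``.
    """
    total = reference.total_entries()
    if total == 0:
        raise ValueError("reference has no protein entries; cannot lay out a circle")
    return 360.0 / (total + opts.bait_units + 2 * opts.spacer_units)


def _direction_sign(opts: LayoutOptions) -> float:
    return -1.0 if opts.clockwise else 1.0


def _segment_sign(seg: Segment) -> float:
    """Infer the layout direction a segment was built with from its angles."""
    if seg.width_deg == 0:
        return 1.0
    fwd = normalize_angle(seg.start_angle + seg.width_deg)
    return 1.0 if math.isclose(fwd, seg.end_angle, abs_tol=1e-6) else -1.0


def compute_segments(
    reference: Reference,
    bait_label: str,
    set_colors: list[RGB],
    opts: LayoutOptions = LayoutOptions(),
) -> list[Segment]:
    """Tile the ring: bait, spacer, the sets in order, spacer.

    The bait segment is centered on ``opts.bait_center_angle``; widths are
    ``n_units * unit_angle`` so the segments sum to exactly 360 degrees.
    Empty sets get a zero-width segment (warned) so set indices stay aligned
    with the reference.
    """
    if len(set_colors) != len(reference.sets):
        raise ValueError("set_colors must align one-to-one with reference.sets")
    unit = unit_angle(reference, opts)
    sign = _direction_sign(opts)

    plan: list[tuple[str, str, Optional[int], float, RGB]] = [
        ("bait", bait_label, None, opts.bait_units, BLACK),
        ("spacer", "", None, opts.spacer_units, WHITE),
    ]
    for i, pset in enumerate(reference.sets):
        if not pset.entries:
            logger.warning("protein set %r is empty: zero-width segment", pset.name)
        plan.append(("set", pset.name, i, float(len(pset.entries)), set_colors[i]))
    plan.append(("spacer", "", None, opts.spacer_units, WHITE))

    segments: list[Segment] = []
    cursor = opts.bait_center_angle - sign * (opts.bait_units * unit) / 2.0
    for kind, label, set_index, n_units, color in plan:
        width = n_units * unit
        start = normalize_angle(cursor)
        end = normalize_angle(cursor + sign * width)
        segments.append(
            Segment(kind, label, set_index, start, end, width, n_units, color)
        )
        cursor += sign * width
    return segments


def anchor_angle(segments: list[Segment], set_index: int, entry_index: int) -> float:
    """Midpoint angle of one protein's slot inside its set segment.

    ``set_start + (entry_index + 0.5) * unit_angle`` advancing in the layout
    direction; strictly interior to the segment.
    """
    for seg in segments:
        if seg.kind == "set" and seg.set_index == set_index:
            if seg.n_units == 0:
                raise IndexError(f"set {set_index} is empty; no anchors")
            if not 0 <= entry_index < seg.n_units:
                raise IndexError(
                    f"entry_index {entry_index} out of range for set {set_index} "
                    f"({int(seg.n_units)} entries)"
                )
            unit = seg.width_deg / seg.n_units
            sign = _segment_sign(seg)
            return normalize_angle(seg.start_angle + sign * (entry_index + 0.5) * unit)
    raise IndexError(f"no set segment with index {set_index}")


def bait_anchor(segments: list[Segment]) -> float:
    """Midpoint angle of the bait segment (all arcs originate here)."""
    for seg in segments:
        if seg.kind == "bait":
            sign = _segment_sign(seg)
            return normalize_angle(seg.start_angle + sign * seg.width_deg / 2.0)
    raise ValueError("no bait segment in layout")


def polar_point(angle_deg: float, radius: float, center: Point = (0.0, 0.0)) -> Point:
    rad = math.radians(angle_deg)
    return (center[0] + radius * math.cos(rad), center[1] + radius * math.sin(rad))


def arc_path(
    from_angle: float,
    to_angle: float,
    opts: LayoutOptions = LayoutOptions(),
    center: Point = (0.0, 0.0),
    radius: float | None = None,
) -> tuple[Point, Point, Point, bool]:
    """Quadratic-Bezier geometry for one arc.

    Returns ``(start_point, control_point, end_point, degenerate)``.
    Endpoints lie on the ring's inner edge; the control point is the circle
    center displaced toward the chord midpoint by ``opts.arc_tension``.
    Near-coincident endpoints are flagged degenerate (drawn as a stub toward
    the center) and warned about.
    """
    r = opts.radius if radius is None else radius
    p0 = polar_point(from_angle, r, center)
    p1 = polar_point(to_angle, r, center)
    sep = abs(normalize_angle(from_angle) - normalize_angle(to_angle))
    sep = min(sep, 360.0 - sep)
    degenerate = sep < DEGENERATE_ARC_EPS
    if degenerate:
        logger.warning(
            "degenerate arc: endpoints %.6f and %.6f deg nearly coincide; "
            "drawing a stub toward the center", from_angle, to_angle,
        )
    chord_mid = ((p0[0] + p1[0]) / 2.0, (p0[1] + p1[1]) / 2.0)
    t = opts.arc_tension
    control = (
        center[0] + t * (chord_mid[0] - center[0]),
        center[1] + t * (chord_mid[1] - center[1]),
    )
    return p0, control, p1, degenerate


def bezier_point(p0: Point, c: Point, p1: Point, t: float) -> Point:
    """Evaluate the quadratic Bezier at parameter ``t``."""
    u = 1.0 - t
    return (
        u * u * p0[0] + 2 * u * t * c[0] + t * t * p1[0],
        u * u * p0[1] + 2 * u * t * c[1] + t * t * p1[1],
    )


def build_diagram(
    e: Experiment,
    reference: Reference,
    scheme: ColorScheme,
    reappearance_on: bool = True,
    opts: LayoutOptions = LayoutOptions(),
    dedupe: bool = True,
    arc_stroke: float = 1.2,
) -> CircularDiagram:
    """Compose the full pipeline into resolved geometry.

    dedupe -> map -> color assignment -> segments -> per-arc anchors/paths.
    Arc color is the containing set's color for 'ppi' and black for 'ivtk';
    'ivtk' arcs are ordered after 'ppi' so substrates draw on top.
    """
    mapping = map_experiment(e, reference, reappearance_on=reappearance_on, dedupe=dedupe)
    set_colors = assign_set_colors(reference, scheme)
    segments = compute_segments(reference, e.bait_id, set_colors, opts)
    origin = bait_anchor(segments)

    arcs: list[ArcGeometry] = []
    for mapped in mapping.arcs:
        target = anchor_angle(segments, mapped.occurrence.set_index, mapped.occurrence.entry_index)
        _, control, _, degenerate = arc_path(origin, target, opts)
        color = BLACK if mapped.arc_class == "ivtk" else set_colors[mapped.occurrence.set_index]
        arcs.append(
            ArcGeometry(
                from_angle=origin,
                to_angle=target,
                control_point=control,
                color=color,
                stroke_width=arc_stroke,
                arc_class=mapped.arc_class,
                degenerate=degenerate,
            )
        )
    arcs.sort(key=lambda a: a.arc_class == "ivtk")  # stable: ppi first, ivtk on top

    legend = [(pset.name, set_colors[i]) for i, pset in enumerate(reference.sets)]
    return CircularDiagram(
        segments=segments,
        arcs=arcs,
        options=opts,
        legend=legend,
        bait_label=e.bait_id,
        unmatched=list(mapping.unmatched),
        mapping=mapping,
    )
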