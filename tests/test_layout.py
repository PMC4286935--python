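"""Angular layout: unit angle, segment tiling, anchors, arc geometry."""

import logging
import math

import pytest

from conftest import make_experiment, make_reference
from proteoring.formats import ColorScheme, parse_color_scheme, parse_experiment, parse_reference
from proteoring.fixtures import FixtureSpec, generate_fixture
from proteoring.layout import (
    CircularDiagram,
    LayoutOptions,
    anchor_angle,
    arc_path,
    bait_anchor,
    bezier_point,
    build_diagram,
    compute_segments,
    normalize_angle,
    unit_angle,
)
from proteoring.mapping import assign_set_colors, map_experiment

DEFAULTS = LayoutOptions()


def sized_reference(sizes):
    return make_reference(
        {f"S{k}": [f"Q{k}_{i}" for i in range(n)] for k, n in enumerate(sizes)}
    )


def segments_for(sizes, opts=DEFAULTS):
    r = sized_reference(sizes)
    colors = [(10 * i % 256, 0, 0) for i in range(len(sizes))]
    return compute_segments(r, "BAIT", colors, opts)


class TestUnitAngle:
    @pytest.mark.parametrize(
        ("sizes", "expected"),
        [
            ([6, 3], 20.0),
            ([351], 1.0),  # 351 + 3 bait + 2x3 spacers = 360 units
            ([10, 5, 5], 360.0 / 29.0),
        ],
    )
    def test_unit_is_360_over_total_units(self, sizes, expected):
        assert unit_angle(sized_reference(sizes)) == pytest.approx(expected, abs=1e-12)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError, match="no protein entries"):
            unit_angle(make_reference({"A": []}))


class TestComputeSegments:
    def test_worked_micro_example(self):
        """Sets {6, 3} with defaults: 20 deg unit, widths 60/60/120/60/60."""
        segs = segments_for([6, 3])
        assert [s.kind for s in segs] == ["bait", "spacer", "set", "set", "spacer"]
        assert [s.width_deg for s in segs] == pytest.approx([60, 60, 120, 60, 60], abs=1e-9)
        assert segs[0].color == (0, 0, 0)
        assert segs[1].color == (255, 255, 255)

    def test_bait_centered_on_requested_angle(self):
        segs = segments_for([6, 3])
        assert bait_anchor(segs) == pytest.approx(90.0)
        segs = segments_for([6, 3], LayoutOptions(bait_center_angle=0.0))
        assert bait_anchor(segs) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(7))
    def test_tiling_and_exclusive_coverage(self, seed):
        """Widths sum to 360 and every angle is inside exactly one segment."""
        import random

        rng = random.Random(seed + 500)
        sizes = [rng.randint(1, 30) for _ in range(rng.randint(1, 8))]
        clockwise = bool(seed % 2)
        segs = segments_for(sizes, LayoutOptions(clockwise=clockwise))
        assert sum(s.width_deg for s in segs) == pytest.approx(360.0, abs=1e-6)
        # independent coverage probe: sample angles, count containing segments
        sign = -1.0 if clockwise else 1.0
        for k in range(720):
            theta = k * 0.5 + 0.123
            containing = 0
            for s in segs:
                offset = sign * (theta - s.start_angle) % 360.0
                if offset < s.width_deg:
                    containing += 1
            assert containing == 1, f"angle {theta} covered {containing} times"

    @pytest.mark.parametrize("seed", range(7))
    def test_set_widths_proportional_to_sizes(self, seed):
        import random

        rng = random.Random(seed + 40)
        sizes = [rng.randint(1, 50) for _ in range(rng.randint(2, 6))]
        segs = [s for s in segments_for(sizes) if s.kind == "set"]
        total_width = sum(s.width_deg for s in segs)
        for s, n in zip(segs, sizes):
            assert s.width_deg / total_width == pytest.approx(n / sum(sizes), rel=1e-9)

    def test_spacer_is_exactly_three_protein_widths_by_default(self):
        segs = segments_for([17, 9, 4])
        unit = unit_angle(sized_reference([17, 9, 4]))
        for s in segs:
            if s.kind == "spacer":
                assert s.width_deg / unit == pytest.approx(3.0, abs=1e-12)

    def test_empty_set_gets_zero_width_but_keeps_index(self, caplog):
        r = make_reference({"A": ["P1"], "B": [], "C": ["P2"]})
        with caplog.at_level(logging.WARNING, logger="proteoring.layout"):
            segs = compute_segments(r, "K", [(1, 1, 1)] * 3)
        set_segs = [s for s in segs if s.kind == "set"]
        assert [s.set_index for s in set_segs] == [0, 1, 2]
        assert set_segs[1].width_deg == 0.0
        assert any("empty" in rec.message for rec in caplog.records)


class TestAnchors:
    def test_anchor_is_slot_midpoint(self):
        segs = segments_for([6, 3])
        s0 = next(s for s in segs if s.set_index == 0)
        # first slot midpoint lies half a unit into the segment, clockwise
        expected = normalize_angle(s0.start_angle - 0.5 * 20.0)
        assert anchor_angle(segs, 0, 0) == pytest.approx(expected)

    def test_anchors_strictly_interior_and_monotone(self):
        segs = segments_for([6, 3])
        for set_index, n in [(0, 6), (1, 3)]:
            seg = next(s for s in segs if s.set_index == set_index)
            offsets = []
            for ei in range(n):
                a = anchor_angle(segs, set_index, ei)
                offset = (seg.start_angle - a) % 360.0  # clockwise layout
                assert 0.0 < offset < seg.width_deg
                offsets.append(offset)
            assert offsets == sorted(offsets)

    def test_out_of_range_indices_raise(self):
        segs = segments_for([6, 3])
        with pytest.raises(IndexError):
            anchor_angle(segs, 0, 6)
        with pytest.raises(IndexError):
            anchor_angle(segs, 5, 0)

    def test_bait_anchor_inside_bait_segment(self):
        segs = segments_for([10, 2, 7], LayoutOptions(bait_center_angle=217.0))
        a = bait_anchor(segs)
        bait = next(s for s in segs if s.kind == "bait")
        offset = (bait.start_angle - a) % 360.0
        assert 0.0 < offset < bait.width_deg


class TestArcPath:
    def test_tension_zero_passes_through_center(self):
        p0, c, p1, degenerate = arc_path(90.0, 270.0, DEFAULTS)
        assert not degenerate
        assert c == pytest.approx((0.0, 0.0), abs=1e-12)
        mid = bezier_point(p0, c, p1, 0.5)
        assert mid == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_nearly_coincident_endpoints_flagged_degenerate(self, caplog):
        with caplog.at_level(logging.WARNING, logger="proteoring.layout"):
            *_, degenerate = arc_path(90.0, 90.0001, DEFAULTS)
        assert degenerate
        assert any("degenerate" in rec.message for rec in caplog.records)

    def test_higher_tension_pulls_midpoint_toward_chord(self):
        lo = LayoutOptions(arc_tension=0.0)
        hi = LayoutOptions(arc_tension=1.0)
        p0, c0, p1, _ = arc_path(40.0, 170.0, lo)
        _, c1, _, _ = arc_path(40.0, 170.0, hi)
        chord_mid = ((p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2)

        def dist_to_chord_mid(c):
            m = bezier_point(p0, c, p1, 0.5)
            return math.hypot(m[0] - chord_mid[0], m[1] - chord_mid[1])

        assert dist_to_chord_mid(c1) < dist_to_chord_mid(c0)

    def test_endpoints_on_ring_inner_edge(self):
        p0, _, p1, _ = arc_path(33.0, 201.0, DEFAULTS)
        assert math.hypot(*p0) == pytest.approx(DEFAULTS.radius)
        assert math.hypot(*p1) == pytest.approx(DEFAULTS.radius)


class TestBuildDiagram:
    def test_minimal_ppi_arc_takes_set_color(self):
        r = make_reference({"A": ["P1"]})
        e = make_experiment("K", [("ppi", "P1")])
        d = build_diagram(e, r, ColorScheme([(255, 0, 0)]))
        assert len(d.arcs) == 1
        assert d.arcs[0].color == (255, 0, 0)
        assert d.arcs[0].from_angle == pytest.approx(bait_anchor(d.segments))

    def test_ivtk_arc_is_black(self):
        r = make_reference({"A": ["P1"]})
        e = make_experiment("K", [("ivtk", "P1")])
        d = build_diagram(e, r, ColorScheme([(255, 0, 0)]))
        assert d.arcs[0].color == (0, 0, 0)

    def test_ivtk_arcs_drawn_after_ppi(self):
        r = make_reference({"A": ["P1", "P2", "P3"]})
        e = make_experiment("K", [("ivtk", "P1"), ("ppi", "P2"), ("ivtk", "P3")])
        d = build_diagram(e, r, ColorScheme([(0, 255, 0)]))
        assert [a.arc_class for a in d.arcs] == ["ppi", "ivtk", "ivtk"]

    @pytest.mark.parametrize("reappearance_on", [True, False])
    def test_arc_counts_match_mapping(self, reappearance_on):
        fx = generate_fixture(FixtureSpec(seed=21, cross_set_duplication=0.3))
        e = parse_experiment(fx.experiment)
        r = parse_reference(fx.reference)
        c = parse_color_scheme(fx.scheme)
        d = build_diagram(e, r, c, reappearance_on=reappearance_on)
        res = map_experiment(e, r, reappearance_on=reappearance_on)
        assert len(d.arcs) == len(res.arcs)
        assert d.unmatched == res.unmatched

    def test_every_prey_anchor_inside_a_set_segment(self):
        fx = generate_fixture(FixtureSpec(seed=8, cross_set_duplication=0.25))
        d = build_diagram(
            parse_experiment(fx.experiment),
            parse_reference(fx.reference),
            parse_color_scheme(fx.scheme),
        )
        set_segs = [s for s in d.segments if s.kind == "set" and s.width_deg > 0]
        bait = next(s for s in d.segments if s.kind == "bait")
        for arc in d.arcs:
            inside = [
                s for s in set_segs
                if (s.start_angle - arc.to_angle) % 360.0 < s.width_deg
            ]
            assert len(inside) == 1
            assert (bait.start_angle - arc.from_angle) % 360.0 < bait.width_deg

    def test_geometry_is_deterministic(self):
        fx = generate_fixture(FixtureSpec(seed=14))
        args = (
            parse_experiment(fx.experiment),
            parse_reference(fx.reference),
            parse_color_scheme(fx.scheme),
        )
        d1, d2 = build_diagram(*args), build_diagram(*args)
        assert d1.segments == d2.segments and d1.arcs == d2.arcs

    def test_scene_json_round_trip(self):
        fx = generate_fixture(FixtureSpec(seed=9))
        d = build_diagram(
            parse_experiment(fx.experiment),
            parse_reference(fx.reference),
            parse_color_scheme(fx.scheme),
            opts=LayoutOptions(arc_tension=0.4, clockwise=False),
        )
        d2 = CircularDiagram.from_scene_json(d.to_scene_json())
        assert d2.segments == d.segments
        assert d2.arcs == d.arcs
        assert d2.options == d.options
        assert d2.legend == d.legend
        assert d2.unmatched == d.unmatched
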