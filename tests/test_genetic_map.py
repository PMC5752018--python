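"""Segment notation parsing/formatting and cM interval algebra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sssltools.genetic_map import (
    CMInterval,
    GeneticMap,
    Marker,
    SegmentNotationError,
    SubstitutedSegment,
    estimate_segment_length,
    format_segment_notation,
    intersect,
    parse_segment_notation,
    segment_to_interval,
    subtract,
)

from conftest import grid_membership


class TestParseNotation:
    @pytest.mark.parametrize(
        "text, chrom, left, inner, right, terminal",
        [
            (  # primary-SSSL segment with both flanking markers
                "RM596—RM271-RM269-RM258-RM304—PSM167",
                10,
                "RM596",
                ("RM271", "RM269", "RM258", "RM304"),
                "PSM167",
                None,
            ),
            ("A—B—C", 1, "A", ("B",), "C", None),
            (  # ASCII double hyphen accepted on input
                "RM170--RM190-RM217--RM314",
                6,
                "RM170",
                ("RM190", "RM217"),
                "RM314",
                None,
            ),
            (  # chromosome-end anchor attached with a double hyphen
                "Short arm—PSM306-RM569-RM489—RM545",
                3,
                None,
                ("PSM306", "RM569", "RM489"),
                "RM545",
                "Short arm",
            ),
            (  # chromosome-end anchor attached with a single hyphen
                "Short arm-RM569-PSM429-RM232-RM563—RM282",
                3,
                None,
                ("RM569", "PSM429", "RM232", "RM563"),
                "RM282",
                "Short arm",
            ),
            ("X1-X2-X3", 2, None, ("X1", "X2", "X3"), None, None),
            ("B", 2, None, ("B",), None, None),
        ],
    )
    def test_examples(self, text, chrom, left, inner, right, terminal):
        seg = parse_segment_notation(text, chrom)
        assert seg.left_flank == left
        assert seg.inner_markers == inner
        assert seg.right_flank == right
        assert seg.terminal_label == terminal
        assert seg.chromosome == chrom

    @pytest.mark.parametrize(
        "text",
        [
            "",
            "  ",
            "—A—",  # empty flank token
            "A—B—C—D",  # too many separators
            "A—B-B—C",  # duplicate inner marker
            "A—A-B—C",  # flank duplicates inner
            "A—B-C—Short arm",  # terminal label on the right
        ],
    )
    def test_malformed(self, text):
        with pytest.raises(SegmentNotationError):
            parse_segment_notation(text, 1)


class TestFormatNotation:
    def test_flanked_segment_renders_with_em_dashes(self):
        seg = SubstitutedSegment(
            chromosome=3,
            inner_markers=("RM3894", "RM3372"),
            left_flank="PSM304",
            right_flank="RM569",
        )
        assert format_segment_notation(seg) == "PSM304—RM3894-RM3372—RM569"

    def test_inner_only_single_hyphens(self):
        seg = SubstitutedSegment(chromosome=1, inner_markers=("A", "B", "C"))
        assert format_segment_notation(seg) == "A-B-C"

    names = st.text(alphabet="RMPS0123456789", min_size=2, max_size=6).map(
        lambda s: "M" + s
    )

    @given(
        inner=st.lists(names, min_size=1, max_size=5, unique=True),
        left=st.one_of(st.none(), names),
        right=st.one_of(st.none(), names),
        terminal=st.sampled_from([None, "Short arm"]),
    )
    def test_round_trip(self, inner, left, right, terminal):
        if left in inner or right in inner or (left is not None and left == right):
            return
        if terminal is not None:
            left = None
        if left is None and terminal is None and right is not None and len(inner) == 1:
            return  # single-token "B—C" is documented as ambiguous
        seg = SubstitutedSegment(
            chromosome=1,
            inner_markers=tuple(inner),
            left_flank=left,
            right_flank=right,
            terminal_label=terminal,
        )
        text = format_segment_notation(seg)
        assert parse_segment_notation(text, 1) == seg
        assert format_segment_notation(parse_segment_notation(text, 1)) == text


class TestSegmentLength:
    def test_midpoint_convention_hand_example(self, toy_map):
        seg = SubstitutedSegment(
            chromosome=1, inner_markers=("M1", "M3"), left_flank="F0", right_flank="F1"
        )
        # span 10 + half of 2.0 + half of 4.0
        assert estimate_segment_length(seg, toy_map) == pytest.approx(13.0)
        assert estimate_segment_length(seg, toy_map, "flank_to_flank") == pytest.approx(16.0)

    def test_coincident_flanks_zero_length(self):
        gmap = GeneticMap(
            [Marker("L", 1, 5.0), Marker("A", 1, 5.0), Marker("R", 1, 5.0)]
        )
        seg = SubstitutedSegment(
            chromosome=1, inner_markers=("A",), left_flank="L", right_flank="R"
        )
        assert estimate_segment_length(seg, gmap) == 0.0

    def test_no_flanks_equals_inner_span(self, toy_map):
        seg = SubstitutedSegment(chromosome=1, inner_markers=("M1", "M2", "M3"))
        assert estimate_segment_length(seg, toy_map) == pytest.approx(10.0)

    def test_terminal_label_anchors_at_zero(self, toy_map):
        seg = SubstitutedSegment(
            chromosome=1,
            inner_markers=("M1", "M3"),
            terminal_label="Short arm",
            right_flank="F1",
        )
        # left gap is the full 10 cM to the chromosome top
        assert estimate_segment_length(seg, toy_map) == pytest.approx(10 + 5.0 + 2.0)

    def test_adding_outer_inner_marker_never_shortens(self, toy_map):
        base = SubstitutedSegment(
            chromosome=1, inner_markers=("M1", "M2"), left_flank="F0"
        )
        wider = SubstitutedSegment(
            chromosome=1, inner_markers=("M1", "M2", "M3"), left_flank="F0"
        )
        assert estimate_segment_length(wider, toy_map) >= estimate_segment_length(
            base, toy_map
        )

    def test_unknown_marker_raises(self, toy_map):
        seg = SubstitutedSegment(chromosome=1, inner_markers=("NOPE",))
        with pytest.raises(KeyError):
            estimate_segment_length(seg, toy_map)

    def test_flank_inside_span_raises(self, toy_map):
        seg = SubstitutedSegment(
            chromosome=1, inner_markers=("M1", "M3"), left_flank="M2"
        )
        with pytest.raises(ValueError):
            estimate_segment_length(seg, toy_map)


class TestSegmentToInterval:
    def test_hand_example(self, toy_map):
        seg = SubstitutedSegment(
            chromosome=1, inner_markers=("M1", "M3"), left_flank="F0", right_flank="F1"
        )
        iv = segment_to_interval(seg, toy_map)
        assert (iv.start, iv.end) == (9.0, 22.0)
        for name in seg.inner_markers:
            assert iv.contains(toy_map.position(name))

    def test_point_segment(self):
        gmap = GeneticMap([Marker("A", 1, 7.0)])
        seg = SubstitutedSegment(chromosome=1, inner_markers=("A",))
        iv = segment_to_interval(seg, gmap)
        assert iv.length == 0.0

    def test_length_matches_estimate(self, toy_map):
        rng = np.random.default_rng(0)
        names = ["F0", "M1", "M2", "M3", "F1", "END"]
        for _ in range(50):
            i = int(rng.integers(1, 4))
            j = int(rng.integers(i, 5))
            seg = SubstitutedSegment(
                chromosome=1,
                inner_markers=tuple(names[i : j + 1]),
                left_flank=names[i - 1] if rng.random() < 0.5 else None,
                right_flank=names[j + 1] if j + 1 < len(names) and rng.random() < 0.5 else None,
            )
            iv = segment_to_interval(seg, toy_map)
            assert iv.length == pytest.approx(estimate_segment_length(seg, toy_map))


class TestIntervalAlgebra:
    def test_intersection_and_difference(self):
        a = CMInterval(1, 0, 10)
        b = CMInterval(1, 5, 15)
        assert intersect(a, b) == CMInterval(1, 5, 10)
        assert subtract(a, b) == [CMInterval(1, 0, 5)]
        assert intersect(CMInterval(1, 0, 4), CMInterval(1, 5, 9)) is None
        assert subtract(a, CMInterval(1, 3, 6)) == [
            CMInterval(1, 0, 3),
            CMInterval(1, 6, 10),
        ]
        assert subtract(a, CMInterval(1, -1, 11)) == []

    def test_chromosome_mismatch(self):
        with pytest.raises(ValueError):
            intersect(CMInterval(1, 0, 1), CMInterval(2, 0, 1))
        with pytest.raises(ValueError):
            subtract(CMInterval(1, 0, 1), CMInterval(2, 0, 1))

    def test_agrees_with_grid_membership(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            s1, s2 = np.round(rng.uniform(0, 30, 2), 2)
            e1, e2 = s1 + round(rng.uniform(0, 10), 2), s2 + round(rng.uniform(0, 10), 2)
            a, b = CMInterval(1, s1, e1), CMInterval(1, s2, e2)
            inter = intersect(a, b)
            diff = subtract(a, b)
            grid = np.arange(0, 45, 0.01)
            # skip points at interval boundaries (closed-endpoint conventions)
            eps = 5e-3
            away = np.ones_like(grid, dtype=bool)
            for x in (s1, e1, s2, e2):
                away &= np.abs(grid - x) > eps
            in_a = (grid >= s1) & (grid <= e1)
            in_b = (grid >= s2) & (grid <= e2)
            got_inter = grid_membership([inter] if inter else [], 0, 45 - 0.01)[: len(grid)]
            got_diff = grid_membership(diff, 0, 45 - 0.01)[: len(grid)]
            assert np.array_equal(got_inter[away], (in_a & in_b)[away])
            assert np.array_equal(got_diff[away], (in_a & ~in_b)[away])
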