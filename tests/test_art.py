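"""Art-modality metrics: worked examples and geometric invariances."""

import math

import pytest

from strokenote.art import (
    art_metrics,
    canvas_usage,
    color_tool_usage,
    erasure_pct,
    stroke_aggregate,
    stroke_features,
    time_budget,
)
from strokenote.events import ArtSession

from conftest import stroke


def art(strokes, w=300, h=300, duration=None, **kw):
    if duration is None:
        duration = max((s.end for s in strokes), default=0.0)
    return ArtSession(strokes=strokes, canvas_width=w, canvas_height=h,
                      duration=duration, **kw)


class TestTimeBudget:
    def test_two_strokes_in_ten_seconds(self):
        session = art([stroke([(0, 1, 1), (2, 5, 5)]), stroke([(5, 1, 1), (7, 5, 5)])],
                      duration=10)
        assert time_budget(session) == pytest.approx((4, 40, 6))

    def test_empty_session(self):
        assert time_budget(art([], duration=10)) == (0, 0, 10)

    def test_full_coverage_is_100_pct(self):
        session = art([stroke([(0, 1, 1), (10, 5, 5)])], duration=10)
        assert time_budget(session)[1] == pytest.approx(100.0)


class TestColorToolUsage:
    def test_blue_then_red_shares_and_one_switch(self):
        session = art([stroke([(0, 1, 1), (3, 5, 5)], color="blue"),
                       stroke([(4, 1, 1), (5, 5, 5)], color="red")], duration=5)
        u = color_tool_usage(session)
        assert u["color_use_pct"]["blue"] == pytest.approx(75.0)
        assert u["color_use_pct"]["red"] == pytest.approx(25.0)
        assert u["color_switches"] == 1

    def test_two_of_ten_palette_colors_is_20_pct(self):
        session = art([stroke([(0, 1, 1), (1, 2, 2)], color="blue"),
                       stroke([(2, 1, 1), (3, 2, 2)], color="red")])
        assert color_tool_usage(session)["pct_colors_used"] == pytest.approx(20.0)

    def test_erasure_share_of_drawing_time(self):
        session = art([stroke([(0, 1, 1), (8, 5, 5)]),
                       stroke([(8.5, 1, 1), (10.5, 5, 5)], tool="eraser")],
                      duration=12)
        assert erasure_pct(session) == pytest.approx(20.0)

    def test_color_shares_plus_eraser_partition_drawing_time(self):
        session = art([stroke([(0, 1, 1), (3, 5, 5)], color="blue"),
                       stroke([(4, 1, 1), (6, 5, 5)], tool="eraser"),
                       stroke([(7, 1, 1), (9, 5, 5)], color="green")], duration=10)
        total = sum(color_tool_usage(session)["color_use_pct"].values())
        assert total + erasure_pct(session) == pytest.approx(100.0, abs=1e-6)


class TestStrokeFeatures:
    def test_three_four_five_triangle(self):
        f = stroke_features(stroke([(0, 0, 0), (1, 3, 4)]))
        assert f.length == pytest.approx(5.0)
        assert f.velocity == pytest.approx(5.0)
        assert f.direction == pytest.approx(math.atan2(-4, 3))
        assert f.amplitude == pytest.approx(5.0)

    def test_rotation_sense_on_screen(self):
        # screen coords (y down): right, down, left, up = clockwise visually
        cw = stroke([(0, 0, 0), (1, 10, 0), (2, 10, 10), (3, 0, 10), (4, 0, 0)])
        ccw = stroke([(0, 0, 0), (1, 0, 10), (2, 10, 10), (3, 10, 0), (4, 0, 0)])
        assert stroke_features(cw).rotation == "cw"
        assert stroke_features(ccw).rotation == "ccw"

    def test_straight_stroke_has_no_rotation(self):
        f = stroke_features(stroke([(0, 0, 0), (1, 5, 5), (2, 10, 10)]))
        assert f.rotation == "none"

    def test_single_sample_stroke_is_all_zero(self):
        f = stroke_features(stroke([(0, 5, 5)]))
        assert (f.length, f.velocity, f.amplitude, f.rotation) == (0, 0, 0, "none")


class TestStrokeAggregate:
    def test_counts_and_mean_length(self):
        session = art([stroke([(0, 0, 0), (1, 5, 0)]),  # length 5
                       stroke([(2, 0, 0), (3, 3, 0)])])  # length 3
        agg = stroke_aggregate(session)
        assert agg["stroke_count"] == 2
        assert agg["total_stroke_length"] == pytest.approx(8.0)
        assert agg["mean_stroke_length"] == pytest.approx(4.0)

    def test_constant_pressure(self):
        session = art([stroke([(0, 0, 0, 0.5), (1, 5, 0, 0.5), (2, 9, 0, 0.5)])])
        agg = stroke_aggregate(session)
        assert agg["mean_pressure"] == pytest.approx(0.5)
        assert agg["pressure_max"] == pytest.approx(0.5)

    def test_velocity_is_length_over_net_time(self):
        session = art([stroke([(0, 0, 0), (2, 10, 0)])])
        assert stroke_aggregate(session)["mean_drawing_velocity"] == pytest.approx(5.0)


class TestCanvasUsage:
    def test_stroke_in_one_cell_of_nine(self):
        session = art([stroke([(0, 10, 10), (1, 50, 50)])])  # top-left cell
        got = canvas_usage(session, 3, 3)
        assert got["canvas_cell_occupancy"] == pytest.approx(100 / 9)

    def test_straight_left_to_right_crosses_twice(self):
        session = art([stroke([(0, 50, 150), (1, 150, 150), (2, 250, 150)])])
        got = canvas_usage(session, 3, 3)
        assert got["horizontal_crossings"] == 2
        assert got["vertical_crossings"] == 0

    def test_resampling_does_not_double_count_crossings(self):
        coarse = art([stroke([(0, 50, 150), (2, 250, 150)])])
        fine = art([stroke([(i * 0.1, 50 + 10 * i, 150) for i in range(21)])])
        a = canvas_usage(coarse, 3, 3)
        b = canvas_usage(fine, 3, 3)
        assert a["horizontal_crossings"] == b["horizontal_crossings"] == 2

    def test_all_time_in_center(self):
        session = art([stroke([(0, 120, 120), (1, 180, 180)])])
        got = canvas_usage(session, 3, 3)
        assert got["pct_time_in_center"] == pytest.approx(100.0)
        assert got["pct_time_on_boundary"] == 0.0

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            canvas_usage(art([]), 1, 3)


class TestFullRecord:
    def test_empty_session(self):
        m = art_metrics(art([], duration=5))
        assert m.stroke_count == 0 and m.total_stroke_length == 0
        assert m.erasure_pct_of_drawing_time is None
        assert m.mean_pressure is None

    def test_hand_computed_three_stroke_fixture(self, three_stroke_art_session):
        m = art_metrics(three_stroke_art_session)
        assert m.total_duration_min == pytest.approx(0.2)
        assert m.net_drawing_time_s == pytest.approx(5.0)  # 2 + 2 + 1
        assert m.pct_net_drawing_time == pytest.approx(100 * 5 / 12)
        assert m.idle_time_s == pytest.approx(7.0)
        assert m.erasure_pct_of_drawing_time == pytest.approx(20.0)  # 1 of 5 s
        assert m.color_use_pct == {"blue": pytest.approx(40.0),
                                   "red": pytest.approx(40.0)}
        assert m.tool_use_pct["eraser"] == pytest.approx(20.0)
        assert m.stroke_count == 3
        # lengths: 80 (pencil), 200 (ink), 10 (eraser)
        assert m.total_stroke_length == pytest.approx(290.0)
        assert m.mean_stroke_length == pytest.approx(290 / 3)
        assert m.mean_drawing_velocity == pytest.approx(290 / 5)
        assert m.pct_colors_used == pytest.approx(20.0)  # blue, red of 10
        assert m.pct_tools_used == pytest.approx(50.0)  # 3 of 6
        assert m.horizontal_crossings == 2  # the ink stroke spans 3 columns
        assert m.color_by_tool_crosstab == {("pencil", "blue"): pytest.approx(2.0),
                                            ("ink_pen", "red"): pytest.approx(2.0)}

    def test_recomputation_identical(self, three_stroke_art_session):
        assert art_metrics(three_stroke_art_session) == art_metrics(
            three_stroke_art_session)


class TestInvariances:
    @pytest.fixture
    def session(self):
        s1 = stroke([(0, 10, 10), (1, 60, 40), (2, 90, 20)], color="blue")
        s2 = stroke([(3, 50, 150), (4, 150, 180), (5, 250, 150), (6, 150, 100)],
                    color="red")
        return art([s1, s2], duration=8)

    @staticmethod
    def transform(session, scale=1.0, dx=0.0, dy=0.0, w=1000, h=1000):
        strokes = [
            stroke([(s.t, s.x * scale + dx, s.y * scale + dy, s.pressure)
                    for s in st.samples], tool=st.tool, color=st.color)
            for st in session.strokes
        ]
        return art(strokes, w=w, h=h, duration=session.duration)

    def test_rigid_translation_preserves_kinematics(self, session):
        m0 = art_metrics(self.transform(session))
        m1 = art_metrics(self.transform(session, dx=40, dy=25))
        assert m1.total_stroke_length == pytest.approx(m0.total_stroke_length)
        assert m1.mean_drawing_velocity == pytest.approx(m0.mean_drawing_velocity)
        assert m1.rotation_counts == m0.rotation_counts

    def test_uniform_scaling_scales_lengths_keeps_percentages(self, session):
        c = 3.0
        m0 = art_metrics(self.transform(session))
        m1 = art_metrics(self.transform(session, scale=c, w=3000, h=3000))
        assert m1.total_stroke_length == pytest.approx(c * m0.total_stroke_length)
        assert m1.pct_net_drawing_time == pytest.approx(m0.pct_net_drawing_time)
        assert m1.color_use_pct == pytest.approx(m0.color_use_pct)
        assert m1.rotation_counts == m0.rotation_counts
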