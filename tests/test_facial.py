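"""Geometric facial features F1-F7 and their window aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from playaffect.exceptions import InvalidInputError
from playaffect.facial import (
    LandmarkTrack,
    aggregate_window,
    eye_area,
    eyebrow_activity,
    face_area,
    face_motion,
    facial_com,
    frame_features,
    mouth_corner,
    mouth_outer,
    window_features,
)
from playaffect.segmentation import AnalysisWindow


def frames_strategy():
    coord = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)
    return st.lists(st.tuples(coord, coord), min_size=68, max_size=68).map(np.array)


class TestPerFrame:
    def test_all_points_coincident_zero_everything(self):
        frame = np.ones((68, 2)) * 7.0
        assert mouth_outer(frame) == 0.0
        assert mouth_corner(frame) == 0.0
        assert eye_area(frame) == 0.0
        assert eyebrow_activity(frame) == 0.0
        assert face_area(frame) == 0.0

    def test_outer_lip_unit_square_perimeter(self, template):
        frame = template.copy()
        corners = [(0, 0), (1, 0), (1, 1), (0, 1)]
        for i in range(12):  # 12 lip points collapsed onto 4 corners in order
            frame[48 + i] = corners[i // 3]
        assert mouth_outer(frame) == pytest.approx(4.0)

    def test_mouth_corner_3_4_5(self, template):
        frame = template.copy()
        frame[48], frame[54] = (0.0, 0.0), (3.0, 4.0)
        assert mouth_corner(frame) == pytest.approx(5.0)

    def test_eye_area_unit_square_one_eye_collapsed(self, template):
        frame = template.copy()
        square = [(0, 0), (0.5, 0), (1, 0), (1, 1), (0.5, 1), (0, 1)]
        frame[36:42] = square  # degenerate hexagon on a unit square
        frame[42:48] = 5.0     # other eye collapsed to a point
        assert eye_area(frame) == pytest.approx(1.0)

    def test_collinear_eye_points_zero_area(self, template):
        frame = template.copy()
        frame[36:48, 1] = 0.0
        frame[36:48, 0] = np.arange(12)
        assert eye_area(frame) == 0.0

    def test_inner_brows_distance(self, template):
        frame = template.copy()
        frame[21], frame[22] = (-1.0, 0.0), (1.0, 0.0)
        assert eyebrow_activity(frame) == pytest.approx(2.0)

    def test_frown_reduces_brow_distance_by_20pct(self, template):
        neutral = eyebrow_activity(template)
        frame = template.copy()
        mid = (frame[21] + frame[22]) / 2
        for i in (21, 22):  # move each inner brow 20% of the way to the midline
            frame[i] = mid + (frame[i] - mid) * 0.8
        assert eyebrow_activity(frame) == pytest.approx(0.8 * neutral)

    def test_collinear_frame_zero_hull_area(self):
        frame = np.column_stack([np.arange(68.0), np.arange(68.0)])
        assert face_area(frame) == 0.0

    def test_template_mouth_perimeter_matches_hand_summation(self, template):
        lip = template[48:60]
        expected = sum(
            float(np.hypot(*(lip[(i + 1) % 12] - lip[i]))) for i in range(12)
        )
        assert mouth_outer(template) == pytest.approx(expected, rel=1e-12)

    def test_template_eye_area_matches_independent_shoelace(self, template):
        def shoelace(poly):
            a = 0.0
            for i in range(len(poly)):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % len(poly)]
                a += x1 * y2 - x2 * y1
            return abs(a) / 2
        expected = shoelace(template[36:42]) + shoelace(template[42:48])
        assert eye_area(template) == pytest.approx(expected, rel=1e-12)

    def test_template_hull_area_matches_shapely(self, template):
        from shapely.geometry import MultiPoint

        expected = MultiPoint(template.tolist()).convex_hull.area
        assert face_area(template) == pytest.approx(expected, rel=1e-9)

    def test_malformed_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            mouth_outer(np.zeros((67, 2)))
        with pytest.raises(InvalidInputError):
            eye_area(np.full((68, 2), np.nan))

    @given(frame=frames_strategy(),
           k=st.floats(min_value=0.1, max_value=50.0),
           shift=st.tuples(st.floats(-500, 500), st.floats(-500, 500)))
    @settings(deadline=None, max_examples=50)
    def test_translation_invariance_and_scaling_laws(self, frame, k, shift):
        moved = frame + np.asarray(shift)
        for fn in (mouth_outer, mouth_corner, eye_area, eyebrow_activity, face_area):
            assert fn(moved) == pytest.approx(fn(frame), rel=1e-6, abs=1e-6)
        for fn in (mouth_outer, mouth_corner, eyebrow_activity):  # lengths ~ k
            assert fn(frame * k) == pytest.approx(k * fn(frame), rel=1e-6, abs=1e-6)
        for fn in (eye_area, face_area):  # areas ~ k^2
            assert fn(frame * k) == pytest.approx(k**2 * fn(frame), rel=1e-6, abs=1e-4)


class TestMotionFeatures:
    def make_track(self, offsets, template, fps=50.0):
        pts = template[None] + np.asarray(offsets)[:, None, :]
        return LandmarkTrack(fps=fps, points=pts)

    def test_static_track_zero_motion(self, template):
        track = self.make_track(np.zeros((100, 2)), template)
        assert np.all(face_motion(track) == 0.0)
        assert np.all(facial_com(track) == 0.0)

    def test_constant_velocity_full_window_sum(self, template):
        n = 120
        offsets = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        track = self.make_track(offsets, template, fps=50.0)
        series = face_motion(track)
        assert series[0] == 0.0
        assert series[60] == pytest.approx(50.0)  # 50 unit steps in the trailing 1 s
        assert face_motion(track, 60) == pytest.approx(50.0)

    def test_random_walk_matches_bruteforce_sum(self, template, rng):
        offsets = np.cumsum(rng.standard_normal((80, 2)), axis=0)
        track = self.make_track(offsets, template, fps=50.0)
        series = face_motion(track)
        nose = track.points[:, 30]
        for i in (0, 1, 30, 49, 50, 79):
            expected = sum(
                float(np.linalg.norm(nose[j] - nose[j - 1]))
                for j in range(max(1, i - 49), i + 1)
            )
            assert series[i] == pytest.approx(expected, rel=1e-9)

    def test_rigid_translation_com_displacement(self, template):
        offsets = np.array([[0.0, 0.0], [3.0, 4.0]])
        track = self.make_track(offsets, template)
        assert facial_com(track, 0) == 0.0
        assert facial_com(track, 1) == pytest.approx(5.0)

    def test_opposing_deformation_cancels_com(self, template):
        pts = np.stack([template, template.copy()])
        pts[1, 0] += (10.0, 0.0)   # one landmark right...
        pts[1, 1] -= (10.0, 0.0)   # ...another equally left
        track = LandmarkTrack(fps=50.0, points=pts)
        assert facial_com(track, 1) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_index(self, template):
        track = self.make_track(np.zeros((10, 2)), template)
        with pytest.raises(InvalidInputError):
            face_motion(track, 10)


class TestAggregation:
    def test_constant_series(self):
        w = AnalysisWindow(0.0, 1.0)
        series = np.full(50, 3.5)
        assert aggregate_window(series, "F1", w, fps=50.0) == 3.5
        assert aggregate_window(series, "F3", w, fps=50.0) == 0.0

    def test_two_point_mean_and_population_std(self):
        w = AnalysisWindow(0.0, 1.0)
        series = np.array([0.0, 2.0])
        assert aggregate_window(series, "F5", w, fps=2.0) == 1.0
        assert aggregate_window(series, "F4", w, fps=2.0) == 1.0  # n-denominator

    def test_random_series_matches_two_pass_oracle(self, rng):
        series = rng.normal(10.0, 2.0, 150)
        w = AnalysisWindow(0.0, 3.0)
        mean = sum(series) / len(series)
        var = sum((v - mean) ** 2 for v in series) / len(series)
        assert aggregate_window(series, "F2", w, fps=50.0) == pytest.approx(mean)
        assert aggregate_window(series, "F6", w, fps=50.0) == pytest.approx(var**0.5)

    def test_mean_of_concatenation_is_mean_of_window_means(self, rng):
        series = rng.normal(size=100)
        a = aggregate_window(series, "F1", AnalysisWindow(0.0, 1.0), fps=50.0)
        b = aggregate_window(series, "F1", AnalysisWindow(1.0, 1.0), fps=50.0)
        both = aggregate_window(series, "F1", AnalysisWindow(0.0, 2.0), fps=50.0)
        assert both == pytest.approx((a + b) / 2)

    def test_window_past_series_end_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate_window(np.ones(50), "F1", AnalysisWindow(0.5, 1.0), fps=50.0)

    def test_window_features_table(self, template, rng):
        n = 150
        pts = template[None] + rng.normal(0, 0.1, (n, 1, 2))
        track = LandmarkTrack(fps=50.0, points=pts)
        wins = [AnalysisWindow(0.0, 1.0), AnalysisWindow(1.0, 1.0)]
        table = window_features(track, wins)
        assert list(table.columns) == ["window_start_s", *[f"F{i}" for i in range(1, 8)]]
        per_frame = frame_features(track)
        assert table.loc[0, "F1"] == pytest.approx(per_frame["F1"].iloc[:50].mean())
        assert table.loc[1, "F3"] == pytest.approx(per_frame["F3"].iloc[50:100].std(ddof=0))
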