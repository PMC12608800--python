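import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

from thermarousal import (FEATURE_COLUMNS, FilterConfig, ThermalNormalization,
                          align_streams, assemble_features, atc, eod_filter,
                          eod_raw, features_from_tracks, lt_differences,
                          place_rois, roi_mean_luminance, smooth_lt)
from thermarousal.features import _rotate
from thermarousal.io_streams import LandmarkStream, ThermalSequence
from thermarousal.synthetic import render_thermal_frames


def rotate_about(points, angle_deg, center):
    return _rotate(np.asarray(points, float), np.deg2rad(angle_deg),
                   np.asarray(center, float))


class TestPlaceRois:
    def test_upright_face_gives_axis_aligned_rects(self, template_face,
                                                   scheme):
        rois = place_rois(template_face, scheme)
        assert set(rois) == {"nose", "right_cheek", "left_cheek"}
        nose = rois["nose"]
        # axis aligned: unique x and y values, correct size
        assert np.ptp(nose[:, 0]) == pytest.approx(10.0)
        assert np.ptp(nose[:, 1]) == pytest.approx(30.0)
        np.testing.assert_allclose(nose[0, 1], nose[1, 1])
        # nose centred on the ridge midpoint
        center = nose.mean(axis=0)
        mid = (template_face[scheme.nose_root]
               + template_face[scheme.nose_apex]) / 2
        np.testing.assert_allclose(center, mid, atol=1e-9)

    def test_cheeks_sit_below_the_eyes(self, template_face, scheme):
        rois = place_rois(template_face, scheme)
        for name, lower in (("right_cheek", scheme.right_eye_lower),
                            ("left_cheek", scheme.left_eye_lower)):
            assert rois[name][:, 1].min() > template_face[lower, 1]
            assert np.ptp(rois[name][:, 0]) == pytest.approx(20.0)

    def test_rotated_face_rotates_rois_rigidly(self, template_face, scheme):
        pivot = template_face[scheme.nostril_center]
        rotated = rotate_about(template_face, 10.0, pivot)
        rois_up = place_rois(template_face, scheme)
        rois_rot = place_rois(rotated, scheme)
        for name in rois_up:
            expected = rotate_about(rois_up[name], 10.0, pivot)
            np.testing.assert_allclose(rois_rot[name], expected, atol=1e-9)

    def test_roi_leaving_frame_flags_invalid(self, template_face):
        shifted = template_face + np.array([310.0, 0.0])  # nose at the edge
        assert place_rois(shifted) is None


class TestRoiMeanLuminance:
    def test_constant_frame(self, template_face):
        frame = np.full((480, 640), 128.0)
        rois = place_rois(template_face)
        assert roi_mean_luminance(frame, rois["nose"]) == 128.0

    def test_axis_aligned_two_by_two(self):
        frame = np.zeros((10, 10))
        frame[2, 2], frame[2, 3], frame[3, 2], frame[3, 3] = 10, 20, 30, 40
        poly = np.array([[1.5, 1.5], [3.5, 1.5], [3.5, 3.5], [1.5, 3.5]])
        assert roi_mean_luminance(frame, poly) == 25.0

    def test_matches_shapely_on_random_rotated_rois(self):
        rng = np.random.default_rng(7)
        yy, xx = np.mgrid[0:120, 0:120]
        frame = 0.7 * xx + 1.3 * yy  # gradient image
        for _ in range(20):
            center = rng.uniform(30, 90, 2)
            w, h = rng.uniform(5, 25, 2)
            rect = np.array([[-w / 2, -h / 2], [w / 2, -h / 2],
                             [w / 2, h / 2], [-w / 2, h / 2]]) + center
            poly = rotate_about(rect, rng.uniform(0, 360), center)
            got = roi_mean_luminance(frame, poly)
            shp = Polygon(poly).buffer(1e-9)
            vals = [frame[y, x] for y in range(120) for x in range(120)
                    if shp.contains(Point(x, y))]
            assert got == pytest.approx(np.mean(vals), rel=1e-9)

    def test_empty_polygon_rejected(self):
        poly = np.array([[0.2, 0.2], [0.4, 0.2], [0.4, 0.4], [0.2, 0.4]])
        with pytest.raises(ValueError):
            roi_mean_luminance(np.zeros((10, 10)), poly + 0.1)


class TestTemporalOperators:
    def test_lt_differences_constant(self):
        n, r, l = (np.full(5, 34.0), np.full(5, 33.5), np.full(5, 33.0))
        d1, d2, d3 = lt_differences(n, r, l)
        np.testing.assert_allclose([d1[0], d2[0], d3[0]], [0.5, 1.0, 0.5])

    def test_lt_differences_antisymmetry(self):
        rng = np.random.default_rng(8)
        n, r, l = rng.normal(33, 1, (3, 50))
        d1, d2, d3 = lt_differences(n, r, l)
        s1, s2, s3 = lt_differences(n, l, r)  # cheeks swapped
        np.testing.assert_allclose(s3, -d3)
        np.testing.assert_allclose((s1, s2), (d2, d1))

    def test_lt_differences_length_mismatch(self):
        with pytest.raises(ValueError):
            lt_differences(np.zeros(3), np.zeros(3), np.zeros(4))

    def test_smooth_constant_is_fixed_point(self, filter_cfg):
        x = np.full(40, 33.3)
        np.testing.assert_allclose(smooth_lt(x, filter_cfg), x, atol=1e-12)

    def test_smooth_truncates_at_edges(self, filter_cfg):
        np.testing.assert_allclose(
            smooth_lt(np.array([1.0, 2.0, 3.0]), filter_cfg),
            [1.5, 2.0, 2.5])

    def test_smooth_matches_naive_windowed_mean(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 200)
        for win in (3, 5, 9):
            cfg = FilterConfig(smooth_window=win)
            got = smooth_lt(x, cfg)
            k = win // 2
            naive = np.array([x[max(0, i - k):i + k + 1].mean()
                              for i in range(x.size)])
            np.testing.assert_allclose(got, naive, atol=1e-9)

    def test_atc_constant_is_zero(self, filter_cfg):
        out = atc(np.full(100, 33.0), filter_cfg)
        assert np.isnan(out[:30]).all()
        np.testing.assert_allclose(out[30:], 0.0, atol=1e-12)

    def test_atc_linear_ramp(self, filter_cfg):
        f = np.arange(200)
        out = atc(30.0 + 0.01 * f, filter_cfg)
        np.testing.assert_allclose(out[30:], 0.3, atol=1e-12)

    def test_atc_telescopes(self, filter_cfg):
        rng = np.random.default_rng(10)
        x = rng.normal(33, 0.5, 301)
        out = atc(x, filter_cfg)
        total = sum(out[30 * k] for k in range(1, 11))
        assert total == pytest.approx(x[300] - x[0], abs=1e-9)

    def test_atc_translation_equivariant(self, filter_cfg):
        rng = np.random.default_rng(11)
        x = rng.normal(33, 0.5, 120)
        np.testing.assert_allclose(atc(x, filter_cfg)[30:],
                                   atc(x + 5.0, filter_cfg)[30:], atol=1e-9)

    def test_atc_short_series_all_invalid(self, filter_cfg):
        assert np.isnan(atc(np.zeros(10), filter_cfg)).all()


class TestEOD:
    def test_vertical_distance(self, template_face, scheme):
        pts = template_face.copy()
        pts[scheme.left_eye_upper] = (100.0, 200.0)
        pts[scheme.left_eye_lower] = (100.0, 212.0)
        assert eod_raw(pts, "left", scheme) == pytest.approx(12.0)

    def test_closed_eye_is_zero(self, template_face, scheme):
        pts = template_face.copy()
        pts[scheme.right_eye_upper] = pts[scheme.right_eye_lower]
        assert eod_raw(pts, "right", scheme) == 0.0

    def test_three_four_five_triangle(self, template_face, scheme):
        pts = template_face.copy()
        pts[scheme.left_eye_upper] = (100.0, 200.0)
        pts[scheme.left_eye_lower] = (103.0, 204.0)
        assert eod_raw(pts, "left", scheme) == pytest.approx(5.0)

    def test_filter_unit_dc_gain(self, filter_cfg):
        out = eod_filter(np.full(600, 12.0), 60.0, filter_cfg)
        np.testing.assert_allclose(out, 12.0, atol=1e-9)

    def test_filter_attenuates_blink_band(self, filter_cfg):
        t = np.arange(1200) / 60.0
        x = np.sin(2 * np.pi * 5.0 * t)  # 5 Hz, 10x the cutoff
        out = eod_filter(x, 60.0, filter_cfg)
        assert np.abs(out[120:-120]).max() < 0.05

    def test_filter_rejects_blink_dips(self, filter_cfg):
        fps = 60.0
        t = np.arange(int(20 * fps)) / fps
        ramp = 12.0 + 0.1 * t
        x = ramp.copy()
        depth = 11.0
        centers = [3.0, 8.5, 14.0, 17.5]
        for c in centers:
            span = np.abs(t - c) <= 0.075  # 150 ms blink
            x[span] -= depth * 0.5 * (1 + np.cos(np.pi * (t[span] - c) / 0.075))
        out = eod_filter(x, fps, filter_cfg)
        for c in centers:
            i = int(c * fps)
            assert abs(out[i] - ramp[i]) < 0.2 * depth

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            eod_filter(np.zeros(100), 60.0, FilterConfig(eod_cutoff_hz=30.0))


class TestAssembleFeatures:
    def test_shape_mask_and_column_order(self, short_participant,
                                         short_alignment):
        scn, p = short_participant
        fm = features_from_tracks(p.roi_temps, p.landmarks, short_alignment)
        assert fm.values.shape == (scn.n_thermal, 11)
        assert fm.columns == FEATURE_COLUMNS
        assert not fm.valid[:30].any()          # ATC lag masks 1st second
        assert fm.valid[30:].all()
        assert not np.isnan(fm.values[fm.valid]).any()

    def test_constant_input_gives_constant_features(self):
        n_th, n_vis = 120, 240
        from thermarousal.synthetic import _face_template
        from thermarousal import LandmarkScheme
        pts = np.repeat(_face_template(LandmarkScheme())[None], n_vis, axis=0)
        lms = LandmarkStream(points=pts, fps=60.0)
        tracks = {"nose": np.full(n_th, 33.0),
                  "right_cheek": np.full(n_th, 34.0),
                  "left_cheek": np.full(n_th, 34.0)}
        amap = align_streams(n_vis, n_th)
        fm = features_from_tracks(tracks, lms, amap)
        v = fm.values[fm.valid]
        np.testing.assert_allclose(v[:, 0], v[0, 0])        # constant LT
        np.testing.assert_allclose(np.ptp(v[:, 3:6], axis=0), 0.0,
                                   atol=1e-12)              # constant dLT
        np.testing.assert_allclose(v[:, 6:9], 0.0, atol=1e-9)  # zero ATC
        np.testing.assert_allclose(v[:, 9], 12.0, atol=1e-6)   # EOD passes

    def test_lt_values_stay_inside_normalization_band(self, short_participant,
                                                      short_alignment):
        _, p = short_participant
        fm = features_from_tracks(p.roi_temps, p.landmarks, short_alignment)
        norm = ThermalNormalization()
        lts = fm.values[fm.valid][:, :3]
        assert lts.min() >= norm.t_min and lts.max() <= norm.t_max

    def test_step_change_appears_in_atc(self):
        n_th, n_vis = 240, 480
        from thermarousal.synthetic import _face_template
        from thermarousal import LandmarkScheme
        pts = np.repeat(_face_template(LandmarkScheme())[None], n_vis, axis=0)
        lms = LandmarkStream(points=pts, fps=60.0)
        nose = np.full(n_th, 34.0)
        nose[120:] -= 0.5                      # instantaneous nasal cooling
        tracks = {"nose": nose, "right_cheek": np.full(n_th, 34.0),
                  "left_cheek": np.full(n_th, 34.0)}
        fm = features_from_tracks(tracks, lms, align_streams(n_vis, n_th))
        atc_nose = fm.values[:, 6]
        assert atc_nose[140] == pytest.approx(-0.5, abs=0.05)
        assert abs(atc_nose[60]) < 0.05 and abs(atc_nose[220]) < 0.05

    def test_detector_failures_propagate_to_mask(self, short_participant,
                                                 short_alignment):
        scn, p = short_participant
        valid = p.landmarks.valid.copy()
        valid[100:120] = False
        lms = LandmarkStream(points=p.landmarks.points, fps=60.0, valid=valid)
        fm = features_from_tracks(p.roi_temps, lms, short_alignment)
        mapped = short_alignment.indices
        bad_thermal = np.isin(mapped, np.arange(100, 120))
        assert not fm.valid[bad_thermal].any()

    def test_image_path_agrees_with_track_path(self):
        from thermarousal import SyntheticScenario, simulate_participant
        scn = SyntheticScenario(duration_s=4.0, n_episodes=1,
                                episode_duration_s=(1.0, 1.5),
                                refractory_s=0.5, noise_sd_c=0.0,
                                drift_sd=0.0, seed=5)
        p = simulate_participant(scn, 0)
        seq = render_thermal_frames(p.roi_temps, p.landmarks)
        amap = align_streams(scn.n_visible, scn.n_thermal)
        fm_img = assemble_features(seq, p.landmarks, amap)
        fm_trk = features_from_tracks(p.roi_temps, p.landmarks, amap)
        sel = fm_img.valid & fm_trk.valid
        np.testing.assert_allclose(fm_img.values[sel], fm_trk.values[sel],
                                   atol=1e-9)
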