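import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from filotrack import AnalysisParams, Calibration, SegmentationParams
from filotrack.errors import DegenerateSeriesError
from filotrack.morphodynamics import (
    background_annulus, boundary_profile, classify_states, corrected_length,
    delta_length, directional_movement, length_series, measure_fluorescence,
    predicted_base_fluorescence, preprocess_series, resample_boundary,
    straightness, tip_persistence,
)
from filotrack.segmentation import (SegmentationParams as SP, geometry_from_mask,
                                    split_body_protrusions)
from filotrack.synthetic import rasterize_capsule, rasterize_disk
from filotrack.tracking import Track

from conftest import analytic_geometry, capsule_geometry

CAL = Calibration(65.0, 2.0)


# -------------------------------------------------------------------- length

class TestCorrectedLength:
    def test_fwhm_width_formula(self):
        p = SegmentationParams(sigma_log=2.6)
        assert p.width_px * 65.0 == pytest.approx(
            2 * math.sqrt(2 * math.log(2)) * 2.6 * 65.0)
        assert p.width_px * 65.0 == pytest.approx(398.0, abs=1.0)

    def test_degenerate_d_zero_leaves_half_perimeter(self):
        geom = analytic_geometry((50, 50), (50, 50), width_px=6.0)
        geom.perimeter_px = 40.0
        geom.euclidean_d_px = 0.0
        p = SegmentationParams()
        assert corrected_length(geom, p, CAL) == pytest.approx(
            CAL.px_to_um(20.0))

    @pytest.mark.parametrize("length_um", [2.0, 5.0, 10.0, 15.0])
    def test_capsule_lengths_recovered_within_ten_percent(self, length_um):
        p = SegmentationParams(sigma_log=2.6)
        L = CAL.um_to_px(length_um)
        base = np.array([30.0, 30.0])
        tip = base + L * np.array([math.sin(0.7), math.cos(0.7)])
        shape = (int(tip[0]) + 20, int(tip[1]) + 20)
        geom = geometry_from_mask(rasterize_capsule(shape, base, tip, p.width_px),
                                  base, p)
        est = corrected_length(geom, p, CAL)
        assert est == pytest.approx(length_um, rel=0.10)


class TestStraightness:
    def test_straight_capsule_close_to_one(self):
        p = SegmentationParams()
        geom = capsule_geometry((60, 20), (60, 120), p.width_px, shape=(120, 160))
        L = corrected_length(geom, p, CAL)
        res = straightness(geom, L, p, CAL)
        assert res.straightness == pytest.approx(1.0, abs=0.05)
        assert res.reliable

    def test_semicircular_arc_ratio(self):
        # half-annulus protrusion: D = diameter, length = pi*R -> 2/pi
        shape = (140, 140)
        rr, cc = np.mgrid[:140, :140]
        R, w = 40.0, 6.0
        d = np.sqrt((rr - 100.0) ** 2 + (cc - 70.0) ** 2)
        mask = (np.abs(d - R) <= w / 2) & (rr <= 100.0)
        p = SegmentationParams(sigma_log=w / (2 * math.sqrt(2 * math.log(2))))
        geom = geometry_from_mask(mask, (100.0, 30.0), p)
        L = corrected_length(geom, p, CAL)
        res = straightness(geom, L, p, CAL)
        assert res.straightness == pytest.approx(2 / math.pi, rel=0.08)

    def test_waviness_is_complement(self):
        geom = analytic_geometry((50, 20), (50, 80))
        res = straightness(geom, 3.0, SegmentationParams(), CAL)
        assert res.straightness + res.waviness == pytest.approx(1.0, abs=1e-12)

    def test_zero_length_flagged(self):
        geom = analytic_geometry((50, 20), (50, 80))
        res = straightness(geom, 0.0, SegmentationParams(), CAL)
        assert math.isnan(res.straightness) and not res.reliable


# ------------------------------------------------------------------ movement

def _track_from_points(points):
    """points: list of (base_rc, tip_rc) per frame."""
    return Track(0, [(f, analytic_geometry(b, t))
                     for f, (b, t) in enumerate(points)])


class TestDirectionalMovement:
    def test_pure_elongation_one_pixel_per_frame(self):
        base = (60.0, 30.0)
        pts = [(base, (60.0, 60.0 + k)) for k in range(6)]
        mv = directional_movement(_track_from_points(pts), CAL)
        assert math.isnan(mv.at[0, "dctm_nm_s"])
        assert np.allclose(mv["dctm_nm_s"].iloc[1:], 32.5)
        assert np.allclose(mv["dcbm_nm_s"].iloc[1:], 0.0)

    def test_elongation_dctm_equals_dl(self):
        base = (60.0, 30.0)
        pts = [(base, (60.0, 60.0 + 1.7 * k)) for k in range(8)]
        tr = _track_from_points(pts)
        mv = directional_movement(tr, CAL)
        lengths = length_series(tr, SegmentationParams(), CAL)
        dl_um = delta_length(lengths)
        dctm_um_per_frame = mv["dctm_nm_s"] * CAL.frame_interval_s / 1000.0
        diff = (dl_um - dctm_um_per_frame).dropna().abs()
        assert (diff < 1e-6).all()

    def test_rigid_rotation_projects_out_lateral_motion(self):
        # 5 deg/frame rotation about a fixed base: residual DCTM is
        # sin(delta/2) of the tip speed (~4.4%), far below uncorrected speed
        base = np.array([80.0, 80.0])
        L = 60.0
        pts = []
        for k in range(10):
            th = math.radians(5.0 * k)
            pts.append((tuple(base), tuple(base + L * np.array([math.sin(th),
                                                                math.cos(th)]))))
        mv = directional_movement(_track_from_points(pts), CAL)
        tip_speed = 2 * L * math.sin(math.radians(2.5)) * CAL.pixel_size_nm \
            / CAL.frame_interval_s
        resid = mv["dctm_nm_s"].dropna().abs().max()
        assert resid < 0.05 * tip_speed
        assert resid == pytest.approx(tip_speed * math.sin(math.radians(2.5)),
                                      rel=1e-6)

    def test_static_track_zero_everywhere(self):
        pts = [((60.0, 30.0), (60.0, 90.0))] * 5
        mv = directional_movement(_track_from_points(pts), CAL)
        assert np.allclose(mv.iloc[1:], 0.0)

    def test_degenerate_axis_gives_nan(self):
        pts = [((60.0, 30.0), (60.0, 90.0)), ((60.0, 30.0), (60.0, 30.0))]
        mv = directional_movement(_track_from_points(pts), CAL)
        assert math.isnan(mv.at[1, "dctm_nm_s"])

    def test_gap_breaks_series(self):
        g = analytic_geometry((60, 30), (60, 90))
        tr = Track(0, [(0, g), (1, g), (3, g)])
        mv = directional_movement(tr, CAL)
        assert math.isnan(mv.at[3, "dctm_nm_s"])  # no frame-2 predecessor
        assert mv.at[1, "dctm_nm_s"] == 0.0


# ------------------------------------------------------------- preprocessing

class TestPreprocess:
    P = AnalysisParams()

    def test_outlier_removed_before_smoothing(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        x[100] = 1e6
        out = preprocess_series(x, self.P)
        assert out.abs().max() < 100

    def test_constant_series_unchanged(self):
        out = preprocess_series(np.full(30, 3.5), self.P)
        assert np.allclose(out, 3.5)

    def test_rolling_mean_of_spike(self):
        out = preprocess_series(pd.Series([0.0, 0, 5, 0, 0]),
                                AnalysisParams(percentile_low=0,
                                               percentile_high=100))
        assert out.iloc[2] == pytest.approx(1.0)

    def test_missing_values_stay_missing(self):
        x = pd.Series([1.0, np.nan, 2.0, 3.0, 1.0, np.nan])
        out = preprocess_series(x, self.P)
        assert out.isna().tolist() == x.isna().tolist()


class TestStates:
    P = AnalysisParams()

    def _series(self, values):
        return pd.Series(np.asarray(values, float))

    def test_constant_extension(self):
        s = self._series([50.0] * 30)
        cls = classify_states(s, self._series([0.0] * 30), self.P, CAL)
        assert cls.tip_fractions["extending"] == 1.0
        assert cls.base_fractions["stable"] == 1.0

    def test_constant_retraction_and_stall(self):
        r = classify_states(self._series([-50.0] * 30),
                            self._series([-50.0] * 30), self.P, CAL)
        assert r.tip_fractions["retracting"] == 1.0
        assert r.base_fractions["retracting"] == 1.0
        st_ = classify_states(self._series([0.0] * 30),
                              self._series([0.0] * 30), self.P, CAL)
        assert st_.tip_fractions["stalling"] == 1.0

    def test_square_wave_splits_evenly(self):
        # +-65 nm/s, 20-s half-period (10 frames at 2 s)
        wave = np.tile(np.concatenate([np.full(10, 65.0), np.full(10, -65.0)]), 6)
        cls = classify_states(self._series(wave), self._series(wave), self.P, CAL)
        f = cls.tip_fractions
        window_edge = 5 / 10  # one window per half-period is ambiguous
        assert abs(f["extending"] - f["retracting"]) <= window_edge
        assert f["extending"] + f["retracting"] + f["stalling"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, bench):
        # every classified benchmark track
        from filotrack import pipeline
        metrics = pipeline.measure_tracks(bench["tracks"], bench["segs"],
                                          bench["movie"], bench["cfg"])
        for tid, sub in metrics.groupby("track_id"):
            d = preprocess_series(sub.set_index("frame")["dctm_nm_s"], self.P)
            try:
                cls = classify_states(d, d, self.P, CAL)
            except DegenerateSeriesError:
                continue
            assert sum(cls.tip_fractions.values()) == pytest.approx(1.0)

    def test_short_track_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            classify_states(self._series([50.0] * 3), self._series([0.0] * 3),
                            self.P, CAL)


class TestPersistence:
    P = AnalysisParams()

    def test_white_noise_persistence_near_one_lag(self):
        rng = np.random.default_rng(11)
        res = tip_persistence(rng.normal(0, 1, 600), self.P, CAL)
        assert 1.0 <= res.seconds <= 3.0
        assert not res.censored

    def test_ar1_ordering(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            def ar1(phi, n=300):
                x = np.zeros(n)
                eps = rng.normal(0, 1, n)
                for t in range(1, n):
                    x[t] = phi * x[t - 1] + eps[t]
                return x
            hi = tip_persistence(ar1(0.9), self.P, CAL).seconds
            lo = tip_persistence(ar1(0.2), self.P, CAL).seconds
            wins += hi > lo
        assert wins >= 95

    def test_alternating_series_crosses_before_first_lag(self):
        x = np.tile([5.0, -5.0], 20)
        res = tip_persistence(x, self.P, CAL)
        assert res.seconds < 2.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            tip_persistence(np.full(40, 2.0), self.P, CAL)


# -------------------------------------------------------------- fluorescence

def _simple_seg(shape=(120, 120)):
    mask = rasterize_disk(shape, (60, 40), 25).copy()
    mask |= rasterize_capsule(shape, (60, 65), (60, 100), 5.0)
    seg = split_body_protrusions(mask, 4)
    lab = max(seg.labels, key=lambda l: (seg.protrusion_labels == l).sum())
    from filotrack.segmentation import assign_base_tip
    geom = assign_base_tip(seg, lab, SegmentationParams())
    return seg, geom


class TestFluorescence:
    def test_uniform_image_flags_normalised_values(self):
        seg, geom = _simple_seg()
        fl = measure_fluorescence(seg, geom, np.full((120, 120), 7.0))
        assert fl.proj_mean == fl.body_mean == fl.tip_mean == 7.0
        assert math.isnan(fl.normalized_tip)

    def test_normalised_tip_arithmetic(self):
        seg, geom = _simple_seg()
        cell = seg.body_mask | (seg.protrusion_labels > 0)
        img = np.full((120, 120), 10.0)          # background 10
        img[seg.body_mask] = 100.0               # body 100
        tip_disk = (np.arange(120)[:, None] - geom.tip_rc[0]) ** 2 + \
            (np.arange(120)[None, :] - geom.tip_rc[1]) ** 2 <= geom.tip_radius_px ** 2
        img[tip_disk & cell] = 200.0             # bright tip signal, in-cell
        fl = measure_fluorescence(seg, geom, img)
        assert fl.background == pytest.approx(10.0)
        assert fl.body_mean == pytest.approx(100.0)
        assert fl.tip_thresh_mean == pytest.approx(200.0)
        assert fl.normalized_tip == pytest.approx(190.0 / 90.0, rel=1e-6)

    def test_tip_thresholded_mean_keeps_bright_half(self):
        seg, geom = _simple_seg()
        img = np.full((120, 120), 100.0)
        rows = np.arange(120)[:, None]
        cols = np.arange(120)[None, :]
        tip_disk = (rows - geom.tip_rc[0]) ** 2 + \
            (cols - geom.tip_rc[1]) ** 2 <= geom.tip_radius_px ** 2
        bright = tip_disk & (rows <= geom.tip_rc[0])
        img[bright] = 200.0
        fl = measure_fluorescence(seg, geom, img)
        assert fl.tip_thresh_mean == pytest.approx(200.0)

    def test_offset_invariance_after_background_subtraction(self):
        seg, geom = _simple_seg()
        rng = np.random.default_rng(2)
        img = rng.uniform(50, 150, (120, 120))
        img[seg.body_mask] += 100
        a = measure_fluorescence(seg, geom, img)
        b = measure_fluorescence(seg, geom, img + 37.0)
        assert b.normalized_tip == pytest.approx(a.normalized_tip, abs=1e-9)
        assert b.normalized_base == pytest.approx(a.normalized_base, abs=1e-9)

    def test_background_annulus_excludes_cell(self):
        seg, _ = _simple_seg()
        ring = background_annulus(seg)
        cell = seg.body_mask | (seg.protrusion_labels > 0)
        assert ring.any() and not (ring & cell).any()


class TestPredictedBase:
    def _seg_stack(self, n, advance=0.0):
        segs = []
        for t in range(n):
            mask = rasterize_disk((120, 120), (60, 40 + advance * t), 25)
            segs.append(split_body_protrusions(mask, 2))
        return segs

    def _track_starting_at(self, t0):
        geom = analytic_geometry((60.0, 65.0), (60.0, 90.0))
        return Track(0, [(t0, geom), (t0 + 1, geom)])

    def test_static_boundary_predicts_same_point(self):
        segs = self._seg_stack(6)
        imgs = [np.full((120, 120), 5.0)] * 6
        table, _ = predicted_base_fluorescence(
            self._track_starting_at(4), segs, imgs,
            SegmentationParams(base_back_frames=4), AnalysisParams())
        assert table["base_y"].nunique() == 1
        assert table["base_x"].nunique() == 1

    def test_advancing_boundary_back_projects(self):
        segs = self._seg_stack(6, advance=2.0)
        imgs = [np.full((120, 120), 5.0)] * 6
        table, _ = predicted_base_fluorescence(
            self._track_starting_at(5), segs, imgs,
            SegmentationParams(base_back_frames=4), AnalysisParams())
        xs = table.sort_values("frame")["base_x"].to_numpy()
        assert np.all(np.diff(xs) > 0)  # earlier boundaries sit further back

    def test_preformation_accumulation_detected(self):
        segs = self._seg_stack(8)
        imgs = []
        for t in range(8):
            img = np.full((120, 120), 10.0)
            img[segs[0].body_mask] = 100.0
            rr, cc = np.ogrid[:120, :120]
            spot = (rr - 60) ** 2 + (cc - 65) ** 2 <= 16
            img[spot] += 30.0 * t  # rising accumulation at the future base
            imgs.append(img)
        table, pre = predicted_base_fluorescence(
            self._track_starting_at(7), segs, imgs,
            SegmentationParams(base_back_frames=6), AnalysisParams())
        norm = table.sort_values("frame")["normalized_base"].to_numpy()
        assert norm[-1] > norm[0]
        assert pre == pytest.approx(np.mean(norm[-3:]))

    def test_track_starting_at_first_frame_rejected(self):
        segs = self._seg_stack(3)
        with pytest.raises(DegenerateSeriesError):
            predicted_base_fluorescence(self._track_starting_at(0), segs,
                                        [np.zeros((120, 120))] * 3,
                                        SegmentationParams(), AnalysisParams())


class TestBoundaryProfile:
    def test_static_cell_zero_velocity_and_point_count(self):
        masks = [rasterize_disk((100, 100), (50, 50), 30)] * 3
        segs = [split_body_protrusions(m, 2) for m in masks]
        img = np.full((3, 100, 100), 20.0)
        img[:, masks[0]] = 200.0
        prof = boundary_profile(segs, img, CAL, n_points=64)
        assert (prof.groupby("frame")["point"].count() == 64).all()
        assert np.allclose(prof[prof.frame < 2]["velocity"], 0.0)

    def test_expanding_disk_positive_velocity(self):
        segs, imgs = [], []
        for t in range(4):
            mask = rasterize_disk((100, 100), (50, 50), 25 + t)
            segs.append(split_body_protrusions(mask, 2))
            img = np.full((100, 100), 20.0)
            img[mask] = 200.0
            imgs.append(img)
        prof = boundary_profile(segs, np.stack(imgs), CAL, n_points=40)
        v = prof[prof.frame < 3]["velocity"]
        assert (v.dropna() >= 0).mean() > 0.9
        assert v.mean() > 0

    def test_resample_boundary_spacing(self):
        theta = np.linspace(0, 2 * np.pi, 400)
        circle = np.stack([50 + 20 * np.sin(theta), 50 + 20 * np.cos(theta)], 1)
        pts = resample_boundary(circle, 16)
        assert pts.shape == (16, 2)
        gaps = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        assert gaps.std() / gaps.mean() < 0.05
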