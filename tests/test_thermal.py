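"""Thermal stage: registration, sync, segmentation, ROI placement, tracking,
median extraction and cleaning."""

from __future__ import annotations

import numpy as np
import pytest

from thermostress.errors import (
    DegenerateGeometryError,
    FaceNotFoundError,
    ROIPlacementError,
    StreamSyncError,
    UnrecoverableSignalError,
)
from thermostress.rois import ROI_NAMES
from thermostress.synthgen import CohortConfig, face_geometry, generate_thermal_frames, roi_centres
from thermostress.thermal import (
    ROISignal,
    ThermalFrameStack,
    clean_signal,
    estimate_affine,
    extract_roi_signals,
    place_rois,
    segment_face,
    synchronize_streams,
    track_centres,
)


class TestAffine:
    def test_identity(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [7.0, 3.0]])
        A = estimate_affine(pts, pts)
        assert np.allclose(A.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-12)

    def test_translation_recovered(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        dst = src + [5.0, 3.0]
        A = estimate_affine(src, dst)
        assert np.abs(A.apply(src) - dst).max() < 1e-9

    def test_general_affine_exact_when_consistent(self):
        rng = np.random.default_rng(0)
        M = np.array([[1.2, -0.3, 4.0], [0.5, 0.9, -2.0]])
        src = rng.uniform(-10, 10, size=(6, 2))
        dst = src @ M[:, :2].T + M[:, 2]
        A = estimate_affine(src, dst)
        assert np.allclose(A.matrix, M, atol=1e-9)

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateGeometryError):
            estimate_affine(src, src)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            estimate_affine([[0, 0], [1, 1]], [[0, 0], [1, 1]])

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(1)
        M = np.array([[0.8, 0.1, -3.0], [-0.2, 1.1, 5.0]])
        src = rng.uniform(-5, 5, size=(8, 2))
        A = estimate_affine(src, src @ M[:, :2].T + M[:, 2])
        back = A.inverse().apply(A.apply(src))
        assert np.abs(back - src).max() < 1e-9


class TestSynchronize:
    def test_rate_arithmetic(self):
        rgb_t = np.arange(900) / 30.0
        ir_t = np.arange(150) / 5.0
        pairing = synchronize_streams(rgb_t, ir_t)
        assert len(pairing.pairs) == 150
        assert [j for _, j in pairing.pairs] == [6 * i for i in range(150)]
        assert pairing.unpaired_ir == []

    def test_offset_start_nearest_pairing(self):
        rgb_t = np.arange(900) / 30.0 + 0.01
        ir_t = np.arange(150) / 5.0
        pairing = synchronize_streams(rgb_t, ir_t)
        # brute-force nearest oracle
        for i, j in pairing.pairs:
            gaps = np.abs(rgb_t - ir_t[i])
            assert j == np.argmin(gaps)
            assert gaps[j] <= 1.0 / 60 + 1e-12

    def test_trailing_ir_flagged_not_dropped(self):
        rgb_t = np.arange(150) / 30.0  # 5 s of RGB
        ir_t = np.arange(30) / 5.0     # 6 s of IR
        pairing = synchronize_streams(rgb_t, ir_t)
        assert len(pairing.pairs) + len(pairing.unpaired_ir) == 30
        assert pairing.unpaired_ir  # trailing frames flagged

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(StreamSyncError):
            synchronize_streams(np.arange(10) / 30.0, 100.0 + np.arange(10) / 5.0)


class TestSegmentFace:
    def test_uniform_cold_frame_rejected(self):
        with pytest.raises(FaceNotFoundError):
            segment_face(np.full((32, 32), 25.0))

    def test_warm_block_segmented_exactly(self):
        frame = np.full((32, 32), 22.0)
        frame[8:20, 10:22] = 33.0
        mask = segment_face(frame)
        expected = np.zeros((32, 32), bool)
        expected[8:20, 10:22] = True
        assert np.array_equal(mask, expected)

    def test_boundary_temperature_excluded(self):
        frame = np.full((8, 8), 25.0)
        frame[2, 2] = 30.0   # exactly at the lower threshold: excluded
        frame[3, 3] = 30.01
        mask = segment_face(frame)
        assert not mask[2, 2]
        assert mask[3, 3]

    def test_contour_separates_face_from_torso(self):
        frame = np.full((40, 20), 34.0)  # everything warm
        contour = np.array([[0, 0], [0, 19], [19, 19], [19, 0]], float)
        mask = segment_face(frame, contour=contour)
        assert mask[:18].any()
        assert not mask[25:].any()


class TestPlaceROIs:
    def _landmarks(self, shape):
        return {n: c for n, c in roi_centres((0, 0), shape).items()}

    def test_proportional_pixel_count(self):
        face = np.ones((40, 25), bool)  # 1000 px
        rois = place_rois(self._landmarks((40, 25)), face, 0.02)
        assert len(rois) == 14
        assert {r.name for r in rois} == set(ROI_NAMES)
        for r in rois:
            assert r.mask.sum() == 20

    def test_doubling_face_doubles_roi(self):
        small = np.ones((40, 25), bool)
        big = np.ones((80, 25), bool)
        n_small = place_rois(self._landmarks((40, 25)), small, 0.02)[0].mask.sum()
        n_big = place_rois(self._landmarks((80, 25)), big, 0.02)[0].mask.sum()
        assert abs(n_big - 2 * n_small) <= 1

    def test_roi_mask_subset_of_face(self):
        face = np.zeros((40, 40), bool)
        face[5:35, 5:35] = True
        lm = {n: (5 + fr * 29, 5 + fc * 29) for n, (fr, fc) in
              __import__("thermostress.rois", fromlist=["ROI_LAYOUT"]).ROI_LAYOUT.items()}
        for roi in place_rois(lm, face, 0.02):
            assert not (roi.mask & ~face).any()

    def test_centre_outside_face_rejected(self):
        face = np.zeros((40, 25), bool)
        face[0:20] = True
        lm = self._landmarks((40, 25))  # bottom-row centres fall outside
        with pytest.raises(ROIPlacementError):
            place_rois(lm, face, 0.02)


def _constant_stack(n_frames=5, frame_size=(64, 64), temp=33.0, motion=None, noise=0.0):
    cfg = CohortConfig(
        n_subjects=2, session_duration_s=n_frames / 5.0, frame_size=frame_size, seed=0
    )
    truth = {name: np.full(n_frames, temp) for name in ROI_NAMES}
    if motion is None:
        motion = np.zeros((n_frames, 2), int)
    stack, _ = generate_thermal_frames(
        truth, motion, noise, cfg, rng=np.random.default_rng(0)
    )
    return stack


class TestTracking:
    def test_static_stack_constant_tracks(self):
        stack = _constant_stack()
        centres = {n: tuple(map(int, stack.landmarks[0][n])) for n in ROI_NAMES}
        result = track_centres(stack, centres)
        assert result.lost == {}
        for n in ROI_NAMES:
            assert np.all(result.tracks[n] == result.tracks[n][0])

    def test_planted_translation_recovered_exactly(self):
        n = 6
        motion = np.column_stack([np.zeros(n, int), np.arange(n)])  # +1 col/frame
        stack = _constant_stack(n_frames=n, motion=motion)
        centres = {n_: tuple(map(int, stack.landmarks[0][n_])) for n_ in ROI_NAMES}
        result = track_centres(stack, centres)
        assert result.lost == {}
        for name in ROI_NAMES:
            trk = result.tracks[name]
            assert np.array_equal(trk - trk[0], motion)

    def test_track_to_edge_flagged(self):
        # a lone warm blob walking towards the frame edge
        T, H, W = 12, 32, 32
        frames = np.full((T, H, W), 25.0)
        for t in range(T):
            c = 16 + 2 * t
            if c < W - 1:
                frames[t, 14:19, max(c - 2, 0) : c + 3] = 33.0
        stack = ThermalFrameStack(
            frames=frames, fs=5.0, timestamps=np.arange(T) / 5.0
        )
        result = track_centres(stack, {"blob": (16, 16)})
        assert "blob" in result.lost
        # the lost frame is where the search window would leave the image
        assert 3 <= result.lost["blob"] < T


class TestExtraction:
    def test_constant_roi_constant_signal(self):
        stack = _constant_stack(temp=33.0)
        centres = {n: tuple(map(int, stack.landmarks[0][n])) for n in ROI_NAMES}
        mask = segment_face(stack.frames[0], contour=stack.contours[0])
        rois = place_rois(stack.landmarks[0], mask, 0.02)
        tracks = track_centres(stack, centres)
        out = extract_roi_signals(stack, rois, tracks)
        assert len(out.signals) == 14
        for name in ROI_NAMES:
            assert len(out.signals[name]) == stack.n_frames
            assert np.allclose(out.signals[name].values, 33.0)

    def test_median_ignores_hot_pixel(self):
        """Median of {32, 32, 32, 40, 32} is 32: one corrupted pixel in a
        5-pixel ROI cannot move the extracted sample."""
        frames = np.full((1, 16, 16), 31.0)
        frames[0, 8, 6:11] = [32.0, 32.0, 32.0, 40.0, 32.0]
        stack = ThermalFrameStack(frames=frames, fs=5.0, timestamps=np.array([0.0]))
        mask = np.zeros((16, 16), bool)
        mask[8, 6:11] = True
        from thermostress.thermal import ROISpec, TrackResult

        roi = ROISpec(name="Nose", centre=(8, 8), area_fraction=0.02, mask=mask)
        tracks = TrackResult(tracks={"Nose": np.array([[8, 8]])}, lost={})
        out = extract_roi_signals(stack, [roi], tracks)
        assert out.signals["Nose"].values[0] == 32.0

    def test_median_robust_to_minority_corruption(self):
        """Corrupting <50% of ROI pixels never moves the median beyond the
        clean-pixel range."""
        rng = np.random.default_rng(3)
        clean = rng.uniform(32.0, 34.0, size=25)
        for n_bad in (1, 5, 12):
            vals = clean.copy()
            vals[:n_bad] = 1000.0
            med = np.median(vals)
            assert clean.min() <= med <= clean.max() + 1e-12 or n_bad >= 13


class TestCleaning:
    def test_constant_unchanged(self):
        out = clean_signal(np.full(50, 33.0))
        assert np.allclose(out.values, 33.0)
        assert not out.flags.any()

    def test_single_spike_removed(self):
        rng = np.random.default_rng(0)
        x = 33.0 + 0.05 * rng.standard_normal(200)
        x[100] += 10.0
        out = clean_signal(x)
        assert np.abs(out.values - 33.0).max() < 0.5

    def test_adjacent_outliers_replaced_by_nearest_valid(self):
        x = np.full(40, 30.0)
        x += np.linspace(0, 0.1, 40)  # slight slope so SD > 0
        x[20] = 80.0
        x[21] = 80.0
        out = clean_signal(x, window=1)  # isolate the outlier rule
        assert out.values[20] == out.values[19]
        assert out.values[21] == out.values[22] or out.values[21] == out.values[19]
        assert out.flags[20] and out.flags[21]

    def test_all_outliers_impossible_on_constant(self):
        # constant signal has SD 0: nothing is an outlier, nothing fails
        out = clean_signal(np.full(20, 5.0), window=3)
        assert not out.flags.any()

    def test_cleaning_idempotent_on_cohort_signals(self, small_cfg):
        from thermostress.pipeline import extract_thermal_signals
        from thermostress.synthgen import iter_sessions

        rec, _ = next(iter_sessions(small_cfg))
        signal_set = extract_thermal_signals(rec.thermal)
        for name in ("Nose", "R-Cheek", "Forehead"):
            once = signal_set.signals[name]  # already cleaned by the stage
            twice = clean_signal(once)
            assert np.array_equal(once.values, twice.values)


class TestEndToEndRecovery:
    def test_zero_noise_recovers_planted_trajectories(self):
        """With zero pixel noise the full thermal stage reproduces the
        planted ROI trajectories to < 1e-9 degC, including under motion."""
        cfg = CohortConfig(
            n_subjects=2, session_duration_s=10.0, frame_size=(64, 64),
            thermal_noise_sd=0.0, seed=5,
        )
        n = int(cfg.session_duration_s * cfg.fs_thermal)
        rng = np.random.default_rng(8)
        truth = {
            name: 33.0 + 0.5 * np.sin(np.linspace(0, 3, n) + i)
            for i, name in enumerate(ROI_NAMES)
        }
        steps = rng.choice([-1, 0, 1], size=(n, 2))
        steps[0] = 0
        motion = np.clip(np.cumsum(steps, axis=0), -3, 3)
        stack, _ = generate_thermal_frames(truth, motion, 0.0, cfg)
        mask = segment_face(stack.frames[0], contour=stack.contours[0])
        rois = place_rois(stack.landmarks[0], mask, 0.02)
        tracks = track_centres(stack, {r.name: r.centre for r in rois})
        assert tracks.lost == {}
        out = extract_roi_signals(stack, rois, tracks)
        for name in ROI_NAMES:
            assert np.abs(out.signals[name].values - truth[name]).max() < 1e-9
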