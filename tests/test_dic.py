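"""DIC engine: grid construction, subset matching, incremental tracking."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from corneadic import dic, synthetic
from corneadic.dic import DICConfig, TrackingError, build_grid, match_subset, track_incremental
from corneadic.synthetic import render_reference


@pytest.fixture(scope="module")
def speckle_frame(small_config):
    rng = np.random.default_rng(42)
    return render_reference(small_config, rng)


def brute_force_grid_count(mask, step, subset_size, mask_dilation):
    """Independent recount of admissible lattice sites (nested-loop flood)."""
    half = subset_size // 2
    allowed = ndi.binary_dilation(mask, iterations=mask_dilation) if mask_dilation else mask
    h, w = mask.shape
    count = 0
    for y in range(half + 1, h - half - 1, step):
        for x in range(half + 1, w - half - 1, step):
            if not mask[y, x]:
                continue
            if allowed[y - half : y + half + 1, x - half : x + half + 1].all():
                count += 1
    return count


class TestBuildGrid:
    def test_full_mask_gives_interior_lattice(self):
        grid = build_grid(np.ones((100, 100), bool), step=10, subset_size=21)
        half = 10
        assert grid.points[:, 0].min() >= half and grid.points[:, 0].max() <= 99 - half
        assert grid.points[:, 1].min() >= half and grid.points[:, 1].max() <= 99 - half
        assert grid.n_points == len(range(half + 1, 100 - half - 1, 10)) ** 2

    def test_mask_thinner_than_subset_is_empty(self):
        mask = np.zeros((100, 100), bool)
        mask[48:53] = True  # 5 px band << subset 21
        with pytest.raises(ValueError, match="empty measurement grid"):
            build_grid(mask, step=10, subset_size=21)

    def test_band_mask_count_matches_brute_force(self, small_exam):
        seq, _ = small_exam
        mask = dic.segment_cornea(seq.frames[0])
        grid = build_grid(mask, step=8, subset_size=25, mask_dilation=3)
        assert grid.n_points == brute_force_grid_count(mask, 8, 25, 3)

    def test_row_major_ordering(self, small_exam):
        seq, _ = small_exam
        grid = build_grid(dic.segment_cornea(seq.frames[0]), step=8, subset_size=21)
        keys = [(y, x) for x, y in grid.points]
        assert keys == sorted(keys)


class TestMatchSubset:
    def test_identity_match(self, speckle_frame, small_config):
        pt = (small_config.apex_x, small_config.band_apex_row)
        res = match_subset(speckle_frame, speckle_frame, point=pt)
        assert res.valid
        assert res.du == pytest.approx(0.0, abs=1e-6)
        assert res.dv == pytest.approx(0.0, abs=1e-6)
        assert res.quality == pytest.approx(1.0, abs=1e-9)

    def test_integer_shift_exact(self, speckle_frame, small_config):
        shifted = np.roll(np.roll(speckle_frame, 2, axis=0), 3, axis=1)
        pt = (small_config.apex_x, small_config.band_apex_row)
        res = match_subset(speckle_frame, shifted, point=pt)
        assert res.du == pytest.approx(3.0, abs=1e-4)
        assert res.dv == pytest.approx(2.0, abs=1e-4)
        assert res.quality > 0.999

    def test_subpixel_shift_recovered(self, speckle_frame, small_config):
        """Bicubic-warped (0.50, -0.25) px shift recovered within 0.02 px."""
        coef = ndi.spline_filter(speckle_frame, order=3, mode="mirror")
        yy, xx = np.mgrid[0 : speckle_frame.shape[0], 0 : speckle_frame.shape[1]].astype(float)
        warped = ndi.map_coordinates(coef, [yy + 0.25, xx - 0.50], order=3, prefilter=False, mode="mirror")
        for px in (80.0, 144.0, 200.0):
            py = float(small_config.band_center(px))
            res = match_subset(speckle_frame, warped, point=(px, py))
            assert res.du == pytest.approx(0.50, abs=0.02)
            assert res.dv == pytest.approx(-0.25, abs=0.02)

    def test_flat_subset_flagged_invalid(self):
        flat = np.full((64, 64), 37.0)
        res = match_subset(flat, flat, point=(32.0, 32.0), subset_size=21)
        assert not res.valid

    def test_intensity_affine_invariance(self, speckle_frame, small_config):
        """ZNSSD matching is unchanged under I -> a*I + b."""
        coef = ndi.spline_filter(speckle_frame, order=3, mode="mirror")
        yy, xx = np.mgrid[0 : speckle_frame.shape[0], 0 : speckle_frame.shape[1]].astype(float)
        warped = ndi.map_coordinates(coef, [yy - 0.3, xx - 0.7], order=3, prefilter=False, mode="mirror")
        pt = (small_config.apex_x, small_config.band_apex_row)
        base = match_subset(speckle_frame, warped, point=pt)
        scaled = match_subset(1.7 * speckle_frame + 11.0, 1.7 * warped + 11.0, point=pt)
        assert scaled.du == pytest.approx(base.du, abs=1e-6)
        assert scaled.dv == pytest.approx(base.dv, abs=1e-6)


class TestTrackIncremental:
    def test_static_sequence_gives_zero_field(self, speckle_frame, small_config):
        frames = np.repeat(speckle_frame[None], 5, axis=0)
        seq = dic.ImageSequence(frames, frame_interval=1.0)
        grid = build_grid(dic.segment_cornea(speckle_frame), step=8, subset_size=21)
        field = track_incremental(seq, grid, DICConfig(subset_size=21, step=8))
        assert np.abs(field.U).max() < 1e-4 and np.abs(field.V).max() < 1e-4
        assert field.quality[1:].min() > 0.999
        assert field.valid.all()

    def test_frame_zero_field_and_increment_identity(self, small_tracked):
        _, _, _, field = small_tracked
        assert not np.any(field.U[0]) and not np.any(field.V[0])
        ok = field.valid.all(axis=0)
        assert np.allclose(field.U[:, ok], np.cumsum(field.dU[:, ok], axis=0))
        assert np.allclose(field.V[:, ok], np.cumsum(field.dV[:, ok], axis=0))

    def test_pure_rigid_drift_accumulates_exactly(self, small_config):
        """140 frames of (0.2, 0.1) px/frame drift accumulate to (27.8, 13.9)
        within 0.05 px despite per-increment interpolation error."""
        cfg = dataclasses.replace(
            small_config,
            n_frames=140,
            peak_frame=70,
            amplitude_peak=0.0,
            lateral_coupling=0.0,
            rigid_drift=(0.2, 0.1),
            image_height=144,
        )
        seq, _ = synthetic.render_sequence(cfg)
        grid = build_grid(dic.segment_cornea(seq.frames[0]), step=16, subset_size=21)
        field = track_incremental(seq, grid, DICConfig(subset_size=21, step=16))
        ok = field.valid[-1]
        assert np.abs(field.U[-1, ok] - 27.8).max() < 0.05
        assert np.abs(field.V[-1, ok] - 13.9).max() < 0.05

    def test_puff_tracking_matches_ground_truth(self, small_tracked):
        seq, truth, grid, field = small_tracked
        f = truth.sample_fields(grid.points)
        err = (field.V - f["V"])[field.valid]
        assert np.sqrt((err**2).mean()) < 0.05
        assert field.valid.mean() > 0.9

    def test_translation_equivariance(self, small_config):
        """Cropping the whole sequence by an integer offset shifts the grid but
        leaves recovered displacements unchanged."""
        cfg = dataclasses.replace(small_config, n_frames=6, peak_frame=3)
        seq, _ = synthetic.render_sequence(cfg)
        dy, dx = 4, 6
        a = seq.frames[:, : -dy or None, : -dx or None]
        b = seq.frames[:, dy:, dx:]
        grid_a = build_grid(dic.segment_cornea(a[0]), step=16, subset_size=21)
        pts_b = grid_a.points - [dx, dy]
        grid_b = dic.MeasurementGrid(pts_b, step=16, subset_size=21)
        fa = track_incremental(dic.ImageSequence(a, 1.0), grid_a, DICConfig(subset_size=21, step=16))
        fb = track_incremental(dic.ImageSequence(b, 1.0), grid_b, DICConfig(subset_size=21, step=16))
        m = fa.valid & fb.valid
        assert np.abs(fa.U[m] - fb.U[m]).max() < 1e-6
        assert np.abs(fa.V[m] - fb.V[m]).max() < 1e-6

    def test_error_growth_sublinear_in_frame_count(self, small_config):
        """Accumulated drift error grows sublinearly with frame count."""
        errs = {}
        for T in (35, 70, 140):
            cfg = dataclasses.replace(
                small_config,
                n_frames=T,
                peak_frame=T // 2,
                amplitude_peak=0.0,
                lateral_coupling=0.0,
                rigid_drift=(0.2, 0.1),
                image_height=144,
            )
            seq, _ = synthetic.render_sequence(cfg)
            grid = build_grid(dic.segment_cornea(seq.frames[0]), step=20, subset_size=21)
            field = track_incremental(seq, grid, DICConfig(subset_size=21, step=20))
            ok = field.valid[-1]
            truth_u = 0.2 * (T - 1)
            truth_v = 0.1 * (T - 1)
            errs[T] = max(
                np.abs(field.U[-1, ok] - truth_u).max(),
                np.abs(field.V[-1, ok] - truth_v).max(),
            )
        eps = 1e-3
        assert (errs[140] + eps) / 140 < 1.5 * (errs[35] + eps) / 35
        assert errs[140] < 0.05

    def test_mass_dropout_raises(self, speckle_frame, small_config):
        """Replacing later frames with noise kills correlation and must fail loudly."""
        rng = np.random.default_rng(0)
        frames = np.repeat(speckle_frame[None], 4, axis=0).astype(float)
        frames[2:] = rng.uniform(0, 255, frames[2:].shape)
        seq = dic.ImageSequence(frames, frame_interval=1.0)
        grid = build_grid(dic.segment_cornea(speckle_frame), step=8, subset_size=21)
        with pytest.raises(TrackingError) as e:
            track_incremental(seq, grid, DICConfig(subset_size=21, step=8))
        assert e.value.frame == 2
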