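"""Projection, segmentation, polishing and invasion-feature extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from sagakit import imaging
from sagakit import synthetic_data as sd
from sagakit.imaging import SegmentationParams

from conftest import disk_mask


def dice(a, b):
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestStdProject:
    def test_sample_sd_value(self):
        stack = np.zeros((1, 4, 1, 1))
        stack[0, :, 0, 0] = [0, 2, 0, 2]
        out = imaging.std_project(stack)
        assert out[0, 0, 0] == pytest.approx(np.sqrt(4 / 3))

    def test_constant_column_is_zero_and_nonnegative(self, rng):
        stack = np.tile(rng.uniform(0, 10, size=(3, 1, 8, 8)), (1, 5, 1, 1))
        out = imaging.std_project(stack)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_invariant_under_z_permutation(self, rng):
        stack = rng.uniform(0, 100, size=(2, 6, 10, 10))
        perm = rng.permutation(6)
        np.testing.assert_allclose(imaging.std_project(stack),
                                   imaging.std_project(stack[:, perm]))

    def test_single_plane_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="skip"):
            imaging.std_project(np.zeros((2, 1, 4, 4)))


class TestSmooth:
    def test_sigma_zero_is_identity(self, rng):
        series = rng.uniform(size=(3, 8, 8))
        np.testing.assert_array_equal(imaging.smooth(series, 0.0), series)

    def test_constant_image_preserved(self):
        series = np.full((4, 16, 16), 7.0)
        np.testing.assert_allclose(imaging.smooth(series, 2.0), 7.0)

    def test_interior_impulse_mass_preserved(self):
        series = np.zeros((9, 31, 31))
        series[4, 15, 15] = 1.0
        out = imaging.smooth(series, 1.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)


class TestSegment:
    def test_constant_image_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            masks = imaging.segment(np.full((2, 16, 16), 3.0),
                                    SegmentationParams())
        assert not masks.data.any()
        assert masks.warnings

    def test_graphcut_matches_threshold_oracle_on_bimodal(self, clean_phantom):
        spec, stack, truth = clean_phantom
        series = imaging.smooth(imaging.std_project(stack), 1.0)
        gc = imaging.segment(series, SegmentationParams(method="graphcut"))
        th = imaging.segment(series, SegmentationParams(method="threshold"))
        assert dice(gc.data, th.data) >= 0.99

    def test_noiseless_phantom_recovers_truth_mask(self, clean_phantom):
        spec, stack, truth = clean_phantom
        # noiseless input: light smoothing preserves the exact boundary
        series = imaging.smooth(imaging.std_project(stack), 0.5)
        masks = imaging.polish(imaging.segment(series, SegmentationParams()))
        truth_mask = sd.rasterized_truth_mask(spec, truth)
        assert dice(masks.data, truth_mask) >= 0.99

    def test_graphcut_fills_interior_noise_dropouts(self, rng):
        # a frame pair with salt noise: smoothness should keep regions coherent
        frame = np.where(disk_mask((64, 64), (32, 32), 15), 100.0, 10.0)
        series = np.stack([frame, frame]) + rng.normal(0, 15, (2, 64, 64))
        gc = imaging.segment(series, SegmentationParams(lam=4.0))
        truth = np.stack([disk_mask((64, 64), (32, 32), 15)] * 2)
        assert dice(gc.data, truth) >= 0.95


class TestPolish:
    def test_solid_disk_unchanged(self):
        mask = disk_mask((64, 64), (32, 32), 15)[None]
        out = imaging.polish(mask, SegmentationParams())
        np.testing.assert_array_equal(out.data[0], mask[0])

    def test_hole_filled_and_speck_removed(self):
        frame = disk_mask((64, 64), (30, 30), 12).copy()
        frame[29:32, 29:32] = False          # interior hole
        frame[5:7, 55:57] = True             # distant speck
        out = imaging.polish(frame[None], SegmentationParams())
        assert out.data[0, 30, 30]           # hole removed
        assert not out.data[0, 5, 55]        # speck dropped
        labels, n = ndimage.label(out.data[0])
        assert n == 1

    def test_temporal_component_tracking_prefers_overlap(self):
        # frame 0: one blob; frame 1: same blob (smaller) + larger distractor
        f0 = disk_mask((64, 64), (20, 20), 10)
        f1 = disk_mask((64, 64), (20, 20), 7) | disk_mask((64, 64), (48, 48), 12)
        out = imaging.polish(np.stack([f0, f1]), SegmentationParams(closing_radius=0))
        assert out.data[1, 20, 20]
        assert not out.data[1, 48, 48]

    def test_empty_frame_passes_through_with_warning(self):
        mask = np.zeros((1, 16, 16), bool)
        with pytest.warns(UserWarning, match="empty"):
            out = imaging.polish(mask, SegmentationParams())
        assert not out.data.any()


class TestComputeFeatures:
    def test_disk_limits(self):
        mask = disk_mask((96, 96), (48, 48), 20)[None]
        row = imaging.compute_features(mask, SegmentationParams()).iloc[0]
        assert row.invasive_radius == pytest.approx(20, abs=0.5)
        assert row.circularity == pytest.approx(1.0, abs=0.1)
        assert row.branch_count == 0
        assert row.invasive_area <= 0.02 * row.area
        assert row.centroid_y == pytest.approx(48, abs=0.1)

    def test_square_circularity(self):
        mask = np.zeros((1, 80, 80), bool)
        mask[0, 20:60, 20:60] = True
        row = imaging.compute_features(mask, SegmentationParams()).iloc[0]
        assert row.circularity == pytest.approx(np.pi / 4, abs=0.08)
        assert row.area == 1600

    def test_star_phantom_branches_radius_and_ray_area(self, clean_phantom):
        spec, stack, truth = clean_phantom
        mask = sd.rasterized_truth_mask(spec, truth)[-1][None]
        row = imaging.compute_features(mask, SegmentationParams()).iloc[0]
        t = len(truth.frame) - 1
        assert row.branch_count == spec.n_branches
        assert row.invasive_radius == pytest.approx(truth.true_invasive_radius[t], abs=1.0)
        assert row.invasive_area == pytest.approx(truth.true_invasive_area[t],
                                                  rel=0.25)

    def test_area_identity_and_empty_frame(self):
        frames = np.stack([disk_mask((64, 64), (32, 32), 10),
                           np.zeros((64, 64), bool)])
        table = imaging.compute_features(frames, SegmentationParams())
        assert (table.invasive_area + table.core_area == table.area).all()
        empty = table.iloc[1]
        assert empty.area == 0 and np.isnan(empty.circularity)

    def test_invasive_radius_lower_bound(self, small_phantom):
        spec, stack, truth = small_phantom
        mask = sd.rasterized_truth_mask(spec, truth)
        table = imaging.compute_features(mask, SegmentationParams())
        assert (table.invasive_radius >=
                np.sqrt(table.area / np.pi) - 1).all()


class TestFeatureTimecourse:
    def test_growing_phantom_monotone_radius_and_units(self, small_phantom):
        spec, stack, truth = small_phantom
        table = imaging.feature_timecourse(stack, frame_interval=30.0,
                                           pixel_size=1.5)
        assert (np.diff(table.invasive_radius) > -0.5).all()
        assert table.time_h.tolist() == pytest.approx(
            (np.arange(6) * 0.5).tolist())
        assert table.area_um2.iloc[0] == pytest.approx(
            table.area.iloc[0] * 2.25)

    def test_phantom_truth_recovery(self, small_phantom):
        spec, stack, truth = small_phantom
        table = imaging.feature_timecourse(stack)
        # frame 0 has zero-length rays, undetectable by construction
        got = table.branch_count.to_numpy()[1:]
        assert np.abs(got - spec.n_branches).max() <= 1
        err = np.abs(table.invasive_radius.to_numpy() - truth.true_invasive_radius)
        assert err.max() <= 2.0

    def test_branchless_phantom_counts_zero(self):
        spec = sd.SpheroidPhantomSpec(image_shape=(3, 5, 96, 96),
                                      core_radius=16, n_branches=0,
                                      noise_sd=0.5, seed=2)
        stack, _ = sd.generate_spheroid_stack(spec)
        table = imaging.feature_timecourse(stack)
        assert table.branch_count.tolist() == [0, 0, 0]

    def test_circularity_decreases_as_rays_grow(self, small_phantom):
        spec, stack, truth = small_phantom
        mask = sd.rasterized_truth_mask(spec, truth)
        table = imaging.compute_features(mask, SegmentationParams())
        circ = table.circularity.to_numpy()
        assert (np.diff(circ) < 0).all()
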