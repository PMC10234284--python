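"""Engineered features: object filters, mesoscale density, 44-slot vector."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import convolve2d

from dfoct.features import (
    FEATURE_NAMES,
    FeatureVector,
    ObjectTable,
    assemble_feature_vector,
    circular_mean_sd_deg,
    extract_cells,
    extract_fibers,
    extract_roi_features,
    fat_and_cellregion_features,
    mesoscale_regions,
)
from dfoct.reconstruct import DynamicImage
from dfoct.segment import DYNAMIC_CLASSES, STATIC_CLASSES, SegmentationMask, mask_from_ground_truth


def _dyn_mask(cell_mask):
    labels = np.where(cell_mask, 0, 2).astype(np.int32)
    return SegmentationMask(labels=labels, class_map=dict(enumerate(DYNAMIC_CLASSES)))


def _static_mask(fiber=None, fat=None, shape=(64, 64)):
    labels = np.full(shape, 2, dtype=np.int32)
    if fiber is not None:
        labels[fiber] = 0
    if fat is not None:
        labels[fat] = 3
    return SegmentationMask(labels=labels, class_map=dict(enumerate(STATIC_CLASSES)))


def _dyn_image(shape=(64, 64), rgb=None):
    if rgb is None:
        rgb = np.zeros(shape + (3,))
    return DynamicImage(
        hue=np.zeros(shape), saturation=np.zeros(shape),
        value_raw=rgb.mean(axis=-1), rgb=rgb, mode="hsv",
    )


class TestExtractCells:
    def test_area_filter_at_20_pixels(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[2:3, 2:21] = True      # 19 px blob: filtered
        mask[10:15, 10:15] = True   # 25 px blob: kept
        table = extract_cells(_dyn_mask(mask), _dyn_image())
        assert len(table) == 1
        assert table.df.iloc[0]["area_px"] == 25

    def test_empty_mask_gives_empty_table(self):
        table = extract_cells(_dyn_mask(np.zeros((32, 32), dtype=bool)), _dyn_image((32, 32)))
        assert len(table) == 0

    def test_ellipse_eccentricity_from_moments(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = ((xx - 32) / 10.0) ** 2 + ((yy - 32) / 6.0) ** 2 <= 1.0
        table = extract_cells(_dyn_mask(mask), _dyn_image())
        # semi-axes 10 and 6: e = sqrt(1 - 36/100) = 0.8
        assert table.df.iloc[0]["eccentricity"] == pytest.approx(0.8, abs=0.03)


class TestMesoscale:
    def test_empty_mask_no_regions(self):
        m = mesoscale_regions(np.zeros((64, 64), dtype=bool), 60, 0.05,
                              object_centroids=np.empty((0, 2)))
        assert m.n_regions == 0 and m.n_objects_outside == 0

    def test_full_mask_single_region(self):
        m = mesoscale_regions(np.ones((64, 64), dtype=bool), 16, 0.5)
        assert m.n_regions == 1
        assert m.density.max() == pytest.approx(1.0)

    def test_matches_dense_convolution_oracle(self, rng):
        """Box-filter density equals brute-force dense convolution (1e-10)."""
        for _ in range(5):
            mask = rng.random((64, 64)) < 0.2
            m = mesoscale_regions(mask, window_px=9, density_threshold=0.05)
            kernel = np.ones((9, 9)) / 81.0
            dense = convolve2d(mask.astype(float), kernel, mode="same")
            np.testing.assert_allclose(m.density, dense, atol=1e-10)
            np.testing.assert_array_equal(m.region_mask, dense > 0.05)

    def test_filled_square_region_matches_thresholded_convolution(self):
        mask = np.zeros((360, 360), dtype=bool)
        mask[100:130, 100:130] = True
        m = mesoscale_regions(mask, window_px=60, density_threshold=0.05)
        # integer convolution: exact window sums, so the 0.05 boundary
        # (exactly 180 of 3600 pixels) is decided without float noise
        counts = convolve2d(mask.astype(np.int64), np.ones((60, 60), dtype=np.int64),
                            mode="same")
        assert m.n_regions == 1
        np.testing.assert_array_equal(m.region_mask, counts / 3600.0 > 0.05)

    def test_threshold_is_strict(self):
        mask = np.ones((10, 10), dtype=bool)
        m = mesoscale_regions(mask, window_px=1, density_threshold=0.999)
        assert m.n_regions == 1  # density 1.0 > 0.999
        m2 = mesoscale_regions(mask.astype(float) * 0, window_px=1, density_threshold=0.001)
        assert m2.n_regions == 0


class TestExtractFibers:
    def test_area_filter_at_100_pixels(self):
        fiber = np.zeros((64, 64), dtype=bool)
        fiber[5:6, 0:99 % 64] = True  # thin blob < 100 px
        fiber[20:25, 10:40] = True    # 150 px blob
        table, _ = extract_fibers(_static_mask(fiber=fiber), np.ones((64, 64)))
        assert len(table) == 1

    def test_horizontal_segment_orientation_zero(self):
        fiber = np.zeros((64, 64), dtype=bool)
        fiber[30:33, 5:60] = True
        table, _ = extract_fibers(_static_mask(fiber=fiber), np.ones((64, 64)))
        assert abs(table.df.iloc[0]["orientation_deg"]) < 2.0

    def test_no_fibers(self):
        table, meso = extract_fibers(_static_mask(), np.ones((64, 64)))
        assert len(table) == 0 and meso.n_regions == 0


class TestFatAndCellRegion:
    def test_no_fat(self):
        prop, table, _, _ = fat_and_cellregion_features(_static_mask(), np.ones((64, 64)))
        assert prop == 0.0 and len(table) == 0

    def test_quarter_fat_proportion(self):
        fat = np.zeros((64, 64), dtype=bool)
        fat[:32, :32] = True
        prop, _, _, _ = fat_and_cellregion_features(_static_mask(fat=fat), np.ones((64, 64)))
        assert prop == pytest.approx(0.25)

    def test_constant_image_zero_intensity_sd(self):
        _, _, mean, sd = fat_and_cellregion_features(_static_mask(), np.full((64, 64), 0.7))
        assert mean == pytest.approx(0.7)
        assert sd == pytest.approx(0.0, abs=1e-12)


class TestCircularStats:
    def test_single_angle_zero_sd(self):
        m, s = circular_mean_sd_deg(np.array([37.0]))
        assert m == pytest.approx(37.0) and s == 0.0

    def test_axial_wraparound(self):
        # 85 and -85 deg are 10 deg apart axially; mean is +-90, not 0
        m, _ = circular_mean_sd_deg(np.array([85.0, -85.0]))
        assert min(abs(m - 90.0), abs(m + 90.0)) < 1e-9


class TestAssemble:
    def _empty(self):
        empty = ObjectTable(df=pd.DataFrame())
        meso = mesoscale_regions(np.zeros((32, 32), dtype=bool), 8, 0.05)
        return empty, meso

    def test_all_empty_inputs_give_zero_vector(self):
        empty, meso = self._empty()
        fv = assemble_feature_vector(empty, meso, empty, meso, 0.0, empty, 0.0, 0.0,
                                     cell_density=0.0, fiber_density=0.0)
        assert np.all(fv.values == 0.0)

    def test_two_cell_diameter_statistics(self):
        cells = ObjectTable(df=pd.DataFrame([
            {"equivalent_diameter_px": 10.0, "eccentricity": 0.0, "mean_r": 0, "mean_g": 0,
             "mean_b": 0, "intensity_sd": 0, "centroid_y": 1, "centroid_x": 1},
            {"equivalent_diameter_px": 14.0, "eccentricity": 0.0, "mean_r": 0, "mean_g": 0,
             "mean_b": 0, "intensity_sd": 0, "centroid_y": 2, "centroid_x": 2},
        ]))
        empty, meso = self._empty()
        fv = assemble_feature_vector(cells, meso, empty, meso, 0.0, empty, 0.0, 0.0,
                                     cell_density=0.0, fiber_density=0.0)
        d = fv.as_dict()
        assert d["cell_diameter_mean"] == pytest.approx(12.0)
        assert d["cell_diameter_sd"] == pytest.approx(2.0)  # population sd
        assert d["cell_count"] == 2

    def test_schema_has_44_fixed_names(self):
        assert len(FEATURE_NAMES) == 44
        assert len(set(FEATURE_NAMES)) == 44
        with pytest.raises(ValueError):
            FeatureVector(values=np.zeros(43))


class TestFullChain:
    def test_vector_length_and_monotonicity(self, small_healthy_pair, small_tumoral_pair):
        """Any valid ROI yields 44 features; the denser tumoral phantom never
        scores lower on the cell count/density slots."""
        from dfoct.reconstruct import reconstruct

        vals = {}
        for name, ((stack, static, gt), _) in (
            ("healthy", small_healthy_pair), ("tumoral", small_tumoral_pair)
        ):
            img = reconstruct(stack)
            fv = extract_roi_features(
                mask_from_ground_truth(gt, "dynamic"), img,
                mask_from_ground_truth(gt, "static"), static,
            )
            assert fv.values.shape == (44,)
            vals[name] = fv.as_dict()
        assert vals["tumoral"]["cell_count"] >= vals["healthy"]["cell_count"]
        assert vals["tumoral"]["cell_density"] >= vals["healthy"]["cell_density"]
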