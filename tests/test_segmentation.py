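"""Segmentation primitives: normalisation, band-pass, cell and
mitochondrion labelling, watershed splitting, MFI measurement."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from mitorhythm import (
    CalibratedImage,
    ParameterError,
    SegmentationParams,
    SyntheticImageSpec,
    bandpass_filter,
    generate_mito_image,
    measure_mfi,
    normalize_image,
    segment_cells,
    segment_mitochondria,
    split_touching,
)
from conftest import make_dumbbell


class TestNormalize:
    def test_constant_image_maps_to_zero(self):
        img = CalibratedImage(np.full((8, 8), 42.0), 0.1)
        assert normalize_image(img).data.max() == 0

    def test_linear_map_with_round_half_up(self):
        img = CalibratedImage(np.array([[10.0, 15.0], [20.0, 10.0]]), 0.1)
        out = normalize_image(img).data
        assert out[0, 0] == 0 and out[1, 0] == 65535
        assert out[0, 1] == 32768  # 32767.5 rounds half up

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        img = CalibratedImage(rng.uniform(0, 500, (16, 16)), 0.1)
        once = normalize_image(img)
        twice = normalize_image(once)
        np.testing.assert_array_equal(once.data, twice.data)


class TestBandpass:
    def test_constant_annihilated(self):
        img = CalibratedImage(np.full((32, 32), 7.0), 0.1)
        assert bandpass_filter(img, 0.1, 0.5).data.max() == 0.0

    def test_impulse_response_peaks_at_impulse(self):
        data = np.zeros((33, 33))
        data[16, 16] = 100.0
        out = bandpass_filter(CalibratedImage(data, 0.1), 0.1, 0.5).data
        assert np.unravel_index(np.argmax(out), out.shape) == (16, 16)

    def test_sigma_order_enforced(self):
        img = CalibratedImage(np.zeros((8, 8)), 0.1)
        with pytest.raises(ParameterError):
            bandpass_filter(img, 0.5, 0.1)

    def test_tube_response_beats_smooth_gradient_background(self):
        # tube of width ~2*sigma_small on a gradient: centreline response must
        # dominate the background response everywhere along the tube
        h, w = 40, 60
        gradient = np.linspace(0, 50, w)[None, :].repeat(h, axis=0)
        tube = gradient.copy()
        tube[19:21, 10:50] += 100.0
        img = bandpass_filter(CalibratedImage(tube, 0.1), 0.1, 0.5).data
        bg = bandpass_filter(CalibratedImage(gradient, 0.1), 0.1, 0.5).data
        assert (img[20, 12:48] > bg.max()).all()


class TestSegmentCells:
    def test_three_separated_cells(self, default_params):
        spec = SyntheticImageSpec(
            image_size=(256, 256), n_cells=3, mito_per_cell=4, noise_sd=0.0, seed=5,
            cell_radius_um=4.0,
        )
        img, truth = generate_mito_image(spec)
        labels = segment_cells(normalize_image(img), default_params)
        assert labels.max() == 3
        # oracle: connected components of the ground-truth cell mask
        assert ndimage.label(truth.cell_labels > 0)[1] == 3

    def test_blank_image_zero_labels(self, default_params):
        img = CalibratedImage(np.zeros((64, 64)), 0.1)
        assert segment_cells(img, default_params).max() == 0

    def test_fused_cells_split_toggle(self):
        # two discs joined by a thin neck, as an intensity image
        mask = make_dumbbell(r=10, gap_bridge=3, shape=(48, 72))
        img = CalibratedImage(np.where(mask, 200.0, 5.0), 0.1)
        on = segment_cells(img, SegmentationParams(cell_smooth_sigma_um=0.2, split_enabled=True, min_cell_area_um2=1.0))
        off = segment_cells(img, SegmentationParams(cell_smooth_sigma_um=0.2, split_enabled=False, min_cell_area_um2=1.0))
        assert on.max() == 2
        assert off.max() == 1


class TestSplitTouching:
    def test_single_circle_unchanged(self):
        mask = np.zeros((32, 32), bool)
        yy, xx = np.mgrid[:32, :32]
        mask[(yy - 16) ** 2 + (xx - 16) ** 2 <= 100] = True
        out = split_touching(mask, prominence_um=0.15, pixel_size_um=0.1)
        assert out.max() == 1
        np.testing.assert_array_equal(out > 0, mask)

    def test_dumbbell_splits_into_two(self):
        r = 8
        mask = make_dumbbell(r=r, gap_bridge=1)
        # brute-force geometric oracle: the distance transform has two prominent
        # maxima (disc centres at depth ~r) separated by a shallow bridge (~1 px)
        dt = ndimage.distance_transform_edt(mask)
        bridge_max = dt[20, 32]  # bridge midpoint
        assert dt.max() >= r - 1 and bridge_max <= 2.0
        out = split_touching(mask, prominence_um=0.15, pixel_size_um=0.1)
        assert out.max() == 2

    def test_foreground_pixel_conservation(self):
        mask = make_dumbbell(r=6, gap_bridge=3)
        out = split_touching(mask, prominence_um=0.2, pixel_size_um=0.1)
        np.testing.assert_array_equal(out > 0, mask)

    def test_label_count_monotone_in_prominence(self):
        mask = make_dumbbell(r=8, gap_bridge=1)
        counts = [
            split_touching(mask, prominence_um=p, pixel_size_um=0.1).max()
            for p in (2.0, 0.6, 0.3, 0.1, 0.02)
        ]
        assert counts == sorted(counts)
        assert counts[0] == 1  # huge prominence: fallback marker keeps the blob whole

    def test_empty_mask(self):
        assert split_touching(np.zeros((8, 8), bool), 0.15, 0.1).max() == 0


class TestSegmentMitochondria:
    def test_recovers_disjoint_capsules(self, noiseless_scene, default_params):
        spec, img, truth = noiseless_scene
        norm = normalize_image(img)
        cells = segment_cells(norm, default_params)
        mito = segment_mitochondria(norm, default_params, cells)
        assert mito.max() == truth.n_objects

    def test_object_outside_cells_excluded(self, default_params):
        data = np.full((96, 96), 2.0)
        yy, xx = np.mgrid[:96, :96]
        cellmask = (yy - 30) ** 2 + (xx - 30) ** 2 <= 25**2
        data[cellmask] += 30.0
        data[28:32, 20:40] += 180.0  # inside the cell
        data[70:74, 60:80] += 180.0  # far outside any cell
        img = CalibratedImage(ndimage.gaussian_filter(data, 0.8), 0.1)
        norm = normalize_image(img)
        cells = segment_cells(norm, default_params)
        assert cells.max() == 1
        mito = segment_mitochondria(norm, default_params, cells)
        assert mito.max() == 1
        assert (mito[cells == 0] == 0).all()

    def test_tiny_speck_removed(self):
        params = SegmentationParams(min_object_area_um2=0.1)
        data = np.full((64, 64), 2.0)
        yy, xx = np.mgrid[:64, :64]
        data[(yy - 32) ** 2 + (xx - 32) ** 2 <= 28**2] += 30.0
        data[30:34, 20:40] += 180.0
        data[45, 45] += 180.0  # 1-px speck: 0.01 um2 < 0.1 um2
        img = CalibratedImage(data, 0.1)
        norm = normalize_image(img)
        cells = segment_cells(norm, params)
        mito = segment_mitochondria(norm, params, cells)
        assert mito.max() == 1

    def test_shape_mismatch_rejected(self, default_params):
        img = CalibratedImage(np.zeros((16, 16)), 0.1)
        with pytest.raises(ParameterError):
            segment_mitochondria(img, default_params, np.zeros((8, 8), int))

    def test_threshold_monotonicity(self, noiseless_scene):
        spec, img, truth = noiseless_scene
        norm = normalize_image(img)
        counts = []
        for thr in (500.0, 2000.0, 8000.0, 20000.0):
            p = SegmentationParams(threshold_method="fixed", fixed_threshold=thr, split_enabled=False)
            bp = bandpass_filter(norm, p.bandpass_sigma_small_um, p.bandpass_sigma_large_um)
            counts.append(int((bp.data > thr).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_pixel_size_invariance_at_2x_scale(self, default_params):
        # same physical scene sampled at 0.1 and 0.05 um/px: object counts agree
        base = dict(n_cells=1, mito_per_cell=5, noise_sd=0.0, seed=11, cell_radius_um=5.5)
        for px, size in ((0.1, (160, 160)), (0.05, (320, 320))):
            spec = SyntheticImageSpec(image_size=size, pixel_size_um=px, **base)
            img, truth = generate_mito_image(spec)
            norm = normalize_image(img)
            cells = segment_cells(norm, default_params)
            mito = segment_mitochondria(norm, default_params, cells)
            assert mito.max() == truth.n_objects


class TestMFI:
    def test_uniform_and_two_label_means(self):
        data = np.zeros((10, 10))
        labels = np.zeros((10, 10), int)
        data[:5], labels[:5] = 50.0, 1
        data[5:], labels[5:] = 150.0, 2
        table = measure_mfi(CalibratedImage(data, 0.1), labels).set_index("label")
        assert table.loc[1, "mean_intensity"] == 50.0
        assert table.loc[2, "mean_intensity"] == 150.0

    def test_merged_label_is_weighted_mean_of_parts(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 100, (12, 12))
        labels = np.zeros((12, 12), int)
        labels[:4] = 1
        labels[4:] = 2
        parts = measure_mfi(CalibratedImage(data, 0.1), labels)
        merged = measure_mfi(CalibratedImage(data, 0.1), (labels > 0).astype(int))
        w = parts.n_pixels.to_numpy()
        assert merged.mean_intensity[0] == pytest.approx(np.average(parts.mean_intensity, weights=w))

    def test_empty_label_map(self):
        table = measure_mfi(CalibratedImage(np.ones((4, 4)), 0.1), np.zeros((4, 4), int))
        assert table.empty
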