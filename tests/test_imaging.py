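"""Nucleus segmentation, marker positivity and the expression index."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from gcquant import synthetic as syn
from gcquant.imaging import (
    _ball_height,
    denoise,
    expression_index,
    measure_and_call,
    positivity_threshold,
    quantify,
    rolling_ball_background,
    segment_nuclei,
    subtract_background,
)
def make_disk_image(centers, radii_px, shape=(128, 128), level=1000.0,
                    background=0.0):
    """Hard-edged disk phantom with an exact label map."""
    img = np.full(shape, background, float)
    labels = np.zeros(shape, np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for i, ((cy, cx), r) in enumerate(zip(centers, radii_px), start=1):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[inside] = level
        labels[inside] = i
    return img, labels


def bruteforce_opening(img, radius_px):
    """Direct erosion-then-dilation with the hemisphere structuring function."""
    h = _ball_height(radius_px)
    r = (h.shape[0] - 1) // 2
    fin = np.isfinite(h)
    padded = np.pad(img, r, mode="edge")
    ero = np.zeros_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            ero[i, j] = np.min(win[fin] - h[fin])
    ero_p = np.pad(ero, r, mode="edge")
    out = np.zeros_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = ero_p[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = np.max(win[fin] + h[fin])
    return out


def bruteforce_median(img, radius_px):
    from skimage.morphology import disk

    fp = disk(radius_px).astype(bool)
    r = radius_px
    padded = np.pad(img, r, mode="edge")
    out = np.zeros_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = np.median(win[fp])
    return out


class TestBackgroundSubtraction:
    def test_flat_image_removed(self):
        img = np.full((32, 32), 500.0)
        out = subtract_background(img, pixel_size_um=1.0, radius_um=8)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_matches_bruteforce_opening(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (48, 48))
        bg = rolling_ball_background(img, radius_px=5)
        np.testing.assert_allclose(bg, bruteforce_opening(img, 5), atol=1e-9)

    def test_small_disk_preserved(self):
        img, _ = make_disk_image([(32, 32)], [4], shape=(64, 64),
                                 level=1000.0, background=100.0)
        out = subtract_background(img, pixel_size_um=1.0, radius_um=20)
        # disk diameter (8 px) far below ball radius: contrast survives
        assert out[32, 32] >= 0.95 * 900.0

    def test_ramp_background_flattened(self):
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        ramp = 2.0 * xx
        # keep disks a ball radius away from the x edges, where the
        # nearest-edge padding flattens the background estimate
        centers = [(20, 25), (48, 45), (76, 65)]
        disks, labels = make_disk_image(centers, [5] * 3, shape=(96, 96),
                                        level=800.0, background=0.0)
        img = ramp + disks
        out = subtract_background(img, pixel_size_um=1.0, radius_um=30)
        means = ndi.mean(out, labels=labels, index=[1, 2, 3])
        amplitude = ramp.max()
        assert np.ptp(means) <= 0.05 * amplitude

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.ones((8, 8)), pixel_size_um=2.0,
                                radius_um=1.0)


class TestDenoise:
    def test_constant_unchanged(self):
        img = np.full((16, 16), 7.0)
        np.testing.assert_allclose(denoise(img, 1.0, radius_um=2), img)

    def test_impulse_removed(self):
        img = np.zeros((16, 16))
        img[8, 8] = 100.0
        out = denoise(img, 1.0, radius_um=2)
        assert out[8, 8] == 0.0

    def test_matches_bruteforce_median(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 50, (32, 32))
        out = denoise(img, pixel_size_um=1.0, radius_um=3)
        np.testing.assert_allclose(out, bruteforce_median(img, 3), atol=1e-12)


class TestSegmentation:
    def test_blank_image_empty_result(self):
        rng = np.random.default_rng(0)
        fp = 0
        for seed in range(20):
            img = np.abs(np.random.default_rng(seed).normal(0, 5, (128, 128)))
            labels = segment_nuclei(img, pixel_size_um=0.5)
            fp += labels.max() > 0
        assert fp == 0

    def test_separated_disks_counted_exactly(self):
        cfg = syn.ImageSimConfig(seed=2, n_nuclei=20, touching_fraction=0.0,
                                 shape=(512, 512))
        nuclear, _, truth = syn.gen_image(cfg)
        corrected = subtract_background(nuclear, cfg.pixel_size_um)
        smoothed = denoise(corrected, cfg.pixel_size_um)
        labels = segment_nuclei(smoothed, cfg.pixel_size_um)
        assert labels.max() == 20
        # centroids within 2 px of ground truth
        centroids = np.array(ndi.center_of_mass(labels > 0, labels,
                                                range(1, 21)))
        dists = np.sort(
            [np.min(np.hypot(*(truth.centers - c).T)) for c in centroids]
        )
        assert dists.max() <= 2.0

    def test_touching_pair_split_by_watershed(self):
        cfg = syn.ImageSimConfig(seed=4, n_nuclei=2, touching_fraction=1.0,
                                 shape=(128, 128))
        nuclear, _, truth = syn.gen_image(cfg)
        corrected = subtract_background(nuclear, cfg.pixel_size_um)
        smoothed = denoise(corrected, cfg.pixel_size_um)
        with_ws = segment_nuclei(smoothed, cfg.pixel_size_um,
                                 use_watershed=True)
        without_ws = segment_nuclei(smoothed, cfg.pixel_size_um,
                                    use_watershed=False)
        assert with_ws.max() == 2
        assert without_ws.max() == 1

    def test_translation_and_rotation_equivariance(self):
        cfg = syn.ImageSimConfig(seed=6, n_nuclei=12, shape=(256, 256),
                                 marker_positive_fraction=0.5)
        nuclear, marker, _ = syn.gen_image(cfg)
        ref = quantify(nuclear, marker, cfg.pixel_size_um, threshold=1500)
        rot = quantify(np.rot90(nuclear), np.rot90(marker),
                       cfg.pixel_size_um, threshold=1500)
        shifted = quantify(np.roll(nuclear, (7, -5), (0, 1)),
                           np.roll(marker, (7, -5), (0, 1)),
                           cfg.pixel_size_um, threshold=1500)
        assert ref.n_total == rot.n_total == shifted.n_total
        assert ref.n_positive == rot.n_positive == shifted.n_positive
        assert rot.expression_index == pytest.approx(ref.expression_index,
                                                     rel=0.02)

    def test_pixel_size_invariance(self):
        counts, means = [], []
        for px in (0.3, 0.6):
            cfg = syn.ImageSimConfig(
                seed=8, n_nuclei=10, pixel_size_um=px,
                shape=(int(154 / px), int(154 / px)),
            )
            nuclear, marker, _ = syn.gen_image(cfg)
            res = quantify(nuclear, marker, px, threshold=np.inf)
            counts.append(res.n_total)
            means.append(np.sort(res.per_nucleus["mean_marker"].to_numpy()))
        assert counts[0] == counts[1] == 10
        np.testing.assert_allclose(means[0], means[1], rtol=0.03)


class TestMeasureAndCall:
    def _fixture(self):
        marker = np.zeros((30, 40))
        labels = np.zeros((30, 40), np.int32)
        for i, level in enumerate([10.0, 20.0, 30.0, 2.0], start=1):
            labels[5:15, 10 * (i - 1) : 10 * (i - 1) + 8] = i
            marker[labels == i] = level
        return labels, marker

    def test_expression_index_formula(self):
        labels, marker = self._fixture()
        res = measure_and_call(labels, marker, pixel_size_um=1.0, threshold=5.0)
        assert res.n_total == 4
        assert res.n_positive == 3
        assert res.average_positive_intensity == pytest.approx(20.0)
        assert expression_index(res) == pytest.approx(60.0)

    def test_no_positives_zero_index(self):
        labels, marker = self._fixture()
        res = measure_and_call(labels, marker, 1.0, threshold=100.0)
        assert res.n_positive == 0
        assert res.expression_index == 0.0

    def test_boundary_mean_equal_threshold_is_negative(self):
        labels = np.zeros((10, 10), np.int32)
        labels[2:6, 2:6] = 1
        marker = np.where(labels == 1, 50.0, 0.0)
        res = measure_and_call(labels, marker, 1.0, threshold=50.0)
        assert res.n_positive == 0

    def test_homogeneity_of_index(self):
        labels, marker = self._fixture()
        res = measure_and_call(labels, marker, 1.0, threshold=5.0)
        doubled = measure_and_call(labels, 2 * marker, 1.0, threshold=10.0)
        assert doubled.n_positive == res.n_positive
        assert doubled.expression_index == pytest.approx(
            2 * res.expression_index
        )

    def test_threshold_source_required(self):
        labels, marker = self._fixture()
        with pytest.raises(ValueError):
            measure_and_call(labels, marker, 1.0)

    def test_control_calibrated_positivity(self):
        rng = np.random.default_rng(9)
        recalls, precisions = [], []
        for seed in range(10):
            ctl_cfg = syn.ImageSimConfig(
                seed=100 + seed, n_nuclei=20, marker_positive_fraction=0.0,
                shape=(384, 384),
            )
            test_cfg = syn.ImageSimConfig(
                seed=200 + seed, n_nuclei=20, marker_positive_fraction=0.5,
                shape=(384, 384),
            )
            ctl_nuc, ctl_mark, _ = syn.gen_image(ctl_cfg)
            ctl = quantify(ctl_nuc, ctl_mark, ctl_cfg.pixel_size_um,
                           threshold=np.inf)
            thr = positivity_threshold(
                ctl.per_nucleus["mean_marker"].to_numpy()
            )
            nuc, mark, truth = syn.gen_image(test_cfg)
            res = quantify(nuc, mark, test_cfg.pixel_size_um, threshold=thr)
            n_true_pos = int(truth.positive.sum())
            called = res.per_nucleus["positive"]
            recalls.append(min(called.sum(), n_true_pos) / n_true_pos)
            precisions.append(
                min(called.sum(), n_true_pos) / max(called.sum(), 1)
            )
        assert np.mean(recalls) >= 0.95
        assert np.mean(precisions) >= 0.95
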