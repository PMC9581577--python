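import numpy as np
import pytest
from scipy.stats import norm

from spheromea.imaging import (HueMap, cluster_ratio, electrode_clusterness,
                               hue_map, inpaint_electrodes,
                               normalize_cluster_ratio, segment_clusters)
from spheromea.model import ElectrodeLayout


def _gray_image(h=120, w=120, value=0.6):
    return np.full((h, w, 3), value)


def _disk_mask(h, w, cy, cx, r):
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


class TestInpaint:
    def test_black_disk_filled_to_surround(self):
        img = _gray_image()
        img[_disk_mask(120, 120, 60, 60, 10)] = 0.0
        out = inpaint_electrodes(img)
        # filled to the uniform surround within 1 grayscale unit (1/255)
        assert np.abs(out - 0.6).max() < 1 / 255

    def test_no_dark_pixels_unchanged(self):
        # uniform background with sparse brighter speckle: no pixel falls
        # below mean - 1 SD, so the electrode mask is empty
        rng = np.random.default_rng(0)
        img = _gray_image()
        idx = rng.integers(0, 120, (30, 2))
        img[idx[:, 0], idx[:, 1]] = 0.7
        out = inpaint_electrodes(img)
        np.testing.assert_array_equal(out, img)

    def test_maximum_principle(self):
        # fill values stay within the range of surrounding boundary values
        rng = np.random.default_rng(1)
        img = np.clip(0.6 + rng.normal(0, 0.03, (120, 120, 3)), 0.45, 0.75)
        disk = _disk_mask(120, 120, 60, 60, 12)
        img[disk] = 0.0
        out = inpaint_electrodes(img)
        ring = _disk_mask(120, 120, 60, 60, 20) & ~_disk_mask(
            120, 120, 60, 60, 15)
        for c in range(3):
            filled = out[:, :, c][disk]
            lo, hi = img[:, :, c][ring].min(), img[:, :, c][ring].max()
            assert filled.min() >= lo - 1e-6
            assert filled.max() <= hi + 1e-6

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            inpaint_electrodes(np.zeros((20, 20, 3)))


class TestHueMap:
    def test_achromatic_image_flat_map(self):
        rng = np.random.default_rng(2)
        g = 0.5 + rng.normal(0, 0.02, (200, 200))
        img = np.stack([g, g, g], axis=-1)  # R = G = B
        hm = hue_map(img, um_per_px=2.0)
        assert np.abs(hm.values).max() < 1e-9

    def test_red_disk_positive_blob(self):
        img = _gray_image(300, 300)
        disk = _disk_mask(300, 300, 150, 150, 25)  # 100 um at 2 um/px
        img[:, :, 0][disk] += 0.15
        img[:, :, 2][disk] -= 0.15
        hm = hue_map(img, um_per_px=2.0)
        inside = hm.values[disk].mean()
        far = np.abs(hm.values[~_disk_mask(300, 300, 150, 150, 100)]).max()
        assert inside > 0.1
        assert far < 0.25 * inside

    def test_single_pixel_speckle_suppressed(self):
        img = _gray_image(200, 200)
        img[100, 100, 0] += 0.3  # unfiltered ratio contrast at one pixel
        raw_contrast = (0.9 / 0.6) - 1.0
        hm = hue_map(img, um_per_px=2.0)
        assert hm.values.max() < 0.1 * raw_contrast

    def test_orientation_flag_inverts(self):
        img = _gray_image(120, 120)
        disk = _disk_mask(120, 120, 60, 60, 15)
        img[:, :, 0][disk] += 0.2
        pos = hue_map(img, um_per_px=2.0).values
        neg = hue_map(img, um_per_px=2.0, red_over_blue=False).values
        assert pos[disk].mean() > 0 > neg[disk].mean()

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            hue_map(_gray_image(), um_per_px=0.0)


class TestSegmentation:
    def test_gaussian_noise_tail_fraction(self):
        rng = np.random.default_rng(3)
        hm = HueMap(values=rng.normal(0, 1, (600, 600)), um_per_px=2.0)
        pre = segment_clusters(hm, k=1.4, erode=False)
        assert cluster_ratio(pre) == pytest.approx(norm.cdf(-1.4), abs=0.01)
        post = segment_clusters(hm, k=1.4, erode=True)
        assert cluster_ratio(post) < 0.5 * cluster_ratio(pre)

    def test_disk_recovered_within_15_percent(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 0.01, (300, 300))
        disk = _disk_mask(300, 300, 150, 150, 40)
        v[disk] += 0.12  # 12 noise SDs
        hm = HueMap(values=v, um_per_px=2.0)
        mask = segment_clusters(hm, k=1.4)
        assert mask.sum() == pytest.approx(disk.sum(), rel=0.15)
        # precision/recall against the true disk
        tp = (mask & disk).sum()
        assert tp / mask.sum() >= 0.85
        assert tp / disk.sum() >= 0.85

    def test_constant_map_empty_mask(self):
        hm = HueMap(values=np.full((50, 50), 0.3), um_per_px=2.0)
        assert not segment_clusters(hm, k=1.4).any()

    def test_ratio_monotone_in_cluster_area(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.01, (300, 300))
        ratios = []
        for r in (15, 30, 45):
            v = noise.copy()
            v[_disk_mask(300, 300, 150, 150, r)] += 0.1
            m = segment_clusters(HueMap(values=v, um_per_px=2.0), k=1.4)
            ratios.append(cluster_ratio(m))
        assert ratios[0] < ratios[1] < ratios[2]


class TestClusterRatioScalars:
    def test_empty_and_full(self):
        assert cluster_ratio(np.zeros((10, 10), bool)) == 0.0
        assert cluster_ratio(np.ones((10, 10), bool)) == 1.0

    def test_disk_pixel_count(self):
        m = _disk_mask(100, 200, 50, 100, 20)
        assert cluster_ratio(m) == pytest.approx(np.pi * 400 / 20_000,
                                                 rel=0.02)

    def test_normalization(self):
        out = normalize_cluster_ratio(np.array([0.05, 0.10, 0.20]))
        np.testing.assert_allclose(out, [1.0, 2.0, 4.0])

    def test_first_day_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_cluster_ratio(np.array([0.0, 0.1]))


class TestElectrodeClusterness:
    def _layout(self):
        return ElectrodeLayout(["a", "b", "c"], x=[100.0, 300.0, 500.0],
                               y=[100.0, 100.0, 100.0])

    def test_constant_map_scores_constant(self):
        hm = HueMap(values=np.full((200, 400), 0.7), um_per_px=2.0)
        scores = electrode_clusterness(hm, self._layout())
        for v in scores.values():
            assert v == pytest.approx(0.7)

    def test_cluster_on_electrode_is_maximal(self):
        v = np.zeros((200, 400))
        v[_disk_mask(200, 400, 50, 150, 20)] = 1.0  # on electrode b
        hm = HueMap(values=v, um_per_px=2.0)
        scores = electrode_clusterness(hm, self._layout())
        assert scores["b"] > scores["a"] and scores["b"] > scores["c"]

    def test_content_outside_window_ignored(self):
        base = np.zeros((200, 400))
        hm1 = HueMap(values=base.copy(), um_per_px=2.0)
        far = base.copy()
        far[_disk_mask(200, 400, 50, 200, 15)] = 5.0  # > 31 um from all
        hm2 = HueMap(values=far, um_per_px=2.0)
        s1 = electrode_clusterness(hm1, self._layout())
        s2 = electrode_clusterness(hm2, self._layout())
        assert s1["a"] == s2["a"] and s1["c"] == s2["c"]

    def test_outside_image_flagged_nan(self):
        hm = HueMap(values=np.zeros((50, 50)), um_per_px=2.0)
        lay = ElectrodeLayout(["far"], x=[1000.0], y=[1000.0])
        scores = electrode_clusterness(hm, lay)
        assert np.isnan(scores["far"])
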