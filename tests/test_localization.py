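"""Cluster extraction geometry: components, hulls, bboxes, squaring, crops."""

import numpy as np
import pytest

from dermseg import (Cluster, LocalizationParams, SyntheticParams,
                     crop_and_resize, decompose, find_clusters, fix_ratio,
                     generate_sample, localize, rgb_to_optical_density,
                     compute_quantity_maps)

from conftest import flood_fill_components


def disc_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


class TestFindClusters:
    def test_empty_mask_gives_empty_list(self):
        assert find_clusters(np.zeros((20, 20), bool)) == []

    def test_filled_rectangle_geometry(self):
        m = np.zeros((64, 64), bool)
        m[10:20, 30:50] = True
        (c,) = find_clusters(m, min_area=1)
        assert c.bbox == (10, 30, 20, 50)
        assert c.area == 200

    def test_two_separated_discs(self):
        m = disc_mask((64, 64), (15, 15), 6) | disc_mask((64, 64), (45, 45), 6)
        clusters = find_clusters(m, min_area=1)
        assert len(clusters) == 2
        assert clusters[0].bbox[0] < clusters[1].bbox[0]  # row-major order

    def test_l_shape_single_cluster_bbox_matches_pixel_extremes(self):
        m = np.zeros((40, 40), bool)
        m[5:30, 5:10] = True
        m[25:30, 5:30] = True
        (c,) = find_clusters(m, min_area=1)
        coords = np.argwhere(m)
        assert c.bbox == (coords[:, 0].min(), coords[:, 1].min(),
                          coords[:, 0].max() + 1, coords[:, 1].max() + 1)

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(10):
            m = rng.random((32, 32)) > 0.85
            clusters = find_clusters(m, min_area=1)
            comps = flood_fill_components(m)
            assert len(clusters) == len(comps)
            assert sorted(c.area for c in clusters) == sorted(len(p) for p in comps)

    def test_min_area_filter(self):
        m = np.zeros((64, 64), bool)
        m[5, 5] = True                      # area 1 -> dropped
        m[20:30, 20:30] = True              # area 100 -> kept
        clusters = find_clusters(m, min_area=10)
        assert len(clusters) == 1
        assert clusters[0].area == 100

    def test_containment_of_component_pixels(self, rng):
        m = rng.random((48, 48)) > 0.88
        for c in find_clusters(m, min_area=1):
            rmin, cmin, rmax, cmax = c.bbox
            sub = np.zeros_like(m)
            sub[rmin:rmax, cmin:cmax] = True
            # every cluster pixel count is accounted inside its own bbox
            assert (m & sub).sum() >= c.area


class TestFixRatio:
    @staticmethod
    def make(bbox):
        return Cluster(contour=np.empty((0, 2)), hull=np.empty((0, 2)),
                       bbox=bbox, area=1)

    def test_square_bbox_identity_without_padding(self):
        c = self.make((10, 10, 20, 20))
        assert fix_ratio(c, (64, 64), 0.0).bbox == (10, 10, 20, 20)

    def test_symmetric_growth_to_square(self):
        c = self.make((45, 35, 55, 65))  # 10x30 centered in a large image
        bbox = fix_ratio(c, (100, 100), 0.0).bbox
        assert bbox == (35, 35, 65, 65)

    def test_out_of_image_bbox_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fix_ratio(self.make((10, 10, 80, 20)), (64, 64), 0.0)

    def test_random_bboxes_contained_clipped_idempotent(self, rng):
        for _ in range(1000):
            h, w = int(rng.integers(40, 120)), int(rng.integers(40, 120))
            rmin = int(rng.integers(0, h - 2))
            cmin = int(rng.integers(0, w - 2))
            rmax = int(rng.integers(rmin + 1, h))
            cmax = int(rng.integers(cmin + 1, w))
            pad = float(rng.choice([0.0, 0.15, 0.3]))
            out = fix_ratio(self.make((rmin, cmin, rmax, cmax)), (h, w), pad).bbox
            # contains original, within bounds
            assert out[0] <= rmin and out[1] <= cmin
            assert out[2] >= rmax and out[3] >= cmax
            assert out[0] >= 0 and out[1] >= 0 and out[2] <= h and out[3] <= w
            # square unless the image is too small in that axis
            side_r, side_c = out[2] - out[0], out[3] - out[1]
            if side_r != side_c:
                assert side_r == h or side_c == w
            if pad == 0.0:
                again = fix_ratio(self.make(out), (h, w), 0.0).bbox
                assert again == out


class TestCropAndResize:
    def test_full_frame_crop(self, default_sample):
        c = TestFixRatio.make((0, 0) + default_sample.image.shape[:2])
        crop_and_resize(default_sample.image, c, 48)
        assert c.crop.shape == (48, 48, 3)

    def test_shape_contract(self, default_sample):
        c = TestFixRatio.make((10, 10, 40, 40))
        crop_and_resize(default_sample.image, c, 64)
        assert c.crop.shape == (64, 64, 3)
        assert c.crop.dtype == np.uint8

    def test_crop_is_hemoglobin_enriched(self):
        """A lesion crop should carry more hemoglobin signal than the image
        at large (checked through the decomposition module)."""
        s = generate_sample(SyntheticParams(seed=13, noise_sd=0.005), 0)
        od = rgb_to_optical_density(s.image)
        pair = decompose(s.image, rng_seed=13)
        q = compute_quantity_maps(od, pair.density)
        (c, *_) = localize(s.image, s.mask, LocalizationParams(min_area=5))
        rmin, cmin, rmax, cmax = c.bbox
        assert q.q_h[rmin:rmax, cmin:cmax].mean() > q.q_h.mean()


class TestLocalize:
    def test_count_preserved_for_separated_blobs(self):
        p = SyntheticParams(height=96, width=96, lesions_per_image=(3, 3),
                            lesion_radius=(6.0, 6.0), seed=21,
                            phenotype_map=("single",))
        s = generate_sample(p, 0)
        clusters = localize(s.image, s.mask, LocalizationParams(min_area=5))
        assert len(clusters) == 3
        for c in clusters:
            assert c.crop is not None

    def test_empty_mask_is_empty_list(self, default_sample):
        assert localize(default_sample.image,
                        np.zeros(default_sample.image.shape[:2], bool)) == []

    def test_dimension_mismatch_rejected(self, default_sample):
        with pytest.raises(ValueError, match="dimensions"):
            localize(default_sample.image, np.zeros((10, 10), bool))

    def test_count_correctness_over_seeded_masks(self, rng):
        """50 seeded masks with k in 1..4 well-separated discs: exactly k
        clusters, each truth centroid inside exactly one bbox."""
        for trial in range(50):
            k = trial % 4 + 1
            p = SyntheticParams(height=96, width=96, lesions_per_image=(k, k),
                                lesion_radius=(5.0, 8.0), seed=trial,
                                phenotype_map=("single",))
            s = generate_sample(p, 0)
            clusters = find_clusters(s.mask, min_area=5)
            assert len(clusters) == k
            for pix in flood_fill_components(s.mask):
                cy = np.mean([r for r, _ in pix])
                cx = np.mean([c for _, c in pix])
                hits = [c for c in clusters
                        if c.bbox[0] <= cy < c.bbox[2] and c.bbox[1] <= cx < c.bbox[3]]
                assert len(hits) == 1
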