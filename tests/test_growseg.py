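import numpy as np
import pytest
from skimage.morphology import disk

from fazseg import (
    BinaryMask,
    GrowParams,
    NoFazFoundError,
    ParameterError,
    compute_area_mm2,
    compute_circularity,
    jaccard_index,
    localization_success,
    region_grow,
    segment_faz,
)
from fazseg.growseg import circularity, erode_seed

from conftest import make_gray
from oracles import binary_erode, flood_fill_interval


class TestErodeSeed:
    def test_square_erosion_matches_oracle(self):
        m = np.zeros((15, 15), dtype=bool)
        m[3:12, 3:12] = True  # 9x9 solid square
        out = erode_seed(BinaryMask(m), radius=2)
        np.testing.assert_array_equal(out.pixels, binary_erode(m, disk(2)))
        assert out.pixels.sum() == 25  # 5x5 centered square

    def test_small_blob_falls_back_to_centroid_pixel(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4:6, 4:6] = True
        out = erode_seed(BinaryMask(m), radius=3)
        assert out.pixels.sum() == 1
        r, c = np.nonzero(out.pixels)
        assert (r[0], c[0]) == (round(4.5), round(4.5))

    def test_always_contained_in_preliminary(self, rng):
        for _ in range(5):
            m = rng.uniform(size=(20, 20)) > 0.55
            if not m.any():
                continue
            out = erode_seed(BinaryMask(m), radius=2)
            assert not (out.pixels & ~m).any()

    def test_empty_preliminary_rejected(self):
        with pytest.raises(ParameterError):
            erode_seed(BinaryMask(np.zeros((5, 5), dtype=bool)), 1)


def _disc_in_ring(n=40, disc_val=0.1, ring_val=0.9, outside_val=0.5):
    rr, cc = np.mgrid[0:n, 0:n]
    d2 = (rr - n // 2) ** 2 + (cc - n // 2) ** 2
    img = np.full((n, n), outside_val)
    img[d2 <= 14**2] = ring_val
    disc = d2 <= 11**2
    img[disc] = disc_val
    return img, disc


class TestRegionGrow:
    def test_fills_dark_disc_inside_bright_ring(self):
        img, disc = _disc_in_ring()
        seed = np.zeros_like(disc)
        seed[18:23, 18:23] = True
        res = region_grow(make_gray(img), BinaryMask(seed),
                          GrowParams(tolerance_frac=0.3, abs_floor=0.0))
        np.testing.assert_array_equal(res.mask.pixels, disc)
        assert res.converged

    def test_matches_flood_fill_oracle_with_frozen_arv(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            img = np.round(rng.uniform(size=(30, 30)), 2)
            seed = np.zeros((30, 30), dtype=bool)
            seed[14:16, 14:16] = True
            params = GrowParams(tolerance_frac=0.3, abs_floor=0.0,
                                update_arv=False, allow_deletion=False)
            res = region_grow(make_gray(img), BinaryMask(seed), params)
            arv = img[seed].mean()
            expected = flood_fill_interval(img, seed, arv * 0.7, arv * 1.3)
            np.testing.assert_array_equal(res.mask.pixels, expected)

    def test_tiny_tolerance_keeps_exact_value_component(self):
        img = np.full((10, 10), 0.5)
        img[:, 6:] = 0.8
        seed = np.zeros((10, 10), dtype=bool)
        seed[5, 2] = True
        res = region_grow(make_gray(img), BinaryMask(seed),
                          GrowParams(tolerance_frac=1e-9, abs_floor=0.0))
        np.testing.assert_array_equal(res.mask.pixels, img == 0.5)

    def test_fixed_point_converges_in_one_sweep(self):
        img, disc = _disc_in_ring()
        res = region_grow(make_gray(img), BinaryMask(disc),
                          GrowParams(tolerance_frac=0.3, abs_floor=0.0))
        np.testing.assert_array_equal(res.mask.pixels, disc)
        assert res.converged and res.iterations == 1

    def test_anchor_seed_never_deleted(self):
        # seed deliberately put on pixels far from the region average
        img = np.full((12, 12), 0.9)
        img[5:7, 5:7] = 0.1
        seed = np.zeros((12, 12), dtype=bool)
        seed[5:7, 5:7] = True
        res = region_grow(make_gray(img), BinaryMask(seed), GrowParams())
        assert (res.mask.pixels & seed).sum() == seed.sum()

    def test_termination_bound(self):
        img, _ = _disc_in_ring()
        seed = np.zeros_like(img, dtype=bool)
        seed[20, 20] = True
        res = region_grow(make_gray(img), BinaryMask(seed),
                          GrowParams(max_iterations=2))
        assert res.iterations <= 2

    def test_empty_seed_rejected(self):
        with pytest.raises(ParameterError):
            region_grow(make_gray(np.full((5, 5), 0.5)),
                        BinaryMask(np.zeros((5, 5), dtype=bool)), GrowParams())


class TestAreaAndCircularity:
    def test_full_frame_area_equals_field_area(self):
        full = BinaryMask(np.ones((320, 320), dtype=bool))
        assert abs(compute_area_mm2(full, 3) - 9.0) < 1e-12
        assert abs(compute_area_mm2(full, 6) - 36.0) < 1e-12

    def test_partial_mask_area_matches_arithmetic(self):
        m = np.zeros((320, 320), dtype=bool)
        m.ravel()[:11378] = True
        got = compute_area_mm2(BinaryMask(m), 3)
        assert abs(got - 11378 * 9 / 102400) < 1e-12

    def test_empty_mask_has_zero_area(self):
        assert compute_area_mm2(BinaryMask(np.zeros((10, 10), dtype=bool)), 3) == 0.0

    def test_square_closed_form_with_analytic_perimeter(self):
        s = 37
        assert abs(circularity(s * s, 4 * s) - np.pi / 4) < 1e-6

    def test_digital_disc_near_one(self):
        m = np.zeros((120, 120), dtype=bool)
        m[7:108, 7:108] = disk(50)
        assert compute_circularity(BinaryMask(m)) >= 0.95

    def test_thin_bar_is_far_from_circular(self):
        m = np.zeros((10, 60), dtype=bool)
        m[5, 5:55] = True
        assert compute_circularity(BinaryMask(m)) < 0.2

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            compute_circularity(BinaryMask(np.zeros((5, 5), dtype=bool)))


class TestSegmentFaz:
    def test_artifact_free_phantom_segmented_accurately(self, clean_phantom):
        img, gt, _ = clean_phantom
        res = segment_faz(img)
        assert localization_success(res.preliminary_mask, gt)
        assert jaccard_index(res.mask, gt) >= 0.8
        assert res.params is not None  # config embedded for reproducibility

    def test_border_artifact_band_does_not_distract(self, artifact_phantom):
        img, gt, _ = artifact_phantom
        res = segment_faz(img)
        assert localization_success(res.preliminary_mask, gt)

    def test_avascular_free_image_is_localization_failure(self):
        # all-bright image with no avascular zone: the inverted frame is
        # one border-connected region, discarded as peripheral
        px = np.tile(np.linspace(0.7, 0.9, 320), (320, 1))
        with pytest.raises(NoFazFoundError):
            segment_faz(make_gray(px))
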