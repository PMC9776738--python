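import math

import numpy as np
import pytest
from skimage import draw

from priorgrow import (
    AllRegionsAbnormalError,
    GrowthParams,
    ValidationError,
    check_credible,
    combine,
    compute_initial_threshold,
    grow_region,
    update_threshold,
)
from priorgrow.growing import restriction_radius_px

from conftest import make_region


def floodfill_bruteforce(image, seed, threshold, connectivity=8):
    """Fixpoint flood fill by repeated full-image sweeps (pure numpy shifts)."""
    image = np.asarray(image, dtype=float)
    pred = np.abs(image - image[seed]) <= threshold
    region = np.zeros_like(pred)
    region[seed] = True
    shifts = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    if connectivity == 8:
        shifts += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    while True:
        grown = region.copy()
        for dr, dc in shifts:
            shifted = np.zeros_like(region)
            rs = slice(max(dr, 0), region.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), region.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), region.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), region.shape[1] + min(-dc, 0))
            shifted[rs, cs] = region[rd, cd]
            grown |= shifted & pred
        if np.array_equal(grown, region):
            return region
        region = grown


class TestInitialThreshold:
    def test_fraction_of_range(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[0, 0] = 250
        assert compute_initial_threshold(img, 0.2) == 50.0

    def test_uint16_range(self):
        img = np.full((4, 4), 100, dtype=np.uint16)
        img[0, 0] = 1100
        assert compute_initial_threshold(img, 0.2) == pytest.approx(200.0)

    def test_constant_image_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert compute_initial_threshold(np.full((4, 4), 9), 0.2) == 0.0


class TestGrowRegion:
    def test_uniform_image_covers_everything(self):
        img = np.full((16, 16), 40, dtype=np.uint8)
        reg = grow_region(img, (5, 5), 0.0)
        assert reg.mask.all()

    def test_zero_threshold_unique_seed_is_singleton(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[8, 8] = 99
        reg = grow_region(img, (8, 8), 0.0)
        assert reg.area_px == 1 and reg.mask[8, 8]

    def test_disk_fixture_exact(self):
        img = np.full((64, 64), 50, dtype=np.uint8)
        rr, cc = draw.disk((32, 32), 12, shape=img.shape)
        img[rr, cc] = 200
        reg = grow_region(img, (32, 32), 30.0)
        expected = np.zeros_like(img, dtype=bool)
        expected[rr, cc] = True
        assert np.array_equal(reg.mask, expected)
        assert np.array_equal(reg.mask, floodfill_bruteforce(img, (32, 32), 30.0))

    def test_base_is_seed_intensity_not_running_mean(self):
        # ramp: with a running mean the region would creep across the whole
        # gradient; with a fixed base it must stop at |I - base| <= t
        img = np.tile(np.arange(64, dtype=np.uint8), (4, 1))
        reg = grow_region(img, (0, 0), 10.0)
        assert reg.mask[:, :11].all() and not reg.mask[:, 11:].any()
        assert reg.base_intensity == 0.0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bruteforce_on_random_fixtures(self, connectivity):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            seed = tuple(rng.integers(0, 32, 2))
            t = float(rng.integers(0, 120))
            reg = grow_region(img, seed, t, connectivity)
            assert np.array_equal(reg.mask, floodfill_bruteforce(img, seed, t, connectivity))

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(77)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        seed = (16, 16)
        prev = grow_region(img, seed, 5.0).mask
        for t in (15.0, 40.0, 90.0):
            cur = grow_region(img, seed, t).mask
            assert np.all(prev <= cur)
            prev = cur

    def test_out_of_bounds_seed(self):
        with pytest.raises(ValidationError):
            grow_region(np.zeros((8, 8)), (8, 0), 1.0)


class TestUpdateThreshold:
    def _disk_region(self, center, radius, shape=(100, 100)):
        img = np.full(shape, 100, dtype=np.uint8)
        rr, cc = draw.disk(center, radius + 0.5, shape=shape)
        img[rr, cc] = 200
        return grow_region(img, center, 30.0)

    def test_radius_is_max_boundary_distance_plus_margin(self):
        # region: disk of radius 10 around the seed; margin 6 -> circle radius 16.
        # A probe at distance 16 must be inside the update circle, one at 17 outside.
        seed = (50, 50)
        region = self._disk_region(seed, 10)
        assert region.boundary_pixels.shape[0] > 0
        probe_in = np.full((100, 100), 100, dtype=np.uint8)
        probe_in[50, 66] = 255  # distance 16
        assert update_threshold(probe_in, seed, region, 0.2, 6.0) == pytest.approx(0.2 * 155)
        probe_out = np.full((100, 100), 100, dtype=np.uint8)
        probe_out[50, 67] = 255  # distance 17
        with pytest.warns(UserWarning, match="constant"):
            assert update_threshold(probe_out, seed, region, 0.2, 6.0) == 0.0

    def test_fraction_of_circle_range_with_bruteforce_roi(self):
        rng = np.random.default_rng(8)
        img = rng.integers(40, 241, (100, 100)).astype(np.uint8)
        seed = (40, 60)
        region = self._disk_region(seed, 8)
        got = update_threshold(img, seed, region, 0.2, 6.0)
        # exhaustive per-pixel disk membership
        bp = region.boundary_pixels
        L = max(math.hypot(r - seed[0], c - seed[1]) for r, c in bp) + 6.0
        vals = [
            img[r, c]
            for r in range(100)
            for c in range(100)
            if math.hypot(r - seed[0], c - seed[1]) <= L
        ]
        assert got == pytest.approx(0.2 * (max(vals) - min(vals)))

    def test_constant_roi_warns_zero(self):
        img = np.full((64, 64), 77, dtype=np.uint8)
        region = grow_region(img, (32, 32), 1.0)  # covers everything
        region.mask[:] = False
        region.mask[30:35, 30:35] = True
        with pytest.warns(UserWarning, match="constant"):
            assert update_threshold(img, (32, 32), region, 0.2, 6.0) == 0.0

    def test_empty_region_falls_back_to_whole_image(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[0, 0] = 100
        region = grow_region(img, (8, 8), 0.0)
        region.mask[:] = False
        with pytest.warns(UserWarning, match="empty previous region"):
            assert update_threshold(img, (8, 8), region, 0.2, 6.0) == pytest.approx(20.0)


class TestCredibility:
    def test_predicted_size_mode(self):
        img = np.full((80, 80), 10, dtype=np.uint8)
        rr, cc = draw.disk((40, 40), 21, shape=img.shape)  # ~4.2 cm at 1 mm/px
        img[rr, cc] = 200
        region = grow_region(img, (40, 40), 30.0, spacing_mm=1.0)
        ok = GrowthParams(predicted_max_size_cm=5.0)
        bad = GrowthParams(predicted_max_size_cm=4.0)
        assert check_credible(region, None, None, ok)
        assert not check_credible(region, None, None, bad)

    def test_circle_mode_area_bound(self):
        m = np.zeros((100, 100), dtype=bool)
        rr, cc = draw.disk((50, 50), 20, shape=m.shape)
        m[rr, cc] = True
        contour = make_region(m)
        params = GrowthParams()
        small = np.zeros((100, 100), dtype=np.uint8)
        rr, cc = draw.disk((50, 50), 15, shape=(100, 100))
        small[rr, cc] = 200
        region = grow_region(small, (50, 50), 30.0)
        assert check_credible(region, contour, (50, 50), params)
        huge = np.full((100, 100), 200, dtype=np.uint8)
        region = grow_region(huge, (50, 50), 30.0)  # grows to the whole frame
        assert region.area_px == 10000
        assert not check_credible(region, contour, (50, 50), params)

    def test_region_equal_to_contour_always_credible_in_circle_mode(self):
        # geometric fact: a region fits inside its own circumscribed circle
        rng = np.random.default_rng(12)
        for _ in range(10):
            m = np.zeros((90, 90), dtype=bool)
            # random star-convex blob: radius varies with angle
            angles = np.linspace(0, 2 * math.pi, 180, endpoint=False)
            radii = 12 + 10 * rng.random(8)
            rad = np.interp(angles, np.linspace(0, 2 * math.pi, 8, endpoint=False), radii, period=2 * math.pi)
            for a, r in zip(angles, rad):
                rr, cc = draw.line(45, 45, int(45 + r * math.cos(a)), int(45 + r * math.sin(a)))
                m[rr, cc] = True
            from scipy import ndimage

            m = ndimage.binary_fill_holes(ndimage.binary_closing(m, np.ones((3, 3))))
            contour = make_region(m)
            img = np.where(m, 200, 10).astype(np.uint8)
            region = grow_region(img, (45, 45), 30.0)
            assert np.array_equal(region.mask, m)
            assert check_credible(region, contour, (45, 45), GrowthParams())

    def test_restriction_radius_reaches_farthest_corner(self):
        m = np.zeros((40, 40), dtype=bool)
        m[10:21, 10:21] = True
        r = restriction_radius_px(make_region(m), (15, 15))
        assert r == pytest.approx(math.hypot(5.5, 5.5))


class TestCombine:
    def _region_from_mask(self, mask, credible=True):
        img = np.where(mask, 200, 0).astype(np.uint8)
        seed = tuple(np.argwhere(mask)[0])
        reg = grow_region(img, seed, 30.0)
        reg.credible = credible
        return reg

    def test_single_credible_is_identity(self):
        m = np.zeros((32, 32), dtype=bool)
        m[4:10, 4:10] = True
        mask, boundary = combine([self._region_from_mask(m)])
        assert np.array_equal(mask, m)
        assert boundary.shape[0] >= 4

    def test_disjoint_union_adds_areas(self):
        a = np.zeros((32, 32), dtype=bool)
        a[2:8, 2:8] = True
        b = np.zeros((32, 32), dtype=bool)
        b[20:28, 20:28] = True
        ra, rb = self._region_from_mask(a), self._region_from_mask(b)
        # regions grown separately on their own images
        ra.mask, rb.mask = a, b
        mask, _ = combine([ra, rb])
        assert mask.sum() == a.sum() + b.sum()

    def test_abnormal_regions_contribute_nothing(self):
        rng = np.random.default_rng(4)
        masks = [rng.random((16, 16)) > 0.6 for _ in range(5)]
        flags = [True, False, True, False, True]
        regions = []
        for m, f in zip(masks, flags):
            m[0, 0] = True  # keep nonempty
            reg = self._region_from_mask(m, credible=f)
            reg.mask = m
            regions.append(reg)
        mask, _ = combine(regions)
        expected = np.zeros((16, 16), dtype=bool)
        for m, f in zip(masks, flags):
            if f:
                expected |= m  # pixelwise OR oracle
        assert np.array_equal(mask, expected)

    def test_all_abnormal_is_explicit_failure(self):
        m = np.zeros((16, 16), dtype=bool)
        m[3:6, 3:6] = True
        reg = self._region_from_mask(m, credible=False)
        with pytest.raises(AllRegionsAbnormalError) as err:
            combine([reg])
        assert err.value.diagnostics

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            combine([])
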