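"""Dropout detection against strict thresholds and a flood-fill oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvdquant.detection import (
    ZoneAssignmentError,
    assign_zone,
    binarize_dark,
    detect_mvd,
    label_components,
)
from mvdquant.io import ZoneSet
from mvdquant.vessels import VesselMask

from conftest import make_image

PX_MM2 = 11.25**2 / 1e6


def flood_fill_regions(binary, connectivity):
    """Brute-force connected components by explicit flood fill."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = np.zeros_like(binary)
    regions = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy, dx in neigh:
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < h and 0 <= xx < w and binary[yy, xx]
                                and not seen[yy, xx]):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                regions.append(frozenset(comp))
    return regions


def brute_force_mvd(image, zones, vessel_mask, grey_threshold, min_area_px,
                    connectivity):
    """Independent reference implementation of the detection rule."""
    eligible = (
        (image.grid < grey_threshold)
        & image.valid_mask
        & ~vessel_mask
        & (zones.alpha | zones.beta)
    )
    return [
        comp for comp in flood_fill_regions(eligible, connectivity)
        if len(comp) > min_area_px
    ]


class TestBinarize:
    def test_grey_exactly_at_threshold_is_excluded(self):
        img = make_image(np.full((10, 10), 50))
        assert not binarize_dark(img, 50).any()

    def test_grey_one_below_threshold_is_included(self):
        img = make_image(np.full((10, 10), 49))
        assert binarize_dark(img, 50).all()

    def test_invalid_pixels_never_dark(self):
        grid = np.full((10, 10), 10, dtype=np.uint8)
        img = make_image(grid)
        img.valid_mask[:5] = False
        dark = binarize_dark(img, 50)
        assert not dark[:5].any() and dark[5:].all()

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_dark(make_image(np.zeros((4, 4))), 256)


class TestLabelComponents:
    def test_diagonal_pixels_connectivity(self):
        grid = np.zeros((4, 4), dtype=bool)
        grid[1, 1] = grid[2, 2] = True
        assert label_components(grid, 8)[1] == 1
        assert label_components(grid, 4)[1] == 2

    def test_empty_grid_has_zero_components(self):
        assert label_components(np.zeros((5, 5), dtype=bool), 8)[1] == 0

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_components(np.zeros((3, 3), dtype=bool), 6)

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        connectivity=st.sampled_from([4, 8]),
    )
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        binary = rng.random((30, 30)) < 0.35
        labels, n = label_components(binary, connectivity)
        ours = {
            frozenset(map(tuple, np.argwhere(labels == lab).tolist()))
            for lab in range(1, n + 1)
        }
        assert ours == set(flood_fill_regions(binary, connectivity))


class TestAssignZone:
    def _zones(self):
        beta = np.zeros((10, 10), dtype=bool)
        alpha = np.zeros((10, 10), dtype=bool)
        beta[:, :5] = True
        alpha[:, 5:] = True
        return ZoneSet(disc=np.zeros((10, 10), dtype=bool),
                       alpha=alpha, beta=beta)

    def test_majority_rules(self):
        zones = self._zones()
        # 3 beta pixels vs 2 alpha pixels
        px = np.array([[0, 0], [0, 1], [0, 2], [0, 5], [0, 6]])
        assert assign_zone(px, zones) == "beta"
        # 2 beta vs 3 alpha
        px = np.array([[0, 3], [0, 4], [0, 5], [0, 6], [0, 7]])
        assert assign_zone(px, zones) == "alpha"

    def test_exact_tie_goes_to_beta(self):
        zones = self._zones()
        px = np.array([[0, 4], [0, 5]])
        assert assign_zone(px, zones) == "beta"

    def test_region_outside_both_zones_errors(self):
        zones = self._zones()
        zones.beta[:] = False
        zones.alpha[:] = False
        with pytest.raises(ZoneAssignmentError):
            assign_zone(np.array([[1, 1]]), zones)


class TestDetectMvd:
    def test_uniform_bright_image_yields_nothing(self, full_zone_image):
        image, zones = full_zone_image
        assert detect_mvd(image, zones) == []

    def test_area_exactly_20_px_is_excluded(self, full_zone_image):
        image, zones = full_zone_image
        image.grid[5:10, 5:9] = 30  # 20 px exactly
        assert detect_mvd(image, zones) == []

    def test_area_25_px_detected_with_exact_mm2(self, full_zone_image):
        image, zones = full_zone_image
        image.grid[5:10, 5:10] = 30  # 25 px
        regions = detect_mvd(image, zones)
        assert len(regions) == 1
        r = regions[0]
        assert r.area_px == 25
        assert r.area_mm2 == pytest.approx(25 * 1.265625e-4, rel=0, abs=0)
        assert r.zone == "beta"
        assert r.min_grey == 30

    def test_sorted_by_area_then_centroid(self, full_zone_image):
        image, zones = full_zone_image
        image.grid[1:6, 1:6] = 10    # 25 px at top-left
        image.grid[20:26, 20:26] = 10  # 36 px lower-right
        image.grid[1:6, 30:35] = 10  # 25 px top-right
        regions = detect_mvd(image, zones)
        assert [r.area_px for r in regions] == [36, 25, 25]
        assert regions[1].centroid[1] < regions[2].centroid[1]
        assert [r.region_id for r in regions] == [1, 2, 3]

    def test_vessel_mask_can_split_regions(self, full_zone_image):
        image, zones = full_zone_image
        image.grid[10, 2:38] = 20  # a 36-px dark line
        vessels = VesselMask.from_mask(np.zeros((40, 40), dtype=bool))
        vessels.mask[10, 15] = True  # split into 13 px + 22 px
        regions = detect_mvd(image, zones, vessels=vessels)
        # only the 22-px half survives the strict >20 px rule
        assert [r.area_px for r in regions] == [22]

    def test_zone_clip_separates_dark_disc_from_dropout(self):
        grid = np.full((30, 30), 200, dtype=np.uint8)
        disc = np.zeros((30, 30), dtype=bool)
        beta = np.zeros((30, 30), dtype=bool)
        disc[:, :10] = True
        beta[:, 10:20] = True
        grid[:, :10] = 20  # dark disc
        grid[5:10, 8:15] = 20  # dropout overlapping the disc border
        zones = ZoneSet(disc=disc, alpha=np.zeros_like(disc), beta=beta)
        regions = detect_mvd(make_image(grid), zones, min_area_px=20)
        assert len(regions) == 1
        # only in-zone pixels counted: 5 rows x 5 cols (cols 10..14)
        assert regions[0].area_px == 25

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           connectivity=st.sampled_from([4, 8]))
    def test_equals_brute_force_on_random_grids(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, 256, size=(48, 48), dtype=np.uint8)
        image = make_image(grid)
        beta = rng.random((48, 48)) < 0.5
        alpha = ~beta & (rng.random((48, 48)) < 0.3)
        zones = ZoneSet(disc=np.zeros((48, 48), dtype=bool),
                        alpha=alpha, beta=beta)
        vessels = VesselMask.from_mask(rng.random((48, 48)) < 0.1)
        regions = detect_mvd(image, zones, vessels=vessels,
                             connectivity=connectivity)
        expected = brute_force_mvd(image, zones, vessels.mask, 50, 20,
                                   connectivity)
        assert {r.pixel_set for r in regions} == set(expected)

    def test_monotone_in_thresholds(self, rng):
        grid = rng.integers(0, 120, size=(60, 60), dtype=np.uint8)
        image = make_image(grid)
        zones = ZoneSet(disc=np.zeros((60, 60), dtype=bool),
                        alpha=np.zeros((60, 60), dtype=bool),
                        beta=np.ones((60, 60), dtype=bool))

        def total(grey, area):
            return sum(
                r.area_px
                for r in detect_mvd(image, zones, grey_threshold=grey,
                                    min_area_px=area)
            )

        for lo, hi in [(30, 50), (50, 80), (80, 120)]:
            assert total(lo, 20) <= total(hi, 20)
        for big, small in [(40, 20), (20, 10), (10, 0)]:
            assert total(50, big) <= total(50, small)

    def test_region_areas_conserve_union(self, rng):
        grid = rng.integers(0, 100, size=(50, 50), dtype=np.uint8)
        image = make_image(grid)
        zones = ZoneSet(disc=np.zeros((50, 50), dtype=bool),
                        alpha=np.zeros((50, 50), dtype=bool),
                        beta=np.ones((50, 50), dtype=bool))
        regions = detect_mvd(image, zones)
        union = set()
        for r in regions:
            assert not (union & r.pixel_set)  # disjoint
            union |= r.pixel_set
        assert sum(r.area_mm2 for r in regions) == pytest.approx(
            len(union) * PX_MM2
        )
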