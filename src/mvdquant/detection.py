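"""Microvascular dropout (flow-void) detection.

A dropout region is a connected set of analysis-eligible pixels inside the
peripapillary atrophy zones whose grey value is strictly below the dark
threshold (default 50) and whose pixel count strictly exceeds the minimum
area (default 20 px).  Both inequalities are strict and both constants are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage

from .io import EnFaceImage, ZoneSet
from .vessels import VesselMask, apply_vessel_mask

__all__ = [
    "MvDRegion",
    "binarize_dark",
    "label_components",
    "assign_zone",
    "detect_mvd",
]

DEFAULT_GREY_THRESHOLD = 50
DEFAULT_MIN_AREA_PX = 20


class ZoneAssignmentError(ValueError):
    """Raised when a region intersects neither PPA zone."""


@dataclass
class MvDRegion:
    """One detected dropout region.

    ``pixels`` is an (n, 2) array of (row, col) coordinates in lexicographic
    order; ``area_mm2`` is exactly ``area_px`` times the physical pixel
    area.
    """

    region_id: int
    pixels: np.ndarray
    area_px: int
    area_mm2: float
    centroid: tuple[float, float]
    zone: str
    min_grey: int
    mean_grey: float

    @cached_property
    def pixel_set(self) -> frozenset:
        return frozenset(map(tuple, self.pixels.tolist()))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def binarize_dark(
    image: EnFaceImage, grey_threshold: int = DEFAULT_GREY_THRESHOLD
) -> np.ndarray:
    """True exactly at valid pixels with grey strictly below the threshold."""
    if not 0 <= grey_threshold <= 255:
        raise ValueError(
            f"grey_threshold must lie in [0, 255], got {grey_threshold}"
        )
    return (image.grid < grey_threshold) & image.valid_mask


def label_components(binary: np.ndarray, connectivity: int = 8):
    """Label maximal connected components, labels dense from 1.

    Returns ``(labels, n_components)`` as :func:`scipy.ndimage.label` does.
    """
    binary = np.asarray(binary, dtype=bool)
    return ndimage.label(binary, structure=_structure(connectivity))


def assign_zone(pixels: np.ndarray, zones: ZoneSet) -> str:
    """Zone of the majority of the region's pixels; ties go to beta.

    Beta is the primary zone of the analysis (dropout is universally found
    there), hence the tie-break.
    """
    pixels = np.asarray(pixels)
    rows, cols = pixels[:, 0], pixels[:, 1]
    n_beta = int(np.count_nonzero(zones.beta[rows, cols]))
    n_alpha = int(np.count_nonzero(zones.alpha[rows, cols]))
    if n_beta == 0 and n_alpha == 0:
        raise ZoneAssignmentError(
            "region intersects neither the alpha nor the beta zone"
        )
    return "alpha" if n_alpha > n_beta else "beta"


def detect_mvd(
    image: EnFaceImage,
    zones: ZoneSet,
    vessels: VesselMask | None = None,
    grey_threshold: int = DEFAULT_GREY_THRESHOLD,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    connectivity: int = 8,
    clip_before_label: bool = True,
) -> list[MvDRegion]:
    """Detect dropout regions inside the PPA zones of one eye.

    Pipeline: exclude vessel pixels, restrict to the alpha/beta union,
    threshold dark pixels, label connected components, drop components with
    ``area_px <= min_area_px``, and assign each survivor to its majority
    zone.  With ``clip_before_label`` (default) components are formed from
    zone pixels only, so dark structures outside the zones (e.g. the disc)
    can never merge with in-zone dropout; the alternative labels first and
    clips afterwards.

    Regions are returned sorted by area descending, ties broken by centroid
    (row, then col).
    """
    if zones.shape != image.grid.shape:
        raise ValueError(
            f"zone masks shape {zones.shape} differs from image "
            f"shape {image.grid.shape}"
        )
    if min_area_px < 0:
        raise ValueError("min_area_px must be >= 0")
    if vessels is not None:
        image = apply_vessel_mask(image, vessels)

    dark = binarize_dark(image, grey_threshold)
    zone_union = zones.ppa_union
    if clip_before_label:
        labels, n = label_components(dark & zone_union, connectivity)
    else:
        labels, n = label_components(dark, connectivity)
        labels = np.where(zone_union, labels, 0)

    pixel_area_mm2 = image.pixel_pitch_um**2 / 1e6
    regions: list[MvDRegion] = []
    if n:
        # one pass over all component pixel indices, grouped by label
        flat_order = np.argsort(labels, axis=None, kind="stable")
        flat_sorted = labels.ravel()[flat_order]
        start = np.searchsorted(flat_sorted, np.arange(1, n + 2))
        for lab in range(1, n + 1):
            idx = flat_order[start[lab - 1]:start[lab]]
            area = idx.size
            if area <= min_area_px:
                continue
            rows, cols = np.unravel_index(np.sort(idx), labels.shape)
            pixels = np.column_stack([rows, cols])
            greys = image.grid[rows, cols]
            regions.append(
                MvDRegion(
                    region_id=-1,
                    pixels=pixels,
                    area_px=int(area),
                    area_mm2=float(area) * pixel_area_mm2,
                    centroid=(float(rows.mean()), float(cols.mean())),
                    zone=assign_zone(pixels, zones),
                    min_grey=int(greys.min()),
                    mean_grey=float(greys.mean()),
                )
            )
    regions.sort(key=lambda r: (-r.area_px, r.centroid[0], r.centroid[1]))
    for i, region in enumerate(regions, start=1):
        region.region_id = i
    return regions
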