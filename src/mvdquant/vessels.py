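"""Large choroidal vessel exclusion.

Large vessels appear in the en-face choroid angiogram as bright elongated
trees; they are removed ahead of dropout detection and density computation
so that neither statistic is contaminated by vessel lumina.  Vessel pixels
are invalidated, never inpainted: fabricated grey values would feed the
dark-threshold rule.

The segmentation rule is deliberately transparent: connected bright
components (grey >= ``bright_threshold``) are kept as vessels when their
skeleton is long enough (``min_length_px``) and their mean width — area
divided by skeleton length — is at least ``min_width_px``.  The elongation
requirement discards compact bright speckle clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .io import EnFaceImage

__all__ = ["VesselMask", "segment_large_vessels", "apply_vessel_mask"]


@dataclass
class VesselMask:
    """Binary vessel mask plus the fraction of image pixels it covers."""

    mask: np.ndarray
    vessel_fraction: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "VesselMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, vessel_fraction=float(mask.mean()))

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "VesselMask":
        return cls(mask=np.zeros(shape, dtype=bool), vessel_fraction=0.0)


def segment_large_vessels(
    image: EnFaceImage,
    bright_threshold: int = 180,
    min_width_px: float = 4.0,
    min_length_px: int = 30,
) -> VesselMask:
    """Segment bright elongated structures as large vessels."""
    if not 0 <= bright_threshold <= 255:
        raise ValueError(
            f"bright_threshold must lie in [0, 255], got {bright_threshold}"
        )
    if min_width_px < 0 or min_length_px < 0:
        raise ValueError("width/length thresholds must be non-negative")

    bright = (image.grid >= bright_threshold) & image.valid_mask
    labels, n = ndimage.label(
        bright, structure=ndimage.generate_binary_structure(2, 2)
    )
    if n == 0:
        return VesselMask.empty(image.grid.shape)

    skeleton = skeletonize(bright)
    # per-component pixel and skeleton-pixel counts
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    skel_len = np.bincount(labels[skeleton].ravel(), minlength=n + 1)
    keep = np.zeros(n + 1, dtype=bool)
    lengths = skel_len[1:]
    widths = np.divide(
        areas[1:], lengths, out=np.zeros_like(areas[1:], dtype=float),
        where=lengths > 0,
    )
    keep[1:] = (lengths >= min_length_px) & (widths >= min_width_px)
    return VesselMask.from_mask(keep[labels])


def apply_vessel_mask(image: EnFaceImage, vessels: VesselMask) -> EnFaceImage:
    """Return a copy of ``image`` with vessel pixels marked invalid.

    Grey values are untouched; the operation is idempotent.
    """
    if vessels.mask.shape != image.grid.shape:
        raise ValueError(
            f"vessel mask shape {vessels.mask.shape} differs from image "
            f"shape {image.grid.shape}"
        )
    out = image.copy()
    out.valid_mask &= ~vessels.mask
    return out
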