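"""Per-eye zone metrics: areas, dropout totals, flow density, presence.

Areas are exact integer pixel counts scaled by the physical pixel area
(pitch squared); at the default 11.25 um pitch one pixel is 126.5625 um².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .detection import MvDRegion
from .io import EnFaceImage, ZoneSet
from .vessels import VesselMask, apply_vessel_mask

__all__ = [
    "pixel_area_um2",
    "pixel_area_mm2",
    "zone_area_mm2",
    "mean_flow_density",
    "summarize_eye",
    "EyeMetrics",
    "DensityResult",
]

DEFAULT_SIGNAL_THRESHOLD = 50


def pixel_area_um2(image: EnFaceImage) -> float:
    """Physical area of one pixel in um² (pitch squared)."""
    return image.pixel_pitch_um**2


def pixel_area_mm2(image: EnFaceImage) -> float:
    return pixel_area_um2(image) / 1e6


def zone_area_mm2(mask: np.ndarray, image: EnFaceImage) -> float:
    """Area of a binary mask in mm², by pixel counting."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.grid.shape:
        raise ValueError(
            f"mask shape {mask.shape} differs from image shape "
            f"{image.grid.shape}"
        )
    return int(np.count_nonzero(mask)) * pixel_area_mm2(image)


class DensityResult(NamedTuple):
    """Flow density of one zone.

    ``count`` is the number of valid zone pixels carrying blood signal
    (grey >= threshold); ``fraction`` normalizes by the number of zone
    pixels for unit-robust comparisons.  ``empty_zone`` flags a zone with
    no pixels, for which both values are 0 by convention.
    """

    count: int
    fraction: float
    empty_zone: bool


def mean_flow_density(
    image: EnFaceImage,
    zone_mask: np.ndarray,
    vessels: VesselMask | None = None,
    signal_threshold: int = DEFAULT_SIGNAL_THRESHOLD,
) -> DensityResult:
    """Count valid non-vessel zone pixels occupied by blood signal."""
    if not 0 <= signal_threshold <= 255:
        raise ValueError(
            f"signal_threshold must lie in [0, 255], got {signal_threshold}"
        )
    zone_mask = np.asarray(zone_mask, dtype=bool)
    if zone_mask.shape != image.grid.shape:
        raise ValueError("zone mask shape differs from image shape")
    if vessels is not None:
        image = apply_vessel_mask(image, vessels)
    n_zone = int(np.count_nonzero(zone_mask))
    if n_zone == 0:
        return DensityResult(count=0, fraction=0.0, empty_zone=True)
    signal = (image.grid >= signal_threshold) & image.valid_mask & zone_mask
    count = int(np.count_nonzero(signal))
    return DensityResult(count=count, fraction=count / n_zone,
                         empty_zone=False)


@dataclass
class EyeMetrics:
    """The per-eye quantities entering the cohort statistics."""

    eye_id: str
    ppa_beta_area_mm2: float
    ppa_alpha_area_mm2: float
    mvd_total_area_beta_mm2: float
    mvd_total_area_alpha_mm2: float
    mvd_present: bool
    mvd_present_alpha: bool
    n_regions_beta: int
    n_regions_alpha: int
    density_beta: int
    density_alpha: int
    density_beta_fraction: float
    density_alpha_fraction: float


def summarize_eye(
    regions: Sequence[MvDRegion],
    zones: ZoneSet,
    image: EnFaceImage,
    vessels: VesselMask | None = None,
    signal_threshold: int = DEFAULT_SIGNAL_THRESHOLD,
) -> EyeMetrics:
    """Aggregate detections and masks into one eye's metric set.

    Eyes without any detected region report zero dropout area but stay in
    the cohort; presence is tracked separately.
    """
    beta_regions = [r for r in regions if r.zone == "beta"]
    alpha_regions = [r for r in regions if r.zone == "alpha"]
    dens_beta = mean_flow_density(image, zones.beta, vessels, signal_threshold)
    dens_alpha = mean_flow_density(image, zones.alpha, vessels,
                                   signal_threshold)
    return EyeMetrics(
        eye_id=image.eye_id,
        ppa_beta_area_mm2=zone_area_mm2(zones.beta, image),
        ppa_alpha_area_mm2=zone_area_mm2(zones.alpha, image),
        mvd_total_area_beta_mm2=sum(r.area_mm2 for r in beta_regions),
        mvd_total_area_alpha_mm2=sum(r.area_mm2 for r in alpha_regions),
        mvd_present=len(regions) > 0,
        mvd_present_alpha=len(alpha_regions) > 0,
        n_regions_beta=len(beta_regions),
        n_regions_alpha=len(alpha_regions),
        density_beta=dens_beta.count,
        density_alpha=dens_alpha.count,
        density_beta_fraction=dens_beta.fraction,
        density_alpha_fraction=dens_alpha.fraction,
    )
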