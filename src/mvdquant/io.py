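"""Reading and writing of en-face OCTA images, zone masks, manifests and config.

All detection math downstream assumes 8-bit grey values; this module is the
boundary where that invariant (and grid congruence between image and masks)
is enforced.  Images and masks are exchanged as 8-bit grayscale PNG, the
per-eye covariate table as CSV, and run configuration as YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

#: physical field of view of the default acquisition, in micrometres
FIELD_WIDTH_UM = 4500.0
#: default grid size: one pixel per cluster of the 4.5 mm scan cube
DEFAULT_WIDTH_PX = 400
#: default pixel pitch, 4500 um / 400 clusters
DEFAULT_PIXEL_PITCH_UM = FIELD_WIDTH_UM / DEFAULT_WIDTH_PX

#: artifact flags that exclude an eye from analysis
ALLOWED_ARTIFACT_FLAGS = frozenset(
    {"double_vessel", "motion", "segmentation_error_gt3"}
)

MANIFEST_COLUMNS = (
    "eye_id",
    "subject_id",
    "age",
    "sex",
    "SE",
    "AL",
    "quality_score",
    "artifact_flags",
)

#: spherical-equivalent inclusion interval, diopters
SE_INCLUSION_RANGE = (-10.0, -0.5)


class ImageFormatError(ValueError):
    """Raised when an input file violates the 8-bit grayscale contract."""


class MaskError(ValueError):
    """Raised for malformed or mutually inconsistent zone masks."""


class ManifestError(ValueError):
    """Raised for manifest files missing required structure."""


@dataclass
class EnFaceImage:
    """A single en-face angiogram of the peripapillary region.

    ``grid`` holds 8-bit grey values; ``valid_mask`` marks pixels eligible
    for analysis (large-vessel exclusion clears entries in it without
    touching the grey values).
    """

    eye_id: str
    grid: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ImageFormatError(
                f"image grid must be 2-D, got shape {self.grid.shape}"
            )
        if self.grid.size == 0:
            raise ImageFormatError("image grid is empty")
        if self.grid.min() < 0 or self.grid.max() > 255:
            raise ImageFormatError("grey values must lie in [0, 255]")
        self.grid = self.grid.astype(np.uint8)
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.grid.shape:
                raise MaskError("valid_mask shape differs from image grid")

    @property
    def height_px(self) -> int:
        return self.grid.shape[0]

    @property
    def width_px(self) -> int:
        return self.grid.shape[1]

    @property
    def field_width_um(self) -> float:
        """Physical width of the scanned field implied by pitch and grid."""
        return self.pixel_pitch_um * self.width_px

    def copy(self) -> "EnFaceImage":
        return EnFaceImage(
            eye_id=self.eye_id,
            grid=self.grid.copy(),
            pixel_pitch_um=self.pixel_pitch_um,
            valid_mask=self.valid_mask.copy(),
        )


@dataclass
class ZoneSet:
    """Binary masks of the optic disc and the PPA alpha/beta zones.

    Masks live on the image grid and are pairwise disjoint: a pixel belongs
    to at most one anatomical zone.
    """

    disc: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.disc = np.asarray(self.disc, dtype=bool)
        self.alpha = np.asarray(self.alpha, dtype=bool)
        self.beta = np.asarray(self.beta, dtype=bool)
        shapes = {m.shape for m in (self.disc, self.alpha, self.beta)}
        if len(shapes) != 1:
            raise MaskError(f"zone masks have differing shapes: {shapes}")
        for a, b, names in (
            (self.disc, self.alpha, "disc/alpha"),
            (self.disc, self.beta, "disc/beta"),
            (self.alpha, self.beta, "alpha/beta"),
        ):
            n_overlap = int(np.count_nonzero(a & b))
            if n_overlap:
                raise MaskError(
                    f"zone masks {names} overlap on {n_overlap} pixel(s)"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.disc.shape

    @property
    def ppa_union(self) -> np.ndarray:
        """Pixels belonging to either PPA zone (the MvD search region)."""
        return self.alpha | self.beta


@dataclass(frozen=True)
class EyeRecord:
    """Clinical covariates and QC fields for one analyzed eye."""

    eye_id: str
    subject_id: str
    age: float
    sex: str
    se: float
    al: float
    quality_score: int
    artifact_flags: frozenset = frozenset()
    group: str | None = None
    excluded: bool = False
    exclusion_reason: str | None = None


def _grid_from_pil(img: Image.Image, path: Path) -> np.ndarray:
    if img.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
        raise ImageFormatError(
            f"{path}: {img.mode}-mode image; expected 8-bit grayscale"
        )
    arr = np.asarray(img)
    if arr.ndim == 3:
        # RGB(A) export of a grayscale angiogram: all channels must agree
        rgb = arr[..., :3]
        if not (np.array_equal(rgb[..., 0], rgb[..., 1])
                and np.array_equal(rgb[..., 0], rgb[..., 2])):
            raise ImageFormatError(
                f"{path}: multi-channel image with unequal channels"
            )
        arr = rgb[..., 0]
    if arr.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: {arr.dtype} pixel depth; expected 8-bit grayscale"
        )
    return arr


def read_image(
    path: str | Path,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
    eye_id: str | None = None,
) -> EnFaceImage:
    """Read an 8-bit grayscale PNG as an :class:`EnFaceImage`.

    The pixel pitch is configuration, not file metadata: PNG carries no
    physical scale, so images of non-default size require an explicit pitch.
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise ImageFormatError(f"{path}: not a readable image ({exc})") from exc
    arr = _grid_from_pil(img, path)
    return EnFaceImage(
        eye_id=eye_id if eye_id is not None else path.stem,
        grid=arr,
        pixel_pitch_um=pixel_pitch_um,
    )


def write_image(image: EnFaceImage, path: str | Path) -> Path:
    """Write the grey grid to ``path`` as 8-bit grayscale PNG."""
    path = Path(path)
    Image.fromarray(image.grid, mode="L").save(path, format="PNG")
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as a {0, 255} 8-bit PNG."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")
    return Path(path)


def read_mask(path: str | Path, image: EnFaceImage) -> np.ndarray:
    """Read one binary {0, 255} mask congruent with ``image``.

    Any grey value other than 0 or 255 is an error rather than a threshold:
    semi-transparent mask exports would otherwise be resolved silently.
    """
    arr = _grid_from_pil(Image.open(path), Path(path))
    if arr.shape != image.grid.shape:
        raise MaskError(
            f"{path}: mask shape {arr.shape} differs from image "
            f"shape {image.grid.shape}"
        )
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise MaskError(
            f"{path}: mask contains non-binary values {bad.tolist()}; "
            "expected only 0 and 255"
        )
    return arr == 255


def read_zoneset(
    disc_path: str | Path,
    alpha_path: str | Path,
    beta_path: str | Path,
    image: EnFaceImage,
) -> ZoneSet:
    """Read the three zone masks; overlap between any two is an error."""
    return ZoneSet(
        disc=read_mask(disc_path, image),
        alpha=read_mask(alpha_path, image),
        beta=read_mask(beta_path, image),
    )


def _parse_flags(raw) -> frozenset:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text:
        return frozenset()
    flags = frozenset(part.strip() for part in text.split(";") if part.strip())
    unknown = flags - ALLOWED_ARTIFACT_FLAGS
    if unknown:
        raise ManifestError(f"unknown artifact flag(s): {sorted(unknown)}")
    return flags


def read_manifest(path: str | Path) -> list[EyeRecord]:
    """Read the per-eye covariate table.

    Eyes whose spherical equivalent falls outside the inclusion interval
    are returned flagged ``excluded`` (with a reason) rather than dropped,
    so callers can report them.  The ``group`` column is filled from SE
    when absent.
    """
    from .cohort import classify_group

    df = pd.read_csv(path, dtype={"eye_id": str, "subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: manifest missing column(s) {missing}")
    lo, hi = SE_INCLUSION_RANGE
    records = []
    for row in df.itertuples(index=False):
        se = float(row.SE)
        excluded = False
        reason = None
        group = getattr(row, "group", None)
        if isinstance(group, float) and np.isnan(group):
            group = None
        if not lo <= se <= hi:
            excluded = True
            reason = f"SE {se:+.2f} D outside inclusion range [{lo}, {hi}]"
            group = None
        elif group is None:
            group = classify_group(se)
        records.append(
            EyeRecord(
                eye_id=str(row.eye_id),
                subject_id=str(row.subject_id),
                age=float(row.age),
                sex=str(row.sex),
                se=se,
                al=float(row.AL),
                quality_score=int(row.quality_score),
                artifact_flags=_parse_flags(row.artifact_flags),
                group=group,
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    return records


def write_manifest(records: Sequence[EyeRecord], path: str | Path) -> Path:
    rows = []
    for r in records:
        rows.append(
            {
                "eye_id": r.eye_id,
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "SE": r.se,
                "AL": r.al,
                "quality_score": r.quality_score,
                "artifact_flags": ";".join(sorted(r.artifact_flags)),
                "group": r.group if r.group is not None else "",
            }
        )
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS) + ["group"])
    df.to_csv(path, index=False)
    return Path(path)


@dataclass
class RunConfig:
    """Tunable constants of the detection pipeline.

    Defaults encode the study conditions: 11.25 um pitch (4.5 mm field over
    400 clusters), dark threshold 50, minimum region area 20 px (strictly
    exceeded), 8-connectivity, and a signal threshold of 50 for flow
    density.
    """

    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    grey_threshold: int = 50
    min_area_px: int = 20
    connectivity: int = 8
    signal_threshold: int = 50
    vessel_bright_threshold: int = 180
    vessel_min_width_px: float = 4.0
    vessel_min_length_px: int = 30
    vessel_masking_scope: str = "image"  # or "zones"
    clip_before_label: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("grey_threshold", "signal_threshold",
                     "vessel_bright_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255], got {v}")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.vessel_masking_scope not in ("image", "zones"):
            raise ValueError("vessel_masking_scope must be 'image' or 'zones'")


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; unknown keys are an error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    return Path(path)
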