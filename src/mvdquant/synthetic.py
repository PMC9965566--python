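"""Synthetic peripapillary OCTA cohort generator.

No patient data ship with this package, so every downstream stage is
exercised against simulated eyes: a speckled en-face choroid background,
bright large-vessel trees, a dark optic disc, a PPA-beta ring adjacent to
the disc with an optional PPA-alpha ring peripheral to it, and planted dark
dropout regions with known ground truth.

Covariates (age, sex, SE, AL) and the true zone/dropout areas are drawn
from packaged *profiles* ("high_myopia", "mild_moderate") whose constants
were calibrated so that the full detection pipeline reproduces the cohort
statistics of the study the generator emulates (group means of dropout and
beta-zone area, dropout prevalence, and the dropout-area correlations with
SE, AL and beta-zone area).  Calibration constants live in the versioned
YAML files under :mod:`mvdquant.profiles`, not in code.

The generative model, per eye:

* SE and age are truncated normals; sex is Bernoulli.
* AL is linear in SE plus noise (axial elongation with myopia).
* True beta-zone area is linear in SE and in the AL residual, plus noise,
  truncated to a plausible interval.
* Dropout is present with a per-group probability; when present, total
  dropout area is ``coeff * beta_area**power`` times mean-one lognormal
  noise — a convex monotone coupling whose power and noise width set the
  cohort-level correlation with beta area.
* The total is split into one or more connected blobs grown inside the
  beta ring (never touching each other, the disc, or the alpha ring);
  with some probability an extra blob is planted in the alpha ring.

Rendered grey values are constructed so that the detector's rules are
exact on synthetic data: planted pixels are strictly below 50, background
speckle is clipped to stay above it, vessels are bright, and the disc lies
outside the analysis zones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.ndimage import binary_dilation, gaussian_filter

from . import __version__
from .io import (
    EnFaceImage,
    EyeRecord,
    ZoneSet,
    write_image,
    write_manifest,
    write_mask,
)

__all__ = [
    "GeneratorProfile",
    "EyeTruth",
    "PlantedRegion",
    "load_profile",
    "list_profiles",
    "sample_covariates",
    "sample_eye_truth",
    "render_eye",
    "generate_cohort",
]


class GenerationError(RuntimeError):
    """Raised when a sampled geometry cannot host the requested dropout."""


# ---------------------------------------------------------------------------
# profile


@dataclass
class TruncatedNormalSpec:
    """Truncated normal with an explicit location parameter.

    ``loc`` is the pre-truncation location calibrated so that the mean of
    the *truncated* distribution equals ``target_mean``.
    """

    target_mean: float
    sd: float
    lo: float
    hi: float
    loc: float

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lo - self.loc) / self.sd
        b = (self.hi - self.loc) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.loc, scale=self.sd, size=n, random_state=rng
        )

    def mean(self) -> float:
        a = (self.lo - self.loc) / self.sd
        b = (self.hi - self.loc) / self.sd
        return float(stats.truncnorm.mean(a, b, loc=self.loc, scale=self.sd))


@dataclass
class GeneratorProfile:
    name: str
    n_eyes: int
    # image grid
    size_px: int
    pixel_pitch_um: float
    # geometry
    disc_radius_px_mean: float
    disc_radius_px_sd: float
    disc_center_jitter_px: float
    # covariates
    se: TruncatedNormalSpec
    age: TruncatedNormalSpec
    female_prob: float
    al_mean: float
    al_se_slope: float
    al_noise_sd: float
    # true beta-zone area model (mm^2)
    beta_loc_mm2: float
    beta_sd_mm2: float
    beta_se_slope: float
    beta_al_slope: float
    beta_lo_mm2: float
    beta_hi_mm2: float
    # alpha zone model
    alpha_presence_prob: float
    alpha_area_mean_mm2: float
    alpha_area_sd_mm2: float
    alpha_lo_mm2: float
    alpha_hi_mm2: float
    # dropout model
    mvd_presence_prob: float
    mvd_coupling_coeff: float
    mvd_coupling_power: float
    mvd_noise_cv: float
    mvd_min_area_px: int
    mvd_max_frac_of_beta: float
    mvd_extra_region_lambda: float
    mvd_grey_mean: float
    mvd_grey_sd: float
    alpha_mvd_prob: float
    alpha_mvd_area_mean_mm2: float
    alpha_mvd_area_sd_mm2: float
    # rendering
    background_mean_grey: float
    background_speckle_sd: float
    background_floor_grey: float
    background_correlation_length_px: float
    vessel_n_trees: int
    vessel_width_px: tuple[float, float]
    vessel_grey: tuple[float, float]
    vessel_steps: int
    disc_grey: float
    # QC fields
    quality_score_lo: int
    quality_score_hi: int
    artifact_prob: float
    seed: int | None = None

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_pitch_um**2 / 1e6

    def validate(self) -> None:
        if self.n_eyes < 0:
            raise ValueError("n_eyes must be >= 0")
        for p in (
            self.female_prob,
            self.alpha_presence_prob,
            self.mvd_presence_prob,
            self.alpha_mvd_prob,
            self.artifact_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for sd in (
            self.se.sd,
            self.age.sd,
            self.al_noise_sd,
            self.beta_sd_mm2,
            self.alpha_area_sd_mm2,
            self.mvd_noise_cv,
            self.background_speckle_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        # dropout grey support must stay strictly below the dark threshold
        if not 0 <= self.mvd_grey_mean <= 49:
            raise ValueError("mvd_grey_mean must lie in [0, 49]")
        # texture alone must not trip the dark threshold
        if self.background_mean_grey <= 50 + 3 * self.background_speckle_sd:
            raise ValueError(
                "background mean grey must exceed 50 + 3 * speckle sd"
            )
        if self.background_floor_grey < 50:
            raise ValueError("background floor must be >= the dark threshold")
        if not 0 < self.mvd_max_frac_of_beta <= 1:
            raise ValueError("mvd_max_frac_of_beta must lie in (0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorProfile":
        data = dict(data)
        for key in ("se", "age"):
            data[key] = TruncatedNormalSpec(**data[key])
        for key in ("vessel_width_px", "vessel_grey"):
            data[key] = tuple(data[key])
        profile = cls(**data)
        profile.validate()
        return profile

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def list_profiles() -> list[str]:
    """Names of the profiles packaged with mvdquant."""
    root = resources.files("mvdquant") / "profiles"
    return sorted(p.name[:-5] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_profile(name_or_path: str | Path) -> GeneratorProfile:
    """Load a packaged profile by name, or any profile YAML by path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        return GeneratorProfile.from_yaml(path)
    ref = resources.files("mvdquant") / "profiles" / f"{name_or_path}.yaml"
    if not ref.is_file():
        raise FileNotFoundError(
            f"unknown profile {name_or_path!r}; packaged profiles: "
            f"{list_profiles()}"
        )
    return GeneratorProfile.from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# covariate sampling (vectorized; also the fast path for calibration checks)


def _latent_uniforms(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """(n, d) matrix of stratified, mutually decorrelated uniforms.

    Quantile-balanced (Latin-hypercube) sampling: each column holds one
    uniform draw per equal-probability stratum in random order, so the
    marginals of a finite cohort cover every quantile band once and the
    cohort is statistically representative of the profile rather than a
    high-variance draw from it.  Columns are then rank-decorrelated
    (Iman-Conover): the normal scores of the matrix are rotated towards a
    diagonal correlation matrix and each column is re-ordered to the
    rotated ranks, which leaves every marginal exactly stratified while
    suppressing spurious sample correlation between independent latents.
    """
    u = (np.array([rng.permutation(n) for _ in range(d)]).T
         + rng.random((n, d))) / n
    if n < 3 * d + 2:
        return u
    z = stats.norm.ppf(u)
    corr = np.corrcoef(z, rowvar=False)
    try:
        lower = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        return u
    z_star = solve_triangular(lower, z.T, lower=True).T
    out = np.empty_like(u)
    order = np.argsort(z_star, axis=0)
    ranks = np.empty((n,), dtype=np.intp)
    for j in range(d):
        ranks[order[:, j]] = np.arange(n)
        out[:, j] = np.sort(u[:, j])[ranks]
    return out


def _truncnorm_ppf(
    u: np.ndarray, mean, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Inverse CDF of a (possibly per-eye) truncated normal."""
    mean = np.asarray(mean, dtype=float)
    if sd <= 0:
        return np.clip(mean, lo, hi) * np.ones_like(u)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def sample_covariates(
    profile: GeneratorProfile, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-eye covariates and continuous true areas for ``n`` eyes.

    This is the pixel-free part of the generative model; rasterization of
    zones and dropout blobs happens in :func:`sample_eye_truth`.  Each
    latent variable is sampled by stratified inverse transform (see
    :func:`_stratified_uniform`).
    """
    lat = _latent_uniforms(n, 9, rng)
    se_spec, age_spec = profile.se, profile.age
    se = _truncnorm_ppf(lat[:, 0], se_spec.loc,
                        se_spec.sd, se_spec.lo, se_spec.hi)
    age = _truncnorm_ppf(lat[:, 1], age_spec.loc,
                         age_spec.sd, age_spec.lo, age_spec.hi)
    female = lat[:, 2] < profile.female_prob
    al_resid = stats.norm.ppf(lat[:, 3],
                              scale=max(profile.al_noise_sd, 1e-12))
    al = (
        profile.al_mean
        + profile.al_se_slope * (se - profile.se.target_mean)
        + al_resid
    )

    beta_mean = (
        profile.beta_loc_mm2
        + profile.beta_se_slope * (se - profile.se.target_mean)
        + profile.beta_al_slope * al_resid
    )
    beta = _truncnorm_ppf(
        lat[:, 4], beta_mean, profile.beta_sd_mm2,
        profile.beta_lo_mm2, profile.beta_hi_mm2,
    )

    alpha_present = lat[:, 5] < profile.alpha_presence_prob
    alpha = np.zeros(n)
    m = int(alpha_present.sum())
    if m:
        alpha[alpha_present] = _truncnorm_ppf(
            (rng.permutation(m) + rng.random(m)) / m,
            profile.alpha_area_mean_mm2,
            profile.alpha_area_sd_mm2, profile.alpha_lo_mm2,
            profile.alpha_hi_mm2,
        )

    px_mm2 = profile.pixel_area_mm2
    min_area_mm2 = profile.mvd_min_area_px * px_mm2
    present = lat[:, 6] < profile.mvd_presence_prob
    cv = profile.mvd_noise_cv
    # multiplicative noise from a +-2 sigma truncated log-normal: wide
    # enough to decouple dropout from beta area within a group, bounded so
    # single eyes cannot dominate cohort statistics
    noise = np.exp(
        stats.truncnorm.ppf(lat[:, 7], -2.0, 2.0, loc=0.0,
                            scale=max(cv, 1e-12))
    )
    mvd_beta = (
        profile.mvd_coupling_coeff
        * beta**profile.mvd_coupling_power
        * noise
    )
    mvd_beta = np.clip(mvd_beta, min_area_mm2,
                       profile.mvd_max_frac_of_beta * beta)
    mvd_beta = np.where(present, mvd_beta, 0.0)

    alpha_mvd_present = alpha_present & (
        lat[:, 8] < profile.alpha_mvd_prob
    )
    mvd_alpha = np.zeros(n)
    if alpha_mvd_present.any():
        k = int(alpha_mvd_present.sum())
        raw = stats.norm.ppf(
            (rng.permutation(k) + rng.random(k)) / k,
            loc=profile.alpha_mvd_area_mean_mm2,
            scale=max(profile.alpha_mvd_area_sd_mm2, 1e-12),
        )
        cap = profile.mvd_max_frac_of_beta * alpha[alpha_mvd_present]
        mvd_alpha[alpha_mvd_present] = np.clip(raw, min_area_mm2, cap)
        # alpha rings too small for a minimal blob carry no dropout
        too_small = cap < min_area_mm2
        mvd_alpha[np.flatnonzero(alpha_mvd_present)[too_small]] = 0.0

    quality = rng.integers(profile.quality_score_lo,
                           profile.quality_score_hi + 1, n)
    flagged = rng.random(n) < profile.artifact_prob

    width = max(3, len(str(max(n, 1))))
    return pd.DataFrame(
        {
            "eye_id": [f"{profile.name}_{i:0{width}d}" for i in range(n)],
            "subject_id": [f"S{i:0{width}d}_{profile.name}"
                           for i in range(n)],
            "age": age,
            "sex": np.where(female, "F", "M"),
            "SE": se,
            "AL": al,
            "quality_score": quality,
            "artifact_flags": np.where(flagged, "motion", ""),
            "group": np.where(se <= -6.0, "high", "mild_moderate"),
            "true_beta_mm2": beta,
            "alpha_present": alpha_present,
            "true_alpha_mm2": alpha,
            "mvd_present": present & (mvd_beta > 0),
            "true_mvd_beta_mm2": mvd_beta,
            "alpha_mvd_present": alpha_mvd_present & (mvd_alpha > 0),
            "true_mvd_alpha_mm2": mvd_alpha,
        }
    )


# ---------------------------------------------------------------------------
# rasterized ground truth


@dataclass
class PlantedRegion:
    """One planted dropout blob: (n, 2) pixel array and its zone."""

    pixels: np.ndarray
    zone: str

    @property
    def area_px(self) -> int:
        return int(len(self.pixels))


@dataclass
class EyeTruth:
    """Ground truth for one synthetic eye.

    Areas are the *realized* ones — pixel counts of the rasterized masks
    and blobs times the pixel area — which is what the detector can be
    held to exactly.
    """

    record: EyeRecord
    zones: ZoneSet
    regions: list[PlantedRegion]
    pixel_pitch_um: float
    ppa_beta_area_mm2: float
    ppa_alpha_area_mm2: float
    mvd_area_beta_mm2: float
    mvd_area_alpha_mm2: float

    @property
    def mvd_mask(self) -> np.ndarray:
        mask = np.zeros(self.zones.shape, dtype=bool)
        for region in self.regions:
            mask[region.pixels[:, 0], region.pixels[:, 1]] = True
        return mask


_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _grow_blob(
    allowed: np.ndarray,
    n_px: int,
    rng: np.random.Generator,
    max_attempts: int = 20,
) -> np.ndarray | None:
    """Grow a connected blob of exactly ``n_px`` pixels inside ``allowed``.

    Stochastic breadth-first growth over the 4-neighborhood: the blob is
    connected under both 4- and 8-connectivity and has an irregular,
    dropout-like outline.  Returns an (n_px, 2) array, or None if no seed
    admits the requested size.
    """
    h, w = allowed.shape
    candidates = np.flatnonzero(allowed)
    if candidates.size < n_px:
        return None
    state = np.zeros((h, w), dtype=np.uint8)  # 0 new, 1 frontier, 2 chosen
    for _ in range(max_attempts):
        state[:] = 0
        start = int(candidates[rng.integers(candidates.size)])
        r0, c0 = divmod(start, w)
        frontier = [(r0, c0)]
        state[r0, c0] = 1
        chosen: list[tuple[int, int]] = []
        while frontier and len(chosen) < n_px:
            i = int(rng.integers(len(frontier)))
            frontier[i], frontier[-1] = frontier[-1], frontier[i]
            r, c = frontier.pop()
            state[r, c] = 2
            chosen.append((r, c))
            for dr, dc in _N4:
                rr, cc = r + dr, c + dc
                if (0 <= rr < h and 0 <= cc < w and allowed[rr, cc]
                        and state[rr, cc] == 0):
                    state[rr, cc] = 1
                    frontier.append((rr, cc))
        if len(chosen) == n_px:
            return np.array(sorted(chosen), dtype=np.intp)
    return None


def _split_sizes(
    total_px: int, min_px: int, lam: float, rng: np.random.Generator
) -> list[int]:
    """Split a pixel budget into region sizes, each at least ``min_px``."""
    k_max = max(1, total_px // min_px)
    k = min(1 + int(rng.poisson(lam)), k_max)
    if k == 1:
        return [total_px]
    weights = rng.dirichlet(np.ones(k))
    spare = total_px - k * min_px
    sizes = [min_px + int(np.floor(w * spare)) for w in weights]
    sizes[0] += total_px - sum(sizes)
    return sizes


def _raster_zones(
    row: pd.Series, profile: GeneratorProfile, rng: np.random.Generator
) -> ZoneSet:
    size = profile.size_px
    jitter = profile.disc_center_jitter_px
    cy, cx = (size - 1) / 2 + rng.uniform(-jitter, jitter, 2)
    disc_r = float(
        np.clip(
            rng.normal(profile.disc_radius_px_mean,
                       profile.disc_radius_px_sd),
            0.5 * profile.disc_radius_px_mean,
            1.5 * profile.disc_radius_px_mean,
        )
    )
    yy, xx = np.ogrid[:size, :size]
    dist = np.hypot(yy - cy, xx - cx)
    disc = dist <= disc_r

    px_mm2 = profile.pixel_area_mm2
    beta_px = max(0, round(float(row.true_beta_mm2) / px_mm2))
    r_beta = np.sqrt(disc_r**2 + beta_px / np.pi)
    beta = (dist > disc_r) & (dist <= r_beta)

    alpha = np.zeros_like(disc)
    if bool(row.alpha_present) and row.true_alpha_mm2 > 0:
        alpha_px = round(float(row.true_alpha_mm2) / px_mm2)
        r_alpha = np.sqrt(r_beta**2 + alpha_px / np.pi)
        alpha = (dist > r_beta) & (dist <= r_alpha)
    return ZoneSet(disc=disc, alpha=alpha, beta=beta)


def sample_eye_truth(
    profile: GeneratorProfile,
    rng: np.random.Generator,
    row: pd.Series | None = None,
    max_retries: int = 3,
) -> EyeTruth:
    """Sample one eye's ground truth: covariates, zone masks, planted blobs.

    The continuous true areas from the covariate model are rasterized; all
    reported truth areas are realized pixel counts.  If the sampled rings
    cannot host the requested blobs the geometry is resampled a bounded
    number of times before erroring.
    """
    if row is None:
        row = sample_covariates(profile, 1, rng).iloc[0]
    px_mm2 = profile.pixel_area_mm2

    last_error = "unknown"
    for _ in range(max_retries):
        zones = _raster_zones(row, profile, rng)
        structure = np.ones((3, 3), dtype=bool)
        blocked = binary_dilation(zones.disc, structure=structure)
        regions: list[PlantedRegion] = []
        ok = True

        budgets: list[tuple[str, int]] = []
        if bool(row.mvd_present):
            total = round(float(row.true_mvd_beta_mm2) / px_mm2)
            for size in _split_sizes(total, profile.mvd_min_area_px,
                                     profile.mvd_extra_region_lambda, rng):
                budgets.append(("beta", size))
        if bool(row.alpha_mvd_present):
            budgets.append(
                ("alpha", round(float(row.true_mvd_alpha_mm2) / px_mm2))
            )

        for zone_name, size in budgets:
            zone_mask = zones.beta if zone_name == "beta" else zones.alpha
            blob = _grow_blob(zone_mask & ~blocked, size, rng)
            if blob is None:
                ok = False
                last_error = (
                    f"could not place a {size}-px blob in the "
                    f"{zone_name} ring of eye {row.eye_id}"
                )
                break
            regions.append(PlantedRegion(pixels=blob, zone=zone_name))
            planted = np.zeros(zones.shape, dtype=bool)
            planted[blob[:, 0], blob[:, 1]] = True
            blocked |= binary_dilation(planted, structure=structure)
        if not ok:
            continue

        record = EyeRecord(
            eye_id=str(row.eye_id),
            subject_id=str(row.subject_id),
            age=float(row.age),
            sex=str(row.sex),
            se=float(row.SE),
            al=float(row.AL),
            quality_score=int(row.quality_score),
            artifact_flags=frozenset(
                f for f in str(row.artifact_flags).split(";") if f
            ),
            group=str(row.group),
        )
        mvd_beta_px = sum(r.area_px for r in regions if r.zone == "beta")
        mvd_alpha_px = sum(r.area_px for r in regions if r.zone == "alpha")
        return EyeTruth(
            record=record,
            zones=zones,
            regions=regions,
            pixel_pitch_um=profile.pixel_pitch_um,
            ppa_beta_area_mm2=int(zones.beta.sum()) * px_mm2,
            ppa_alpha_area_mm2=int(zones.alpha.sum()) * px_mm2,
            mvd_area_beta_mm2=mvd_beta_px * px_mm2,
            mvd_area_alpha_mm2=mvd_alpha_px * px_mm2,
        )
    raise GenerationError(last_error)


# ---------------------------------------------------------------------------
# rendering


def _draw_vessel_trees(
    canvas: np.ndarray,
    zones: ZoneSet,
    profile: GeneratorProfile,
    rng: np.random.Generator,
) -> None:
    """Mark vessel-tree pixels on ``canvas`` (bool, modified in place).

    Each tree is a wiggly trunk leaving the disc border radially, plus two
    branches; strokes are thickened by a per-tree width.
    """
    size = profile.size_px
    rows, cols = np.nonzero(zones.disc)
    if rows.size == 0:
        cy = cx = (size - 1) / 2
        disc_r = 0.0
    else:
        cy, cx = rows.mean(), cols.mean()
        disc_r = np.sqrt(rows.size / np.pi)

    w_lo, w_hi = profile.vessel_width_px
    for _ in range(profile.vessel_n_trees):
        width = rng.uniform(w_lo, w_hi)
        theta = rng.uniform(0, 2 * np.pi)
        paths = [(theta, profile.vessel_steps)]
        start = np.array(
            [cy + (disc_r + 1) * np.sin(theta),
             cx + (disc_r + 1) * np.cos(theta)]
        )
        stroke = np.zeros_like(canvas)
        for theta0, steps in paths:
            pos = start.copy()
            direction = theta0
            for step in range(steps):
                direction += rng.normal(0.0, 0.15)
                pos += np.array([np.sin(direction), np.cos(direction)])
                r, c = int(round(pos[0])), int(round(pos[1]))
                if not (0 <= r < size and 0 <= c < size):
                    break
                stroke[r, c] = True
                if step == steps // 2 and len(paths) < 3:
                    paths.append(
                        (direction + rng.choice([-1.0, 1.0])
                         * rng.uniform(0.4, 0.9), steps // 2)
                    )
                    start = pos.copy()
        radius = max(1, int(round(width / 2)))
        yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
        disk = (yy**2 + xx**2) <= radius**2
        canvas |= binary_dilation(stroke, structure=disk)


def render_eye(
    truth: EyeTruth,
    profile: GeneratorProfile,
    rng: np.random.Generator,
) -> tuple[EnFaceImage, ZoneSet, np.ndarray]:
    """Render the en-face angiogram for a sampled eye truth.

    Returns the image, the zone set, and the ground-truth dropout mask.
    Painting order (background, vessels, disc, dropout last) guarantees
    every planted pixel is strictly below the dark threshold.
    """
    size = profile.size_px
    if profile.background_speckle_sd > 0:
        noise = rng.standard_normal((size, size))
        corr = profile.background_correlation_length_px
        if corr > 0:
            noise = gaussian_filter(noise, sigma=corr, mode="reflect")
            noise /= noise.std()
        img = profile.background_mean_grey \
            + profile.background_speckle_sd * noise
        # truncate the speckle so texture alone can never trip the
        # dark threshold (the tail mass removed is ~Phi(-4))
        img = np.maximum(img, profile.background_floor_grey)
    else:
        img = np.full((size, size), profile.background_mean_grey,
                      dtype=float)

    if profile.vessel_n_trees > 0:
        vessel_canvas = np.zeros((size, size), dtype=bool)
        _draw_vessel_trees(vessel_canvas, truth.zones, profile, rng)
        lo, hi = profile.vessel_grey
        img[vessel_canvas] = rng.uniform(lo, hi,
                                         int(vessel_canvas.sum()))

    img[truth.zones.disc] = profile.disc_grey

    for region in truth.regions:
        greys = np.clip(
            rng.normal(profile.mvd_grey_mean, profile.mvd_grey_sd,
                       region.area_px),
            0, 49,
        )
        img[region.pixels[:, 0], region.pixels[:, 1]] = greys

    grid = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = EnFaceImage(
        eye_id=truth.record.eye_id,
        grid=grid,
        pixel_pitch_um=profile.pixel_pitch_um,
    )
    return image, truth.zones, truth.mvd_mask


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    profile: GeneratorProfile,
    out_dir: str | Path,
    seed: int | None = None,
    n_eyes: int | None = None,
) -> dict:
    """Write a full synthetic cohort to ``out_dir``.

    Per eye: the angiogram PNG, the three zone-mask PNGs, and the
    ground-truth dropout mask PNG; plus ``manifest.csv`` and
    ``truth.json`` for the whole cohort.  Output is byte-identical across
    runs with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = profile.seed
    rng = np.random.default_rng(seed)
    n = profile.n_eyes if n_eyes is None else n_eyes

    covariates = sample_covariates(profile, n, rng)
    records = []
    truth_entries = []
    for i in range(n):
        row = covariates.iloc[i]
        try:
            truth = sample_eye_truth(profile, rng, row=row)
            image, zones, mvd_mask = render_eye(truth, profile, rng)
        except (GenerationError, OSError) as exc:
            raise GenerationError(f"eye index {i}: {exc}") from exc
        eye_id = truth.record.eye_id
        write_image(image, out_dir / f"{eye_id}.png")
        write_mask(zones.disc, out_dir / f"{eye_id}_disc.png")
        write_mask(zones.alpha, out_dir / f"{eye_id}_alpha.png")
        write_mask(zones.beta, out_dir / f"{eye_id}_beta.png")
        write_mask(mvd_mask, out_dir / f"{eye_id}_mvd_truth.png")
        records.append(truth.record)
        truth_entries.append(
            {
                "eye_id": eye_id,
                "ppa_beta_area_mm2": truth.ppa_beta_area_mm2,
                "ppa_alpha_area_mm2": truth.ppa_alpha_area_mm2,
                "mvd_area_beta_mm2": truth.mvd_area_beta_mm2,
                "mvd_area_alpha_mm2": truth.mvd_area_alpha_mm2,
                "regions": [
                    {"zone": r.zone, "area_px": r.area_px}
                    for r in truth.regions
                ],
            }
        )

    manifest_path = write_manifest(records, out_dir / "manifest.csv")
    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "profile": profile.name,
                "seed": seed,
                "n_eyes": n,
                "package_version": __version__,
                "eyes": truth_entries,
            },
            indent=1,
            sort_keys=True,
        )
    )
    return {
        "out_dir": out_dir,
        "manifest": manifest_path,
        "truth": truth_path,
        "n_eyes": n,
    }
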