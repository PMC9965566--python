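"""End-to-end helpers tying the stages together.

These functions are the library form of the command-line pipeline:
simulate (or load) a cohort, run vessel exclusion and dropout detection on
every eye, collect per-eye metrics, and compute the cohort summary.  The
in-memory variant (:func:`simulate_and_analyze`) avoids the PNG round trip
and is what the acceptance machinery and most tests use; by round-trip
losslessness it is equivalent to analyzing files written by
:func:`mvdquant.synthetic.generate_cohort`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import records_to_frame, summarize_cohort
from .detection import MvDRegion, detect_mvd
from .io import EnFaceImage, RunConfig, ZoneSet, read_image, \
    read_manifest, read_zoneset
from .metrics import EyeMetrics, summarize_eye
from .synthetic import GeneratorProfile, load_profile, render_eye, \
    sample_covariates, sample_eye_truth
from .vessels import VesselMask, segment_large_vessels

__all__ = ["analyze_eye", "analyze_cohort_dir", "simulate_and_analyze"]


def analyze_eye(
    image: EnFaceImage,
    zones: ZoneSet,
    config: RunConfig | None = None,
) -> tuple[list[MvDRegion], EyeMetrics, VesselMask]:
    """Vessel exclusion, dropout detection and metrics for one eye."""
    config = config or RunConfig()
    vessels = segment_large_vessels(
        image,
        bright_threshold=config.vessel_bright_threshold,
        min_width_px=config.vessel_min_width_px,
        min_length_px=config.vessel_min_length_px,
    )
    if config.vessel_masking_scope == "zones":
        vessels = VesselMask.from_mask(vessels.mask & zones.ppa_union)
    regions = detect_mvd(
        image,
        zones,
        vessels=vessels,
        grey_threshold=config.grey_threshold,
        min_area_px=config.min_area_px,
        connectivity=config.connectivity,
        clip_before_label=config.clip_before_label,
    )
    metrics = summarize_eye(
        regions, zones, image, vessels,
        signal_threshold=config.signal_threshold,
    )
    return regions, metrics, vessels


def analyze_cohort_dir(
    cohort_dir: str | Path,
    config: RunConfig | None = None,
    summarize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict | None]:
    """Analyze a cohort previously written by ``generate_cohort``.

    Returns (per-eye metrics frame, manifest frame, cohort summary); the
    summary is ``None`` with ``summarize=False`` (e.g. for partial cohorts
    that cannot support the group statistics).
    """
    config = config or RunConfig()
    cohort_dir = Path(cohort_dir)
    records = read_manifest(cohort_dir / "manifest.csv")
    metrics_rows = []
    for rec in records:
        image = read_image(
            cohort_dir / f"{rec.eye_id}.png",
            pixel_pitch_um=config.pixel_pitch_um,
            eye_id=rec.eye_id,
        )
        zones = read_zoneset(
            cohort_dir / f"{rec.eye_id}_disc.png",
            cohort_dir / f"{rec.eye_id}_alpha.png",
            cohort_dir / f"{rec.eye_id}_beta.png",
            image,
        )
        _, metrics, _ = analyze_eye(image, zones, config)
        metrics_rows.append(vars(metrics))
    metrics_df = pd.DataFrame(metrics_rows)
    manifest_df = records_to_frame(records)
    summary = summarize_cohort(metrics_df, manifest_df) if summarize \
        else None
    return metrics_df, manifest_df, summary


def simulate_and_analyze(
    profiles: Sequence[GeneratorProfile | str],
    seed: int,
    config: RunConfig | None = None,
    n_eyes: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the given cohorts in memory and run the full pipeline.

    Each profile gets an independent child seed derived from ``seed`` so
    the composition is deterministic.  Returns (metrics frame, manifest
    frame, cohort summary) over the pooled eyes.
    """
    config = config or RunConfig()
    metrics_rows = []
    records = []
    seeds = np.random.SeedSequence(seed).spawn(len(profiles))
    for k, prof in enumerate(profiles):
        profile = load_profile(prof) if isinstance(prof, str) else prof
        rng = np.random.default_rng(seeds[k])
        n = profile.n_eyes if n_eyes is None else n_eyes[k]
        covariates = sample_covariates(profile, n, rng)
        for i in range(n):
            truth = sample_eye_truth(profile, rng, row=covariates.iloc[i])
            image, zones, _ = render_eye(truth, profile, rng)
            _, metrics, _ = analyze_eye(image, zones, config)
            metrics_rows.append(vars(metrics))
            records.append(truth.record)
    metrics_df = pd.DataFrame(metrics_rows)
    manifest_df = records_to_frame(records)
    summary = summarize_cohort(metrics_df, manifest_df)
    return metrics_df, manifest_df, summary
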