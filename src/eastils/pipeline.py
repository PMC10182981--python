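"""End-to-end driver: simulate → stains → detect → classify → score → stats.

The pipeline runs per-tile image analysis (stain recalibration with a
default-vector fallback, watershed detection, cell expansion, feature
extraction with 25/50 µm neighbourhood smoothing, classification), applies
the slide-level QC rule (exclude slides with >10% misclassified cells
against the reference labelling), and aggregates per-slide area summaries
into easTILs% scores.  Cohort-level statistics run on a cohort table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .classify import CellClassifier, classify_cells, qc_slide, train_classifier
from .features import SMOOTHING_RADII_UM, compute_features, smooth_features
from .scoring import (EASTILS_CUTOFF, STILS_CUTOFF, RegionAnnotation,
                      assign_cells_to_region, dichotomize, summarize_areas)
from .segmentation import CellObject, DetectionParams, detect_nuclei, expand_cells
from .stain import (ImageTile, StainEstimationError, StainProfile, deconvolve,
                    estimate_stain_vectors, rgb_to_od)
from .stats import (chi_square_2x2, delong_paired_test, km_logrank, logistic_model,
                    mann_whitney, pearson_r, pool_control_arms, roc_auc,
                    wilcoxon_signed_rank)
from .synthetic import SyntheticGroundTruth, TileSpec, generate_tile

__all__ = [
    "PipelineConfig",
    "analyze_tile",
    "match_cells_to_truth",
    "run_pipeline",
    "run_cohort_stats",
]


@dataclass
class PipelineConfig:
    """Configuration for a simulate-mode pipeline run."""

    n_tiles: int = 10
    n_training_tiles: int = 4
    tile_spec: TileSpec = field(default_factory=TileSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    area_basis: str = "cell"
    eastils_cutoff: float = EASTILS_CUTOFF
    stils_cutoff: float = STILS_CUTOFF
    classifier_width: int = 64
    seed: int = 0
    out_dir: str | Path | None = None


def analyze_tile(
    tile: ImageTile,
    params: DetectionParams = DetectionParams(),
) -> tuple[list[CellObject], StainProfile]:
    """Stain recalibration + detection + expansion + features for one tile.

    Falls back to the conventional H&E stain vectors when per-tile
    estimation fails (e.g. a near-blank tile).
    """
    try:
        profile = estimate_stain_vectors(tile)
    except StainEstimationError:
        profile = StainProfile()
    od = rgb_to_od(tile, profile.background)
    stains = deconvolve(od, profile)
    hema = stains.channel("hematoxylin")
    eosin = stains.channel("eosin")
    cells = detect_nuclei(hema, params)
    cells = expand_cells(cells, params)
    if cells:
        cells = compute_features(cells, hema, eosin)
        for radius in SMOOTHING_RADII_UM:
            cells = smooth_features(cells, radius)
    return cells, profile


def match_cells_to_truth(
    cells: list[CellObject],
    truth: SyntheticGroundTruth,
    max_distance_um: float = 5.0,
) -> list[str | None]:
    """Greedy nearest-center matching of detections to planted cells.

    Returns one reference label per detection (None = no planted cell within
    ``max_distance_um``, i.e. a false positive).
    """
    if not truth.cells:
        return [None] * len(cells)
    centers = np.array([c.center_um for c in truth.cells])
    labels = [c.class_label for c in truth.cells]
    taken = np.zeros(len(truth.cells), dtype=bool)
    out: list[str | None] = []
    for cell in cells:
        d = np.linalg.norm(centers - np.asarray(cell.centroid_um), axis=1)
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] <= max_distance_um:
            taken[j] = True
            out.append(labels[j])
        else:
            out.append(None)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate-mode end-to-end run; deterministic given ``config.seed``.

    Trains the cell classifier on the first ``n_training_tiles`` tiles
    (reference labels from the planted ground truth), evaluates the rest,
    applies the slide QC rule, and returns per-slide area summaries plus a
    manifest.  Artifacts are written under ``config.out_dir`` when set.
    """
    rng_seeds = [config.seed + 1000 * i for i in range(config.n_tiles)]
    tiles = []
    for i, s in enumerate(rng_seeds):
        spec = dataclasses.replace(config.tile_spec, seed=s)
        tile, truth = generate_tile(spec)
        tiles.append((f"tile_{i:03d}", tile, truth))

    # per-tile image analysis + reference labels
    analyzed = []
    for name, tile, truth in tiles:
        cells, profile = analyze_tile(tile, config.detection)
        refs = match_cells_to_truth(cells, truth)
        analyzed.append((name, tile, truth, cells, profile, refs))

    train_cells, train_labels = [], []
    for name, _, _, cells, _, refs in analyzed[: config.n_training_tiles]:
        for c, r in zip(cells, refs):
            if r is not None:
                train_cells.append(c)
                train_labels.append(r)
    model = train_classifier(train_cells, train_labels,
                             hidden_width=config.classifier_width, random_state=config.seed)

    summaries, manifest_slides = [], []
    for name, tile, truth, cells, profile, refs in analyzed:
        classify_cells(model, cells)
        matched = [(c, r) for c, r in zip(cells, refs) if r is not None]
        qc = qc_slide([c.class_label for c, _ in matched], [r for _, r in matched]) if matched else None
        region = RegionAnnotation([truth.region_polygon])
        in_region = assign_cells_to_region(cells, region)
        summary = summarize_areas(in_region, region, area_basis=config.area_basis)
        eastils = summary.eastils_percent
        row = {
            "slide": name,
            "n_cells": len(cells),
            "region_area_mm2": summary.region_area_mm2,
            "lymphocyte_area_mm2": summary.lymphocyte_area_mm2,
            "tumor_area_mm2": summary.tumor_area_mm2,
            "stromal_area_mm2": summary.stromal_area_mm2,
            "eastils_percent": eastils,
            "eastils_category": dichotomize(eastils, config.eastils_cutoff).label
            if eastils is not None else None,
            "true_eastils_percent": truth.eastils_percent,
            "qc_pass": bool(qc.passed) if qc else False,
            "qc_fraction_misclassified": qc.fraction if qc else None,
        }
        summaries.append(row)
        manifest_slides.append({"slide": name, "qc_pass": row["qc_pass"], "n_cells": len(cells)})

    summary_df = pd.DataFrame(summaries)
    manifest = {
        "seed": config.seed,
        "n_tiles": config.n_tiles,
        "excluded_slides": [s["slide"] for s in manifest_slides if not s["qc_pass"]],
        "slides": manifest_slides,
        "training_accuracy": model.training_accuracy_,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(out / "area_summaries.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        model.save(out / "classifier.json")
        for name, tile, truth, cells, profile, _ in analyzed:
            (out / f"{name}.stains.json").write_text(profile.to_json())
            (out / f"{name}.cells.geojson").write_text(json.dumps(eio.cells_to_geojson(cells)))
    return {"summaries": summary_df, "manifest": manifest, "model": model}


def run_cohort_stats(
    cohort: pd.DataFrame,
    eastils_cutoff: float = EASTILS_CUTOFF,
    stils_cutoff: float = STILS_CUTOFF,
) -> dict:
    """The full cohort analysis battery on a cohort table.

    Control arms are pooled against bevacizumab before arm-level analyses.
    Returns a dict of :class:`~eastils.stats.TestResult` objects.
    """
    df = pool_control_arms(cohort)
    pcr = df["pcr"].astype(bool)
    e = df["eastils_percent"].to_numpy()
    s = df["stils_percent"].to_numpy()
    out: dict = {}
    out["mw_eastils_by_pcr"] = mann_whitney(e[pcr], e[~pcr])
    out["mw_stils_by_pcr"] = mann_whitney(s[pcr], s[~pcr])
    out["pearson_eastils_stils"] = pearson_r(e, s)

    high = e > eastils_cutoff
    table = np.array(
        [[int((pcr & high).sum()), int((~pcr & high).sum())],
         [int((pcr & ~high).sum()), int((~pcr & ~high).sum())]]
    )
    out["chi2_pcr_by_eastils_high"] = chi_square_2x2(table)
    out["roc_eastils"] = roc_auc(e, pcr)
    out["roc_stils"] = roc_auc(s, pcr)
    out["delong_eastils_vs_stils"] = delong_paired_test(e, s, pcr)
    out["km_efs_by_eastils"] = km_logrank(
        df["efs_months"], df["efs_event"], np.where(high, "high", "low")
    )
    out["km_efs_by_arm"] = km_logrank(df["efs_months"], df["efs_event"], df["arm"])

    paired = df.dropna(subset=["post_eastils_percent"])
    if len(paired) >= 5:
        out["wilcoxon_pre_post_eastils"] = wilcoxon_signed_rank(
            paired["eastils_percent"], paired["post_eastils_percent"]
        )
    df_lr = df.assign(eastils_high=high.astype(int))
    out["logistic_continuous"] = logistic_model(
        df_lr, "pcr ~ er_positive + arm + disease_type + eastils_percent"
    )
    out["logistic_categorical"] = logistic_model(
        df_lr, "pcr ~ er_positive + arm + disease_type + eastils_high"
    )
    out["logistic_interaction"] = logistic_model(df_lr, "pcr ~ eastils_percent * arm")
    return out
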