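"""Marker-based cell classification, expression binning, and the full pipeline.

A cell is called a neuron on strong KCC2 mRNA expression (>= 10 KCC2 speckles)
and non-neuronal on zero KCC2 speckles; cells with 1-9 speckles are left
unclassified and excluded from neuron/non-neuron denominators.  NKCC1 speckle
counts are binned as none (0), low (1-4), moderate (5-10), high (11-15) and
very_high (>= 16); the bins partition the non-negative integers.

``run_rnascope_pipeline`` composes the whole image workflow: nucleus
segmentation -> radial expansion -> negative-control threshold calibration ->
spot detection -> centroid assignment -> classification -> binning ->
summaries, deterministically for a fixed configuration.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cellseg, speckle
from .synthgen import ImageBundle

__all__ = [
    "PipelineConfig",
    "EXPRESSION_BINS",
    "classify_cells",
    "bin_expression",
    "summarize",
    "run_rnascope_pipeline",
]

logger = logging.getLogger(__name__)

CLASSES = ("neuron", "non_neuronal", "unclassified")
#: (name, lowest count, highest count) — a partition of the non-negative integers
EXPRESSION_BINS = (
    ("none", 0, 0),
    ("low", 1, 4),
    ("moderate", 5, 10),
    ("high", 11, 15),
    ("very_high", 16, None),
)


@dataclass
class PipelineConfig:
    """All tunables of the image pipeline, with assay-defined defaults."""

    expansion_radius_px: float = 10.0
    min_spot_area_px: int = 8
    target_background_rate: float = 0.1  # speckles/cell on the negative control
    neuron_min_kcc2: int = 10
    nonneuronal_max_kcc2: int = 0
    kcc2_channel: str = "KCC2"
    nkcc1_channel: str = "NKCC1"
    negctrl_channel: str = "NEGCTRL"
    smoothing_sigma: float = 2.0
    min_object_area_px: int = 50
    split_touching: bool = True
    intensity_threshold: float | None = None  # None -> calibrate from negctrl
    seed: int = 0


def classify_cells(records: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Assign neuron / non_neuronal / unclassified from KCC2 speckle counts."""
    config = config or PipelineConfig()
    counts = records["kcc2_count"].to_numpy()
    if np.any(counts < 0):
        raise ValueError("speckle counts must be >= 0")
    out = records.copy()
    out["cell_class"] = np.select(
        [counts >= config.neuron_min_kcc2, counts <= config.nonneuronal_max_kcc2],
        ["neuron", "non_neuronal"],
        default="unclassified",
    )
    return out


def bin_expression(records: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Bin NKCC1 speckle counts into the none/low/moderate/high/very_high scale."""
    counts = records["nkcc1_count"].to_numpy()
    if np.any(counts < 0):
        raise ValueError("speckle counts must be >= 0")
    out = records.copy()
    conditions, names = [], []
    for name, lo, hi in EXPRESSION_BINS:
        cond = counts >= lo if hi is None else (counts >= lo) & (counts <= hi)
        conditions.append(cond)
        names.append(name)
    out["expression_bin"] = np.select(conditions, names, default="none")
    return out


def summarize(
    records: pd.DataFrame, group_by: Sequence[str] = ("region", "cell_class")
) -> pd.DataFrame:
    """Per-group cohort statistics of NKCC1 speckle counts.

    For each group: n cells, fraction of cells with at least one NKCC1
    speckle, fraction in the very_high bin, the full bin histogram, and
    mean/median counts.  Percentages elsewhere in reports are rounded to the
    nearest integer; fractions here are kept exact.
    """
    group_by = [g for g in group_by if g in records.columns]
    if records.empty:
        warnings.warn("no cell records to summarize", stacklevel=2)
        cols = (
            list(group_by)
            + ["n_cells", "frac_nkcc1_pos", "frac_very_high", "mean_nkcc1", "median_nkcc1"]
            + [f"bin_{name}" for name, _, _ in EXPRESSION_BINS]
        )
        return pd.DataFrame(columns=cols)
    rows = []
    grouped = records.groupby(list(group_by), sort=True) if group_by else [((), records)]
    for key, grp in grouped:
        if grp.empty:  # pragma: no cover - pandas drops empty groups
            warnings.warn(f"empty group {key} omitted", stacklevel=2)
            continue
        key = key if isinstance(key, tuple) else (key,)
        counts = grp["nkcc1_count"]
        row = dict(zip(group_by, key))
        row["n_cells"] = len(grp)
        row["frac_nkcc1_pos"] = float((counts >= 1).mean())
        row["frac_very_high"] = float((counts >= 16).mean())
        row["mean_nkcc1"] = float(counts.mean())
        row["median_nkcc1"] = float(counts.median())
        for name, lo, hi in EXPRESSION_BINS:
            in_bin = counts >= lo if hi is None else (counts >= lo) & (counts <= hi)
            row[f"bin_{name}"] = int(in_bin.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def _process_bundle(
    bundle: ImageBundle, config: PipelineConfig
) -> tuple[cellseg.LabelMask, cellseg.LabelMask]:
    t0 = time.perf_counter()
    nuclei = cellseg.segment_nuclei(
        bundle.channels["DAPI"],
        smoothing_sigma=config.smoothing_sigma,
        min_object_area_px=config.min_object_area_px,
        split_touching=config.split_touching,
        pixel_size_um=bundle.pixel_size_um,
    )
    expanded = cellseg.expand_cells(nuclei, config.expansion_radius_px)
    logger.info(
        "segmented %s: %d cells in %.2fs",
        bundle.name,
        nuclei.n_objects,
        time.perf_counter() - t0,
    )
    return nuclei, expanded


def run_rnascope_pipeline(
    bundles: Sequence[ImageBundle],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, speckle.CalibrationResult | None]:
    """Run the full per-cell speckle quantification on one or more scenes.

    Returns (cell record table, summary table, calibration report).  The
    record table has one row per segmented cell with its region tag (the
    bundle name), per-channel speckle counts, class and expression bin.
    Calibration pools the negative-control channels of all bundles; if a
    fixed ``config.intensity_threshold`` is given, calibration is skipped.
    """
    config = config or PipelineConfig()
    if not bundles:
        raise ValueError("no image bundles given")
    masks = []
    for bundle in bundles:
        if "DAPI" not in bundle.channels:
            raise ValueError(f"bundle {bundle.name} lacks a DAPI channel")
        masks.append(_process_bundle(bundle, config))

    calibration: speckle.CalibrationResult | None = None
    total_cells = sum(expanded.n_objects for _, expanded in masks)
    if total_cells == 0:
        threshold = np.inf  # nothing to quantify; skip calibration and detection
    elif config.intensity_threshold is not None:
        threshold = config.intensity_threshold
    else:
        neg_images, neg_masks = [], []
        for bundle, (_, expanded) in zip(bundles, masks):
            if config.negctrl_channel in bundle.channels:
                neg_images.append(bundle.channels[config.negctrl_channel])
                neg_masks.append(expanded)
        if not neg_images:
            raise ValueError(
                "no negative-control channel found and no fixed threshold given"
            )
        calibration = speckle.calibrate_threshold(
            neg_images,
            neg_masks,
            target_rate=config.target_background_rate,
            min_spot_area_px=config.min_spot_area_px,
        )
        threshold = calibration.threshold
        logger.info(
            "calibrated threshold %.1f (%.3f speckles/cell over %d cells)",
            threshold,
            calibration.achieved_rate,
            calibration.n_cells,
        )

    records = []
    all_spots = []
    for bundle, (_, expanded) in zip(bundles, masks):
        probe_channels = [
            ch
            for ch in bundle.channels
            if ch not in ("DAPI", config.negctrl_channel)
        ]
        per_cell: dict[str, pd.Series] = {}
        for ch in probe_channels:
            spots = speckle.detect_spots(
                bundle.channels[ch],
                threshold,
                min_spot_area_px=config.min_spot_area_px,
                channel_name=ch,
            )
            spots = speckle.assign_spots_to_cells(spots, expanded)
            all_spots.extend(spots)
            per_cell[ch] = speckle.count_spots_per_cell(spots, expanded)
        for cell_id in range(1, expanded.n_objects + 1):
            records.append(
                {
                    "region": bundle.name,
                    "cell_id": f"{bundle.name}:{cell_id}",
                    "label": cell_id,
                    "kcc2_count": int(
                        per_cell.get(config.kcc2_channel, pd.Series(dtype=int)).get(
                            cell_id, 0
                        )
                    ),
                    "nkcc1_count": int(
                        per_cell.get(config.nkcc1_channel, pd.Series(dtype=int)).get(
                            cell_id, 0
                        )
                    ),
                }
            )
    record_table = pd.DataFrame(
        records, columns=["region", "cell_id", "label", "kcc2_count", "nkcc1_count"]
    )
    if not record_table.empty:
        record_table = classify_cells(record_table, config)
        record_table = bin_expression(record_table, config)
    else:
        record_table["cell_class"] = pd.Series(dtype=object)
        record_table["expression_bin"] = pd.Series(dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = summarize(record_table)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        record_table.to_csv(out_dir / "cell_records.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        speckle.spots_to_frame(all_spots).to_csv(out_dir / "spots.csv", index=False)
        if calibration is not None:
            calibration.to_json(out_dir / "calibration.json")
    return record_table, summary, calibration
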