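"""Stress-granule detection and per-cell quantification.

Detects granules in a fluorescence channel with Laplacian-of-Gaussian blob
detection followed by half-maximum region growing, assigns each granule to a
cell via the provided label mask, and summarizes per-cell SG burden (granule
count, area fraction, SG-positive call) across conditions and stress durations.
Cell masks are inputs, not computed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.feature import blob_log
from skimage.measure import label as cc_label

from .synthetic import GranuleField

logger = logging.getLogger(__name__)


class ConsistencyError(ValueError):
    """A granule refers to a cell id absent from the mask."""


@dataclass(frozen=True)
class DetectionParams:
    """Settings of the blob detector and post-filters.

    ``min_peak`` is the minimal background-subtracted peak intensity for a
    detection to be kept (the intensity threshold); ``log_threshold`` is the
    scale-normalized LoG response floor passed to the blob detector.
    """

    min_sigma: float = 1.0
    max_sigma: float = 6.0
    num_sigma: int = 11
    log_threshold: float = 8.0
    min_peak: float = 25.0
    min_area: int = 3


@dataclass(frozen=True)
class PositiveRule:
    """A cell is SG-positive iff it has >= min_granules granules covering
    >= min_fraction of its area."""

    min_granules: int = 2
    min_fraction: float = 0.001


@dataclass(frozen=True)
class Granule:
    cell_id: int
    centroid: tuple[float, float]
    area: int
    mean_intensity: float
    peak_intensity: float


@dataclass(frozen=True)
class CellSGStats:
    cell_id: int
    n_granules: int
    area_fraction: float
    cell_px: int = 0
    sg_positive: bool = False


def _grow_region(image: np.ndarray, peak: tuple[int, int], level: float,
                 sigma: float) -> np.ndarray | None:
    """Boolean mask of the half-max region connected to the peak (local window)."""
    h, w = image.shape
    r = int(math.ceil(3.0 * sigma)) + 2
    r0, r1 = max(0, peak[0] - r), min(h, peak[0] + r + 1)
    c0, c1 = max(0, peak[1] - r), min(w, peak[1] + r + 1)
    window = image[r0:r1, c0:c1] >= level
    labels = cc_label(window, connectivity=2)
    lab = labels[peak[0] - r0, peak[1] - c0]
    if lab == 0:
        return None
    out = np.zeros((h, w), dtype=bool)
    out[r0:r1, c0:c1] = labels == lab
    return out


def detect_granules(field: GranuleField, params: DetectionParams = DetectionParams()
                    ) -> list[Granule]:
    """Detect granules on the field's image and assign them to cells.

    Granules whose intensity-weighted centroid falls on background (mask 0)
    are discarded; the result is sorted by (cell_id, centroid).
    """
    mask = field.cell_mask
    if mask.max() == 0:
        raise ValueError("no cells: label mask is empty")
    image = np.asarray(field.image, dtype=float)
    if not np.any(image):
        return []
    bg = float(np.median(image[mask > 0]))
    sub = np.clip(image - bg, 0.0, None)
    blobs = blob_log(sub, min_sigma=params.min_sigma, max_sigma=params.max_sigma,
                     num_sigma=params.num_sigma, threshold=params.log_threshold)
    granules: list[Granule] = []
    seen_peaks: set[tuple[int, int]] = set()
    h, w = image.shape
    for row, col, sigma in blobs:
        r, c = int(round(row)), int(round(col))
        # refine to the local maximum in a 3x3 neighbourhood
        r0, r1 = max(0, r - 1), min(h, r + 2)
        c0, c1 = max(0, c - 1), min(w, c + 2)
        local = image[r0:r1, c0:c1]
        dr, dc = np.unravel_index(np.argmax(local), local.shape)
        peak = (r0 + dr, c0 + dc)
        if peak in seen_peaks:
            continue
        seen_peaks.add(peak)
        peak_val = image[peak]
        net = peak_val - bg
        if net < params.min_peak:
            continue
        region = _grow_region(image, peak, bg + net / 2.0, sigma)
        if region is None:
            continue
        weights = np.clip(image[region] - bg, 0.0, None)
        coords = np.argwhere(region)
        if weights.sum() > 0:
            centroid = tuple((coords * weights[:, None]).sum(axis=0) / weights.sum())
        else:
            centroid = tuple(coords.mean(axis=0))
        # the peak pixel undersamples the true amplitude when the spot centre
        # falls between pixels; correct with the sub-pixel offset and the
        # detected scale before measuring the half-maximum area
        d2 = (peak[0] - centroid[0]) ** 2 + (peak[1] - centroid[1]) ** 2
        amp_est = net * math.exp(min(d2 / (2.0 * sigma ** 2), 1.0))
        region = _grow_region(image, peak, bg + amp_est / 2.0, sigma)
        if region is None:
            continue
        area = int(region.sum())
        if area < params.min_area:
            continue
        cell_id = int(mask[int(round(centroid[0])), int(round(centroid[1]))])
        if cell_id == 0:
            continue
        granules.append(Granule(cell_id=cell_id, centroid=(float(centroid[0]), float(centroid[1])),
                                area=area, mean_intensity=float(image[region].mean()),
                                peak_intensity=float(peak_val)))
    granules.sort(key=lambda g: (g.cell_id, g.centroid))
    return granules


def _border_labels(mask: np.ndarray) -> set[int]:
    edges = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    return set(np.unique(edges)) - {0}


def area_fraction_per_cell(granules: list[Granule], field: GranuleField,
                           exclude_border: bool = True) -> list[CellSGStats]:
    """Per-cell SG stats: granule pixels / cell pixels, zero for granule-free cells.

    Cells touching the image border are excluded by default (their visible area
    is partial, biasing the fraction).
    """
    mask = field.cell_mask
    labels, counts = np.unique(mask[mask > 0], return_counts=True)
    cell_px = dict(zip(labels.tolist(), counts.tolist()))
    excluded = _border_labels(mask) if exclude_border else set()
    per_cell: dict[int, dict] = {
        int(lab): {"n": 0, "area": 0} for lab in labels if lab not in excluded
    }
    for g in granules:
        if g.cell_id not in cell_px:
            raise ConsistencyError(f"granule references unknown cell id {g.cell_id}")
        if g.cell_id in excluded:
            continue
        per_cell[g.cell_id]["n"] += 1
        per_cell[g.cell_id]["area"] += g.area
    return [
        CellSGStats(cell_id=cid, n_granules=d["n"],
                    area_fraction=d["area"] / cell_px[cid], cell_px=cell_px[cid])
        for cid, d in sorted(per_cell.items())
    ]


def classify_sg_positive(stats: list[CellSGStats] | CellSGStats,
                         rule: PositiveRule = PositiveRule()
                         ) -> list[CellSGStats] | CellSGStats:
    """Apply the SG-positive decision rule (granule count AND area fraction)."""
    def one(s: CellSGStats) -> CellSGStats:
        positive = s.n_granules >= rule.min_granules and s.area_fraction >= rule.min_fraction
        return replace(s, sg_positive=positive)
    if isinstance(stats, CellSGStats):
        return one(stats)
    return [one(s) for s in stats]


def quantify_field(field: GranuleField, params: DetectionParams = DetectionParams(),
                   rule: PositiveRule = PositiveRule(), exclude_border: bool = True
                   ) -> pd.DataFrame:
    """Detect + per-cell stats + positivity for one field, as a tidy frame."""
    granules = detect_granules(field, params)
    stats = classify_sg_positive(area_fraction_per_cell(granules, field, exclude_border), rule)
    rows = [
        {**field.metadata, "cell_id": s.cell_id, "n_granules": s.n_granules,
         "area_fraction": s.area_fraction, "cell_px": s.cell_px, "sg_positive": s.sg_positive}
        for s in stats
    ]
    return pd.DataFrame(rows)


def summarize_conditions(per_cell: pd.DataFrame, min_cells_warn: int = 100) -> pd.DataFrame:
    """Population summary per (condition, time).

    Reports %SG-positive cells, the per-cell mean area fraction (and, when a
    ``cell_px`` column is present, the pooled variant: total granule pixels over
    total cell pixels), SDs across fields, and cell counts. Warns — does not
    fail — when a group has fewer than ``min_cells_warn`` cells; empty groups
    are dropped with a warning.
    """
    required = {"condition", "time", "cell_id", "n_granules", "area_fraction", "sg_positive"}
    missing = required - set(per_cell.columns)
    if missing:
        raise ValueError(f"per-cell table missing columns: {sorted(missing)}")
    rows = []
    for (cond, t), grp in per_cell.groupby(["condition", "time"], sort=True):
        if grp.empty:
            logger.warning("empty group (%s, %s) excluded", cond, t)
            continue
        n_cells = len(grp)
        if n_cells < min_cells_warn:
            logger.warning("group (%s, %s) has only %d cells (< %d)", cond, t, n_cells, min_cells_warn)
        pct = 100.0 * grp["sg_positive"].mean()
        if "field" in grp.columns and grp["field"].nunique() > 1:
            by_field = grp.groupby("field")
            sd_pct = float((100.0 * by_field["sg_positive"].mean()).std(ddof=1))
            sd_frac = float(by_field["area_fraction"].mean().std(ddof=1))
            n_fields = int(grp["field"].nunique())
        else:
            sd_pct, sd_frac, n_fields = float("nan"), float("nan"), 1
        if "cell_px" in grp.columns and grp["cell_px"].sum() > 0:
            pooled = float((grp["area_fraction"] * grp["cell_px"]).sum() / grp["cell_px"].sum())
        else:
            pooled = float("nan")
        rows.append({
            "condition": cond, "time": t,
            "pct_sg_positive": pct,
            "mean_area_fraction": float(grp["area_fraction"].mean()),
            "pooled_area_fraction": pooled,
            "mean_area_fraction_positive": float(
                grp.loc[grp["sg_positive"], "area_fraction"].mean()) if grp["sg_positive"].any() else 0.0,
            "sd_pct_across_fields": sd_pct,
            "sd_area_fraction_across_fields": sd_frac,
            "n_cells": n_cells, "n_fields": n_fields,
        })
    return pd.DataFrame(rows)
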