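"""End-to-end orchestration: compensation -> detection -> segmentation ->
lineage -> nanoparticle quantification -> cell-level table.

Every stage consumes only measured data (never simulator ground truth);
each dropped candidate is accounted for so that
``n_candidates == n_cells_kept + sum(drops.values())`` holds per run.
Processing is deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from skimage.transform import downscale_local_mean

from .cell_detect import detect_cells
from .compensation import CompensationModel, unmix
from .config import MARKERS, RunConfig
from .datatypes import CellRecord, FieldOfView
from .errors import InputError
from .io import list_fovs, read_fov, records_to_frame
from .lineage import call_all_positivity, assign_lineage
from .pnp_quant import quantify_cell
from .segment import SegmentationModel, extract_crop, filter_by_area, segment_cell

logger = logging.getLogger(__name__)


@dataclass
class RunStats:
    """Per-stage accounting of candidates and drops."""

    n_fovs: int = 0
    n_candidates: int = 0
    n_cells: int = 0
    drops: Dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.drops[reason] = self.drops.get(reason, 0) + 1

    def log_line(self) -> str:
        return json.dumps(
            {"n_fovs": self.n_fovs, "n_candidates": self.n_candidates,
             "n_cells": self.n_cells, "drops": self.drops}
        )


def _circle_mask(shape_hw: Tuple[int, int], center_xy, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape_hw[0], : shape_hw[1]]
    return (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius**2


def _paste_crop_mask(
    crop_mask: np.ndarray, center_xy, shape_hw: Tuple[int, int]
) -> np.ndarray:
    """Place an 82x82 crop mask back into full (downscaled) frame coords."""
    out = np.zeros(shape_hw, dtype=bool)
    ch, cw = crop_mask.shape
    x0 = int(round(center_xy[0])) - cw // 2
    y0 = int(round(center_xy[1])) - ch // 2
    sy0, sy1 = max(-y0, 0), min(shape_hw[0] - y0, ch)
    sx0, sx1 = max(-x0, 0), min(shape_hw[1] - x0, cw)
    if sy0 < sy1 and sx0 < sx1:
        out[y0 + sy0 : y0 + sy1, x0 + sx0 : x0 + sx1] = crop_mask[sy0:sy1, sx0:sx1]
    return out


def run_fov(
    fov: FieldOfView,
    comp: CompensationModel,
    config: RunConfig,
    seg_model: Optional[SegmentationModel] = None,
    sample_id: str = "",
    fov_id: str = "",
    stats: Optional[RunStats] = None,
) -> List[CellRecord]:
    """Process one field of view into cell records.

    Without ``seg_model`` the Hough circle itself serves as the cell
    contour (lower-fidelity fallback, useful for pipeline runs that do not
    need trained weights).
    """
    stats = stats if stats is not None else RunStats()
    stats.n_fovs += 1
    if fov.fluorescence is None:
        raise InputError(f"{fov_id}: field of view has no fluorescence data")
    abundances = unmix(fov, comp)  # (5, H, W)
    candidates, binary, cd45_ds = detect_cells(abundances[0], config.detect)
    stats.n_candidates += len(candidates)
    if not candidates:
        return []
    ds = config.detect.downscale
    pitch_ds = fov.pixel_pitch_um * ds
    abund_ds = np.stack(
        [downscale_local_mean(a, (ds, ds)) for a in abundances]
    )
    shape_ds = cd45_ds.shape

    # segmentation
    kept: List[Tuple] = []
    for cand in candidates:
        if seg_model is not None:
            crop = extract_crop(cd45_ds, cand.center_ds, config.segment.crop_px)
            crop_mask = segment_cell(crop, seg_model, config.segment.threshold)
            if crop_mask is None:
                stats.drop("segmentation_empty")
                logger.info("%s/%s: candidate at %s dropped (empty segmentation)",
                            sample_id, fov_id, cand.center_ds)
                continue
            mask = _paste_crop_mask(crop_mask, cand.center_ds, shape_ds)
            if not mask.any():
                stats.drop("segmentation_empty")
                continue
        else:
            mask = _circle_mask(shape_ds, cand.center_ds, cand.radius_ds)
        if not filter_by_area(mask, pitch_ds, config.segment):
            stats.drop("area_filter")
            continue
        kept.append((cand, mask))

    all_masks = np.zeros(shape_ds, dtype=bool)
    for _, m in kept:
        all_masks |= m

    records: List[CellRecord] = []
    for idx, (cand, mask) in enumerate(kept):
        others = all_masks & ~mask
        calls = call_all_positivity(abund_ds, mask, others, config.lineage)
        lineage = assign_lineage(calls, config.lineage)
        detections: List = []
        count = 0
        if fov.darkfield is not None:
            mask_full = mask.repeat(ds, axis=0).repeat(ds, axis=1)
            h, w = fov.darkfield.shape[1:3]
            mask_full = mask_full[:h, :w]
            z_step = config.optics.z_step_um
            if fov.z_positions_um is not None and len(fov.z_positions_um) > 1:
                z_step = float(fov.z_positions_um[1] - fov.z_positions_um[0])
            detections, count = quantify_cell(
                fov.darkfield, mask_full, z_step, fov.pixel_pitch_um, config.pnp
            )
        records.append(
            CellRecord(
                sample_id=sample_id,
                fov_id=fov_id,
                cell_id=idx,
                center_ds=cand.center_ds,
                radius_ds=cand.radius_ds,
                mask_ds=mask,
                area_um2=float(mask.sum()) * pitch_ds**2,
                calls=calls,
                lineage=lineage,
                detections=detections,
                pnp_count=count,
            )
        )
    stats.n_cells += len(records)
    return records


def run_sample(
    sample_dir: str,
    comp: CompensationModel,
    config: RunConfig,
    seg_model: Optional[SegmentationModel] = None,
    sample_id: Optional[str] = None,
) -> Tuple[pd.DataFrame, RunStats]:
    """Process every field of view of a sample directory.

    Malformed FOVs are skipped with a logged reason; an empty result is
    returned as an empty table (the CLI exits nonzero on it).
    """
    import os

    if sample_id is None:
        sample_id = os.path.basename(os.path.normpath(sample_dir))
    fov_dirs = list_fovs(sample_dir)
    stats = RunStats()
    records: List[CellRecord] = []
    for fd in fov_dirs:
        t0 = time.time()
        fov_id = os.path.basename(fd)
        try:
            fov = read_fov(fd)
        except (InputError, OSError, ValueError) as exc:
            logger.warning("%s: skipping malformed FOV (%s)", fd, exc)
            stats.drop("malformed_fov")
            continue
        records.extend(
            run_fov(fov, comp, config, seg_model, sample_id, fov_id, stats)
        )
        logger.info(
            json.dumps({"fov": fov_id, "elapsed_s": round(time.time() - t0, 3),
                        "cells_total": len(records)})
        )
    logger.info("%s: %s", sample_id, stats.log_line())
    if not records:
        logger.warning("%s: zero cells found", sample_id)
        return pd.DataFrame(), stats
    return records_to_frame(records), stats


def validate_lineage_against_reference(
    observed: pd.Series, reference: pd.Series
) -> pd.DataFrame:
    """Side-by-side class percentages and absolute differences.

    Both inputs are percentage tables indexed by class label (as produced
    by :func:`pnpcyto.lineage.lineage_fractions`).  Raises
    :class:`InputError` when the class labels do not overlap at all.
    """
    observed = pd.Series(observed, dtype=float)
    reference = pd.Series(reference, dtype=float)
    common = observed.index.intersection(reference.index)
    if len(common) == 0:
        raise InputError(
            "no shared class labels: "
            f"observed={list(observed.index)}, reference={list(reference.index)}"
        )
    missing = reference.index.difference(observed.index).tolist()
    extra = observed.index.difference(reference.index).tolist()
    if missing or extra:
        logger.warning("unmatched classes: missing=%s extra=%s", missing, extra)
    df = pd.DataFrame(
        {"observed_pct": observed[common], "reference_pct": reference[common]}
    )
    df["abs_diff_pct"] = (df["observed_pct"] - df["reference_pct"]).abs()
    return df
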