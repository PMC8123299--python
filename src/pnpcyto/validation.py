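"""Canonical technical-validation experiments on simulated data.

These routines reproduce, at desk scale, the platform's validation
protocol: segmentation quality on held-out annotated crops, nanoparticle
counting accuracy on 98 per-cell darkfield stacks (49 sampled at random
binding levels, 49 at medium/high binding), end-to-end recovery of the
Poisson mean lambda, and detection precision/recall with full event
accounting.  Both the test suite and ``scripts/acceptance.py`` call them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .compensation import CompensationModel, default_mixing_matrix
from .config import OpticsConfig, RunConfig
from .pipeline import RunStats, run_fov
from .pnp_quant import quantify_cell
from .sim import make_training_crops, render_cell_stack, render_fov
from .sim.fov import random_cells


@dataclass
class CountingResult:
    true_counts: np.ndarray
    auto_counts: np.ndarray

    @property
    def r_squared(self) -> float:
        r = np.corrcoef(self.true_counts, self.auto_counts)[0, 1]
        return float(r**2)

    @property
    def mean_absolute_error(self) -> float:
        return float(np.abs(self.auto_counts - self.true_counts).mean())

    @property
    def bias(self) -> float:
        """Relative bias of the total automated count vs ground truth."""
        total = self.true_counts.sum()
        if total == 0:
            return float(self.auto_counts.sum())
        return float((self.auto_counts.sum() - total) / total)


def segmentation_dice(
    n_crops: int = 400,
    seed: int = 42,
    epochs: Optional[int] = None,
    config: Optional[RunConfig] = None,
) -> Tuple[float, object]:
    """Train the contour network on simulated annotated crops; test Dice.

    Follows the training protocol: one fixed 50/25/25 split, Dice loss,
    Adam, 150 epochs, no early stopping, best-validation checkpoint,
    outputs thresholded at 0.5.  Returns (test Dice, model).
    """
    from .segment import evaluate_test_dice, train_unet

    config = config or RunConfig()
    images, masks = make_training_crops(n_crops, seed=seed,
                                        crop_px=config.segment.crop_px)
    model = train_unet(images, masks, config.segment, seed=seed, epochs=epochs)
    dice = evaluate_test_dice(model, images, masks, config.segment, seed=seed)
    return dice, model


def counting_accuracy(
    seed: int = 0,
    n_random: int = 49,
    n_high: int = 49,
    random_lambda: float = 4.0,
    high_range: Tuple[int, int] = (10, 30),
    optics: Optional[OpticsConfig] = None,
    config: Optional[RunConfig] = None,
) -> CountingResult:
    """Automated vs true counts on 98 single-cell darkfield stacks.

    Half the cells carry Poisson(``random_lambda``) particles (a randomly
    sampled binding profile, mostly low); half are drawn uniformly from
    ``high_range`` (medium/high binders), mirroring the validation design
    that oversamples the rare high-binding cells.  Cells are quantified
    inside their true contour.
    """
    config = config or RunConfig()
    optics = optics or replace(config.optics, z_slices=40)
    mixing = CompensationModel.from_matrix(default_mixing_matrix())
    rng = np.random.default_rng(seed)
    loads = np.concatenate(
        [
            rng.poisson(random_lambda, size=n_random),
            rng.integers(high_range[0], high_range[1] + 1, size=n_high),
        ]
    )
    true, auto = [], []
    for i, n in enumerate(loads):
        radius = float(rng.uniform(3.3, 4.5))
        cell, fov = render_cell_stack(
            int(n), optics, mixing, seed=int(rng.integers(2**31)), radius_um=radius
        )
        mask = cell.contour_mask(fov.darkfield.shape[1:3], optics.pixel_pitch_um)
        _, count = quantify_cell(
            fov.darkfield, mask, optics.z_step_um, optics.pixel_pitch_um, config.pnp
        )
        true.append(cell.true_count)
        auto.append(count)
    return CountingResult(np.asarray(true), np.asarray(auto))


def lambda_recovery(
    lam: float,
    n_cells: int = 2000,
    seed: int = 0,
    config: Optional[RunConfig] = None,
    use_hough_contour: bool = True,
) -> Dict[str, float]:
    """End-to-end recovery of a Poisson mean from single-cell stacks.

    Each cell is rendered as its own field of view (fluorescence + a
    9-slice darkfield stack), pushed through the full pipeline —
    compensation, CD45 detection, contour (Hough-circle fallback by
    default), nanoparticle quantification — and the mean automated count
    is compared with the realized ground-truth mean of the same cells.
    Cells the detector misses count as missed (reported), not as zeros.
    """
    config = config or RunConfig()
    optics = replace(config.optics, z_slices=9)
    detect = replace(config.detect, window_px=31)
    cfg = replace(config, optics=optics, detect=detect)
    mixing = CompensationModel.from_matrix(default_mixing_matrix())
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=n_cells)
    stats = RunStats()
    true_sum = 0
    auto, truth = [], []
    for i, n in enumerate(counts):
        cell, fov = render_cell_stack(
            int(n), optics, mixing, seed=int(rng.integers(2**31)),
            radius_um=float(rng.uniform(3.4, 4.4)),
            include_fluorescence=True,
        )
        records = run_fov(fov, mixing, cfg, seg_model=None,
                          sample_id="lam", fov_id=f"cell_{i}", stats=stats)
        if len(records) != 1:
            stats.drop("cell_not_detected")
            continue
        auto.append(records[0].pnp_count)
        truth.append(cell.true_count)
    auto_a, truth_a = np.asarray(auto, float), np.asarray(truth, float)
    lam_hat = float(auto_a.mean()) if len(auto_a) else float("nan")
    lam_true = float(truth_a.mean()) if len(truth_a) else float("nan")
    return {
        "lambda": lam,
        "lambda_hat": lam_hat,
        "lambda_truth_realized": lam_true,
        "relative_bias": (lam_hat - lam_true) / lam_true if lam_true else float("nan"),
        "n_detected": int(len(auto_a)),
        "n_cells": int(n_cells),
    }


def detection_accuracy(
    n_fovs: int = 20,
    cells_per_fov: int = 4,
    seed: int = 0,
    config: Optional[RunConfig] = None,
) -> Dict[str, float]:
    """Cell-detection recall/precision and event conservation on small FOVs.

    Renders fluorescence-only fields with non-overlapping cells, runs the
    pipeline without darkfield, and matches candidates to ground truth
    (match = center within one true radius).  Also checks that every
    candidate is accounted for: kept cells + logged drops.
    """
    config = config or RunConfig()
    detect = replace(config.detect, window_px=31)
    cfg = replace(config, detect=detect)
    optics = config.optics
    mixing = CompensationModel.from_matrix(default_mixing_matrix())
    rng = np.random.default_rng(seed)
    stats = RunStats()
    n_true = n_matched = n_pred = 0
    for f in range(n_fovs):
        cells = random_cells(cells_per_fov, optics, rng, radius_um_range=(3.3, 4.5))
        fov = render_fov(cells, optics, mixing, seed=int(rng.integers(2**31)),
                         include_darkfield=False)
        records = run_fov(fov, mixing, cfg, seg_model=None,
                          sample_id="det", fov_id=f"fov_{f}", stats=stats)
        ds = cfg.detect.downscale
        n_true += len(cells)
        n_pred += len(records)
        used = set()
        for c in cells:
            cx, cy = c.center_px[0] / ds, c.center_px[1] / ds
            r_ds = c.radius_um / (optics.pixel_pitch_um * ds)
            for k, rec in enumerate(records):
                if k in used:
                    continue
                d2 = (rec.center_ds[0] - cx) ** 2 + (rec.center_ds[1] - cy) ** 2
                if d2 <= r_ds**2:
                    used.add(k)
                    n_matched += 1
                    break
    conserved = stats.n_candidates == stats.n_cells + sum(stats.drops.values())
    return {
        "recall": n_matched / n_true if n_true else float("nan"),
        "precision": n_matched / n_pred if n_pred else float("nan"),
        "n_true": n_true,
        "n_candidates": stats.n_candidates,
        "n_kept": stats.n_cells,
        "n_dropped": sum(stats.drops.values()),
        "conserved": bool(conserved),
    }
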