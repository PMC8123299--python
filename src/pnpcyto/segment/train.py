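"""UNET training, inference and the physical area filter.

Training follows the measurement protocol: annotated 82x82 crops are split
50/25/25 into train/validation/test once, the network is optimized with
Adam on a soft-Dice loss for a fixed number of epochs (150 by default, no
early stopping), and the checkpoint with the best validation Dice is kept.
Crops are min-max normalized, which makes inference invariant to affine
intensity shifts of the input.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from skimage.measure import label, regionprops

from ..config import SegmentConfig
from ..errors import DataError
from .nn import Adam, hard_dice, soft_dice_loss
from .unet import UNet


def normalize_crop(crop: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant crop maps to all zeros."""
    crop = np.asarray(crop, dtype=np.float32)
    lo, hi = float(crop.min()), float(crop.max())
    if hi - lo <= 0:
        return np.zeros_like(crop)
    return (crop - lo) / (hi - lo)


def split_indices(
    n: int, split: Tuple[float, float, float], seed: int
) -> Dict[str, np.ndarray]:
    """A single fixed train/validation/test partition of ``n`` items."""
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    return {
        "train": perm[:n_train],
        "val": perm[n_train : n_train + n_val],
        "test": perm[n_train + n_val :],
    }


@dataclass
class SegmentationModel:
    """A trained network plus its training record."""

    net: UNet
    threshold: float = 0.5
    history: Dict[str, List[float]] = field(default_factory=dict)
    best_epoch: int = -1
    best_val_dice: float = float("nan")
    split_sizes: Dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def save(self, path: str) -> None:
        """Native single-file weights plus a JSON metadata sidecar."""
        os.makedirs(path, exist_ok=True)
        state = self.net.state_dict()
        np.savez(os.path.join(path, "weights.npz"), *state)
        meta = {
            "format": "pnpcyto.segmentation/1",
            "levels": self.net.levels,
            "base_channels": self.net.chans[0],
            "threshold": self.threshold,
            "best_epoch": self.best_epoch,
            "best_val_dice": self.best_val_dice,
            "split_sizes": self.split_sizes,
            "seed": self.seed,
            "history": self.history,
        }
        with open(os.path.join(path, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "SegmentationModel":
        with open(os.path.join(path, "model.json")) as fh:
            meta = json.load(fh)
        net = UNet(levels=meta["levels"], base_channels=meta["base_channels"])
        with np.load(os.path.join(path, "weights.npz")) as npz:
            net.load_state_dict([npz[k] for k in npz.files])
        return cls(
            net=net,
            threshold=meta["threshold"],
            history=meta.get("history", {}),
            best_epoch=meta["best_epoch"],
            best_val_dice=meta["best_val_dice"],
            split_sizes=meta.get("split_sizes", {}),
            seed=meta.get("seed", 0),
        )


def _mean_hard_dice(net: UNet, images: np.ndarray, masks: np.ndarray,
                    threshold: float) -> float:
    probs = net.predict(images)
    return float(
        np.mean([hard_dice(p > threshold, m) for p, m in zip(probs, masks)])
    )


def train_unet(
    images: np.ndarray,
    masks: np.ndarray,
    config: Optional[SegmentConfig] = None,
    seed: int = 0,
    epochs: Optional[int] = None,
) -> SegmentationModel:
    """Train on annotated crops; return the best-validation checkpoint.

    ``images``: ``(N, H, W)`` float crops; ``masks``: matching boolean
    annotations.  The split is drawn once from ``seed`` and never changed;
    training runs for exactly ``epochs`` epochs (no early stopping) and the
    parameters with the highest validation Dice are restored at the end.
    Deterministic given ``seed``.
    """
    config = config or SegmentConfig()
    n_epochs = config.epochs if epochs is None else epochs
    images = np.stack([normalize_crop(c) for c in images])
    masks = np.asarray(masks, dtype=np.float32)
    idx = split_indices(len(images), config.split, seed)
    for name, ids in idx.items():
        if len(ids) < 1:
            raise DataError(f"empty {name} split: need more annotated crops")

    net = UNet(levels=config.levels, base_channels=config.base_channels, seed=seed)
    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(seed + 1)
    tr, va = idx["train"], idx["val"]
    history: Dict[str, List[float]] = {"train_loss": [], "val_dice": []}
    best_state, best_dice, best_epoch = None, -1.0, -1
    for epoch in range(n_epochs):
        order = rng.permutation(len(tr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            batch = tr[order[i : i + config.batch_size]]
            x = images[batch]
            t = masks[batch]
            p = net.forward(x)
            loss, dp = soft_dice_loss(p, t, config.dice_smooth)
            opt.zero_grad()
            net.backward(dp)
            opt.step()
            losses.append(loss)
        val_dice = _mean_hard_dice(net, images[va], masks[va] > 0.5, config.threshold)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_dice"].append(val_dice)
        if val_dice > best_dice:
            best_dice, best_epoch = val_dice, epoch
            best_state = net.state_dict()
    net.load_state_dict(best_state)
    return SegmentationModel(
        net=net,
        threshold=config.threshold,
        history=history,
        best_epoch=best_epoch,
        best_val_dice=best_dice,
        split_sizes={k: int(len(v)) for k, v in idx.items()},
        seed=seed,
    )


def evaluate_test_dice(
    model: SegmentationModel,
    images: np.ndarray,
    masks: np.ndarray,
    config: Optional[SegmentConfig] = None,
    seed: int = 0,
) -> float:
    """Mean hard Dice on the held-out test split of the same fixed partition."""
    config = config or SegmentConfig()
    images = np.stack([normalize_crop(c) for c in images])
    idx = split_indices(len(images), config.split, seed)["test"]
    return _mean_hard_dice(
        model.net, images[idx], np.asarray(masks)[idx] > 0.5, model.threshold
    )


def segment_cell(
    crop: np.ndarray,
    model: SegmentationModel,
    threshold: Optional[float] = None,
) -> Optional[np.ndarray]:
    """Segment one crop; keep the foreground region at (or nearest) the center.

    Returns the boolean cell mask, or ``None`` when the network output is
    all background (the candidate is dropped).
    """
    threshold = model.threshold if threshold is None else threshold
    crop = np.asarray(crop)
    if np.ptp(crop) == 0:
        return None  # constant crop: no cell content
    prob = model.net.predict(normalize_crop(crop))
    binary = prob > threshold
    if not binary.any():
        return None
    lab = label(binary, connectivity=2)
    h, w = binary.shape
    center_label = lab[h // 2, w // 2]
    if center_label == 0:
        regions = regionprops(lab)
        d = [
            (r.centroid[0] - h / 2) ** 2 + (r.centroid[1] - w / 2) ** 2
            for r in regions
        ]
        center_label = regions[int(np.argmin(d))].label
    return lab == center_label


def filter_by_area(
    mask: np.ndarray,
    pixel_pitch_ds_um: float,
    config: Optional[SegmentConfig] = None,
) -> bool:
    """Keep a mask iff its physical area lies in [16, 400] um^2 (inclusive)."""
    config = config or SegmentConfig()
    area_um2 = float(np.count_nonzero(mask)) * pixel_pitch_ds_um**2
    return config.min_area_um2 <= area_um2 <= config.max_area_um2


def extract_crop(image: np.ndarray, center_xy: Tuple[float, float],
                 crop_px: int = 82) -> np.ndarray:
    """An 82x82 crop centered on a candidate, reflect-padded at borders."""
    half = crop_px // 2
    x, y = int(round(center_xy[0])), int(round(center_xy[1]))
    pad = ((half, crop_px - half), (half, crop_px - half))
    padded = np.pad(np.asarray(image, dtype=np.float32), pad, mode="reflect")
    return padded[y : y + crop_px, x : x + crop_px]
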