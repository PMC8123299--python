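"""Nanoparticle detection in the darkfield z-stack and multiplet counting.

Per z-slice, scale-normalized Laplacian-of-Gaussian blob detection on the
luminance image finds candidate particle signals; detections outside the
cell contour are rejected.  Per-slice detections are linked into 3D events
with DBSCAN on anisotropy-scaled (x, y, z) coordinates; clusters with too
few or too many members are discarded, and the member at the median slice
becomes the event coordinate.  The red/green intensity ratio at that
coordinate classifies the event as a single particle (ratio in (0, 1]), a
duplet ((1, 2], yellow) or a triplet (> 2, red) — sub-diffraction particle
pairs red-shift the plasmon resonance, so color encodes multiplicity.  The
per-cell count sums multiplicities.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter
from sklearn.cluster import DBSCAN

from .config import PnpConfig
from .datatypes import Pnp2d, PnpDetection
from .errors import InputError

logger = logging.getLogger(__name__)


def _luminance(stack: np.ndarray) -> np.ndarray:
    """(Z, H, W) mean-over-RGB luminance of a (Z, H, W, 3) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[-1] != 3:
        raise InputError(f"expected (Z, H, W, 3) darkfield stack, got {stack.shape}")
    return stack.mean(axis=-1, dtype=np.float32)


def detect_blobs_2d(
    stack: np.ndarray,
    mask_fullres: Optional[np.ndarray] = None,
    config: Optional[PnpConfig] = None,
) -> List[Pnp2d]:
    """Per-slice LoG maxima above threshold, restricted to the cell contour.

    The response is the maximum over the configured Gaussian scales of the
    scale-normalized negative LoG; a pixel is a detection when it is a
    local maximum within its slice and its response exceeds
    ``threshold_mad`` times the slice's median absolute deviation.
    """
    config = config or PnpConfig()
    lum = _luminance(stack)
    response = None
    for sigma in config.log_sigmas:
        # scale-normalized in-plane LoG, vectorized over z (z is not smoothed)
        r = -(sigma**2) * (
            gaussian_filter(lum, sigma=(0, sigma, sigma), order=(0, 2, 0))
            + gaussian_filter(lum, sigma=(0, sigma, sigma), order=(0, 0, 2))
        )
        response = r if response is None else np.maximum(response, r)
    detections: List[Pnp2d] = []
    footprint = np.ones((1, 5, 5), dtype=bool)
    local_max = response == maximum_filter(response, footprint=footprint, mode="nearest")
    for s in range(lum.shape[0]):
        r = response[s]
        # noise scale from the cell interior (the region detections live in)
        ref = r[mask_fullres] if mask_fullres is not None and mask_fullres.any() else r
        med = float(np.median(ref))
        mad = float(np.median(np.abs(ref - med)))
        thr = med + config.threshold_mad * max(mad, 1e-12)
        cand = local_max[s] & (r > thr)
        ys, xs = np.nonzero(cand)
        for y, x in zip(ys, xs):
            if mask_fullres is not None and not mask_fullres[y, x]:
                continue
            detections.append(
                Pnp2d(slice_index=s, position_px=(float(x), float(y)),
                      log_response=float(r[y, x]))
            )
    return detections


def cluster_3d(
    detections: List[Pnp2d],
    z_step_um: float = 0.5,
    pixel_pitch_um: float = 0.0548,
    config: Optional[PnpConfig] = None,
) -> List[PnpDetection]:
    """Link per-slice detections into 3D events with DBSCAN.

    Coordinates are (x, y, z_index * z_scale_px_per_slice): the axial
    spacing in the metric is compressed relative to physical anisotropy so
    the per-slice footprints of one particle, which overlap laterally on
    consecutive slices, stay within reach of ``eps`` while laterally
    distinct particles do not merge.  Clusters whose member count falls
    outside ``[min_cluster, max_cluster]`` are dropped; the retained event
    takes the coordinate of its member at the median slice index (lower
    median for even counts).
    """
    config = config or PnpConfig()
    if not detections:
        return []
    z_scale = config.z_scale_px_per_slice
    pts = np.array(
        [[d.position_px[0], d.position_px[1], d.slice_index * z_scale] for d in detections]
    )
    labels = DBSCAN(eps=config.dbscan_eps, min_samples=1).fit_predict(pts)
    events: List[PnpDetection] = []
    for lab in np.unique(labels):
        members = [d for d, l in zip(detections, labels) if l == lab]
        if not (config.min_cluster <= len(members) <= config.max_cluster):
            continue
        members.sort(key=lambda d: d.slice_index)
        central = members[(len(members) - 1) // 2]
        events.append(
            PnpDetection(
                coordinate=(central.position_px[0], central.position_px[1],
                            central.slice_index),
                member_slices=[m.slice_index for m in members],
            )
        )
    events.sort(key=lambda e: (e.coordinate[2], e.coordinate[1], e.coordinate[0]))
    return events


def classify_color(
    stack: np.ndarray,
    detection: PnpDetection,
    config: Optional[PnpConfig] = None,
    background_mask: Optional[np.ndarray] = None,
) -> PnpDetection:
    """Set the color class and multiplicity of a 3D event in place.

    The ratio is mean(red) / mean(green) over an ``n x n`` neighborhood on
    the event's central slice.  With ``background_subtract`` the slice
    median of each channel (inside ``background_mask`` when given) is
    removed first, so the cell interior's broadband scatter does not dilute
    the spot color.  A non-positive green mean maps to the red class
    (infinite ratio), logged.
    """
    config = config or PnpConfig()
    stack = np.asarray(stack)
    x, y, s = detection.coordinate
    x, y, s = int(round(x)), int(round(y)), int(s)
    half = config.neighborhood_px // 2
    frame = stack[s]
    y0, y1 = max(y - half, 0), min(y + half + 1, frame.shape[0])
    x0, x1 = max(x - half, 0), min(x + half + 1, frame.shape[1])
    red = float(frame[y0:y1, x0:x1, 0].mean())
    green = float(frame[y0:y1, x0:x1, 1].mean())
    if config.background_subtract:
        if background_mask is not None and background_mask.any():
            red -= float(np.median(frame[background_mask, 0]))
            green -= float(np.median(frame[background_mask, 1]))
        else:
            red -= float(np.median(frame[:, :, 0]))
            green -= float(np.median(frame[:, :, 1]))
    if green <= 0:
        logger.info("green channel non-positive at %s; classifying as red", detection.coordinate)
        ratio = float("inf")
    else:
        ratio = red / green
    detection.color_ratio = ratio
    detection.color_class, detection.multiplicity = classify_ratio(ratio)
    return detection


def classify_ratio(ratio: float) -> Tuple[str, int]:
    """Map a red/green ratio to (class, multiplicity).

    Half-open convention: (0, 1] green/singlet, (1, 2] yellow/duplet,
    (2, inf) red/triplet.  Non-positive ratios (background fluctuation)
    count as green.
    """
    if ratio <= 1.0:
        return "green", 1
    if ratio <= 2.0:
        return "yellow", 2
    return "red", 3


def count_cell_pnps(
    detections: List[PnpDetection], config: Optional[PnpConfig] = None
) -> int:
    """Per-cell particle count: sum of multiplicities (or event count)."""
    config = config or PnpConfig()
    if config.count_mode == "events":
        return len(detections)
    return int(sum(d.multiplicity for d in detections))


def quantify_cell(
    stack: np.ndarray,
    mask_fullres: np.ndarray,
    z_step_um: float = 0.5,
    pixel_pitch_um: float = 0.0548,
    config: Optional[PnpConfig] = None,
) -> Tuple[List[PnpDetection], int]:
    """Full per-cell chain: 2D blobs -> 3D events -> color -> count.

    Detection is evaluated on the mask's bounding box (padded by the
    largest LoG scale) — responses outside the contour are rejected anyway.
    """
    config = config or PnpConfig()
    mask_fullres = np.asarray(mask_fullres, dtype=bool)
    if not mask_fullres.any():
        return [], 0
    ys, xs = np.nonzero(mask_fullres)
    pad = int(4 * max(config.log_sigmas))
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, mask_fullres.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, mask_fullres.shape[1])
    sub = np.ascontiguousarray(stack[:, y0:y1, x0:x1])
    blobs = detect_blobs_2d(sub, mask_fullres[y0:y1, x0:x1], config)
    events = cluster_3d(blobs, z_step_um, pixel_pitch_um, config)
    for ev in events:
        classify_color(sub, ev, config, background_mask=mask_fullres[y0:y1, x0:x1])
        ev.coordinate = (ev.coordinate[0] + x0, ev.coordinate[1] + y0, ev.coordinate[2])
    return events, count_cell_pnps(events, config)
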