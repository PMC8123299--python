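"""Candidate cell finding on the compensated CD45 image.

The CD45 plane is downscaled to 1/4 by local mean pooling, binarized with
a local-mean threshold (351 px window, offset 0.05 on the image normalized
to [0, 1]), cleaned by connected-component area filtering (500-6000
downscaled px), and each surviving component is searched with a circular
Hough transform over radii 15-35 px.  At most one circle per component is
retained: the highest Hough score whose center lies inside the component's
bounding box.  Ties break toward the smaller radius, then scanline order.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label, regionprops
from scipy.ndimage import binary_erosion
from skimage.transform import downscale_local_mean, hough_circle

from .config import DetectConfig
from .datatypes import CellCandidate
from .errors import ParameterError


def binarize_cd45(
    cd45_image: np.ndarray, config: Optional[DetectConfig] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Downscale and locally threshold the CD45 abundance image.

    Returns ``(binary, downscaled)``.  A pixel is foreground iff its value
    exceeds the local mean over a ``window_px`` square plus ``offset``,
    after normalizing the downscaled image to [0, 1] by its maximum.
    """
    config = config or DetectConfig()
    img = np.asarray(cd45_image, dtype=np.float32)
    if img.ndim != 2:
        raise ParameterError("binarize_cd45 expects a 2-D abundance image")
    ds = downscale_local_mean(img, (config.downscale, config.downscale)).astype(
        np.float32
    )
    if min(ds.shape) < config.window_px:
        raise ParameterError(
            f"downscaled image {ds.shape} is smaller than the local-threshold "
            f"window ({config.window_px} px); use a smaller detect.window_px"
        )
    peak = float(ds.max())
    norm = ds / peak if peak > 0 else ds
    local_mean = uniform_filter(norm, size=config.window_px, mode="reflect")
    binary = norm > local_mean + config.offset
    return binary, ds


def find_components(
    binary: np.ndarray, config: Optional[DetectConfig] = None
) -> List["regionprops"]:
    """8-connected components with area within the inclusive configured band."""
    config = config or DetectConfig()
    lab = label(binary, connectivity=config.connectivity)
    return [
        r
        for r in regionprops(lab)
        if config.min_component_px <= r.area <= config.max_component_px
    ]


def _component_edges(region, shape, pad):
    """Binary edge map of one component, on a padded crop; returns crop origin."""
    r0, c0, r1, c1 = region.bbox
    r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
    r1p, c1p = min(r1 + pad, shape[0]), min(c1 + pad, shape[1])
    crop = np.zeros((r1p - r0p, c1p - c0p), dtype=bool)
    crop[r0 - r0p : r1 - r0p, c0 - c0p : c1 - c0p] = region.image
    edges = crop & ~binary_erosion(crop)
    return edges, (r0p, c0p)


def hough_cells(
    components: List, binary: np.ndarray, config: Optional[DetectConfig] = None
) -> List[CellCandidate]:
    """One circle per component, by Hough voting on the component's edge map.

    The accumulator is evaluated for every integer radius in the configured
    band; only circle centers inside the component's bounding box qualify.
    Components where no center receives any vote yield nothing.
    """
    config = config or DetectConfig()
    radii = np.arange(config.hough_radius_min, config.hough_radius_max + 1)
    out: List[CellCandidate] = []
    for k, region in enumerate(components):
        edges, (orr, orc) = _component_edges(region, binary.shape, config.hough_radius_max + 2)
        acc = hough_circle(edges, radii)  # (n_radii, h, w), normalized votes
        # restrict candidate centers to the component bounding box
        r0, c0, r1, c1 = region.bbox
        allowed = np.zeros(acc.shape[1:], dtype=bool)
        allowed[r0 - orr : r1 - orr, c0 - orc : c1 - orc] = True
        acc = np.where(allowed[None], acc, -np.inf)
        best = np.argmax(acc)  # first max: smallest radius, then scanline order
        ri, rr, cc = np.unravel_index(best, acc.shape)
        score = float(acc[ri, rr, cc])
        if not np.isfinite(score) or score <= 0:
            continue
        out.append(
            CellCandidate(
                center_ds=(float(cc + orc), float(rr + orr)),
                radius_ds=float(radii[ri]),
                hough_score=score,
                component_id=k,
                component_bbox=region.bbox,
            )
        )
    return out


def detect_cells(
    cd45_image: np.ndarray, config: Optional[DetectConfig] = None
) -> Tuple[List[CellCandidate], np.ndarray, np.ndarray]:
    """Full detection chain; returns (candidates, binary, downscaled image)."""
    config = config or DetectConfig()
    binary, ds = binarize_cd45(cd45_image, config)
    comps = find_components(binary, config)
    return hough_cells(comps, binary, config), binary, ds
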