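"""Per-fluorochrome positivity calls and lineage assignment.

A cell is positive for a fluorochrome when the mean compensated signal
inside its contour exceeds the mean plus twice the standard deviation of
the signal outside.  "Outside" is the ring between the mask dilated by 5
and by 15 px, excluding other cells' masks; if the ring is empty (crowded
field) the whole-image background is used instead.

Lineage follows the marker panel: CD45 gates leukocytes; a single lineage
marker names the class (CD3 T, CD19 B, CD56 NK, CD14 monocyte); the
CD56+CD14+ pair is labeled NK-T; any other multi-marker combination — and
CD45+ cells with no lineage marker — are excluded from subtyping (excluded
CD45+ cells still count toward whole-PBMC aggregates).
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .config import MARKERS, LineageConfig
from .datatypes import PositivityCall

logger = logging.getLogger(__name__)

LINEAGE_CLASSES = ("T", "B", "NKT", "Monocyte", "NK")

_MARKER_TO_CLASS = {"CD3": "T", "CD19": "B", "CD56": "NK", "CD14": "Monocyte"}


def call_positivity(
    abundance_image: np.ndarray,
    mask: np.ndarray,
    fluorochrome: str = "",
    other_masks: Optional[np.ndarray] = None,
    config: Optional[LineageConfig] = None,
) -> PositivityCall:
    """Decide positivity of one cell for one fluorochrome plane.

    ``other_masks`` is a boolean union of neighboring cells' masks to be
    excluded from the outside ring.  Equality with the threshold counts as
    negative.
    """
    config = config or LineageConfig()
    img = np.asarray(abundance_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    # Euclidean distance from the contour defines the dilation ring
    dist = distance_transform_edt(~mask)
    ring = (dist > config.ring_inner_px) & (dist <= config.ring_outer_px)
    outer = dist <= config.ring_outer_px
    if other_masks is not None:
        ring &= ~np.asarray(other_masks, dtype=bool)
    if not ring.any():
        background = ~outer
        if other_masks is not None:
            background &= ~np.asarray(other_masks, dtype=bool)
        logger.info(
            "empty outside ring for %s; falling back to whole-image background",
            fluorochrome or "<plane>",
        )
        ring = background
    mean_in = float(img[mask].mean())
    mean_out = float(img[ring].mean()) if ring.any() else 0.0
    sd_out = float(img[ring].std()) if ring.any() else 0.0
    positive = mean_in > mean_out + config.sd_margin * sd_out
    return PositivityCall(
        fluorochrome=fluorochrome,
        mean_inside=mean_in,
        mean_outside=mean_out,
        sd_outside=sd_out,
        positive=bool(positive),
    )


def call_all_positivity(
    abundances: np.ndarray,
    mask: np.ndarray,
    other_masks: Optional[np.ndarray] = None,
    config: Optional[LineageConfig] = None,
    markers: Sequence[str] = MARKERS,
) -> Dict[str, PositivityCall]:
    """Positivity calls for all 5 planes of a ``(5, H, W)`` abundance image."""
    return {
        m: call_positivity(abundances[i], mask, m, other_masks, config)
        for i, m in enumerate(markers)
    }


def assign_lineage(
    calls: Dict[str, PositivityCall], config: Optional[LineageConfig] = None
) -> str:
    """Map the five positivity booleans to a lineage label.

    Returns one of T, B, NK, NKT, Monocyte, Excluded, NotLeukocyte.
    """
    config = config or LineageConfig()
    if set(calls) != set(MARKERS):
        raise ValueError(f"expected calls for {MARKERS}, got {tuple(calls)}")
    if not calls["CD45"].positive:
        return "NotLeukocyte"
    positive = {m for m in MARKERS[1:] if calls[m].positive}
    if len(positive) == 1:
        return _MARKER_TO_CLASS[positive.pop()]
    if positive == set(config.nkt_pair):
        return "NKT"
    return "Excluded"


def lineage_fractions(cells) -> pd.Series:
    """Percentage per lineage class among classified cells.

    ``cells`` is a sequence of :class:`CellRecord` or a DataFrame with a
    ``lineage`` column.  Excluded and NotLeukocyte cells are reported in
    separate rows, as percentages of all cells, and do not enter the
    subtype percentages.
    """
    if isinstance(cells, pd.DataFrame):
        labels = cells["lineage"]
    else:
        labels = pd.Series([c.lineage for c in cells])
    if len(labels) == 0:
        warnings.warn("no classified cells; empty lineage table", stacklevel=2)
        return pd.Series(dtype=float, name="percent")
    classified = labels[labels.isin(LINEAGE_CLASSES)]
    if len(classified) == 0:
        warnings.warn("all cells excluded or not leukocytes", stacklevel=2)
        return pd.Series(dtype=float, name="percent")
    out = {
        cls: 100.0 * (classified == cls).sum() / len(classified)
        for cls in LINEAGE_CLASSES
    }
    for extra in ("Excluded", "NotLeukocyte"):
        n = int((labels == extra).sum())
        if n:
            out[extra] = 100.0 * n / len(labels)
    return pd.Series(out, name="percent")
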