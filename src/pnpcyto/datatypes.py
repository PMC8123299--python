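"""Shared in-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np


@dataclass
class FieldOfView:
    """One acquisition unit.

    ``darkfield`` is a ``(Z, H, W, 3)`` float array (arbitrary camera units);
    ``fluorescence`` is ``(4, H, W, 3)``, one RGB frame per excitation band
    of the multi-band filter set.  Either may be ``None`` when a stage does
    not need it (bead slides carry only fluorescence).  ``meta`` holds the
    JSON-sidecar fields: pixel pitch, z positions, channel order, seed.
    """

    fluorescence: Optional[np.ndarray] = None
    darkfield: Optional[np.ndarray] = None
    pixel_pitch_um: float = 0.0548
    z_positions_um: Optional[np.ndarray] = None
    channel_order: Tuple[str, ...] = ("R", "G", "B")
    meta: Dict = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        if self.fluorescence is not None:
            return self.fluorescence.shape[1:3]
        if self.darkfield is not None:
            return self.darkfield.shape[1:3]
        raise ValueError("empty FieldOfView")

    def stacked_vector_image(self) -> np.ndarray:
        """Fluorescence as a ``(12, H, W)`` band-major (band, then RGB) array."""
        if self.fluorescence is None:
            raise ValueError("FieldOfView has no fluorescence data")
        f = np.asarray(self.fluorescence)
        n_bands, h, w, _ = f.shape
        return f.transpose(0, 3, 1, 2).reshape(n_bands * 3, h, w)


@dataclass
class GroundTruthPnp:
    """A simulated nanoparticle scattering event.

    ``multiplicity`` counts the particles in the (sub-diffraction) event;
    the red/green scattering ratio encodes it: singlets sit in (0, 1],
    duplets in (1, 2], triplets above 2.
    """

    position_um: Tuple[float, float, float]  # x, y relative to frame origin; z to focus
    multiplicity: int
    true_color_ratio: float

    def __post_init__(self) -> None:
        m, r = self.multiplicity, self.true_color_ratio
        ok = (m == 1 and 0 < r <= 1) or (m == 2 and 1 < r <= 2) or (m == 3 and r > 2)
        if not ok:
            raise ValueError(
                f"color ratio {r} inconsistent with multiplicity {m}"
            )


@dataclass
class GroundTruthCell:
    """A simulated cell with known contour, lineage and nanoparticle load."""

    center_px: Tuple[float, float]           # x, y in full-resolution pixels
    radius_um: float
    lineage: str                              # T, B, NK, NKT, Monocyte or None
    fluorochrome_abundances: np.ndarray       # 5-vector, panel order
    pnp_events: List[GroundTruthPnp] = field(default_factory=list)
    cell_id: int = 0

    @property
    def true_count(self) -> int:
        return int(sum(e.multiplicity for e in self.pnp_events))

    def contour_mask(self, shape_hw: Tuple[int, int], pixel_pitch_um: float) -> np.ndarray:
        """Boolean raster of the cell footprint at full resolution."""
        h, w = shape_hw
        yy, xx = np.ogrid[:h, :w]
        cx, cy = self.center_px
        r_px = self.radius_um / pixel_pitch_um
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2


@dataclass
class CellCandidate:
    """One circle retained from the Hough search, in downscaled pixels."""

    center_ds: Tuple[float, float]  # x, y
    radius_ds: float
    hough_score: float
    component_id: int
    component_bbox: Tuple[int, int, int, int]  # min_row, min_col, max_row, max_col


@dataclass
class Pnp2d:
    """A single-slice blob detection."""

    slice_index: int
    position_px: Tuple[float, float]  # x, y full-resolution
    log_response: float


@dataclass
class PnpDetection:
    """A 3D nanoparticle event linked across slices."""

    coordinate: Tuple[float, float, int]  # x, y, central slice index
    member_slices: List[int]
    color_ratio: float = float("nan")
    multiplicity: int = 0
    color_class: str = ""


@dataclass
class PositivityCall:
    """Inside-vs-outside fluorochrome positivity decision for one cell."""

    fluorochrome: str
    mean_inside: float
    mean_outside: float
    sd_outside: float
    positive: bool


@dataclass
class CellRecord:
    """One analyzed cell: the row unit of the cell-level output table."""

    sample_id: str
    fov_id: str
    cell_id: int
    center_ds: Tuple[float, float]
    radius_ds: float
    mask_ds: Optional[np.ndarray]
    area_um2: float
    calls: Dict[str, PositivityCall]
    lineage: str
    detections: List[PnpDetection]
    pnp_count: int
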