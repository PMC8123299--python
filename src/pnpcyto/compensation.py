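"""Color compensation: bead-calibrated linear spectral unmixing.

A cell stained with one fluorochrome still shows signal in several of the
4 excitation bands x RGB camera channels.  Calibration bead slides, one per
fluorochrome, give the 12-channel signature of each dye: the per-channel
median over the bead pixels of slide *j* forms column *j* of the 12x5
mixing matrix ``M``.  The Moore-Penrose pseudoinverse ``M_inv`` then maps
any pixel's 12-vector back to the 5 per-fluorochrome abundances.  Abundance
units are fractions of the bead-median brightness (columns are not
normalized).  Negative abundances are retained so downstream statistics see
unbiased noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .config import FLUOROCHROMES, N_CHANNELS, CompensateConfig
from .datatypes import FieldOfView
from .errors import CalibrationError, InputError


def default_mixing_matrix() -> np.ndarray:
    """A plausible 12x5 mixing matrix for the five-dye panel.

    Rows are excitation-band-major (band 0 R, G, B, band 1 R, ...).  Each
    dye is brightest in its own excitation band with its emission color on
    the RGB camera, plus realistic cross-excitation bleed.  Values are
    camera units per unit abundance.
    """
    m = np.zeros((N_CHANNELS, 5))

    def put(band, rgb, col, scale=100.0):
        m[3 * band : 3 * band + 3, col] += scale * np.asarray(rgb)

    # BV510-CD45: violet-excited, green-cyan emission
    put(0, (0.10, 0.90, 0.35), 0)
    put(1, (0.02, 0.12, 0.04), 0)
    # BV421-CD19: violet-excited, blue emission
    put(0, (0.05, 0.15, 1.00), 1)
    # AF488-CD14: blue-excited, green emission
    put(1, (0.08, 1.00, 0.15), 2)
    put(0, (0.02, 0.12, 0.03), 2)
    # PE-CD56: green-excited, orange emission
    put(2, (0.90, 0.55, 0.05), 3)
    put(1, (0.18, 0.12, 0.02), 3)
    # AF647-CD3: red-excited, far-red emission
    put(3, (1.00, 0.08, 0.02), 4)
    put(2, (0.10, 0.02, 0.00), 4)
    return m


def _check_rank(m: np.ndarray, rtol: float) -> None:
    s = np.linalg.svd(m, compute_uv=False)
    if s[-1] < rtol * s[0]:
        raise CalibrationError(
            "mixing matrix is rank deficient: two fluorochromes are "
            f"spectrally indistinguishable (singular values {s})"
        )


@dataclass
class CompensationModel:
    """The mixing matrix ``M``, its pseudoinverse and calibration metadata."""

    M: np.ndarray
    M_inv: np.ndarray = None
    fluorochrome_names: Sequence[str] = FLUOROCHROMES
    bead_medians: Optional[np.ndarray] = None  # (5, 12), audit copy of M columns
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (N_CHANNELS, len(self.fluorochrome_names)):
            raise InputError(f"mixing matrix must be 12x5, got {self.M.shape}")
        if np.any(self.M < 0):
            raise CalibrationError("mixing matrix columns must be nonnegative")
        if np.any(self.M.max(axis=0) <= 0):
            raise CalibrationError("every mixing-matrix column needs a positive entry")
        _check_rank(self.M, 1e-9)
        if self.M_inv is None:
            self.M_inv = np.linalg.pinv(self.M)

    @classmethod
    def from_matrix(cls, m: np.ndarray, **kw) -> "CompensationModel":
        return cls(M=m, **kw)

    def unmix(self, fluorescence: np.ndarray) -> np.ndarray:
        """Unmix a ``(4, H, W, 3)`` fluorescence set into ``(5, H, W)`` abundances."""
        return unmix(fluorescence, self)

    def to_json(self, path=None) -> str:
        payload = {
            "format": "pnpcyto.compensation/1",
            "fluorochrome_names": list(self.fluorochrome_names),
            "M": self.M.tolist(),
            "bead_medians": None if self.bead_medians is None else np.asarray(self.bead_medians).tolist(),
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "CompensationModel":
        import os

        if os.path.exists(source):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        beads = payload.get("bead_medians")
        return cls(
            M=np.asarray(payload["M"]),
            fluorochrome_names=tuple(payload["fluorochrome_names"]),
            bead_medians=None if beads is None else np.asarray(beads),
            meta=payload.get("meta", {}),
        )


def detect_beads(
    image: FieldOfView, config: Optional[CompensateConfig] = None
) -> List[np.ndarray]:
    """Find calibration beads on a single-fluorochrome slide.

    Global Otsu threshold on the maximum over the 12 channels, then
    connected components; each component is one bead.  Returns, per bead,
    the flat pixel indices into the ``(H, W)`` frame.
    """
    config = config or CompensateConfig()
    v = image.stacked_vector_image()  # (12, H, W)
    peak = v.max(axis=0)
    if peak.max() <= 0 or np.ptp(peak) == 0:
        raise CalibrationError("bead slide is blank: no signal above zero")
    thr = threshold_otsu(peak)
    binary = peak > thr
    lab = label(binary, connectivity=2)
    groups = [
        np.flatnonzero((lab == r.label).ravel())
        for r in regionprops(lab)
        if r.area >= config.min_bead_px
    ]
    if len(groups) < config.min_beads:
        name = image.meta.get("fluorochrome", "<unknown slide>")
        raise CalibrationError(
            f"slide {name}: found {len(groups)} beads, need >= {config.min_beads}"
        )
    return groups


def bead_centers(image: FieldOfView, config: Optional[CompensateConfig] = None) -> np.ndarray:
    """(x, y) centroids of the detected beads, for validation against truth."""
    h, w = image.shape
    centers = []
    for g in detect_beads(image, config):
        rr, cc = np.unravel_index(g, (h, w))
        centers.append((cc.mean(), rr.mean()))
    return np.asarray(centers)


def build_mixing_matrix(
    bead_slides: Sequence[FieldOfView], config: Optional[CompensateConfig] = None
) -> CompensationModel:
    """Estimate the 12x5 mixing matrix from one bead slide per fluorochrome.

    Column *j* is the per-channel median over the pooled bead pixels of
    slide *j*, after subtracting the per-channel median of the non-bead
    background (camera offset).
    """
    config = config or CompensateConfig()
    if len(bead_slides) != len(FLUOROCHROMES):
        raise InputError(f"need {len(FLUOROCHROMES)} bead slides, got {len(bead_slides)}")
    cols, medians, n_beads = [], [], []
    for j, slide in enumerate(bead_slides):
        groups = detect_beads(slide, config)
        n_beads.append(len(groups))
        v = slide.stacked_vector_image().reshape(N_CHANNELS, -1)
        idx = np.concatenate(groups)
        if config.pooled_median:
            col = np.median(v[:, idx], axis=1)
        else:
            col = np.mean(
                [np.median(v[:, g], axis=1) for g in groups], axis=0
            )
        if config.background_subtract:
            bg_mask = np.ones(v.shape[1], dtype=bool)
            bg_mask[idx] = False
            col = col - np.median(v[:, bg_mask], axis=1)
        col = np.clip(col, 0.0, None)
        cols.append(col)
        medians.append(col)
    m = np.stack(cols, axis=1)
    _check_rank(m, config.rank_rtol)
    return CompensationModel(
        M=m,
        bead_medians=np.stack(medians),
        meta={"n_beads": n_beads},
    )


def unmix(fluorescence, model: CompensationModel) -> np.ndarray:
    """Per-pixel abundances ``a = M_inv . v`` for a ``(4, H, W, 3)`` input.

    Accepts a :class:`FieldOfView` or the raw array.  Output is ``(5, H, W)``;
    negative values are retained by design.
    """
    if isinstance(fluorescence, FieldOfView):
        fluorescence = fluorescence.fluorescence
    f = np.asarray(fluorescence, dtype=float)
    if f.ndim != 4 or f.shape[0] * f.shape[3] != N_CHANNELS:
        raise InputError(
            f"expected (4, H, W, 3) fluorescence, got shape {f.shape}"
        )
    n_bands, h, w, _ = f.shape
    v = f.transpose(0, 3, 1, 2).reshape(N_CHANNELS, h * w)
    a = model.M_inv @ v
    return a.reshape(len(model.fluorochrome_names), h, w)
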