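"""Synthetic field-of-view renderer with complete ground truth.

The optical model is phenomenological, not physical: nanoparticle events
render as lateral Gaussian spots whose peak luminance is
``pnp_to_background_ratio`` times the mean darkfield luminance of the cell
interior, attenuated as a Gaussian in axial distance and visible within
``pnp_z_visibility_um`` of their true z.  Cell interiors carry lognormal
speckle texture (darkfield cell interiors are granular); the space between
cells is dim.  Fluorescence frames are the linear mixture
``M . abundance + noise`` per pixel.  Events closer than the diffraction
limit are generated as one multi-particle event with a red-shifted
scattering color, which is exactly what the duplet/triplet color classes
measure; resolvable events therefore keep a minimum lateral separation.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from ..compensation import CompensationModel
from ..config import MARKERS, OpticsConfig
from ..datatypes import FieldOfView, GroundTruthCell, GroundTruthPnp
from ..errors import InputError

LINEAGES: Tuple[str, ...] = ("T", "B", "NKT", "Monocyte", "NK")

#: Default lineage mixture, close to the flow-cytometry composition of a
#: healthy PBMC sample (T-dominant, few NK cells).
DEFAULT_MIXTURE: Dict[str, float] = {
    "T": 0.70,
    "B": 0.10,
    "NKT": 0.06,
    "Monocyte": 0.08,
    "NK": 0.06,
}

#: CD markers expressed per lineage (besides the pan-leukocyte CD45).
LINEAGE_MARKERS: Dict[str, Tuple[str, ...]] = {
    "T": ("CD3",),
    "B": ("CD19",),
    "NK": ("CD56",),
    "Monocyte": ("CD14",),
    "NKT": ("CD56", "CD14"),
    "None": (),
}

#: Relative frequency of singlet / duplet / triplet scattering events.
MULTIPLICITY_WEIGHTS: Tuple[float, float, float] = (0.60, 0.25, 0.15)

_RATIO_INTERVALS = {1: (1e-3, 1.0), 2: (1.0 + 1e-3, 2.0), 3: (2.0 + 1e-3, 3.0)}


def lineage_abundances(
    lineage: str,
    rng: Optional[np.random.Generator] = None,
    brightness_jitter: float = 0.15,
) -> np.ndarray:
    """Fluorochrome abundance 5-vector for a lineage (panel order).

    Leukocytes always express CD45; exactly the lineage-defining markers
    are positive.  Per-marker brightness is jittered lognormally to emulate
    staining variability.
    """
    a = np.zeros(len(MARKERS))
    if lineage != "None":
        a[MARKERS.index("CD45")] = 1.0
        for m in LINEAGE_MARKERS[lineage]:
            a[MARKERS.index(m)] = 1.0
    if rng is not None and brightness_jitter > 0:
        a = a * np.exp(rng.normal(0.0, brightness_jitter, size=a.shape))
        a[a < 1e-12] = 0.0
    return a


def sample_pnp_events(
    count: int,
    cell: GroundTruthCell,
    optics: OpticsConfig,
    rng: np.random.Generator,
    min_sep_um: float = 0.66,
    radial_margin: float = 0.85,
    multiplicity_weights: Sequence[float] = MULTIPLICITY_WEIGHTS,
) -> List[GroundTruthPnp]:
    """Partition a per-cell particle count into scattering events.

    The count is split into singlets/duplets/triplets; events get lateral
    positions inside ``radial_margin`` of the contour radius with pairwise
    separation >= ``min_sep_um`` (two resolvable spots), and a color ratio
    drawn uniformly from the class interval of their multiplicity.
    """
    events: List[GroundTruthPnp] = []
    mults: List[int] = []
    remaining = int(count)
    w = np.asarray(multiplicity_weights, dtype=float)
    w = w / w.sum()
    while remaining > 0:
        m = int(rng.choice((1, 2, 3), p=w))
        m = min(m, remaining)
        mults.append(m)
        remaining -= m

    r_max_um = radial_margin * cell.radius_um
    z_lim = float(min(cell.radius_um, max(optics.z_positions_um.max() - 0.5, 0.0)))
    cx_um = cell.center_px[0] * optics.pixel_pitch_um
    cy_um = cell.center_px[1] * optics.pixel_pitch_um
    placed: List[Tuple[float, float]] = []
    for m in mults:
        for _ in range(200):
            rad = r_max_um * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            x, y = cx_um + rad * np.cos(ang), cy_um + rad * np.sin(ang)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_sep_um**2 for px, py in placed):
                break
        placed.append((x, y))
        z = rng.uniform(-z_lim, z_lim) if z_lim > 0 else 0.0
        lo, hi = _RATIO_INTERVALS[m]
        events.append(
            GroundTruthPnp(
                position_um=(x, y, z),
                multiplicity=m,
                true_color_ratio=float(rng.uniform(lo, hi)),
            )
        )
    return events


def random_cells(
    n: int,
    optics: OpticsConfig,
    rng: np.random.Generator,
    radius_um_range: Tuple[float, float] = (3.3, 5.5),
    mixture: Optional[Dict[str, float]] = None,
    lambda_by_lineage: Optional[Dict[str, float]] = None,
    edge_margin_px: float = 12.0,
    separation_px: float = 8.0,
    max_tries: int = 2000,
) -> List[GroundTruthCell]:
    """Place ``n`` non-overlapping cells with lineages drawn from a mixture.

    If ``lambda_by_lineage`` is given, each cell's particle count is drawn
    Poisson with the mean of its lineage and converted to events.
    """
    mixture = mixture or DEFAULT_MIXTURE
    names = list(mixture)
    probs = np.asarray([mixture[k] for k in names], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise InputError("lineage mixture must sum to 1")
    h, w = optics.image_height_px, optics.image_width_px
    cells: List[GroundTruthCell] = []
    placed: List[Tuple[float, float, float]] = []
    for i in range(n):
        lineage = names[int(rng.choice(len(names), p=probs))]
        r_um = float(rng.uniform(*radius_um_range))
        r_px = r_um / optics.pixel_pitch_um
        lo = r_px + edge_margin_px
        ok = False
        for _ in range(max_tries):
            x = rng.uniform(lo, w - lo)
            y = rng.uniform(lo, h - lo)
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= (r_px + pr + separation_px) ** 2
                for px, py, pr in placed
            ):
                ok = True
                break
        if not ok:
            raise InputError(
                f"could not place {n} non-overlapping cells in a {w}x{h} frame"
            )
        placed.append((x, y, r_px))
        cell = GroundTruthCell(
            center_px=(x, y),
            radius_um=r_um,
            lineage=lineage,
            fluorochrome_abundances=lineage_abundances(lineage, rng),
            cell_id=i,
        )
        if lambda_by_lineage is not None:
            count = int(rng.poisson(lambda_by_lineage[lineage]))
            cell.pnp_events = sample_pnp_events(count, cell, optics, rng)
        cells.append(cell)
    return cells


def _camera_noise(rng, signal, read_sd, shot):
    """Read + (Gaussian-approximated) shot noise in one float32 draw."""
    var = np.full(signal.shape, read_sd**2, dtype=np.float32)
    if shot:
        var += np.clip(signal, 0.0, None)
    if not var.any():
        return signal
    n = rng.standard_normal(signal.shape, dtype=np.float32)
    return signal + np.sqrt(var) * n


def _speckle(shape, rng, sigma, smooth):
    """Unit-mean lognormal texture with lateral correlation ``smooth`` px."""
    if sigma <= 0:
        return np.ones(shape, dtype=np.float32)
    field = sigma * rng.standard_normal(shape, dtype=np.float32)
    if smooth > 0:
        field = gaussian_filter(field, smooth)
        # smoothing shrinks the variance; rescale to the requested sigma
        sd = field.std()
        if sd > 0:
            field *= sigma / sd
    out = np.exp(field)
    return out / out.mean()


def _add_spot(channel_img, x, y, amp, sigma):
    """Add a lateral Gaussian spot in place; patch limited to +/- 4 sigma."""
    h, w = channel_img.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    channel_img[y0:y1, x0:x1] += amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2)
    ).astype(np.float32)


#: RGB weight of the blue camera channel for a nanoparticle spot.
_SPOT_BLUE_WEIGHT = 0.1


def render_fov(
    cells: Sequence[GroundTruthCell],
    optics: OpticsConfig,
    mixing: CompensationModel,
    seed: int = 0,
    include_darkfield: bool = True,
    include_fluorescence: bool = True,
    overlap_warn_fraction: float = 0.05,
) -> FieldOfView:
    """Render one field of view: darkfield z-stack plus 4-band fluorescence.

    Deterministic given ``seed``.  Raises :class:`InputError` when a cell
    center is outside the frame; warns (but still renders) when cell masks
    overlap by more than ``overlap_warn_fraction`` of their union.
    """
    rng = np.random.default_rng(seed)
    h, w = optics.image_height_px, optics.image_width_px
    for c in cells:
        x, y = c.center_px
        if not (0 <= x < w and 0 <= y < h):
            raise InputError(f"cell {c.cell_id} center {c.center_px} outside frame")

    masks = [c.contour_mask((h, w), optics.pixel_pitch_um) for c in cells]
    if masks:
        total = np.sum(masks, axis=0)
        union = int((total > 0).sum())
        overlap = int((total > 1).sum())
        if union and overlap > overlap_warn_fraction * union:
            warnings.warn(
                f"cells overlap on {overlap} px ({overlap / union:.1%} of their union)",
                stacklevel=2,
            )
        interior = total > 0
    else:
        interior = np.zeros((h, w), dtype=bool)

    fluorescence = None
    if include_fluorescence:
        abundance = np.zeros((len(MARKERS), h, w), dtype=np.float32)
        for c, m in zip(cells, masks):
            abundance[:, m] += np.asarray(c.fluorochrome_abundances, dtype=np.float32)[:, None]
        if optics.fluor_blur_px > 0:
            for k in range(abundance.shape[0]):
                abundance[k] = gaussian_filter(abundance[k], optics.fluor_blur_px)
        v = np.tensordot(mixing.M.astype(np.float32), abundance, axes=(1, 0))  # (12,H,W)
        v = _camera_noise(rng, v, optics.read_noise_sd, optics.shot_noise)
        fluorescence = (
            v.reshape(4, 3, h, w).transpose(0, 2, 3, 1).astype(np.float32)
        )

    darkfield = None
    if include_darkfield:
        z_pos = optics.z_positions_um
        darkfield = np.empty((optics.z_slices, h, w, 3), dtype=np.float32)
        sigma_z = optics.pnp_z_visibility_um / 2.0
        for s, z_s in enumerate(z_pos):
            lum = np.full((h, w), optics.outside_level, dtype=np.float32)
            if interior.any():
                spk = _speckle((h, w), rng, optics.speckle_sigma, optics.speckle_smooth_px)
                lum[interior] = optics.cell_interior_level * spk[interior]
            rgb = np.repeat(lum[:, :, None], 3, axis=2)
            for c in cells:
                for ev in c.pnp_events:
                    ex, ey, ez = ev.position_um
                    dz = z_s - ez
                    if abs(dz) > optics.pnp_z_visibility_um:
                        continue
                    amp = (
                        (optics.pnp_to_background_ratio - 1.0)
                        * optics.cell_interior_level
                        * np.exp(-(dz**2) / (2.0 * sigma_z**2))
                    )
                    rho = ev.true_color_ratio
                    norm = 3.0 / (rho + 1.0 + _SPOT_BLUE_WEIGHT)
                    px = ex / optics.pixel_pitch_um
                    py = ey / optics.pixel_pitch_um
                    for ch, wgt in enumerate((rho, 1.0, _SPOT_BLUE_WEIGHT)):
                        _add_spot(rgb[:, :, ch], px, py, amp * wgt * norm, optics.psf_sigma_px)
            darkfield[s] = _camera_noise(rng, rgb, optics.read_noise_sd, optics.shot_noise)

    return FieldOfView(
        fluorescence=fluorescence,
        darkfield=darkfield,
        pixel_pitch_um=optics.pixel_pitch_um,
        z_positions_um=optics.z_positions_um.copy(),
        meta={"seed": int(seed), "n_cells": len(cells)},
    )


def render_bead_slide(
    fluorochrome_index: int,
    n_beads: int,
    optics: OpticsConfig,
    mixing: CompensationModel,
    seed: int = 0,
    bead_radius_px: float = 8.0,
    bead_abundance: float = 1.0,
) -> Tuple[FieldOfView, np.ndarray]:
    """Render a single-fluorochrome calibration slide.

    Beads are small bright disks expressing only fluorochrome
    ``fluorochrome_index``.  Returns the (fluorescence-only, single-plane)
    field of view and the ground-truth bead centers as an ``(n, 2)`` array
    of (x, y).
    """
    if n_beads < 1:
        raise InputError("need at least one bead")
    rng = np.random.default_rng(seed)
    h, w = optics.image_height_px, optics.image_width_px
    lo = bead_radius_px + 8
    centers = []
    for _ in range(n_beads):
        for _ in range(2000):
            x, y = rng.uniform(lo, w - lo), rng.uniform(lo, h - lo)
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= (4 * bead_radius_px) ** 2
                for px, py in centers
            ):
                break
        else:
            raise InputError("could not place beads without overlap")
        centers.append((x, y))
    abundance = np.zeros((h, w), dtype=np.float32)
    yy, xx = np.mgrid[:h, :w]
    for x, y in centers:
        abundance[(xx - x) ** 2 + (yy - y) ** 2 <= bead_radius_px**2] = bead_abundance
    col = mixing.M[:, fluorochrome_index].astype(np.float32)
    v = col[:, None, None] * abundance[None]
    v = _camera_noise(rng, v, optics.read_noise_sd, optics.shot_noise)
    fluor = v.reshape(4, 3, h, w).transpose(0, 2, 3, 1)
    fov = FieldOfView(
        fluorescence=fluor.astype(np.float32),
        pixel_pitch_um=optics.pixel_pitch_um,
        meta={"fluorochrome": mixing.fluorochrome_names[fluorochrome_index], "seed": int(seed)},
    )
    return fov, np.asarray(centers)


def cell_roi_optics(optics: OpticsConfig, radius_um: float, pad_px: int = 28) -> OpticsConfig:
    """Optics for a single-cell region of interest, sized to the cell."""
    r_px = int(np.ceil(radius_um / optics.pixel_pitch_um))
    size = 2 * (r_px + pad_px)
    size += size % 4  # keep divisible by the detection downscale
    return replace(optics, image_width_px=size, image_height_px=size)


def render_cell_stack(
    cell_count: int,
    optics: OpticsConfig,
    mixing: CompensationModel,
    seed: int = 0,
    radius_um: float = 4.0,
    lineage: str = "T",
    include_fluorescence: bool = False,
) -> Tuple[GroundTruthCell, FieldOfView]:
    """Render one cell, centered in its own ROI, with ``cell_count`` particles.

    The per-cell darkfield stack mirrors the centered 3D region of interest
    the quantification stage operates on.
    """
    rng = np.random.default_rng(seed)
    roi = cell_roi_optics(optics, radius_um)
    center = (roi.image_width_px / 2.0, roi.image_height_px / 2.0)
    cell = GroundTruthCell(
        center_px=center,
        radius_um=radius_um,
        lineage=lineage,
        fluorochrome_abundances=lineage_abundances(lineage, rng),
    )
    cell.pnp_events = sample_pnp_events(cell_count, cell, roi, rng)
    fov = render_fov(
        [cell], roi, mixing, seed=int(rng.integers(2**31)),
        include_fluorescence=include_fluorescence,
    )
    return cell, fov


def make_training_crops(
    n: int,
    seed: int = 0,
    crop_px: int = 82,
    radius_range_ds: Tuple[float, float] = (15.0, 26.0),
    noise_sd: float = 0.05,
    speckle_sigma: float = 0.25,
    neighbor_prob: float = 0.3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Annotated crops for segmentation training, at the detection scale.

    Each crop emulates an unmixed CD45 plane around a candidate: a bright,
    slightly elliptical, speckled cell near the center (jittered a few
    pixels, as the circle detector would deliver it), occasionally a
    partial neighbor at the border, Gaussian noise everywhere.  The
    annotation is the central cell's footprint only.

    Returns ``(images, masks)`` of shapes ``(n, crop, crop)``.
    """
    rng = np.random.default_rng(seed)
    imgs = np.empty((n, crop_px, crop_px), dtype=np.float32)
    msks = np.empty((n, crop_px, crop_px), dtype=bool)
    yy, xx = np.mgrid[:crop_px, :crop_px].astype(np.float32)
    for i in range(n):
        cx = crop_px / 2 + rng.uniform(-6, 6)
        cy = crop_px / 2 + rng.uniform(-6, 6)
        r = rng.uniform(*radius_range_ds)
        ar = rng.uniform(0.85, 1.0)
        th = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        mask = (u / r) ** 2 + (v / (r * ar)) ** 2 <= 1.0
        img = np.zeros((crop_px, crop_px), dtype=np.float32)
        tex = _speckle((crop_px, crop_px), rng, speckle_sigma, 1.5)
        img[mask] = tex[mask]
        if rng.uniform() < neighbor_prob:
            # partial neighbor entering from a border
            ang = rng.uniform(0, 2 * np.pi)
            rn = rng.uniform(*radius_range_ds)
            d = r + rn + rng.uniform(2, 10)
            nx, ny = cx + d * np.cos(ang), cy + d * np.sin(ang)
            nmask = (xx - nx) ** 2 + (yy - ny) ** 2 <= rn**2
            img[nmask & ~mask] = tex[nmask & ~mask]
        img = gaussian_filter(img, 1.0)
        img += rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
        imgs[i] = img
        msks[i] = mask
    return imgs, msks
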