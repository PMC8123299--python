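"""Configuration for every stage of the pipeline.

All printed constants of the measurement protocol live here with their
defaults: the local-threshold window (351 px) and offset (0.05), the
connected-component area band (500-6000 downscaled px), the Hough radius
range (15-35 downscaled px), the segmentation crop size (82 px), training
length (150 epochs), output threshold (0.5), the physical area band
(16-400 um^2), the positivity margin (2 SD), the color-ratio class
boundaries (1 and 2) and the binding-stratification cutoffs (5 and 10
nanoparticles per cell).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml

#: Fluorochrome panel: conjugate and the CD marker it reports, column order
#: of the mixing matrix.
FLUOROCHROMES: Tuple[str, ...] = (
    "BV510-CD45",
    "BV421-CD19",
    "AF488-CD14",
    "PE-CD56",
    "AF647-CD3",
)

#: CD markers in the same column order as :data:`FLUOROCHROMES`.
MARKERS: Tuple[str, ...] = ("CD45", "CD19", "CD14", "CD56", "CD3")

#: Number of excitation bands of the multi-band (Pinkel) filter set.
N_EXCITATION_BANDS = 4

#: Rows of the mixing matrix: 4 excitation bands x RGB camera channels.
N_CHANNELS = N_EXCITATION_BANDS * 3


@dataclass
class OpticsConfig:
    """Acquisition geometry and phenomenological signal model of the simulator.

    The darkfield stack covers ``z_slices`` planes of ``z_step_um`` spacing
    centred on the equatorial plane; with the production settings of 40
    slices at 0.5 um this spans [-10, +9.5] um.  ``pnp_to_background_ratio``
    is the peak luminance of a nanoparticle spot relative to the mean
    darkfield luminance of the cell interior (default 13).  Intensities are
    in arbitrary camera units.
    """

    image_width_px: int = 512
    image_height_px: int = 512
    pixel_pitch_um: float = 0.0548   # um per full-resolution pixel
    z_slices: int = 40
    z_step_um: float = 0.5
    pnp_to_background_ratio: float = 13.0
    psf_sigma_px: float = 2.0        # lateral Gaussian SD of a nanoparticle spot
    pnp_z_visibility_um: float = 2.0  # spot visible within +/- this axial distance
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    cell_interior_level: float = 100.0  # mean darkfield luminance inside a cell
    outside_level: float = 20.0         # darkfield luminance between cells
    speckle_sigma: float = 0.25         # lognormal sigma of interior texture
    speckle_smooth_px: float = 2.0      # lateral correlation of the texture
    fluor_blur_px: float = 1.0          # optical blur of the fluorescence frames

    def __post_init__(self) -> None:
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")
        if self.z_step_um <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("z_step_um and pixel_pitch_um must be positive")
        if self.pnp_to_background_ratio <= 1:
            raise ValueError("pnp_to_background_ratio must exceed 1")

    @property
    def z_positions_um(self):
        """Axial positions of the slices relative to the equatorial plane."""
        import numpy as np

        return (np.arange(self.z_slices) - self.z_slices // 2) * self.z_step_um


@dataclass
class DetectConfig:
    """Cell finding on the compensated CD45 image."""

    downscale: int = 4
    window_px: int = 351          # local-mean window on the downscaled image
    offset: float = 0.05          # added to the local mean, on the [0, 1] scale
    min_component_px: int = 500   # inclusive, downscaled pixels
    max_component_px: int = 6000  # inclusive
    hough_radius_min: int = 15    # downscaled pixels
    hough_radius_max: int = 35
    connectivity: int = 2         # skimage.measure.label connectivity (2 = 8-connected)
    bbox_rule: str = "center"     # "center": circle centre inside component bbox


@dataclass
class SegmentConfig:
    """UNET contour delineation on 82x82 crops of the CD45 image."""

    crop_px: int = 82
    epochs: int = 150
    learning_rate: float = 1e-3
    batch_size: int = 8
    base_channels: int = 4
    levels: int = 3
    threshold: float = 0.5
    min_area_um2: float = 16.0
    max_area_um2: float = 400.0
    dice_smooth: float = 1.0
    split: Tuple[float, float, float] = (0.5, 0.25, 0.25)


@dataclass
class LineageConfig:
    """Per-fluorochrome positivity and lineage assignment."""

    sd_margin: float = 2.0     # positive iff inside mean > outside mean + margin*SD
    ring_inner_px: int = 5     # outside region: ring between these two dilations
    ring_outer_px: int = 15
    nkt_pair: Tuple[str, str] = ("CD56", "CD14")


@dataclass
class PnpConfig:
    """Nanoparticle detection, 3D linking and multiplet color classification."""

    log_sigmas: Tuple[float, ...] = (2.0, 3.0, 4.0)  # full-resolution pixels
    threshold_mad: float = 8.0   # LoG response threshold, in slice MADs
    dbscan_eps: float = 5.0      # px, in the anisotropy-scaled metric
    z_scale_px_per_slice: float = 2.0  # z spacing in the clustering metric
    min_cluster: int = 3         # inclusive band on 2D members per 3D event
    max_cluster: int = 25
    neighborhood_px: int = 3     # color sampled as an n x n mean
    background_subtract: bool = True
    count_mode: str = "multiplicity"  # or "events"


@dataclass
class StatsConfig:
    """Cohort aggregation and nonparametric statistics."""

    cutoff_low: float = 5.0    # binding stratification cutoffs (PNPs per cell)
    cutoff_high: float = 10.0
    alternative: str = "two-sided"
    outlier_iqr_factor: float = 1.5


@dataclass
class CompensateConfig:
    """Bead-based calibration of the mixing matrix."""

    min_beads: int = 7
    min_bead_px: int = 5          # reject sub-bead noise specks
    background_subtract: bool = True
    pooled_median: bool = True
    rank_rtol: float = 1e-6   # smallest/largest singular value below this -> degenerate


@dataclass
class RunConfig:
    """Complete pipeline configuration, one section per stage."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    compensate: CompensateConfig = field(default_factory=CompensateConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    lineage: LineageConfig = field(default_factory=LineageConfig)
    pnp: PnpConfig = field(default_factory=PnpConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {
            "optics": OpticsConfig,
            "compensate": CompensateConfig,
            "detect": DetectConfig,
            "segment": SegmentConfig,
            "lineage": LineageConfig,
            "pnp": PnpConfig,
            "stats": StatsConfig,
        }
        kwargs = {}
        for name, typ in sections.items():
            if name in d:
                sect = dict(d[name])
                # YAML round-trips tuples as lists
                for f in dataclasses.fields(typ):
                    if name in d and f.name in sect and isinstance(sect[f.name], list):
                        sect[f.name] = tuple(sect[f.name])
                kwargs[name] = typ(**sect)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        """Load from a YAML string or file path."""
        import os

        if isinstance(source, str) and (os.path.exists(source) or "\n" not in source and source.endswith((".yml", ".yaml"))):
            with open(source) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(source)
        return cls.from_dict(d or {})
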