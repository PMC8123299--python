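"""Multi-sample cohort simulation with ground truth.

Per-cell nanoparticle counts are Poisson with a mean that depends on the
cell's lineage and the sample's group (patient or control).  The default
means are the cohort-level averages measured on serous ovarian cancer
patients and healthy donors, so a simulated cohort reproduces the study
conditions: strong patient/control separation for T cells, moderate for
B and NK cells, none for monocytes or NK-T cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ..compensation import CompensationModel
from ..config import OpticsConfig
from ..datatypes import FieldOfView, GroundTruthCell
from ..errors import ParameterError
from .fov import DEFAULT_MIXTURE, LINEAGES, random_cells, render_fov

#: Mean nanoparticles per cell by lineage, per cohort (study-level averages).
DEFAULT_LAMBDA: Dict[str, Dict[str, float]] = {
    "patient": {"NK": 2.86, "T": 4.36, "Monocyte": 27.71, "B": 10.45, "NKT": 9.10},
    "control": {"NK": 1.11, "T": 1.38, "Monocyte": 27.58, "B": 5.19, "NKT": 10.03},
}


@dataclass
class CohortSpec:
    """Design of a simulated two-group cohort."""

    n_samples_per_group: Dict[str, int] = field(
        default_factory=lambda: {"patient": 14, "control": 7}
    )
    cells_per_sample: int = 2000
    cells_per_fov: int = 3
    radius_um_range: tuple = (3.3, 4.8)
    lineage_mixture: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    lambda_by_lineage_and_group: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_LAMBDA.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.lineage_mixture.values())
        if not np.isclose(total, 1.0):
            raise ParameterError(f"lineage mixture sums to {total}, not 1")
        for group, table in self.lambda_by_lineage_and_group.items():
            for lin in self.lineage_mixture:
                if lin not in table:
                    raise ParameterError(
                        f"lambda table for group '{group}' is missing lineage '{lin}'"
                    )
                if table[lin] < 0:
                    raise ParameterError("lambda values must be nonnegative")


@dataclass
class SimulatedSample:
    """Ground truth for one sample: cells grouped into fields of view."""

    sample_id: str
    group: str
    cells_by_fov: List[List[GroundTruthCell]]
    fov_seeds: List[int]
    optics: OpticsConfig

    @property
    def truth(self) -> pd.DataFrame:
        rows = []
        for f, cells in enumerate(self.cells_by_fov):
            for c in cells:
                rows.append(
                    {
                        "sample_id": self.sample_id,
                        "fov_id": f"fov_{f:03d}",
                        "cell_id": c.cell_id,
                        "x_px": c.center_px[0],
                        "y_px": c.center_px[1],
                        "radius_um": c.radius_um,
                        "lineage": c.lineage,
                        "true_count": c.true_count,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "fov_id", "cell_id", "x_px", "y_px",
                "radius_um", "lineage", "true_count",
            ],
        )

    def render_fov(self, index: int, mixing: CompensationModel, **kw) -> FieldOfView:
        return render_fov(
            self.cells_by_fov[index], self.optics, mixing,
            seed=self.fov_seeds[index], **kw,
        )


@dataclass
class CohortDataset:
    """All simulated samples of a cohort plus the pooled ground-truth table."""

    spec: CohortSpec
    samples: List[SimulatedSample]

    @property
    def truth(self) -> pd.DataFrame:
        frames = [s.truth.assign(group=s.group) for s in self.samples]
        return pd.concat(frames, ignore_index=True)


def simulate_cohort(
    spec: CohortSpec, optics: Optional[OpticsConfig] = None
) -> CohortDataset:
    """Draw a full cohort's ground truth; rendering happens lazily per FOV.

    Reproducible: the same spec (including its seed) yields bit-identical
    ground-truth tables and rendering seeds.
    """
    optics = optics or OpticsConfig()
    samples: List[SimulatedSample] = []
    sample_index = 0
    for group in sorted(spec.n_samples_per_group):
        lam = spec.lambda_by_lineage_and_group[group]
        for k in range(spec.n_samples_per_group[group]):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, sample_index])
            )
            n_fovs = int(np.ceil(spec.cells_per_sample / spec.cells_per_fov))
            cells_by_fov, fov_seeds = [], []
            n_left = spec.cells_per_sample
            for f in range(n_fovs):
                n_here = min(spec.cells_per_fov, n_left)
                n_left -= n_here
                cells = random_cells(
                    n_here, optics, rng,
                    radius_um_range=spec.radius_um_range,
                    mixture=spec.lineage_mixture,
                    lambda_by_lineage=lam,
                )
                for j, c in enumerate(cells):
                    c.cell_id = j
                cells_by_fov.append(cells)
                fov_seeds.append(int(rng.integers(2**31)))
            samples.append(
                SimulatedSample(
                    sample_id=f"{group}_{k:02d}",
                    group=group,
                    cells_by_fov=cells_by_fov,
                    fov_seeds=fov_seeds,
                    optics=optics,
                )
            )
            sample_index += 1
    return CohortDataset(spec=spec, samples=samples)


def draw_true_counts(
    spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Ground-truth counts only (no geometry): one row per cell.

    A fast path for statistical tests that need cohort count tables but no
    images.
    """
    rng = rng or np.random.default_rng(spec.seed)
    names = list(spec.lineage_mixture)
    probs = np.asarray([spec.lineage_mixture[k] for k in names])
    rows = []
    for group in sorted(spec.n_samples_per_group):
        lam = spec.lambda_by_lineage_and_group[group]
        for k in range(spec.n_samples_per_group[group]):
            lineages = rng.choice(names, size=spec.cells_per_sample, p=probs)
            counts = rng.poisson([lam[l] for l in lineages])
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": f"{group}_{k:02d}",
                        "group": group,
                        "lineage": lineages,
                        "true_count": counts,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
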