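"""Synthetic field-of-view generator: optical contracts and ground truth."""

import numpy as np
import pytest

from pnpcyto.config import OpticsConfig
from pnpcyto.datatypes import GroundTruthCell, GroundTruthPnp
from pnpcyto.errors import InputError, ParameterError
from pnpcyto.sim import (
    CohortSpec,
    draw_true_counts,
    lineage_abundances,
    random_cells,
    render_fov,
    sample_pnp_events,
    simulate_cohort,
)


def _one_cell(optics, count=0, rng=None, ratio=None):
    rng = rng or np.random.default_rng(0)
    cell = GroundTruthCell(
        center_px=(optics.image_width_px / 2, optics.image_height_px / 2),
        radius_um=4.0,
        lineage="T",
        fluorochrome_abundances=lineage_abundances("T"),
    )
    if count:
        cell.pnp_events = sample_pnp_events(count, cell, optics, rng)
    if ratio is not None:
        cx = optics.image_width_px / 2 * optics.pixel_pitch_um
        cy = optics.image_height_px / 2 * optics.pixel_pitch_um
        m = 1 if ratio <= 1 else (2 if ratio <= 2 else 3)
        cell.pnp_events = [
            GroundTruthPnp(position_um=(cx, cy, 0.0), multiplicity=m,
                           true_color_ratio=ratio)
        ]
    return cell


class TestRenderFov:
    def test_empty_field_is_uniform_background_and_zero_fluorescence(
        self, noise_free_optics, mixing
    ):
        fov = render_fov([], noise_free_optics, mixing, seed=0)
        assert np.all(fov.fluorescence == 0.0)
        lum = fov.darkfield.mean(axis=-1)
        assert np.allclose(lum, noise_free_optics.outside_level)

    def test_single_particle_is_brightest_voxel_at_configured_ratio(
        self, noise_free_optics, mixing
    ):
        """Noise-free, a particle at the equatorial plane peaks at exactly
        pnp_to_background_ratio times the cell-interior luminance."""
        optics = noise_free_optics
        cell = _one_cell(optics, ratio=0.5)
        fov = render_fov([cell], optics, mixing, seed=0)
        lum = fov.darkfield.mean(axis=-1)
        mip = lum.max(axis=0)
        z, y, x = np.unravel_index(lum.argmax(), lum.shape)
        assert (y, x) == (optics.image_height_px // 2, optics.image_width_px // 2)
        assert z == optics.z_slices // 2
        interior = optics.cell_interior_level
        assert mip[y, x] == pytest.approx(
            optics.pnp_to_background_ratio * interior, rel=1e-6
        )

    def test_noise_free_unmixing_recovers_abundances(
        self, noise_free_optics, mixing
    ):
        cell = _one_cell(noise_free_optics)
        fov = render_fov([cell], noise_free_optics, mixing, seed=0)
        a = mixing.unmix(fov.fluorescence)
        cy = noise_free_optics.image_height_px // 2
        cx = noise_free_optics.image_width_px // 2
        assert np.allclose(a[:, cy, cx], cell.fluorochrome_abundances, atol=1e-5)
        assert np.allclose(a[:, 2, 2], 0.0, atol=1e-5)

    def test_center_outside_frame_rejected(self, small_optics, mixing):
        cell = _one_cell(small_optics)
        cell.center_px = (-5.0, 10.0)
        with pytest.raises(InputError):
            render_fov([cell], small_optics, mixing, seed=0)

    def test_overlapping_cells_warn_but_render(self, small_optics, mixing):
        c1 = _one_cell(small_optics)
        c2 = _one_cell(small_optics)
        c2.center_px = (c1.center_px[0] + 10, c1.center_px[1])
        with pytest.warns(UserWarning, match="overlap"):
            fov = render_fov([c1, c2], small_optics, mixing, seed=0)
        assert fov.darkfield is not None

    def test_rendering_is_deterministic_given_seed(self, small_optics, mixing):
        cell = _one_cell(small_optics, count=5)
        a = render_fov([cell], small_optics, mixing, seed=7)
        b = render_fov([cell], small_optics, mixing, seed=7)
        assert np.array_equal(a.darkfield, b.darkfield)
        assert np.array_equal(a.fluorescence, b.fluorescence)
        c = render_fov([cell], small_optics, mixing, seed=8)
        assert not np.array_equal(a.darkfield, c.darkfield)


class TestGroundTruth:
    def test_multiplicity_ratio_intervals_enforced(self):
        with pytest.raises(ValueError):
            GroundTruthPnp(position_um=(0, 0, 0), multiplicity=1, true_color_ratio=1.5)
        with pytest.raises(ValueError):
            GroundTruthPnp(position_um=(0, 0, 0), multiplicity=3, true_color_ratio=2.0)
        GroundTruthPnp(position_um=(0, 0, 0), multiplicity=2, true_color_ratio=1.5)

    def test_event_multiplicities_sum_to_count(self, small_optics, rng):
        cell = _one_cell(small_optics)
        for count in (0, 1, 7, 23):
            events = sample_pnp_events(count, cell, small_optics, rng)
            assert sum(e.multiplicity for e in events) == count

    def test_events_keep_minimum_lateral_separation(self, small_optics, rng):
        cell = _one_cell(small_optics)
        events = sample_pnp_events(20, cell, small_optics, rng, min_sep_um=0.66)
        for i, a in enumerate(events):
            for b in events[i + 1 :]:
                d = np.hypot(a.position_um[0] - b.position_um[0],
                             a.position_um[1] - b.position_um[1])
                assert d >= 0.66 - 1e-9

    def test_abundances_match_lineage(self):
        for lineage, positive in [("T", {"CD45", "CD3"}), ("B", {"CD45", "CD19"}),
                                  ("NKT", {"CD45", "CD56", "CD14"}), ("None", set())]:
            a = lineage_abundances(lineage)
            from pnpcyto.config import MARKERS

            got = {m for m, v in zip(MARKERS, a) if v > 0}
            assert got == positive

    def test_cells_do_not_overlap(self, rng):
        optics = OpticsConfig(image_width_px=512, image_height_px=512)
        cells = random_cells(4, optics, rng, radius_um_range=(3.3, 4.5))
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                d = np.hypot(a.center_px[0] - b.center_px[0],
                             a.center_px[1] - b.center_px[1])
                min_d = (a.radius_um + b.radius_um) / optics.pixel_pitch_um
                assert d >= min_d


class TestCohortSimulation:
    def test_zero_lambda_gives_zero_counts(self):
        spec = CohortSpec(
            n_samples_per_group={"patient": 1, "control": 1},
            cells_per_sample=30,
            lambda_by_lineage_and_group={
                g: {k: 0.0 for k in ("T", "B", "NK", "NKT", "Monocyte")}
                for g in ("patient", "control")
            },
            seed=1,
        )
        ds = simulate_cohort(spec, OpticsConfig(image_width_px=512, image_height_px=512))
        assert (ds.truth["true_count"] == 0).all()

    def test_poisson_mean_recovered_within_three_se(self):
        """10,000 T cells at the patient-cohort mean of 4.36 PNPs/cell."""
        lam = 4.36
        spec = CohortSpec(
            n_samples_per_group={"patient": 1},
            cells_per_sample=10_000,
            lineage_mixture={"T": 1.0},
            lambda_by_lineage_and_group={"patient": {"T": lam}},
            seed=5,
        )
        counts = draw_true_counts(spec)["true_count"]
        se = np.sqrt(lam / len(counts))
        assert abs(counts.mean() - lam) <= 3 * se

    def test_fixed_seed_reproduces_ground_truth_exactly(self):
        optics = OpticsConfig(image_width_px=512, image_height_px=512)
        spec = dict(n_samples_per_group={"patient": 1, "control": 1},
                    cells_per_sample=12, seed=9)
        a = simulate_cohort(CohortSpec(**spec), optics).truth
        b = simulate_cohort(CohortSpec(**spec), optics).truth
        assert a.equals(b)

    def test_missing_lineage_in_lambda_table_rejected(self):
        with pytest.raises(ParameterError, match="missing lineage"):
            CohortSpec(
                lambda_by_lineage_and_group={
                    "patient": {"T": 1.0}, "control": {"T": 1.0}
                }
            )

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            CohortSpec(lineage_mixture={"T": 0.5, "B": 0.2})
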