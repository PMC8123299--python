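"""Nanoparticle blob detection, 3D linking and multiplet color classes."""

import numpy as np
import pytest

from pnpcyto.config import OpticsConfig, PnpConfig
from pnpcyto.datatypes import Pnp2d
from pnpcyto.pnp_quant import (
    classify_color,
    classify_ratio,
    cluster_3d,
    count_cell_pnps,
    detect_blobs_2d,
    quantify_cell,
)
from pnpcyto.sim import render_cell_stack


def brute_force_dbscan(points, eps):
    """Connected components of the eps-neighborhood graph (min_samples=1)."""
    n = len(points)
    labels = -np.ones(n, dtype=int)
    current = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            j = stack.pop()
            for k in range(n):
                if labels[k] < 0:
                    if np.linalg.norm(points[j] - points[k]) <= eps:
                        labels[k] = current
                        stack.append(k)
        current += 1
    return labels


@pytest.fixture(scope="module")
def rendered_cell(mixing):
    optics = OpticsConfig(z_slices=15)
    cell, fov = render_cell_stack(6, optics, mixing, seed=42, radius_um=4.0)
    mask = cell.contour_mask(fov.darkfield.shape[1:3], optics.pixel_pitch_um)
    return cell, fov, mask, optics


class TestDetectBlobs:
    def test_rendered_particles_detected_within_one_pixel(self, rendered_cell):
        cell, fov, mask, optics = rendered_cell
        blobs = detect_blobs_2d(fov.darkfield, mask)
        assert blobs
        for ev in cell.pnp_events:
            ex = ev.position_um[0] / optics.pixel_pitch_um
            ey = ev.position_um[1] / optics.pixel_pitch_um
            near = [
                b for b in blobs
                if np.hypot(b.position_px[0] - ex, b.position_px[1] - ey) <= 1.5
            ]
            assert near, f"no detection near event at ({ex:.1f}, {ey:.1f})"

    def test_particle_outside_mask_rejected(self):
        # constructed noise-free stack: a bright spot at (32, 32)
        stack = np.zeros((7, 64, 64, 3), dtype=np.float32)
        yy, xx = np.mgrid[:64, :64]
        spot = 100.0 * np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / 8.0)
        for s in range(2, 6):
            stack[s] += spot[..., None]
        inside = (xx - 32) ** 2 + (yy - 32) ** 2 <= 12**2
        assert detect_blobs_2d(stack, inside)  # retained inside the contour
        far = np.zeros((64, 64), dtype=bool)
        far[:12, 44:] = True  # contour elsewhere: the spot is rejected
        assert detect_blobs_2d(stack, far) == []

    def test_blank_stack_yields_nothing(self):
        stack = np.zeros((5, 64, 64, 3), dtype=np.float32)
        assert detect_blobs_2d(stack, np.ones((64, 64), bool)) == []


class TestCluster3d:
    CFG = PnpConfig(min_cluster=3, max_cluster=20)

    def test_column_of_detections_becomes_one_event_at_lower_median(self):
        dets = [Pnp2d(s, (50.0, 60.0), 1.0) for s in range(4, 10)]  # 6 slices
        events = cluster_3d(dets, config=self.CFG)
        assert len(events) == 1
        # members sorted by slice; lower median of 6 is the 3rd (index 2)
        assert events[0].coordinate == (50.0, 60.0, 6)
        assert events[0].member_slices == list(range(4, 10))

    def test_too_few_members_excluded(self):
        dets = [Pnp2d(2, (10.0, 10.0), 1.0), Pnp2d(7, (10.0, 10.0), 1.0)]
        assert cluster_3d(dets, config=self.CFG) == []

    def test_too_many_members_excluded(self):
        dets = [Pnp2d(s, (10.0, 10.0), 1.0) for s in range(25)]
        assert cluster_3d(dets, config=self.CFG) == []

    def test_two_distant_particles_stay_separate(self):
        a = [Pnp2d(s, (10.0, 10.0), 1.0) for s in range(3, 8)]
        b = [Pnp2d(s, (30.0, 10.0), 1.0) for s in range(3, 8)]  # 20 px apart
        events = cluster_3d(a + b, config=self.CFG)
        assert len(events) == 2

    def test_grouping_matches_brute_force_dbscan(self, rng):
        cfg = PnpConfig(min_cluster=1, max_cluster=100)
        for trial in range(5):
            r = np.random.default_rng(trial)
            dets = [
                Pnp2d(int(r.integers(0, 10)),
                      (float(r.uniform(0, 60)), float(r.uniform(0, 60))), 1.0)
                for _ in range(40)
            ]
            pts = np.array(
                [[d.position_px[0], d.position_px[1],
                  d.slice_index * cfg.z_scale_px_per_slice] for d in dets]
            )
            ref = brute_force_dbscan(pts, cfg.dbscan_eps)
            events = cluster_3d(dets, config=cfg)
            assert len(events) == len(np.unique(ref))


class TestColorClasses:
    @pytest.mark.parametrize("ratio,cls,mult", [
        (0.5, "green", 1), (1.0, "green", 1),
        (1.5, "yellow", 2), (2.0, "yellow", 2),
        (2.5, "red", 3),
    ])
    def test_decision_regions_with_boundaries(self, ratio, cls, mult):
        assert classify_ratio(ratio) == (cls, mult)

    def test_zero_green_is_red(self):
        stack = np.zeros((3, 9, 9, 3), dtype=np.float32)
        stack[1, 4, 4, 0] = 50.0  # red only
        from pnpcyto.datatypes import PnpDetection

        det = PnpDetection(coordinate=(4.0, 4.0, 1), member_slices=[1])
        out = classify_color(stack, det, PnpConfig(background_subtract=False))
        assert out.color_class == "red" and out.multiplicity == 3

    def test_rendered_ratios_recover_multiplicity(self, mixing):
        optics = OpticsConfig(z_slices=15)
        hits = 0
        total = 0
        for seed in range(4):
            cell, fov = render_cell_stack(8, optics, mixing, seed=seed, radius_um=4.2)
            mask = cell.contour_mask(fov.darkfield.shape[1:3], optics.pixel_pitch_um)
            events, _ = quantify_cell(
                fov.darkfield, mask, optics.z_step_um, optics.pixel_pitch_um
            )
            for ev in events:
                truth = min(
                    cell.pnp_events,
                    key=lambda t: (t.position_um[0] / optics.pixel_pitch_um - ev.coordinate[0]) ** 2
                    + (t.position_um[1] / optics.pixel_pitch_um - ev.coordinate[1]) ** 2,
                )
                total += 1
                hits += truth.multiplicity == ev.multiplicity
        assert total > 0 and hits / total >= 0.9


class TestCounting:
    def test_count_sums_multiplicities(self):
        from pnpcyto.datatypes import PnpDetection

        dets = [
            PnpDetection((0, 0, 0), [0], 0.5, 1, "green"),
            PnpDetection((5, 5, 0), [0], 1.5, 2, "yellow"),
        ]
        assert count_cell_pnps(dets) == 3
        assert count_cell_pnps([]) == 0

    def test_event_mode_counts_events(self):
        from pnpcyto.datatypes import PnpDetection

        dets = [PnpDetection((0, 0, 0), [0], 2.5, 3, "red")] * 2
        assert count_cell_pnps(dets, PnpConfig(count_mode="events")) == 2

    def test_rendered_cell_count_matches_truth(self, rendered_cell):
        cell, fov, mask, optics = rendered_cell
        _, count = quantify_cell(
            fov.darkfield, mask, optics.z_step_um, optics.pixel_pitch_um
        )
        assert abs(count - cell.true_count) <= 1
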