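"""Leveling, step heights, boundary tracing and irregularity metrics."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.draw import disk

from gridmech import topography_analysis as ta
from gridmech.synthetic_data import TopographyConfig, gen_topography
from gridmech.types import BoundaryTrace, TopographyMap


def _square_polyline(center, side, angle=0.0, n=400):
    # n divisible by 4 so the exact corners are included
    half = side / 2.0
    t = np.arange(n) / n * 4.0
    edge = np.floor(t).astype(int)
    frac = t - edge
    u = np.where(edge == 0, -half + 2 * half * frac,
        np.where(edge == 1, half,
        np.where(edge == 2, half - 2 * half * frac, -half)))
    v = np.where(edge == 0, -half,
        np.where(edge == 1, -half + 2 * half * frac,
        np.where(edge == 2, half, half - 2 * half * frac)))
    c, s = np.cos(angle), np.sin(angle)
    return np.column_stack([c * u - s * v, s * u + c * v]) + np.asarray(center)


class TestLevelPlane:
    def test_added_plane_is_removed_exactly(self, flat_topo_cfg):
        topo, _ = gen_topography(flat_topo_cfg)
        jj, ii = np.meshgrid(np.arange(topo.shape[1]), np.arange(topo.shape[0]))
        tilted = TopographyMap(
            heights=topo.heights + 0.01 * jj - 0.02 * ii + 3.0,
            pixel_size=topo.pixel_size,
            masks=topo.masks,
        )
        leveled = ta.level_plane(tilted, "ablated")
        np.testing.assert_allclose(
            leveled.heights - leveled.heights.mean(),
            topo.heights - topo.heights.mean(),
            atol=1e-9,
        )
        assert abs(leveled.heights[leveled.masks["ablated"]].mean()) < 1e-9

    def test_flat_map_changes_by_constant_only(self, flat_topo_cfg):
        topo, _ = gen_topography(flat_topo_cfg)
        leveled = ta.level_plane(topo, "ablated")
        np.testing.assert_allclose(np.ptp(topo.heights - leveled.heights), 0.0, atol=1e-9)

    def test_reference_mean_shrinks_with_sample_size(self):
        cfg = TopographyConfig(seed=9, roughness_sd=0.3)
        topo, _ = gen_topography(cfg)
        leveled = ta.level_plane(topo, "ablated")
        n = topo.masks["ablated"].sum()
        assert abs(leveled.heights[topo.masks["ablated"]].mean()) < 3 * 0.3 / np.sqrt(n)

    def test_degenerate_reference_rejected(self, flat_topo_cfg):
        topo, _ = gen_topography(flat_topo_cfg)
        tiny = np.zeros_like(topo.masks["ablated"])
        tiny[5, 5] = True
        with pytest.raises(ValueError):
            ta.level_plane(topo, tiny)


class TestStepHeight:
    def test_noise_free_steps_recover_layer_thicknesses(self, flat_topo_cfg):
        topo, _ = gen_topography(flat_topo_cfg)
        assert ta.step_height(topo, "passivation", "ablated")[0] == pytest.approx(2.0)
        assert ta.step_height(topo, "pattern", "ablated")[0] == pytest.approx(0.5)

    def test_antisymmetry(self, flat_topo_cfg):
        topo, _ = gen_topography(flat_topo_cfg)
        ab = ta.step_height(topo, "passivation", "ablated")[0]
        ba = ta.step_height(topo, "ablated", "passivation")[0]
        assert ab == -ba

    def test_rough_map_estimate_within_clt_bound(self):
        cfg = TopographyConfig(seed=4, roughness_sd=0.3)
        topo, _ = gen_topography(cfg)
        step, _ = ta.step_height(topo, "passivation", "ablated")
        n = min(topo.masks["passivation"].sum(), topo.masks["ablated"].sum())
        assert abs(step - 2.0) < 3 * 0.3 / np.sqrt(n) * 1.6  # median efficiency factor

    def test_overlapping_masks_rejected(self, flat_topo_cfg):
        topo, _ = gen_topography(flat_topo_cfg)
        topo.masks["bad"] = topo.masks["passivation"].copy()
        with pytest.raises(ValueError, match="overlap"):
            ta.step_height(topo, "passivation", "bad")

    def test_constant_offset_invariance(self, flat_topo_cfg):
        topo, _ = gen_topography(flat_topo_cfg)
        shifted = TopographyMap(topo.heights + 11.0, topo.pixel_size, topo.masks)
        assert ta.step_height(shifted, "pattern", "ablated")[0] == pytest.approx(
            ta.step_height(topo, "pattern", "ablated")[0]
        )


class TestTraceBoundary:
    def test_ideal_square_perimeter(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:150, 50:150] = True  # 100 px side
        trace = ta.trace_boundary(mask)
        # marching squares cuts each corner by (2 - sqrt(2))/2 px
        assert trace.length == pytest.approx(400.0, abs=2.0)

    def test_circle_perimeter_matches_geometry(self):
        mask = np.zeros((200, 200), dtype=bool)
        rr, cc = disk((100, 100), 60)
        mask[rr, cc] = True
        trace = ta.trace_boundary(mask)
        # binary-mask staircase inflates the contour by a few percent
        assert trace.length == pytest.approx(2 * np.pi * 60, rel=0.06)

    def test_wandered_boundary_within_one_pixel_of_truth(self):
        cfg = TopographyConfig(seed=2, edge_wander_sd=50.0)
        topo, truth = gen_topography(cfg)
        trace = ta.trace_boundary(topo)
        h = max(
            cKDTree(truth.polyline).query(trace.polyline)[0].max(),
            cKDTree(trace.polyline).query(truth.polyline)[0].max(),
        )
        assert h <= cfg.pixel_size

    def test_multiply_connected_region_rejected(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:30, 10:30] = True
        mask[60:80, 60:80] = True
        with pytest.raises(ValueError, match="simply connected"):
            ta.trace_boundary(mask)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ta.trace_boundary(np.zeros((50, 50), dtype=bool))


class TestBoundaryIrregularity:
    def test_ideal_square_scores_zero(self):
        trace = BoundaryTrace(_square_polyline((0, 0), 1000.0))
        m = ta.boundary_irregularity(trace)
        assert m["rms_deviation"] == pytest.approx(0.0, abs=1e-6)
        assert m["excess_perimeter"] == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        cfg = TopographyConfig(seed=6, edge_wander_sd=50.0)
        _, truth = gen_topography(cfg)
        base = ta.boundary_irregularity(BoundaryTrace(truth.polyline))
        angle = 0.31
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = BoundaryTrace(truth.polyline @ R.T + np.array([123.0, -456.0]))
        rot = ta.boundary_irregularity(moved)
        assert rot["rms_deviation"] == pytest.approx(base["rms_deviation"], rel=1e-3)
        assert rot["excess_perimeter"] == pytest.approx(base["excess_perimeter"], rel=1e-6)

    def test_traced_wander_rms_matches_configured_sd(self):
        vals = []
        for seed in range(10):
            topo, _ = gen_topography(TopographyConfig(seed=seed, edge_wander_sd=50.0))
            vals.append(ta.boundary_irregularity(ta.trace_boundary(topo))["rms_deviation"])
        assert np.median(vals) == pytest.approx(50.0, rel=0.15)


def test_step_recovery_median_over_seeds():
    """Generator at 2.0/0.5 nm layers, 0.3 nm roughness: both steps within
    0.1 nm, median over 20 seeds."""
    e1, e2 = [], []
    for seed in range(20):
        topo, _ = gen_topography(TopographyConfig(seed=seed, roughness_sd=0.3))
        leveled = ta.level_plane(topo, "ablated")
        e1.append(abs(ta.step_height(leveled, "passivation", "ablated")[0] - 2.0))
        e2.append(abs(ta.step_height(leveled, "pattern", "ablated")[0] - 0.5))
    assert np.median(e1) < 0.1
    assert np.median(e2) < 0.1
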