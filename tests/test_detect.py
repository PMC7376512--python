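"""Hot-spot extraction: invasive restriction, placement oracles,
minimum-cell guarantee, masking, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from sklearn.base import clone

from ki67hotspot.detect import (
    HotspotDetector,
    find_circle_hotspot,
    find_contour_hotspot,
    restrict_to_invasive,
    run_app,
    run_apps,
    score_region,
)
from ki67hotspot.experiments import fuzz_slide, _fuzz_config, _heatmap_pair
from ki67hotspot.heatmap import Heatmap, build_count_heatmap
from ki67hotspot.reference import exhaustive_circle, flood_fill, point_in_polygon, sweep_contour
from ki67hotspot.registry import get_app, post_qc_apps
from ki67hotspot.synthetic import SimulationParams, generate_slide
from ki67hotspot.types import CircleRegion, GridRegion, HotspotConfig

from conftest import make_cells, square_roi


class TestRestrictToInvasive:
    def test_identity_on_tumor_cells_in_one_invasive_roi(self, rng):
        cells = make_cells(rng.uniform(0, 100, (30, 2)))
        out = restrict_to_invasive(cells, [square_roi(0, 0, 100)])
        pd.testing.assert_frame_equal(out, cells)

    def test_ki67_positive_immune_cells_are_removed(self, rng):
        tumor = make_cells(rng.uniform(0, 100, (10, 2)), positive=[True] * 10)
        immune = make_cells(rng.uniform(0, 100, (10, 2)), positive=[True] * 10,
                            cell_class="immune", slide_id="I")
        out = restrict_to_invasive(pd.concat([tumor, immune]),
                                   [square_roi(0, 0, 100)])
        assert (out["cell_class"] == "tumor").all()
        assert len(out) == 10

    def test_in_situ_cells_excluded(self, rng):
        inv = make_cells(rng.uniform(0, 100, (10, 2)), roi_id="r1")
        ins = make_cells(rng.uniform(200, 300, (10, 2)), roi_id="r2",
                         slide_id="D")
        rois = [square_roi(0, 0, 100, "r1", "invasive"),
                square_roi(200, 200, 100, "r2", "in_situ")]
        out = restrict_to_invasive(pd.concat([inv, ins]), rois)
        assert len(out) == 10
        assert (out["roi_id"] == "r1").all()

    def test_no_invasive_roi_warns_and_returns_empty(self, rng):
        cells = make_cells(rng.uniform(0, 100, (5, 2)))
        with pytest.warns(UserWarning, match="no invasive ROI"):
            out = restrict_to_invasive(cells, [square_roi(0, 0, 100, "r1",
                                                          "in_situ")])
        assert out.empty


class TestScoreRegion:
    def test_simple_fractions(self):
        xy = np.column_stack([np.linspace(10, 90, 12), np.full(12, 50.0)])
        cells = make_cells(xy, positive=[True] * 3 + [False] * 9)
        n, npos, idx = score_region(CircleRegion(50, 50, 100), cells)
        assert (n, npos, idx) == (12, 3, 25.0)
        cells_all = make_cells(xy, positive=[True] * 12)
        assert score_region(CircleRegion(50, 50, 100), cells_all)[2] == 100.0

    def test_empty_region_flags_undefined_index(self):
        cells = make_cells([[500.0, 500.0]])
        n, npos, idx = score_region(CircleRegion(50, 50, 10), cells)
        assert n == 0 and math.isnan(idx)

    def test_circle_boundary_is_closed(self):
        cells = make_cells([[60.0, 50.0]], positive=[True])
        assert score_region(CircleRegion(50, 50, 10), cells)[0] == 1

    def test_grid_region_matches_ray_casting_oracle(self, rng):
        bins = rng.uniform(size=(6, 6)) < 0.4
        if not bins.any():
            bins[2, 3] = True
        region = GridRegion((0.0, 0.0), 10.0, bins)
        poly = region.to_polygon()
        pts = rng.uniform(-5, 65, (300, 2))
        inside = region.contains(pts[:, 0], pts[:, 1])
        for (x, y), got in zip(pts, inside):
            polys = getattr(poly, "geoms", [poly])
            expect = any(point_in_polygon(np.asarray(p.exterior.coords)[:-1], x, y)
                         for p in polys)
            assert got == expect, (x, y)


def _component_impl(grid, seed):
    labels, _ = ndimage.label(grid, structure=np.ones((3, 3)))
    return labels == labels[seed]


def test_connected_component_matches_bfs_flood_fill(rng):
    for _ in range(30):
        grid = rng.uniform(size=(15, 15)) < 0.45
        seeds = np.argwhere(grid)
        if not len(seeds):
            continue
        seed = tuple(seeds[rng.integers(len(seeds))])
        assert np.array_equal(_component_impl(grid, seed),
                              flood_fill(grid, seed))


class TestCirclePlacement:
    def test_matches_exhaustive_argmax_on_fuzz(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(25):
            cells = fuzz_slide(rng)
            cfg = HotspotConfig("FUZZ", 200, rng.choice(["20x", "40x"]),
                                "positive", "circle")
            hm, pos_cells, bounds, b = _heatmap_pair(cells, cfg, 1300.0)
            res = find_circle_hotspot(hm, cells, cfg)
            from ki67hotspot.reference import brute_force_count_grid
            xy = cells[["x_um", "y_um"]].to_numpy()
            ref_tot = brute_force_count_grid(xy, cfg.drawing_radius_um, b, bounds)
            ref_pos = brute_force_count_grid(
                pos_cells[["x_um", "y_um"]].to_numpy(), cfg.drawing_radius_um,
                b, bounds)
            ref = exhaustive_circle(ref_pos, ref_tot >= cfg.min_cells,
                                    hm.origin, b, cfg.drawing_radius_um, cells)
            if ref is None:
                assert res.status == "no_valid_hotspot"
            else:
                hits += 1
                (cx, cy), n, npos = ref
                assert (res.region.center_x, res.region.center_y) == (cx, cy)
                assert (res.n_cells, res.n_positive) == (n, npos)
        assert hits >= 5  # the fuzz must actually exercise extraction

    def test_row_major_tie_break(self):
        vals = np.zeros((5, 5))
        vals[3, 1] = vals[1, 3] = 7.0  # tie: (1, 3) wins in row-major order
        hm = Heatmap(vals, (0.0, 0.0), 10.0, "count_positive",
                     np.ones((5, 5), dtype=bool))
        cfg = HotspotConfig("T", 200, "40x", "positive", "circle")
        res = find_circle_hotspot(hm, make_cells([[35.0, 15.0]], [True]), cfg)
        assert (res.region.center_x, res.region.center_y) == (35.0, 15.0)

    def test_circle_region_area_is_exact(self):
        for app_id, diam_mm in (("APP05", 1.04), ("APP24", 0.52)):
            cfg = get_app(app_id)
            region = CircleRegion(0, 0, cfg.drawing_radius_um)
            assert region.area_um2 == math.pi * (diam_mm * 1000 / 2) ** 2


class TestContourExtraction:
    def test_matches_full_sweep_oracle_on_fuzz(self):
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(25):
            cells = fuzz_slide(rng)
            cfg = HotspotConfig("FUZZ", int(rng.choice([200, 400])),
                                rng.choice(["20x", "40x"]),
                                rng.choice(["positive", "ratio"]), "contour")
            hm, _, _, b = _heatmap_pair(cells, cfg, 1300.0)
            res = find_contour_hotspot(hm, cells, cfg)
            ref = sweep_contour(hm.values, hm.mask, hm.origin, b, cells,
                                cfg.min_cells)
            if ref is None:
                assert res.status == "no_valid_hotspot"
            else:
                hits += 1
                comp, n, npos = ref
                assert np.array_equal(res.region.bins, comp)
                assert (res.n_cells, res.n_positive) == (n, npos)
        assert hits >= 5

    def test_minimum_cell_guarantee_on_fuzz(self):
        rng = np.random.default_rng(5)
        n_ok = 0
        for _ in range(60):
            cells = fuzz_slide(rng)
            cfg = _fuzz_config(rng)
            cfg = HotspotConfig("F", cfg.min_cells, cfg.fov, cfg.basis, "contour")
            hm, _, _, _ = _heatmap_pair(cells, cfg, 1300.0)
            res = find_contour_hotspot(hm, cells, cfg)
            if res.status == "ok":
                n_ok += 1
                assert res.n_cells >= cfg.min_cells
        assert n_ok >= 10

    def test_degenerate_threshold_returns_full_support_index(self, rng):
        # min_cells equal to the total count forces the lowest level
        xy = rng.uniform(100, 1100, (400, 2))
        cells = make_cells(xy, positive=rng.uniform(size=400) < 0.3)
        cfg = HotspotConfig("D", 400, "40x", "positive", "contour")
        hm, _, _, _ = _heatmap_pair(cells, cfg, 1300.0)
        res = find_contour_hotspot(hm, cells, cfg)
        assert res.status == "ok"
        assert res.n_cells == 400
        global_index = 100.0 * (cells["ki67_status"] == "positive").mean()
        assert res.ki67_index == pytest.approx(global_index)

    def test_insufficient_support_flags_no_valid_hotspot(self, rng):
        cells = make_cells(rng.uniform(0, 1300, (50, 2)),
                           positive=[True] * 50)
        cfg = HotspotConfig("N", 200, "40x", "positive", "contour")
        hm, _, _, _ = _heatmap_pair(cells, cfg, 1300.0)
        res = find_contour_hotspot(hm, cells, cfg)
        assert res.status == "no_valid_hotspot"


def _radial_fixture():
    """Deterministic rings: positivity fraction strictly decays with radius."""
    pts, pos = [], []
    cx = cy = 1300.0
    for k in range(1, 26):
        r = 52.0 * k
        n_k = max(10, int(round(2 * math.pi * r / 26.0)))
        frac = 0.9 * math.exp(-(r / 900.0) ** 2) + 0.05
        c = int(round(frac * n_k))
        for j in range(n_k):
            ang = 2 * math.pi * j / n_k
            pts.append((cx + r * math.cos(ang), cy + r * math.sin(ang)))
            # spread the positives evenly around the ring
            pos.append((j * c) // n_k != ((j + 1) * c) // n_k)
    return make_cells(pts, positive=pos)


def test_contour_index_non_increasing_in_min_cells():
    cells = _radial_fixture()
    rois = [square_roi(0, 0, 2600)]
    indices = []
    for mc in (200, 400, 600, 800, 1000, 1200):
        cfg = HotspotConfig("M", mc, "40x", "positive", "contour")
        res = run_app(cfg, cells, rois)
        assert res.status == "ok"
        indices.append(res.ki67_index)
    for a, b in zip(indices, indices[1:]):
        assert b <= a + 1e-9


def test_ratio_mask_suppresses_sparse_periphery():
    """A sparse all-positive rim must not beat a dense moderate center."""
    rng = np.random.default_rng(11)
    center = make_cells(rng.normal(650, 110, (500, 2)),
                        positive=rng.uniform(size=500) < 0.3)
    edge_xy = np.column_stack([rng.uniform(1240, 1300, 30),
                               rng.uniform(200, 1100, 30)])
    edge = make_cells(edge_xy, positive=[True] * 30, slide_id="E")
    cells = pd.concat([center, edge], ignore_index=True)
    cfg = HotspotConfig("P", 200, "40x", "ratio", "circle")
    hm, pos_cells, bounds, b = _heatmap_pair(cells, cfg, 1300.0)
    # unmasked, the rim's ratio 1.0 dominates the heatmap
    assert hm.values[~hm.mask].max() > hm.values[hm.mask].max()
    res = find_circle_hotspot(hm, cells, cfg)
    assert res.status == "ok"
    assert res.region.center_x < 1000  # placed at the dense center
    # the supporting bin satisfies the minimum total count
    tot = build_count_heatmap(cells, cfg.drawing_radius_um, b, bounds,
                              "count_total")
    iy, ix, ok = tot.bin_indices([res.region.center_x], [res.region.center_y])
    assert ok.all() and tot.values[iy[0], ix[0]] >= cfg.min_cells


class TestRunApp:
    def test_empty_slide_yields_no_valid_hotspot(self):
        cells = make_cells(np.empty((0, 2)))
        res = run_app(get_app("APP24"), cells, [square_roi(0, 0, 1000)])
        assert res.status == "no_valid_hotspot"

    def test_results_are_deterministic(self):
        params = SimulationParams(n_patients=2, seed=3)
        cells, rois, _ = generate_slide(params, "S1")
        a = run_app(get_app("APP24"), cells, rois)
        b = run_app(get_app("APP24"), cells, rois)
        assert a.n_cells == b.n_cells and a.n_positive == b.n_positive
        assert a.ki67_index == b.ki67_index
        assert np.array_equal(a.region.bins, b.region.bins)

    def test_apps_localize_single_dominant_hotspot(self):
        params = SimulationParams(n_patients=2, seed=21,
                                  baseline_pos_prob=0.03,
                                  hotspot_amplitude_range=(0.6, 0.6),
                                  hotspot_sigma_range_um=(260.0, 260.0))
        cells, rois, truth = generate_slide(params, "S1")
        cx, cy = truth.hotspot_centers[0]
        results = run_apps(post_qc_apps(), cells, rois)
        for app_id, res in results.items():
            if res.status != "ok":
                continue
            cfg = get_app(app_id)
            if isinstance(res.region, CircleRegion):
                px, py = res.region.center_x, res.region.center_y
            else:
                c = res.region.to_polygon().centroid
                px, py = c.x, c.y
            d = math.hypot(px - cx, py - cy)
            assert d <= 2 * cfg.drawing_radius_um, (app_id, d)

    def test_different_apps_may_disagree_on_location(self):
        params = SimulationParams(n_patients=2, seed=8)
        cells, rois, _ = generate_slide(params, "S1")
        res = run_apps([get_app(a) for a in ("APP05", "APP20", "APP24")],
                       cells, rois)
        regions = {a: r.region for a, r in res.items() if r.status == "ok"}
        assert len(regions) == 3  # all extract; geometry types differ
        assert isinstance(regions["APP05"], CircleRegion)
        assert isinstance(regions["APP24"], GridRegion)


class TestHotspotDetectorEstimator:
    def test_sklearn_protocol(self):
        det = HotspotDetector(app="APP13", bin_size=50.0)
        assert det.get_params()["app"] == "APP13"
        cloned = clone(det)
        assert cloned.get_params() == det.get_params()
        det.set_params(app="APP24")
        assert det.app == "APP24"

    def test_fit_exposes_scoring_attributes(self):
        params = SimulationParams(n_patients=2, seed=5)
        cells, rois, _ = generate_slide(params, "S1")
        det = HotspotDetector(app="APP24").fit(cells, rois)
        assert det.status_ == "ok"
        assert det.n_cells_ >= 400
        assert det.ki67_index_ == pytest.approx(
            100.0 * det.n_positive_ / det.n_cells_)
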