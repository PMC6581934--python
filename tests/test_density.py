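"""Whole-section densities, TLS detection, and the maximal-window hotspot."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from icscore import (HOTSPOT_AREA_MM2, NoHotspotError, build_regions,
                     assign_cells, density_table, detect_tls, find_hotspot,
                     summarize_densities, whole_section_density, RegionDensity)

from conftest import cells_frame


WINDOW_R = math.sqrt(HOTSPOT_AREA_MM2 / math.pi)


def _label(cells, geometry):
    return assign_cells(cells, geometry)


# ---------------------------------------------------------------------------
# whole-section


class TestWholeSection:
    def test_direct_ratio(self, circular_geometry):
        # 50 CD3 cells in the core of known area -> count / area
        rng = np.random.default_rng(0)
        pts = rng.normal([10, 10], 0.5, size=(50, 2))
        lab = _label(cells_frame(pts), circular_geometry)
        assert (lab["region"] == "core").all()
        d = whole_section_density(lab, circular_geometry, "CD3", "core")
        assert d.cell_count == 50
        assert d.density == pytest.approx(50 / circular_geometry.core_area_mm2)

    def test_zero_cells_zero_density(self, circular_geometry):
        lab = _label(cells_frame(np.empty((0, 2))), circular_geometry)
        d = whole_section_density(lab, circular_geometry, "CD8", "margin")
        assert d.cell_count == 0 and d.density == 0.0

    def test_overlapping_core_counts_inner_band_cells(self, rng):
        # alternative whole-tumour reading: core density counts cells in
        # the inner margin band too and divides by the full tumour area
        from shapely.geometry import Point, Polygon
        section = Polygon([(0, 0), (20, 0), (20, 20), (0, 20)])
        tumour = Point(10, 10).buffer(3.0, quad_segs=256)
        overlap = build_regions(section, tumour, 0.5,
                                core_includes_inner_margin=True)
        disjoint = build_regions(section, tumour, 0.5)
        pts = np.vstack([
            10 + 0.3 * (rng.random((20, 2)) - 0.5),       # deep core
            [[10 + 2.8, 10], [10, 10 + 2.7]],             # inner band
            [[10 + 3.2, 10]],                              # outer band
        ])
        lab_o = assign_cells(cells_frame(pts), overlap)
        lab_d = assign_cells(cells_frame(pts), disjoint)
        assert list(lab_o["region"]) == list(lab_d["region"])  # partition unchanged
        d_over = whole_section_density(lab_o, overlap, "CD3", "core")
        d_disj = whole_section_density(lab_d, disjoint, "CD3", "core")
        assert d_over.cell_count == 22      # inner-band cells included
        assert d_disj.cell_count == 20
        assert d_over.area_mm2 == pytest.approx(tumour.area)

    def test_poisson_rate_recovery(self, circular_geometry, rng):
        # homogeneous Poisson at 400 cells/mm² in the core: the estimator is
        # unbiased with SE sqrt(lambda/area) per replicate
        lam = 400.0
        area = circular_geometry.core_area_mm2
        reps = 50
        est = []
        from icscore.geometry import sample_points_in
        for _ in range(reps):
            n = rng.poisson(lam * area)
            pts = sample_points_in(circular_geometry.core_region, n, rng)
            lab = _label(cells_frame(pts), circular_geometry)
            est.append(whole_section_density(lab, circular_geometry, "CD3", "core").density)
        se = math.sqrt(lam / area / reps)
        assert np.mean(est) == pytest.approx(lam, abs=3 * se)


# ---------------------------------------------------------------------------
# TLS detection


def _tls_brute_force(xy, min_cells, radius):
    """Independent oracle: neighbour counts by full pairwise distances."""
    xy = np.asarray(xy)
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
    return (d <= radius).sum(axis=1)  # includes self


class TestDetectTLS:
    def test_tight_cluster_is_one_zone(self, rng):
        # 60 cells uniform in a 0.1 mm-diameter disk: all pairwise
        # distances are below the 0.15 mm neighbourhood radius
        rad = 0.05 * np.sqrt(rng.random(60))
        ang = rng.uniform(0, 2 * math.pi, 60)
        pts = np.column_stack([5 + rad * np.cos(ang), 5 + rad * np.sin(ang)])
        zones = detect_tls(cells_frame(pts), min_cells=50, radius_mm=0.15)
        assert len(zones) == 1
        assert zones[0].member_cell_count == 60
        # oracle: every point has all 60 neighbours within the radius
        assert (_tls_brute_force(pts, 50, 0.15) >= 50).all()

    def test_uniform_background_yields_no_zones(self, rng):
        # 100 cells/mm² over 25 mm²: expected neighbours per disk
        # ~ 100·π·0.15² ≈ 7 « 50
        pts = rng.uniform(0, 5, size=(2500, 2))
        assert detect_tls(cells_frame(pts)) == []
        assert (_tls_brute_force(pts, 50, 0.15) < 50).all()

    def test_empty_input(self):
        assert detect_tls(cells_frame(np.empty((0, 2)))) == []

    def test_zone_polygons_have_positive_area(self, rng):
        pts = 0.04 * rng.standard_normal((80, 2)) + [2, 2]
        zones = detect_tls(cells_frame(pts), min_cells=40, radius_mm=0.15)
        assert zones and all(z.polygon.area > 0 for z in zones)


# ---------------------------------------------------------------------------
# hotspot search


def _exact_hotspot_count(xy, r):
    """Exact maximal window count by the covering argument, O(n³)-naive.

    Candidate centres: every cell and both circumcentres of every pair of
    cells within 2r; counts by explicit distance checks.
    """
    xy = np.asarray(xy, dtype=float)
    cands = [xy]
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            d = np.linalg.norm(xy[j] - xy[i])
            if 0 < d <= 2 * r:
                mid = (xy[i] + xy[j]) / 2
                h = math.sqrt(max(r * r - (d / 2) ** 2, 0.0))
                perp = np.array([-(xy[j] - xy[i])[1], (xy[j] - xy[i])[0]]) / d
                cands.append(np.array([mid + h * perp, mid - h * perp]))
    cands = np.concatenate(cands)
    dist = np.linalg.norm(xy[None, :, :] - cands[:, None, :], axis=-1)
    return int((dist <= r * (1 + 1e-9)).sum(axis=1).max())


def _fine_grid_count(xy, r, bounds, step=0.01):
    xs = np.arange(bounds[0], bounds[2] + step, step)
    ys = np.arange(bounds[1], bounds[3] + step, step)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    from scipy.spatial import cKDTree
    return int(cKDTree(np.asarray(xy)).query_ball_point(
        grid, r * (1 + 1e-9), return_length=True).max())


class TestFindHotspot:
    def test_single_cluster_all_in_window(self, circular_geometry, rng):
        # 10 cells inside a 0.1 mm-radius cluster fit in one 0.28 mm² window
        pts = 10 + 0.1 * (rng.random((10, 2)) - 0.5)
        lab = _label(cells_frame(pts), circular_geometry)
        hs = find_hotspot(lab, circular_geometry, "CD3", "core")
        assert hs.cell_count == 10
        assert hs.density == pytest.approx(10 / 0.28, rel=1e-9)
        assert hs.window_radius_mm == pytest.approx(0.2985, abs=5e-4)

    def test_default_window_area(self):
        assert HOTSPOT_AREA_MM2 == 0.28

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exact_and_fine_grid_oracles(self, seed):
        # random small instances in a generous region: the returned count
        # must equal the exact covering-argument maximum and be at least
        # the 0.01 mm fine-grid brute force
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 140))
        pts = rng.uniform(8.6, 11.4, size=(n, 2))  # well inside the core
        geo = build_regions(Polygon([(0, 0), (20, 0), (20, 20), (0, 20)]),
                            Point(10, 10).buffer(3.0, quad_segs=64), 0.5)
        lab = _label(cells_frame(pts), geo)
        hs = find_hotspot(lab, geo, "CD3", "core")
        exact = _exact_hotspot_count(pts, WINDOW_R)
        grid = _fine_grid_count(pts, WINDOW_R, (8.0, 8.0, 12.0, 12.0))
        assert hs.cell_count == exact
        assert hs.cell_count >= grid

    def test_tls_exclusion_moves_window(self, circular_geometry, rng):
        from icscore import TLSZone
        dense = 10 + 0.05 * (rng.random((40, 2)) - 0.5)        # inside TLS
        sparse = np.array([[8.5, 10.0], [8.55, 10.0], [8.5, 10.05]])  # in core
        lab = _label(cells_frame(np.vstack([dense, sparse])), circular_geometry)
        tls = [TLSZone(0, Point(10, 10).buffer(0.2), 40)]
        hs = find_hotspot(lab, circular_geometry, "CD3", "core", tls_zones=tls)
        assert hs.cell_count == 3                       # the dense patch is off-limits
        assert 0 in hs.excluded_tls_ids
        # window disk must clear the TLS polygon
        assert Point(hs.centre).distance(tls[0].polygon) >= hs.window_radius_mm - 1e-9

    def test_no_admissible_placement_raises(self, circular_geometry):
        from icscore import TLSZone
        # TLS blankets the entire core: no window can avoid it
        tls = [TLSZone(0, Point(10, 10).buffer(4.0), 1)]
        lab = _label(cells_frame([(10, 10)]), circular_geometry)
        with pytest.raises(NoHotspotError):
            find_hotspot(lab, circular_geometry, "CD3", "core", tls_zones=tls)

    def test_tie_break_prefers_smaller_xy(self, circular_geometry):
        # two isolated single cells give many count-1 windows; the
        # smallest-(x, y) rule must settle on one covering the lower-left
        # cell, deterministically
        lab = _label(cells_frame([(11, 11), (9, 9)]), circular_geometry)
        hs = find_hotspot(lab, circular_geometry, "CD3", "core")
        hs2 = find_hotspot(lab, circular_geometry, "CD3", "core")
        assert hs.cell_count == 1
        assert math.dist(hs.centre, (9, 9)) <= hs.window_radius_mm * (1 + 1e-9)
        assert hs.centre == hs2.centre


# ---------------------------------------------------------------------------
# summaries


class TestSummaries:
    def test_order_statistics(self):
        rows = [RegionDensity("P%d" % i, "CD3", "core", "whole_section", c, 1.0)
                for i, c in enumerate((1, 2, 3, 4, 5))]
        summary, _ = summarize_densities(density_table(rows))
        s = summary.iloc[0]
        assert (s["median"], s["q1"], s["q3"], s["min"], s["max"]) == (3, 2, 4, 1, 5)

    def test_identical_techniques_not_computable(self):
        rows = []
        for i in range(5):
            rows.append(RegionDensity(f"P{i}", "CD3", "core", "whole_section", 7, 1.0))
            rows.append(RegionDensity(f"P{i}", "CD3", "core", "hotspot", 7, 1.0))
        summary, comp = summarize_densities(density_table(rows))
        assert not comp.iloc[0]["computable"]

    def test_quartile_ordering_invariant(self, rng):
        rows = [RegionDensity(f"P{i}", m, r, t, int(c), 1.0)
                for i, (m, r, t, c) in enumerate(
                    (m, r, t, rng.integers(0, 500))
                    for m in ("CD3", "CD8") for r in ("core", "margin")
                    for t in ("whole_section", "hotspot") for _ in range(9))]
        summary, _ = summarize_densities(density_table(rows))
        for _, s in summary.iterrows():
            assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]
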