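"""Immune cell densities: whole-section averages and maximal fixed-area hotspots.

Two measurement techniques are implemented for CD3⁺/CD8⁺ cell densities in
the tumour core and invasive margin:

* ``whole_section``: cells of a marker in a compartment divided by the
  compartment area — the whole-slide average a digital full-section count
  produces.
* ``hotspot``: the maximal count over circular windows of fixed area
  (default 0.28 mm², the punch size of a tissue-microarray core), placed
  inside the compartment and kept clear of tertiary lymphoid structures
  (TLS), divided by the window area.  This emulates picking the densest
  TMA-like spot on the slide.

The hotspot search is an exact maximisation over a finite candidate set:
windows centred on every in-compartment cell of the marker plus a 0.1 mm
grid over the compartment.  For point data a cell-centred window attains
the maximal count up to boundary clipping, which the grid catches; a fine
grid brute force serves as the oracle in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon
from shapely.geometry.base import BaseGeometry
from sklearn.cluster import DBSCAN

from .geometry import TissueGeometry

__all__ = [
    "RegionDensity",
    "HotspotResult",
    "TLSZone",
    "NoHotspotError",
    "whole_section_density",
    "detect_tls",
    "find_hotspot",
    "density_table",
    "summarize_densities",
    "HOTSPOT_AREA_MM2",
]

#: fixed hotspot window area, mm² (the TMA punch cross-section).
HOTSPOT_AREA_MM2 = 0.28

#: spacing of the auxiliary candidate-centre grid, mm.
_GRID_STEP_MM = 0.1

TECHNIQUES = ("whole_section", "hotspot")


class NoHotspotError(RuntimeError):
    """No admissible hotspot placement exists for the compartment."""


@dataclass(frozen=True)
class RegionDensity:
    """Density of one (patient, marker, region, technique) combination."""

    patient_id: str
    marker: str
    region: str
    technique: str
    cell_count: int
    area_mm2: float
    @property
    def density(self) -> float:
        return self.cell_count / self.area_mm2


@dataclass(frozen=True)
class TLSZone:
    """A tertiary lymphoid structure: an organised dense lymphoid aggregate."""

    zone_id: int
    polygon: BaseGeometry
    member_cell_count: int


@dataclass(frozen=True)
class HotspotResult:
    """Maximal fixed-area window for one (patient, marker, region)."""

    centre: tuple[float, float]
    window_radius_mm: float
    cell_count: int
    n_candidates_evaluated: int
    excluded_tls_ids: tuple[int, ...]
    @property
    def window_area_mm2(self) -> float:
        return math.pi * self.window_radius_mm**2
    @property
    def density(self) -> float:
        return self.cell_count / self.window_area_mm2


def whole_section_density(
    labelled_cells: pd.DataFrame,
    geometry: TissueGeometry,
    marker: str,
    region: str,
    patient_id: str = "",
) -> RegionDensity:
    """Average density of a marker over a whole compartment.

    ``labelled_cells`` must carry the ``region`` column from
    :func:`icscore.geometry.assign_cells`.  Under the alternative
    overlapping-core reading (``geometry.overlapping_core``) the core
    count also includes margin-labelled cells lying inside the tumour
    and is normalised by the full tumour area; the default keeps the
    compartments disjoint.
    """
    of_marker = labelled_cells["marker"] == marker
    in_region = labelled_cells["region"] == region
    if region == "core" and geometry.overlapping_core:
        area = geometry.tumour_boundary.area
        margin_cells = labelled_cells["region"] == "margin"
        inner = pd.Series(False, index=labelled_cells.index)
        if margin_cells.any():
            idx = labelled_cells.index[margin_cells]
            pts = shapely.points(
                labelled_cells.loc[idx, "x_mm"].to_numpy(float),
                labelled_cells.loc[idx, "y_mm"].to_numpy(float))
            inner.loc[idx[shapely.covers(geometry.tumour_boundary, pts)]] = True
        in_region = in_region | inner
    else:
        area = geometry.region_area(region)
    if area <= 0:
        raise ValueError(f"region {region!r} has zero area")
    n = int((of_marker & in_region).sum())
    return RegionDensity(patient_id, marker, region, "whole_section", n, area)


def detect_tls(
    cells: pd.DataFrame, min_cells: int = 50, radius_mm: float = 0.15
) -> list[TLSZone]:
    """Detect tertiary lymphoid structures by density-connected clustering.

    All immune cells (both markers) are clustered with neighbourhood radius
    ``radius_mm``; a cluster qualifies when it has a core point with at
    least ``min_cells`` cells within that radius (the point itself
    included).  Each qualifying cluster is returned as its convex hull.
    """
    if min_cells <= 0 or radius_mm <= 0:
        raise ValueError("min_cells and radius_mm must be positive")
    if len(cells) < min_cells:
        return []
    xy = cells[["x_mm", "y_mm"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=radius_mm, min_samples=min_cells).fit_predict(xy)
    zones: list[TLSZone] = []
    for zid in sorted(set(labels) - {-1}):
        member = xy[labels == zid]
        hull = shapely.MultiPoint(member).convex_hull
        if hull.area <= 0:  # degenerate (collinear) cluster
            hull = hull.buffer(0.01)
        zones.append(TLSZone(int(zid), hull, int(len(member))))
    return zones


#: above this many in-region cells, pair-circumcentre candidates are skipped
#: and the search relies on cell centres plus the coarse grid.
_PAIR_CELL_LIMIT = 1500
_PAIR_COUNT_LIMIT = 60_000


def _pair_candidates(cell_xy: np.ndarray, r: float) -> np.ndarray:
    """Centres of radius-r circles through each pair of cells within 2r.

    By the classical covering argument a maximal-count disk can be
    translated until its boundary touches two points (or it covers a
    single point), so cell centres plus these circumcentres contain an
    exact maximiser.  Only used on small instances; the pipeline-scale
    search uses cells plus the coarse grid.
    """
    if len(cell_xy) < 2 or len(cell_xy) > _PAIR_CELL_LIMIT:
        return np.empty((0, 2))
    pairs = cKDTree(cell_xy).query_pairs(2 * r, output_type="ndarray")
    if len(pairs) == 0 or len(pairs) > _PAIR_COUNT_LIMIT:
        return np.empty((0, 2))
    p, q = cell_xy[pairs[:, 0]], cell_xy[pairs[:, 1]]
    d = np.linalg.norm(q - p, axis=1)
    ok = d > 1e-12
    p, q, d = p[ok], q[ok], d[ok]
    mid = (p + q) / 2
    h = np.sqrt(np.maximum(r * r - (d / 2) ** 2, 0.0))
    perp = np.column_stack([-(q - p)[:, 1], (q - p)[:, 0]]) / d[:, None]
    return np.concatenate([mid + h[:, None] * perp, mid - h[:, None] * perp])


def _candidate_centres(
    cell_xy: np.ndarray, region: BaseGeometry, r: float
) -> np.ndarray:
    minx, miny, maxx, maxy = region.bounds
    gx = np.arange(minx, maxx + _GRID_STEP_MM, _GRID_STEP_MM)
    gy = np.arange(miny, maxy + _GRID_STEP_MM, _GRID_STEP_MM)
    gxx, gyy = np.meshgrid(gx, gy)
    grid = np.column_stack([gxx.ravel(), gyy.ravel()])
    parts = [grid]
    if len(cell_xy):
        parts.append(cell_xy)
        parts.append(_pair_candidates(cell_xy, r))
    cand = np.concatenate(parts)
    inside = shapely.covers(region, shapely.points(cand[:, 0], cand[:, 1]))
    return cand[inside]


def find_hotspot(
    labelled_cells: pd.DataFrame,
    geometry: TissueGeometry,
    marker: str,
    region: str,
    window_area_mm2: float = HOTSPOT_AREA_MM2,
    tls_zones: list[TLSZone] | None = None,
) -> HotspotResult:
    """Maximal-count circular window of fixed area inside a compartment.

    The window centre must lie inside the compartment and the full window
    disk must be disjoint from every TLS zone; only the centre is required
    inside because the invasive margin is a narrow band in which full-disk
    containment would rule out almost every placement.  Counted cells are
    the marker's cells labelled with the compartment.  Ties are broken by
    higher count, then smaller centre x, then smaller centre y.

    Raises
    ------
    NoHotspotError
        When no candidate centre survives the TLS-exclusion constraint;
        the caller records the patient as missing for that component.
    """
    if window_area_mm2 <= 0:
        raise ValueError("window_area_mm2 must be positive")
    tls_zones = tls_zones or []
    r = math.sqrt(window_area_mm2 / math.pi)
    reg = geometry.region(region)
    sel = (labelled_cells["marker"] == marker) & (labelled_cells["region"] == region)
    cell_xy = labelled_cells.loc[sel, ["x_mm", "y_mm"]].to_numpy(dtype=float)
    cand = _candidate_centres(cell_xy, reg, r)
    excluded: list[int] = []
    if len(cand) and tls_zones:
        pts = shapely.points(cand[:, 0], cand[:, 1])
        ok = np.ones(len(cand), dtype=bool)
        for z in tls_zones:
            near = shapely.dwithin(z.polygon, pts, r)  # disk touches the TLS
            if near.any():
                excluded.append(z.zone_id)
                ok &= ~near
        cand = cand[ok]
    if len(cand) == 0:
        raise NoHotspotError(
            f"no admissible {window_area_mm2} mm² window in region {region!r}"
        )
    if len(cell_xy):
        # tiny radius inflation so a cell exactly on the window boundary
        # (e.g. under a circumcentre candidate) counts despite rounding
        counts = cKDTree(cell_xy).query_ball_point(
            cand, r * (1 + 1e-9), return_length=True)
    else:
        counts = np.zeros(len(cand), dtype=int)
    # lexsort: last key dominates -> maximal count, then smallest x, then y
    best = np.lexsort((cand[:, 1], cand[:, 0], -counts))[0]
    return HotspotResult(
        centre=(float(cand[best, 0]), float(cand[best, 1])),
        window_radius_mm=r,
        cell_count=int(counts[best]),
        n_candidates_evaluated=int(len(cand)),
        excluded_tls_ids=tuple(excluded),
    )


def density_table(densities: list[RegionDensity]) -> pd.DataFrame:
    """Tidy table of densities, one row per (patient, marker, region, technique)."""
    return pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in densities],
            "marker": [d.marker for d in densities],
            "region": [d.region for d in densities],
            "technique": [d.technique for d in densities],
            "cell_count": [d.cell_count for d in densities],
            "area_mm2": [d.area_mm2 for d in densities],
            "density": [d.density for d in densities],
        }
    )


def summarize_densities(densities: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum distribution summaries and hotspot-vs-whole-section tests.

    Parameters
    ----------
    densities : DataFrame
        Tidy density table (see :func:`density_table`).

    Returns
    -------
    summary : DataFrame
        One row per (marker, region, technique) stratum with ``n``,
        ``median``, ``q1``, ``q3`` (linear-interpolation quartiles),
        ``min``, ``max``.
    comparison : DataFrame
        One row per (marker, region): paired two-sided Wilcoxon
        signed-rank test of hotspot vs whole-section density across
        patients.  Pairs with fewer than two patients, or with every
        paired difference zero, are flagged ``computable = False``.
    """
    rows = []
    for (marker, region, technique), grp in densities.groupby(
        ["marker", "region", "technique"], sort=True
    ):
        v = grp["density"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            dict(marker=marker, region=region, technique=technique, n=len(v),
                 median=med, q1=q1, q3=q3, min=v.min(), max=v.max())
        )
    summary = pd.DataFrame(rows)

    comp_rows = []
    wide = densities.pivot_table(
        index=["patient_id", "marker", "region"], columns="technique",
        values="density", aggfunc="first",
    ).reset_index()
    for (marker, region), grp in wide.groupby(["marker", "region"], sort=True):
        row = dict(marker=marker, region=region, computable=False,
                   n_pairs=0, statistic=np.nan, p_value=np.nan)
        if {"hotspot", "whole_section"} <= set(grp.columns):
            paired = grp.dropna(subset=["hotspot", "whole_section"])
            diff = paired["hotspot"].to_numpy() - paired["whole_section"].to_numpy()
            row["n_pairs"] = int(len(diff))
            if len(diff) >= 2 and np.any(diff != 0):
                stat, p = wilcoxon(diff[diff != 0])  # ties dropped (exact convention)
                row.update(computable=True, statistic=float(stat), p_value=float(p))
        comp_rows.append(row)
    comparison = pd.DataFrame(comp_rows)
    return summary, comparison
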