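"""Plain-text interchange formats: cell CSV, geometry GeoJSON, cohort CSV.

GeoJSON features carry ``properties.role`` ∈ {section, tumour, tls};
coordinates are planar millimetres (no CRS).  Every stage of the
pipeline reads and writes these formats so each stage is independently
re-runnable.
"""

from __future__ import annotations

import json

import pandas as pd
from shapely.geometry import mapping, shape

from .density import TLSZone
from .geometry import TissueGeometry, build_regions

__all__ = [
    "write_cells", "read_cells",
    "write_geometry", "read_geometry",
    "write_cohort", "read_cohort",
]

CELL_COLUMNS = ["patient_id", "marker", "x_mm", "y_mm"]


def write_cells(cells: pd.DataFrame, path) -> None:
    cells[CELL_COLUMNS].to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = set(CELL_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell CSV missing columns: {sorted(missing)}")
    return cells


def write_geometry(
    geometry: TissueGeometry, tls_zones: list[TLSZone], path
) -> None:
    features = [
        {"type": "Feature", "properties": {"role": "section"},
         "geometry": mapping(geometry.section_outline)},
        {"type": "Feature", "properties": {"role": "tumour",
                                           "margin_half_width_mm":
                                           geometry.margin_half_width_mm},
         "geometry": mapping(geometry.tumour_boundary)},
    ]
    for z in tls_zones:
        features.append(
            {"type": "Feature",
             "properties": {"role": "tls", "zone_id": z.zone_id,
                            "member_cell_count": z.member_cell_count},
             "geometry": mapping(z.polygon)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geometry(path, margin_half_width_mm: float | None = None
                  ) -> tuple[TissueGeometry, list[TLSZone]]:
    """Rebuild a TissueGeometry (and TLS zones) from a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    section = tumour = None
    stored_half_width = None
    tls: list[TLSZone] = []
    for feat in doc.get("features", []):
        role = feat.get("properties", {}).get("role")
        geom = shape(feat["geometry"])
        if role == "section":
            section = geom
        elif role == "tumour":
            tumour = geom
            stored_half_width = feat["properties"].get("margin_half_width_mm")
        elif role == "tls":
            props = feat["properties"]
            tls.append(TLSZone(int(props.get("zone_id", len(tls))), geom,
                               int(props.get("member_cell_count", 0))))
    if section is None or tumour is None:
        raise ValueError("GeoJSON must contain one 'section' and one 'tumour' feature")
    half = margin_half_width_mm or stored_half_width or 0.5
    return build_regions(section, tumour, half), tls


COHORT_REQUIRED = ["patient_id", "time_months", "event_os", "event_dss"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(COHORT_REQUIRED) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return cohort
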