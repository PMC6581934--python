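"""Synthetic digital-pathology cohort generator.

Generates, per patient, a tissue geometry (section outline and an
irregular tumour boundary), a marked planar point pattern of CD3⁺/CD8⁺
cells, tertiary lymphoid structures, clinicopathological covariates and
survival outcomes, with the statistical structure the downstream
analysis assumes:

* a standard-normal latent immune level per patient multiplies all
  baseline region intensities by ``exp(latent)``;
* the cell pattern is an inhomogeneous Poisson background plus a
  Thomas-type cluster process of lymphoid aggregates (whose rate does
  not depend on the latent level — the sampling-noise mechanism that
  makes the hotspot maximum a poor readout) plus dense TLS disks;
* death times are exponential with rate
  ``baseline_hazard × exp(−β × latent)``, independently censored.

Determinism: every random draw derives from ``(config.seed,
patient_index, stream)`` through ``numpy.random.SeedSequence``, so a
patient's tissue is reproducible in isolation and the whole cohort is
bit-identical under a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .config import SimulationConfig
from .geometry import TissueGeometry, build_regions, sample_points_in
from .density import TLSZone

__all__ = ["PatientTruth", "simulate_tissue", "simulate_cohort", "patient_label"]

_STREAM_LATENT = 0
_STREAM_TISSUE = 1
_STREAM_OUTCOME = 2


def patient_label(index: int) -> str:
    return f"P{index:03d}"


@dataclass
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    latent_immune_level: float
    true_density: dict          # marker -> region -> cells/mm² (realised intensity)
    survival_time_months: float
    event_overall: int
    event_disease_specific: int
    covariates: dict


def _rng(config: SimulationConfig, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed) & 0x7FFFFFFF,
                               spawn_key=(index, stream))
    )


def latent_immune_level(config: SimulationConfig, index: int) -> float:
    """Deterministic per-patient latent level (shared across streams)."""
    return float(_rng(config, index, _STREAM_LATENT).normal(0.0, config.latent_sd))


def _tumour_polygon(config: SimulationConfig, rng: np.random.Generator) -> Polygon:
    """Circle with low-order Fourier radial perturbation; retried until simple."""
    cx = config.section_width_mm / 2
    cy = config.section_height_mm / 2
    base_r = config.tumour_radius_mm * (
        1 + config.tumour_radius_jitter * rng.uniform(-1, 1)
    )
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    for _ in range(100):
        r = np.full_like(theta, base_r)
        for k in (2, 3, 4):
            amp = config.boundary_irregularity * base_r * rng.uniform(-1, 1) / k
            phase = rng.uniform(0, 2 * np.pi)
            r = r + amp * np.cos(k * theta + phase)
        if np.any(r <= 0):
            continue
        poly = Polygon(np.column_stack([cx + r * np.cos(theta),
                                        cy + r * np.sin(theta)]))
        if poly.is_valid and poly.area > 0:
            return poly
    raise RuntimeError("could not generate a simple tumour boundary in 100 attempts")


def simulate_tissue(
    config: SimulationConfig, patient_index: int
) -> tuple[TissueGeometry, pd.DataFrame, list[TLSZone]]:
    """Generate one patient's geometry, cell map, and TLS zones.

    Returns the tissue geometry, a cell DataFrame (``patient_id``,
    ``marker``, ``x_mm``, ``y_mm``) with every cell inside the section
    outline, and the TLS zones as polygons.
    """
    config.validate()
    rng = _rng(config, patient_index, _STREAM_TISSUE)
    latent = latent_immune_level(config, patient_index)
    pid = patient_label(patient_index)

    section = Polygon([(0, 0), (config.section_width_mm, 0),
                       (config.section_width_mm, config.section_height_mm),
                       (0, config.section_height_mm)])
    tumour = _tumour_polygon(config, rng)
    geometry = build_regions(section, tumour, config.margin_half_width_mm)

    outside = section.difference(tumour.union(geometry.margin_region))
    region_geoms = {"core": geometry.core_region,
                    "margin": geometry.margin_region,
                    "outside": outside}

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    markers: list[np.ndarray] = []

    # (a) inhomogeneous Poisson background, intensity scaled by exp(latent)
    scale = np.exp(latent)
    for marker in ("CD3", "CD8"):
        for region, geom in region_geoms.items():
            lam0 = config.baseline_intensity.get(marker, {}).get(region, 0.0)
            noise = np.exp(rng.normal(0.0, config.component_noise_sd))
            lam = lam0 * scale * noise
            n = rng.poisson(lam * geom.area) if lam > 0 and geom.area > 0 else 0
            if n:
                pts = sample_points_in(geom, n, rng)
                xs.append(pts[:, 0]); ys.append(pts[:, 1])
                markers.append(np.full(n, marker, dtype=object))

    # (b) Thomas-type cluster process: lymphoid aggregates in tumour ∪ margin
    agg_domain = tumour.union(geometry.margin_region)
    n_agg = rng.poisson(config.aggregate_rate * agg_domain.area)
    if n_agg:
        parents = sample_points_in(agg_domain, n_agg, rng)
        for px, py in parents:
            # per-aggregate expected size is lognormal (mean preserved):
            # lymphoid aggregates vary widely, and the hotspot maximum is
            # dominated by the largest one — the sampling-noise mechanism
            sigma = config.aggregate_size_dispersion
            mean_i = config.aggregate_mean_size * np.exp(
                rng.normal(0.0, sigma) - sigma**2 / 2)
            m = rng.poisson(mean_i)
            if m == 0:
                continue
            off = rng.normal(0.0, config.aggregate_sd_mm, size=(m, 2))
            cx_, cy_ = px + off[:, 0], py + off[:, 1]
            is_cd3 = rng.random(m) < config.aggregate_cd3_fraction
            xs.append(cx_); ys.append(cy_)
            markers.append(np.where(is_cd3, "CD3", "CD8").astype(object))

    # (c) TLS: dense disks, centres on the margin band
    tls_zones: list[TLSZone] = []
    n_tls = rng.poisson(config.tls_rate)
    for zid in range(n_tls):
        centre = sample_points_in(geometry.margin_region, 1, rng)[0]
        disk = Point(centre).buffer(config.tls_radius_mm, quad_segs=16)
        rr = config.tls_radius_mm * np.sqrt(rng.random(config.tls_cells))
        aa = rng.uniform(0, 2 * np.pi, config.tls_cells)
        xs.append(centre[0] + rr * np.cos(aa)); ys.append(centre[1] + rr * np.sin(aa))
        is_cd3 = rng.random(config.tls_cells) < config.tls_cd3_fraction
        markers.append(np.where(is_cd3, "CD3", "CD8").astype(object))
        tls_zones.append(TLSZone(zid, disk, int(config.tls_cells)))

    if xs:
        x = np.concatenate(xs); y = np.concatenate(ys)
        marker = np.concatenate(markers)
        keep = shapely.contains_xy(section, x, y)  # clip strays to the section
        cells = pd.DataFrame({"patient_id": pid, "marker": marker[keep],
                              "x_mm": x[keep], "y_mm": y[keep]})
    else:
        cells = pd.DataFrame({"patient_id": pd.Series([], dtype=object),
                              "marker": pd.Series([], dtype=object),
                              "x_mm": pd.Series([], dtype=float),
                              "y_mm": pd.Series([], dtype=float)})
    cells = cells.reset_index(drop=True)
    return geometry, cells, tls_zones


def simulate_cohort(
    config: SimulationConfig, with_tissue: bool = True
) -> tuple[list[PatientTruth], dict]:
    """Generate the full cohort.

    Returns the list of per-patient ground truths and, when
    ``with_tissue``, a dict ``patient_id -> (TissueGeometry, cells,
    tls_zones)``.  Death times are exponential with rate
    ``baseline_hazard_per_month × exp(−immune_effect_beta × latent)``;
    censoring is the minimum of an independent exponential and the
    administrative horizon; a ``dss_fraction`` Bernoulli split flags
    disease-specific deaths.
    """
    config.validate()
    truths: list[PatientTruth] = []
    artefacts: dict = {}
    for i in range(config.n_patients):
        pid = patient_label(i)
        latent = latent_immune_level(config, i)
        rng = _rng(config, i, _STREAM_OUTCOME)

        rate = config.baseline_hazard_per_month * np.exp(
            -config.immune_effect_beta * latent
        )
        t_death = rng.exponential(1.0 / rate)
        t_cens = rng.exponential(1.0 / config.censor_rate_per_month)
        time = min(t_death, t_cens, config.admin_censor_months)
        event_os = int(t_death <= min(t_cens, config.admin_censor_months))
        event_dss = int(event_os and rng.random() < config.dss_fraction)

        covariates = {}
        for var, probs in config.covariate_marginals.items():
            levels = list(probs)
            covariates[var] = levels[rng.choice(len(levels), p=list(probs.values()))]
        if "age_band" in covariates:
            lo, hi = {"<65": (45, 65), "65-75": (65, 75), ">75": (75, 88)}[
                covariates["age_band"]]
            covariates["age_years"] = float(np.round(rng.uniform(lo, hi), 1))

        true_density = {
            m: {r: lam * np.exp(latent) for r, lam in by_region.items()}
            for m, by_region in config.baseline_intensity.items()
        }
        truths.append(PatientTruth(pid, latent, true_density, float(time),
                                   event_os, event_dss, covariates))
        if with_tissue:
            artefacts[pid] = simulate_tissue(config, i)
    return truths, artefacts


def cohort_table(truths: list[PatientTruth]) -> pd.DataFrame:
    """Cohort CSV layout: survival, endpoints, covariates; one row per patient."""
    rows = []
    for t in truths:
        row = {"patient_id": t.patient_id, "time_months": t.survival_time_months,
               "event_os": t.event_overall, "event_dss": t.event_disease_specific}
        row.update(t.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
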