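"""Simulation configuration for the synthetic PDAC cohort generator.

Defaults emulate the study conditions the analysis assumes: a cohort of
79 resected pancreatic ductal adenocarcinoma patients, CD3⁺/CD8⁺ density
scales of hundreds to low thousands of cells/mm², clustered lymphoid
aggregates and occasional tertiary lymphoid structures, survival with a
median overall survival near 20 months and heavy censoring, and
clinicopathological covariate marginals matching a published 79-patient
cohort table.  Density parameters are calibrated to order of magnitude
only; the cohort-level survival parameters are calibrated to the
reported median OS.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

__all__ = ["SimulationConfig", "DEFAULT_COVARIATE_MARGINALS"]


#: marginal probabilities for the clinicopathological covariates,
#: proportional to the published 79-patient cohort counts.
DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"male": 41 / 79, "female": 38 / 79},
    "age_band": {"<65": 36 / 79, "65-75": 35 / 79, ">75": 8 / 79},
    "t_stage": {"T1b": 5 / 79, "T1c": 14 / 79, "T2": 43 / 79, "T3": 17 / 79},
    "n_stage": {"N0": 36 / 79, "N1": 29 / 79, "N2": 14 / 79},
    "stage": {"IA": 8 / 79, "IB": 17 / 79, "IIA": 11 / 79, "IIB": 29 / 79,
              "III": 14 / 79},
    "grade": {"I": 15 / 61, "II": 29 / 61, "III": 17 / 61},
    "pni": {"negative": 42 / 79, "positive": 37 / 79},
    "resection": {"R0": 50 / 79, "R1": 29 / 79},
}


def _default_intensity() -> dict[str, dict[str, float]]:
    # cells/mm² at latent level 0; "outside" is normal pancreatic tissue
    return {
        "CD3": {"core": 400.0, "margin": 450.0, "outside": 150.0},
        "CD8": {"core": 130.0, "margin": 180.0, "outside": 60.0},
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic tissue-and-cohort generator.

    The per-patient latent immune level (standard normal, scale
    ``latent_sd``) multiplies every baseline intensity by
    ``exp(latent)``, with additional independent per-component lognormal
    noise of scale ``component_noise_sd``; lymphoid aggregates arrive at
    a rate independent of the latent level, so the fixed-area hotspot
    maximum is a noisier readout of the latent level than the
    whole-section average.
    """

    n_patients: int = 79
    seed: int = 0

    # --- tissue ---
    section_width_mm: float = 12.0
    section_height_mm: float = 12.0
    tumour_radius_mm: float = 3.0
    tumour_radius_jitter: float = 0.15
    boundary_irregularity: float = 0.08
    margin_half_width_mm: float = 0.5

    # --- immune cell point processes ---
    baseline_intensity: dict = field(default_factory=_default_intensity)
    latent_sd: float = 1.0
    component_noise_sd: float = 0.3
    aggregate_rate: float = 0.25          # expected aggregates per mm² (tumour ∪ margin)
    aggregate_mean_size: float = 400.0     # expected cells per aggregate
    aggregate_size_dispersion: float = 1.0  # lognormal sigma of per-aggregate size
    aggregate_sd_mm: float = 0.13         # Gaussian dispersion of aggregate cells
    aggregate_cd3_fraction: float = 0.7
    tls_rate: float = 1.5                 # expected TLS per section
    tls_cells: int = 250
    tls_radius_mm: float = 0.08
    tls_cd3_fraction: float = 0.7

    # --- survival ---
    immune_effect_beta: float = 0.7       # log-hazard drop per unit latent level
    baseline_hazard_per_month: float = math.log(2) / 20.0
    censor_rate_per_month: float = math.log(2) / 40.0
    admin_censor_months: float = 120.0
    dss_fraction: float = 0.9             # fraction of deaths that are disease-specific

    covariate_marginals: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_COVARIATE_MARGINALS.items()}
    )

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        for name in ("section_width_mm", "section_height_mm", "tumour_radius_mm",
                     "margin_half_width_mm", "baseline_hazard_per_month",
                     "censor_rate_per_month", "admin_censor_months",
                     "aggregate_mean_size", "aggregate_sd_mm", "tls_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("boundary_irregularity", "aggregate_rate", "tls_rate",
                     "latent_sd", "component_noise_sd", "tumour_radius_jitter",
                     "aggregate_size_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for marker, by_region in self.baseline_intensity.items():
            for region, lam in by_region.items():
                if lam < 0:
                    raise ValueError(f"intensity[{marker}][{region}] must be ≥ 0")
        if not 0.0 <= self.dss_fraction <= 1.0:
            raise ValueError("dss_fraction must be in [0, 1]")
        for var, probs in self.covariate_marginals.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"marginals for {var!r} sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability in marginals for {var!r}")
        return self

    # --- JSON round-trip ---------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        """Load from a JSON string or file path."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(source) as fh:
                text = fh.read()
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data).validate()
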