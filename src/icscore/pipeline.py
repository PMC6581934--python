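"""End-to-end analysis pipeline.

Orchestrates simulate → geometry → densities (whole-section and hotspot)
→ ROC cutoffs → ICS → statistics, persisting every intermediate as plain
CSV/GeoJSON/JSON so each stage can be re-run and inspected in isolation,
and emits a report with the cohort association table (chi-square per
covariate vs ICS group), crude and adjusted Cox hazard ratios per
technique and endpoint, per-component crude hazard ratios, and the
density distribution summaries with hotspot-vs-whole-section paired
tests.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .density import (NoHotspotError, RegionDensity, density_table,
                      find_hotspot, summarize_densities, whole_section_density,
                      HOTSPOT_AREA_MM2)
from .geometry import MARKERS, REGIONS, assign_cells
from .io import write_cells, write_cohort, write_geometry
from .scoring import COMPONENTS, CutoffSet, ICSScorer
from .simulate import cohort_table, simulate_cohort
from .survival import ConvergenceError, chisq_test, cox_fit, km_estimate, logrank_test

__all__ = ["AnalysisReport", "run_pipeline", "compare_techniques",
           "compute_densities", "score_cohort", "survival_analysis"]

TECHNIQUES = ("whole_section", "hotspot")

#: covariates cross-tabulated against the ICS group, and the adjusters of
#: the multivariable Cox model.
ASSOCIATION_COVARIATES = ("sex", "age_band", "t_stage", "n_stage", "stage",
                          "grade", "pni", "resection")
ADJUSTERS = ("sex", "age_band", "stage", "grade", "pni", "resection")


def _log(events: list, stage: str, message: str, **extra) -> None:
    evt = {"stage": stage, "message": message, **extra}
    events.append(evt)
    print(json.dumps(evt), file=sys.stderr)


# ---------------------------------------------------------------------------
# stage: densities


def compute_densities(artefacts: dict, events: list | None = None) -> pd.DataFrame:
    """Whole-section and hotspot densities for every patient/marker/region.

    ``artefacts`` maps patient_id -> (geometry, cells, tls_zones).  A
    patient with no admissible hotspot placement for a component gets a
    NaN hotspot density (flagged unscorable downstream).
    """
    events = events if events is not None else []
    densities: list[RegionDensity] = []
    missing_rows: list[dict] = []
    for pid, (geometry, cells, tls_zones) in artefacts.items():
        labelled = assign_cells(cells, geometry)
        for marker in MARKERS:
            for region in REGIONS:
                densities.append(
                    whole_section_density(labelled, geometry, marker, region, pid))
                try:
                    hs = find_hotspot(labelled, geometry, marker, region,
                                      HOTSPOT_AREA_MM2, tls_zones)
                    densities.append(RegionDensity(
                        pid, marker, region, "hotspot",
                        hs.cell_count, hs.window_area_mm2))
                except NoHotspotError as exc:
                    _log(events, "density", "no admissible hotspot",
                         patient_id=pid, marker=marker, region=region,
                         error=str(exc))
                    missing_rows.append(dict(
                        patient_id=pid, marker=marker, region=region,
                        technique="hotspot", cell_count=np.nan,
                        area_mm2=HOTSPOT_AREA_MM2, density=np.nan))
    table = density_table(densities)
    if missing_rows:
        table = pd.concat([table, pd.DataFrame(missing_rows)], ignore_index=True)
    return table


def _component_matrix(densities: pd.DataFrame, technique: str) -> pd.DataFrame:
    """Pivot a tidy density table into the (n, 4) ICS component matrix."""
    sub = densities[densities["technique"] == technique].copy()
    sub["component"] = sub["marker"] + "_" + sub["region"]
    wide = sub.pivot_table(index="patient_id", columns="component",
                           values="density", aggfunc="first")
    return wide.reindex(columns=list(COMPONENTS))


# ---------------------------------------------------------------------------
# stage: scoring


def score_cohort(
    densities: pd.DataFrame,
    cohort: pd.DataFrame,
    fixed_cutoffs: dict[str, CutoffSet] | None = None,
    censored_as_survivors: bool = False,
    events: list | None = None,
) -> tuple[pd.DataFrame, dict[str, CutoffSet]]:
    """Fit cutoffs and score every patient under both techniques.

    Returns the ICS table (one row per patient × technique with the four
    calls, score and group; unscorable patients keep NaN/None) and the
    cutoff sets used.
    """
    events = events if events is not None else []
    cohort = cohort.set_index("patient_id")
    ics_rows = []
    cutoff_sets: dict[str, CutoffSet] = {}
    for technique in TECHNIQUES:
        X = _component_matrix(densities, technique)
        y = cohort.loc[X.index, ["time_months", "event_dss"]].to_numpy(float)
        scorer = ICSScorer(
            cutoffs=(fixed_cutoffs or {}).get(technique),
            censored_as_survivors=censored_as_survivors,
        )
        scorer.fit(X, y)
        cutoff_sets[technique] = scorer.cutoff_set(technique)
        _log(events, "score", "cutoffs fitted", technique=technique,
             n_excluded_censored=scorer.n_excluded_,
             cutoffs={c: float(v) for c, v in zip(COMPONENTS, scorer.cutoffs_)})
        scores = scorer.transform(X)
        groups = scorer.predict(X)
        calls = scorer.component_calls(X)
        for i, pid in enumerate(X.index):
            row = {"patient_id": pid, "technique": technique}
            row.update({c: calls.iloc[i][c] for c in COMPONENTS})
            row["score"] = None if np.isnan(scores[i]) else int(scores[i])
            row["group"] = groups[i]
            ics_rows.append(row)
            if groups[i] is None:
                _log(events, "score", "patient unscorable",
                     patient_id=pid, technique=technique)
    return pd.DataFrame(ics_rows), cutoff_sets


# ---------------------------------------------------------------------------
# stage: statistics


_GROUP_ORDER = ("low", "moderate", "high")


def _group_dummies(groups: pd.Series) -> pd.DataFrame:
    """Reference-coded ICS-group indicators, low = reference."""
    return pd.DataFrame({
        "ics_moderate": (groups == "moderate").astype(float),
        "ics_high": (groups == "high").astype(float),
    }, index=groups.index)


def _covariate_dummies(cohort: pd.DataFrame, variables=ADJUSTERS) -> pd.DataFrame:
    cols = {}
    for var in variables:
        levels = sorted(cohort[var].astype(str).unique())
        for lev in levels[1:]:  # first level is the reference
            cols[f"{var}_{lev}"] = (cohort[var].astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def _cox_block(design: pd.DataFrame, time, event, events: list, label: str) -> dict:
    keep = design.columns[design.nunique() > 1]
    dropped = sorted(set(design.columns) - set(keep))
    try:
        model = cox_fit(design[keep].to_numpy(), time, event, names=list(keep))
        out = {"converged": True, "coefficients": model.summary(),
               "log_likelihood": model.loglik}
    except (ConvergenceError, ValueError) as exc:
        _log(events, "survival", "Cox fit failed", block=label, error=str(exc))
        out = {"converged": False, "error": str(exc)}
    if dropped:
        out["dropped_constant_columns"] = dropped
    return out


def survival_analysis(
    cohort: pd.DataFrame, ics: pd.DataFrame, densities: pd.DataFrame,
    cutoff_sets: dict[str, CutoffSet], events: list | None = None,
) -> dict:
    """Association tables, KM/log-rank, and crude/adjusted Cox models."""
    events = events if events is not None else []
    out: dict = {"techniques": {}}
    for technique in TECHNIQUES:
        block: dict = {}
        sub = ics[ics["technique"] == technique].set_index("patient_id")
        merged = cohort.set_index("patient_id").join(sub[["score", "group"]],
                                                     how="inner")
        scored = merged[merged["group"].notna()].copy()
        block["n_scored"] = int(len(scored))
        block["group_sizes"] = {
            g: int((scored["group"] == g).sum()) for g in _GROUP_ORDER}

        # Table-1-style chi-square association block
        assoc = {}
        for var in ASSOCIATION_COVARIATES:
            if var not in scored.columns:
                continue
            tab = pd.crosstab(scored[var], scored["group"]) \
                    .reindex(columns=_GROUP_ORDER, fill_value=0)
            try:
                res = chisq_test(tab.to_numpy())
                assoc[var] = {"statistic": res.statistic, "df": res.df,
                              "p_value": res.p_value}
            except ValueError as exc:
                assoc[var] = {"p_value": None, "error": str(exc)}
        block["association"] = assoc

        # KM + log-rank + Cox per endpoint
        for endpoint, evcol in (("dss", "event_dss"), ("os", "event_os")):
            ep: dict = {}
            t = scored["time_months"].to_numpy(float)
            e = scored[evcol].to_numpy(int)
            g = scored["group"].to_numpy()
            km_all = km_estimate(t, e)
            ep["survival_rates_1_3_5yr"] = list(km_all.rates_12_36_60)
            ep["median_months"] = km_all.median
            ep["median_ci"] = list(km_all.median_ci)
            by_group = {}
            for grp in _GROUP_ORDER:
                m = g == grp
                if m.sum():
                    km_g = km_estimate(t[m], e[m])
                    by_group[grp] = {
                        "n": int(m.sum()),
                        "median_months": km_g.median,
                        "survival_rates_1_3_5yr": list(km_g.rates_12_36_60),
                    }
            ep["km_by_group"] = by_group
            if len(np.unique(g)) >= 2:
                lr = logrank_test(t, e, g)
                ep["logrank"] = {"statistic": lr.statistic, "df": lr.df,
                                 "p_value": lr.p_value}
            dummies = _group_dummies(scored["group"])
            ep["cox_crude"] = _cox_block(dummies, t, e, events,
                                         f"{technique}/{endpoint}/crude")
            adj = pd.concat([dummies, _covariate_dummies(scored)], axis=1)
            ep["cox_adjusted"] = _cox_block(adj, t, e, events,
                                            f"{technique}/{endpoint}/adjusted")
            block[endpoint] = ep

        # Table-3-style per-component crude HRs (high vs low at the cutoff)
        comp_block = {}
        X = _component_matrix(densities, technique).loc[scored.index]
        cuts = cutoff_sets[technique].as_array()
        for j, comp in enumerate(COMPONENTS):
            col = X.iloc[:, j].to_numpy(float)
            ok = ~np.isnan(col)
            high = (col[ok] >= cuts[j]).astype(float)
            comp_ep = {}
            for endpoint, evcol in (("dss", "event_dss"), ("os", "event_os")):
                comp_ep[endpoint] = _cox_block(
                    pd.DataFrame({"high": high}),
                    scored["time_months"].to_numpy(float)[ok],
                    scored[evcol].to_numpy(int)[ok],
                    events, f"{technique}/{comp}/{endpoint}")
            comp_block[comp] = comp_ep
        block["per_component"] = comp_block
        out["techniques"][technique] = block
    return out


# ---------------------------------------------------------------------------
# report


@dataclass
class AnalysisReport:
    """Full pipeline output, serialisable to JSON."""

    provenance: dict
    cohort_summary: dict
    cutoffs: dict
    density_summary: list
    density_comparison: list
    statistics: dict
    events: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "cohort_summary": self.cohort_summary,
            "cutoffs": self.cutoffs,
            "density_summary": self.density_summary,
            "density_comparison": self.density_comparison,
            "statistics": self.statistics,
            "events": self.events,
        }

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not JSON-serialisable: {type(o)}")
        doc = json.dumps(self.to_dict(), indent=2, default=_default,
                         allow_nan=True)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc


def run_pipeline(
    config: SimulationConfig,
    out_dir=None,
    fixed_cutoffs: dict[str, CutoffSet] | None = None,
) -> AnalysisReport:
    """Execute every stage for both techniques and build the report.

    When ``out_dir`` is given, persists cells.csv, per-patient geometry
    GeoJSON, cohort.csv, densities.csv, cutoffs.json, ics.csv and
    report.json there.
    """
    config.validate()
    events: list = []
    t0 = _time.perf_counter()

    def _stamp(stage: str) -> None:
        # timings go to stderr only, so the stored report stays bit-identical
        print(json.dumps({"stage": stage, "elapsed_s":
                          round(_time.perf_counter() - t0, 2)}), file=sys.stderr)

    truths, artefacts = simulate_cohort(config, with_tissue=True)
    cohort = cohort_table(truths)
    _log(events, "simulate", "cohort generated", n_patients=len(truths))
    _stamp("simulate")

    densities = compute_densities(artefacts, events)
    _log(events, "density", "densities computed", rows=len(densities))
    _stamp("density")

    ics, cutoff_sets = score_cohort(densities, cohort,
                                    fixed_cutoffs=fixed_cutoffs, events=events)
    summary, comparison = summarize_densities(densities.dropna(subset=["density"]))
    stats = survival_analysis(cohort, ics, densities, cutoff_sets, events)
    _log(events, "survival", "statistics computed")
    _stamp("survival")

    config_doc = config.to_json()
    report = AnalysisReport(
        provenance={
            "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
            "seed": config.seed,
            "icscore_version": __version__,
        },
        cohort_summary={
            "n_patients": len(truths),
            "n_events_os": int(cohort["event_os"].sum()),
            "n_events_dss": int(cohort["event_dss"].sum()),
            "median_followup_months": float(np.median(cohort["time_months"])),
        },
        cutoffs={
            tech: {"derivation": cs.derivation,
                   "cutoffs": {k: float(v) for k, v in cs.cutoffs.items()}}
            for tech, cs in cutoff_sets.items()
        },
        density_summary=summary.to_dict(orient="records"),
        density_comparison=comparison.to_dict(orient="records"),
        statistics=stats,
        events=events,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_cells = pd.concat([artefacts[t.patient_id][1] for t in truths],
                              ignore_index=True)
        write_cells(all_cells, out / "cells.csv")
        geo_dir = out / "geometry"
        geo_dir.mkdir(exist_ok=True)
        for t in truths:
            geometry, _, tls_zones = artefacts[t.patient_id]
            write_geometry(geometry, tls_zones, geo_dir / f"{t.patient_id}.geojson")
        write_cohort(cohort, out / "cohort.csv")
        densities.to_csv(out / "densities.csv", index=False)
        ics.to_csv(out / "ics.csv", index=False)
        (out / "cutoffs.json").write_text(json.dumps(
            report.cutoffs, indent=2) + "\n")
        config.to_json(out / "config.json")
        report.to_json(out / "report.json")
    return report


def compare_techniques(report: AnalysisReport) -> pd.DataFrame:
    """Side-by-side hotspot vs whole-section comparison table.

    One row per (marker, region) with the two medians and IQRs, the
    paired Wilcoxon p-value, and the adjusted high-vs-low OS hazard
    ratios of the two techniques.
    """
    techs = report.statistics.get("techniques", {})
    if set(TECHNIQUES) - set(techs):
        raise ValueError("report must contain both technique blocks")
    summary = pd.DataFrame(report.density_summary)
    comparison = pd.DataFrame(report.density_comparison)
    rows = []
    for _, c in comparison.iterrows():
        row = {"marker": c["marker"], "region": c["region"],
               "wilcoxon_p": c.get("p_value"),
               "computable": bool(c.get("computable", False))}
        for tech in TECHNIQUES:
            s = summary[(summary["marker"] == c["marker"])
                        & (summary["region"] == c["region"])
                        & (summary["technique"] == tech)]
            if len(s):
                row[f"{tech}_median"] = float(s["median"].iloc[0])
                row[f"{tech}_iqr"] = float(s["q3"].iloc[0] - s["q1"].iloc[0])
                row[f"{tech}_range"] = float(s["max"].iloc[0] - s["min"].iloc[0])
        rows.append(row)
    table = pd.DataFrame(rows)
    for tech in TECHNIQUES:
        cox = techs[tech]["os"]["cox_adjusted"]
        hr = (cox.get("coefficients", {}).get("ics_high", {}).get("hr")
              if cox.get("converged") else None)
        table[f"{tech}_adjusted_hr_high_vs_low_os"] = hr
    return table
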