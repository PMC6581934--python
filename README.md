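# icscore

Immune cell score (ICS) analysis for pancreatic ductal adenocarcinoma
(PDAC), comparing two techniques for measuring tumour-infiltrating
T-cell densities: whole-section averages versus maximal fixed-area
hotspots.

## The problem

The ICS summarises the host immune response from CD3⁺ and CD8⁺ cell
densities (cells/mm²) in two compartments of a resected tumour section:
the tumour core (CT) and the invasive margin (IM, a 0.5 mm band on each
side of the tumour boundary).  Each of the four (marker × compartment)
densities is called high or low at a cutoff derived from a ROC curve
against 3-year disease-specific mortality (Youden's J, low density
oriented as the positive test); the score is the number of high calls,

    ICS = Σ 1[density ≥ cutoff]  over {CD3, CD8} × {CT, IM},  ICS ∈ 0…4,

grouped low (0–1) / moderate (2) / high (3–4).  The density itself can
be measured two ways: averaging over the whole compartment, or taking
the densest 0.28 mm² circular window (the punch size of a tissue
microarray core), excluding tertiary lymphoid structures.  Because the
hotspot is a maximum over a spatial point pattern, it is a noisy,
upward-biased readout; the package's pipeline quantifies how that
sampling noise degrades the score's prognostic value in Kaplan–Meier /
log-rank and crude/adjusted Cox proportional-hazards analyses.

The package is aimed at digital-pathology and biostatistics users who
start from detected cell coordinates (CSV), tissue polygons (GeoJSON)
and a cohort table (CSV).  Since no patient-level data are published
for the motivating cohort, a synthetic tissue-and-cohort generator with
the study's statistical structure (latent immune level driving both
infiltration and hazard, lymphoid-aggregate clutter, heavy censoring)
makes every stage testable end to end.

## Worked example

```python
from icscore import SimulationConfig, run_pipeline, compare_techniques

report = run_pipeline(SimulationConfig())   # 79 patients, seed 0
for tech, blk in report.statistics["techniques"].items():
    hr = blk["os"]["cox_adjusted"]["coefficients"]["ics_high"]["hr"]
    print(f"{tech:>14}: groups {blk['group_sizes']}  "
          f"adjusted OS HR high-vs-low = {hr:.2f}")

table = compare_techniques(report)
ratio = table["hotspot_median"] / table["whole_section_median"]
print("hotspot / whole-section median density ratios:",
      [round(r, 2) for r in ratio])
```

prints

```
 whole_section: groups {'low': 27, 'moderate': 10, 'high': 42}  adjusted OS HR high-vs-low = 0.29
       hotspot: groups {'low': 20, 'moderate': 27, 'high': 32}  adjusted OS HR high-vs-low = 0.54
hotspot / whole-section median density ratios: [4.62, 4.26, 5.84, 4.19]
```

Reading: under identical simulated biology, the whole-section ICS
separates survival more sharply (adjusted hazard ratio 0.29 for high vs
low score) than the hotspot ICS (0.54), while hotspot densities run
4–6× higher than whole-section averages with a wider spread — the
hotspot maximum is dominated by the largest lymphoid aggregate rather
than by the patient's overall infiltration level.

The same stages are available on files via the CLI:

```sh
icscore simulate --seed 0 --out run/
icscore density  --cells run/cells.csv --geometry run/geometry --out run/densities.csv
icscore score    --densities run/densities.csv --cohort run/cohort.csv --out run/ics.csv
icscore survival --densities run/densities.csv --cohort run/cohort.csv \
                 --ics run/ics.csv --cutoffs run/ics.cutoffs.json --out run/stats.json
# or everything at once:
icscore run-all  --seed 0 --out run/
```

## Library layout

| module | contents |
| --- | --- |
| `icscore.simulate` / `icscore.config` | synthetic tissue + cohort generator and its configuration |
| `icscore.geometry` | core/margin construction from polygons, cell-to-compartment assignment |
| `icscore.density` | whole-section densities, TLS detection, maximal-window hotspot search, distribution summaries |
| `icscore.scoring` | 3-year outcome, ROC cutoffs, `ICSScorer` (sklearn-style fit/transform/predict) |
| `icscore.survival` | Kaplan–Meier, log-rank, Cox PH (Breslow/Newton), Pearson chi-square — from first principles |
| `icscore.pipeline` | end-to-end orchestration, report, technique comparison |
| `icscore.reference` | published 79-patient cohort contingency tables used for validation |

See `docs/methods.md` for the model, parameter defaults and their
rationale, numerical conventions, and limitations.

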