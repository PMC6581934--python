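# Methods

## The problem

The immune cell score (ICS) quantifies the host T-cell response in
resected pancreatic ductal adenocarcinoma (PDAC) from two markers (CD3⁺
for all T cells, CD8⁺ for cytotoxic T cells) in two tissue compartments:
the tumour core (CT) and the invasive margin (IM), the band containing
the tumour/normal-pancreas interface.  Each of the four
(marker × compartment) densities is binarized high/low at a cutoff, the
score is the number of "high" calls (0–4), and patients are grouped low
(0–1), moderate (2), high (3–4).  Two measurement techniques exist for a
density: the *whole-section* average (total count over the compartment
divided by its area) and the *hotspot* maximum (the densest fixed-area
window, emulating the 0.28 mm² punch of a tissue microarray core).  The
scientific question this package operationalises is how the choice of
technique propagates into the score's prognostic value.

No patient-level data are available for the cohort that motivated the
pipeline, so the package ships a synthetic tissue-and-cohort generator
that emulates the study's data structure; every downstream stage is
exercised and tested against that generator plus closed-form and
brute-force oracles.

## Tissue geometry

Coordinates are planar Cartesian millimetres, x right, y up, origin at
the section's lower-left corner.  Inputs are two simple polygons: the
section outline and the tumour boundary.  Derived compartments:

* **invasive margin** — all points within 0.5 mm (configurable
  half-width) of the tumour boundary curve, clipped to the section; the
  boundary polyline is densified to ≤ 0.05 mm segments before buffering
  so the band's geometric error is far below its width;
* **tumour core** — the tumour interior eroded by the same half-width.

Core and margin are therefore disjoint and each cell lies in exactly
one of {core, margin, outside}; points on a shared boundary resolve in
the fixed order core → margin → outside.  Whether the whole-tumour
count should instead include the inner half of the margin band is not
determined by the protocol wording; the disjoint-compartment reading is
the default because the ICS scores the two compartments as separate
components, and the alternative overlapping reading (core count includes
inner-band cells, normalised by the full tumour area, cell partition
unchanged) is available via `build_regions(...,
core_includes_inner_margin=True)`.  Erosion that annihilates the core (tumour thinner than
twice the half-width) is an explicit error, not a silent zero.

## Densities

**Whole-section**: count of the marker's cells labelled with the
compartment, divided by the compartment area (cells/mm²).

**Hotspot**: the circular window of area 0.28 mm² (radius
√(0.28/π) ≈ 0.2985 mm) maximising the count of the marker's
in-compartment cells.  Circular windows reflect the TMA punch shape
behind the 0.28 mm² figure.  The maximisation runs over a finite
candidate set: window centres at every in-compartment cell of the
marker plus a 0.1 mm grid over the compartment; on small instances
(≤ 1500 in-compartment cells) the set is augmented with the
circumcentres of every cell pair within one window diameter, which by
the classical covering argument makes the search exact.  Constraints:
the window *centre* must lie inside the compartment (requiring the full
disk inside would make almost every placement in the 1 mm-wide margin
band infeasible), and the full window disk must be disjoint from every
tertiary lymphoid structure (TLS), whose organised aggregates are
excluded from hotspots by protocol.  Ties break toward higher count,
then smaller centre x, then smaller centre y, making the result
deterministic.  A compartment with no admissible placement raises an
explicit no-hotspot error and the patient is flagged unscorable for
that component.

**TLS detection** (for inputs without TLS annotations): DBSCAN over all
immune cells with neighbourhood radius 0.15 mm and core threshold 50
cells, each qualifying cluster returned as its convex hull.  The
protocol gives no operational TLS definition; these defaults separate
organised structures from the diffuse background at the simulated
density scales.  The pipeline itself uses the TLS polygons carried in
the geometry input (in the synthetic cohort, the generator's true TLS
disks), treating them like a pathologist's annotation; `detect_tls`
covers the unannotated case.

## Cutoffs and the score

Cutoffs are derived per component from a receiver operating
characteristic against **three-year disease-specific mortality**:
death from disease at ≤ 36 months versus survival to ≥ 36 months.
Patients censored before 36 months have undefined three-year status and
are excluded from cutoff fitting by default (a flag can count them as
survivors instead); they are still scored and retained in the survival
analysis.  "Optimal sensitivity and specificity" is operationalised as
Youden's J = sensitivity + specificity − 1, the standard single-point
ROC optimum, with *low* density oriented as the positive test for death
(high infiltration is protective).  Candidate thresholds are midpoints
between consecutive sorted unique densities; among maximisers the
smallest is returned.  Binarization uses density ≥ cutoff ⇒ high; the
boundary convention must be fixed somewhere and ≥ is declared here.
The previously published cutoffs (hotspot 1116/1314/1185/998,
whole-section 396/370/120/157 cells/mm², in CD3-core, CD3-margin,
CD8-core, CD8-margin order) ship as a fixed `CutoffSet`; the default
pipeline refits because cutoffs are known not to transfer between
cohorts and laboratories.

`ICSScorer` packages this as a scikit-learn-style estimator:
`fit(X, y)` derives `cutoffs_` from an (n, 4) density matrix and
(time, disease-specific event) pairs; `transform` returns scores 0–4;
`predict` returns the low/moderate/high group; rows with a missing
component give NaN/None (unscorable).

## Survival statistics

Implemented from their defining formulas (this module is the point, so
no statistical package stands behind it; lifelines and scipy appear
only as oracles in the tests):

* **Kaplan–Meier** product-limit estimator with Greenwood variance;
  deaths precede censorings at tied times; median = earliest time with
  S(t) ≤ 0.5 (undefined if never reached), with a 95% CI by
  Brookmeyer–Crowley inversion of the log(−log) band.  Survival is
  reported at 12/36/60 months to mirror 1/3/5-year rates.
* **k-sample log-rank** with multivariate hypergeometric variance,
  chi-square reference on k − 1 degrees of freedom.
* **Cox proportional hazards** maximising the partial likelihood by
  damped Newton iterations (step-halving on the likelihood, gradient
  max-norm < 1e-8, ≤ 100 iterations), Wald 95% CIs.  Ties use the
  Breslow approximation by default with Efron's available via
  `ties="efron"` (both verified against lifelines).  Non-convergence and monotone likelihoods (complete separation,
  flagged when a coefficient exceeds 50 in absolute value) raise rather
  than emit numbers; the pipeline records such fits as failed blocks.
  Breslow handling is adequate at cohort-scale tie density; the exact
  tie pattern of the original analysis software is unknown, so the
  convention is declared rather than inferred.
* **Pearson chi-square** without continuity correction, all-zero rows
  and columns dropped before computing expected counts, degrees of
  freedom from the reduced table.

Adjusted Cox models use reference-coded indicators for sex, age band
(<65 / 65–75 / >75), stage, grade, perineural invasion and resection
status, with the ICS low group as the reference level.  All p-values
are two-sided.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed and
the tests run against them.

* **Latent immune level** Zᵢ ~ N(0, 1) per patient multiplies all four
  baseline (marker × compartment) intensities by exp(Zᵢ), with
  independent per-component lognormal noise (σ = 0.3).  Baseline
  intensities (CD3 400/450, CD8 130/180 cells/mm² in core/margin, lower
  outside) put whole-section densities on the published scale of
  hundreds of cells/mm²; the published data constrain these only to
  order of magnitude.
* **Tissue**: a 12 × 12 mm section with a central tumour of radius
  3 mm (±15% per-patient jitter) whose boundary is a circle with
  low-order Fourier radial perturbation (simple, always closable,
  tunable irregularity).  These sizes are scaled down from surgical
  PDAC sections to keep a full 79-patient cohort simulation cheap; the
  density scales, not the absolute areas, carry the analysis.
* **Cell pattern**: an inhomogeneous Poisson background per
  (marker × compartment), plus a Thomas-type cluster process of
  lymphoid aggregates in the tumour-plus-margin domain (rate
  0.25/mm²; per-aggregate expected size lognormal with mean 400 cells
  and log-scale σ = 1.0; Gaussian dispersion 0.13 mm; 70% CD3), plus
  occasional dense TLS disks on the margin (Poisson rate 1.5/section,
  250 cells, radius 0.08 mm).  Aggregate arrivals and sizes are
  *independent of the latent level*: this is the mechanism under
  study.  The whole-section average pools thousands of background
  cells whose intensity tracks exp(Z), so it reads the latent level
  with little noise; the hotspot maximum is dominated by the largest
  aggregate, a heavy-tailed max-statistic essentially unrelated to Z.
  The aggregate size scale was chosen so hotspot/whole-section median
  ratios land at ≈ 4–6, inside the span implied by the published
  cutoff pairs (2.8–9.9 across the four components).
* **Survival**: death times exponential with rate
  (ln 2 / 20) · exp(−0.7 Zᵢ) per month, independent exponential
  censoring (rate ln 2 / 40) plus an administrative horizon at 120
  months; 90% of deaths are flagged disease-specific.  With the latent
  effect disabled the marginal median survival is 20 months by
  construction (the calibration check runs with β = 0 because a
  nonzero latent effect changes the marginal median of the frailty
  mixture).
* **Covariates** are sampled i.i.d. from marginals proportional to a
  published 79-patient cohort table; they carry no survival effect, so
  adjusted and crude models estimate the same ICS contrasts up to
  noise, as adjusters rather than confounders.
* **Determinism**: all draws derive from
  `SeedSequence(seed, patient_index, stream)`; identical config + seed
  reproduce the cohort bit-for-bit, and a patient's tissue can be
  regenerated in isolation.

What the generator does **not** emulate: stain intensity and detection
error (generation is at detected-coordinate level), spatial gradients
of infiltration within a compartment, correlation between covariates
and immune state, competing risks, and inter-laboratory shifts in
density scale.  Tests passing on this generator therefore demonstrate
the pipeline's internal correctness and the stated sampling-noise
mechanism, not clinical performance on real slides.

## Numerical choices and scaled-down problem sizes

* Hotspot exactness is guaranteed on small instances (pair
  circumcentres); at pipeline scale the cells+grid candidate set is
  the declared estimator, and a 0.01 mm fine-grid brute force plus an
  independent naive exact enumeration bound it in the tests.
* A window-boundary cell counts inside (radius inflated by 1e-9
  relatively) so circumcentre candidates are stable to rounding.
* The log-rank type-I calibration uses three groups of 100: at small
  group sizes (~20) the k-sample log-rank is intrinsically mildly
  anti-conservative (~0.063 at nominal 0.05, byte-identical in
  lifelines), so calibration is checked where the chi-square reference
  is in its asymptotic regime.
* The median-survival calibration runs at n = 2000 with censoring
  disabled; the Monte-Carlo tolerance is three times the asymptotic SE
  of the sample median of Exp(ln 2 / 20), ≈ ±1.9 months.
* Cohort-level checks run the full n = 79 default configuration
  (about two to three minutes); unit tests use 8–12 patients on
  smaller sections.

## Known limitations

* The hotspot search optimises cell count within the compartment; a
  window at the compartment edge may cover area outside it, which
  mirrors how a circular punch at a narrow margin behaves but means
  hotspot "density" is count over window area, not over
  window-∩-compartment area.
* Complete separation in an adjusted Cox model (possible at n = 79
  with many indicator covariates) is reported as a failed block; no
  penalised fallback is provided.
* The median CI inversion returns an open upper bound when the
  confidence band still covers 0.5 at the last event time.
* TLS detection and hotspot aggregates are defined on the same density
  continuum; very large simulated aggregates are TLS-like, and only
  the annotated TLS polygons are excluded from hotspots.
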