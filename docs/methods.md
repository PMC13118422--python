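# Methods

`carbodose` implements a simulation-based evaluation of carboplatin dose
formulas for breast-cancer patients with preserved renal function
(CrCL ≥ 55 mL/min). It has four scientific layers: (1) a random-effects
meta-analysis that pools published population-PK typical values into one
"typical patient" parameter set; (2) a closed-form two-compartment infusion
model that turns a dose into a predicted AUC over 24 h; (3) the Calvert-type
dose formulas and their target-attainment evaluation, including the α sweep
of the modified formula; (4) a seeded synthetic-cohort generator that stands
in for the non-public hospital datasets.

## 1. Meta-analytic pooling of population-PK parameters

Inputs are one row per published fixed-effect estimate: parameter (CL, V1,
V2, Q, K12, K21 in L/h, L, 1/h), estimate, and either an RSE (%CV) or an SE.
Pooling is inverse-variance random-effects: weights `1/(s_i² + τ²)`, Cochran
Q and I² from fixed-effect weights, τ² by DerSimonian–Laird (closed form) or
REML (bounded scalar maximization of the restricted likelihood, xatol 1e-14).
Pooling can run on the linear or the log scale (delta-method SEs,
back-transformed CI). Parameters reported by a single study (V2, Q in the
packaged table) pass through un-pooled and are excluded from the simulation
set; K12/K21 are pooled only from the studies reporting them directly — no
imputation from Q/V ratios.

Uncertainty harmonization is the decisive choice. Two constructions are
exposed:

- `reported` — the printed RSE/SE is the standard error of the typical value
  (RSE% → SE = estimate·RSE/100). Under this reading, Q < df for V1, K12 and
  K21, so I² = 0 and the pooled K12 is ≈ 0.133 /h.
- `sd_over_sqrt_n` — the printed value is treated as a subject-level SD and
  converted to an SE by √N (the `meta::metamean` workflow for pooling
  mean ± SD summaries). Within-study variances then become small, τ²
  dominates the weights, I² lands in the high 90s (%), and the pooled mean is
  essentially the unweighted study mean. Because τ² dominates, the result is
  insensitive to the exact N once N ≳ 30 (pooled CL moves by < 0.1% between
  N = 30 and N = 300), so a nominal `assumed_n = 100` is used when a study
  table carries no subject counts, as the packaged one does not.

The documented reproduction configuration (`REFERENCE_POOLING_CONFIG`) is
linear scale × REML × `sd_over_sqrt_n`. It yields CL 7.897 L/h,
V1 15.34 L, K12 0.120 /h, K21 0.194 /h with I² between 96% and 99% —
consistent with the published pooled set except for K21, whose printed value
(0.18 /h) lies below any inverse-variance combination of its two source
estimates (0.171, 0.215) under every configuration examined; the package
reports its computed value rather than forcing a match. REML agrees with R
`metafor::rma(method="REML")` to the printed precision of that package
(frozen cross-check values in the test suite); the DL path is additionally
cross-checked against `statsmodels.stats.meta_analysis.combine_effects` at
run time.

Unit standardization to simulation units is exact: CL·1000/60 → mL/min,
K/60 → 1/min, giving CL 131.6 mL/min, V1 15.34 L, K12 0.0020 min⁻¹,
K21 0.0032 min⁻¹.

## 2. Two-compartment infusion model

Central volume V1 with elimination k10 = CL/V1, peripheral exchange k12/k21.
The hybrid constants λ₁ > λ₂ > 0 are the roots of
λ² − (k10+k12+k21)λ + k10·k21 = 0, computed with the numerically stable
product form λ₂ = k10·k21/λ₁. Concentration during a constant-rate infusion
(rate R0, duration T) and after it is the standard biexponential
superposition; AUC is integrated analytically on each piece, and
AUC(0→∞) = dose/CL exactly. Internal units are minutes, mg and mL, so AUC is
natively in mg·min/mL. Validation is dual-route: a high-accuracy ODE
integration of the mass balances (rtol 1e-11) agrees with the closed form to
relative 1e-6 across a ±50% parameter grid, and trapezoidal quadrature of
the analytic profile on a 0.1-min grid reproduces the analytic AUC to 1e-5.

Exposure predictions use typical values only — no inter-individual
variability, matching a typical-patient simulation design. The 24 h AUC
window is anchored at infusion start (3 h infusion, 1440 min horizon); at
pooled values the window captures f24 = 0.98828 of AUC(0→∞), so every
attainment figure is auditable by hand as dose·f24/CL. Model linearity in
dose is exploited for cohorts: the per-unit-dose AUC is computed once and
scaled, which is exactly (not approximately) equivalent to per-patient
simulation and is verified against it to 1e-9 in the tests. Degenerate
(repeated-root) parameter sets are rejected with an explanatory error; they
cannot arise from strictly positive k12.

## 3. Dose formulas, bands and the α sweep

Doses are `target AUC · (renal metric + 25 + α)` with metric = Cockcroft–
Gault CrCL, or CKD-EPI eGFR de-normalized by BSA/1.73 ("absolute" eGFR);
α = 0 for the conventional variants. No GFR cap is applied by default (a cap
option exists but the source datasets exceed 120 mL/min), and doses are kept
at full precision — rounding is report-only.

Renal equations: Cockcroft–Gault with the 0.85 female factor; CKD-EPI 2021
race-free (default) or 2009 without the race coefficient — the source
datasets' version is unknown, so both are selectable and the choice is
recorded in run provenance. BSA: Mosteller (default, ubiquitous in oncology
EHRs) or Du Bois. The CKD-EPI inverse used by the cohort generator is the
exact closed form on the appropriate branch of the piecewise power law,
round-tripping to 1e-9 against a bisection oracle.

Predicted AUCs are classified as under (< 4), target (4–6 inclusive),
gap (6–7 open) and over (≥ 7 mg·min/mL). The gap band is reported explicitly
so the four proportions always sum to 100% — the three named bands alone are
deliberately non-exhaustive. The α sweep evaluates integer α from −25 to 25.
An α qualifies if, against the α = 0 (conventional eGFR) baseline on
unrounded proportions, under-exposure and over-exposure are no worse,
attainment is no worse, and at least one of the three strictly improves; the
selected α is the qualifying value of smallest |α|, ties resolved to the
positive sign (minimal perturbation of the established formula). The ≤/≥
with at-least-one-strict reading is chosen because a purely strict rule
would exclude an α that leaves attainment and over-exposure unchanged while
reducing under-exposure — exactly the improvement profile of interest. The
rule string is recorded in every sweep result.

## 4. Synthetic cohorts

The two source datasets are available only as printed subgroup summaries:
sizes 2/58/57/37 by source × target AUC (5 or 6 mg·min/mL), with mean ± SD
and range of BSA-normalized eGFR, under a CrCL ≥ 55 mL/min inclusion filter.
The generator treats those summaries as a contract:

- eGFR per subgroup is drawn from a truncated normal whose *parent*
  parameters are solved so the truncated distribution matches the printed
  mean/SD, then affine-standardized to the printed ddof=1 sample moments and
  clipped to the printed range. Every seed therefore reproduces the printed
  summaries (to well within 0.5·sd/√n), not just in expectation. The n=2
  subgroup's printed SD exceeds what any distribution on its printed range
  can attain — it is a two-point ddof=1 value, and indeed mean ± sd/√2
  equals the printed range endpoints — so that subgroup is placed exactly
  there.
- Demographics (age 57 ± 10 years on 30–79, height 157 ± 6 cm, weight
  57 ± 9 kg, all female) are documented assumptions for a Korean/Portuguese
  female breast-cancer population; the sources print none. They are
  configurable in the packaged YAML and flagged as assumptions there.
- Serum creatinine is back-solved from each patient's eGFR through the exact
  CKD-EPI inverse, so CrCL and eGFR share one creatinine — their joint
  distribution is mechanistic, with no injected noise. Back-solved
  creatinine is restricted to 0.4–1.4 mg/dL (demographics resampled
  otherwise): the CKD-EPI inverse is ill-conditioned on its flat
  low-creatinine branch, and unconstrained inversion produces creatinines
  near 0.25 mg/dL whose Cockcroft–Gault values are physiologically absurd.
- Patients whose CrCL falls below the cutoff have demographics resampled
  (budget 10·n), mirroring the exclusion filter while preserving the
  calibrated eGFR sample.

Discrepancy regimes: `biased` (default) samples weight from the realistic
marginal, under which Cockcroft–Gault scatters widely around absolute eGFR
patient-by-patient and the CrCL-based formula under-doses markedly more
often — reproducing the qualitative published comparison. `consistent`
derives weight from the agreement condition CG = absolute eGFR (closed form
under Mosteller BSA), a control regime in which the CrCL- and eGFR-based
formulas coincide dose-for-dose.

What the synthetic cohort does *not* emulate: real creatinine assay noise,
within-patient renal-function dynamics, the true joint distribution of body
size with renal function, and any exposure–outcome relationship. Passing
tests on it demonstrate that the pipeline reproduces the published
*qualitative* formula comparison under the printed cohort structure — not
the published headline percentages, which depend on the individual-level
data. The packaged reference cohort uses the published default seed 398.

## Problem sizes and numerical choices

Default runs use the printed cohort structure (n = 154) and the full 51-point
α grid; the whole pipeline completes in about a second. Tolerances: Vieta
check 1e-12, ODE cross-validation 1e-6 relative, CKD-EPI inversion 1e-9,
dose-linearity 1e-12. REML τ² uses bounded minimization on
[0, max(10·var(y), 10·max s²)]. Ties and degenerate inputs: empty cohorts,
empty α grids, mixed-parameter pooling inputs, nonpositive doses and
repeated hybrid roots all raise explicit errors rather than returning
sentinel values.

## Known limitations

- The pooled K21 and the printed between-study I² can be matched only
  approximately; the harmonization that reproduces the published pooled
  set is inferred (SD/√N), not stated by the sources.
- Attainment percentages on synthetic cohorts are seeded regression values,
  not estimates of the real-data percentages.
- No validation against measured concentrations or clinical outcomes is
  possible within this design; the α = 1 refinement is hypothesis-generating.
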