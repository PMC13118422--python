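# carbodose

Carboplatin dosing analysis for patients with preserved renal function
(CrCL ≥ 55 mL/min): pool published population-pharmacokinetic parameter
estimates by random-effects meta-analysis, predict carboplatin exposure with
a closed-form two-compartment infusion model, and evaluate conventional and
modified Calvert dose formulas by probability of target attainment.

Carboplatin is dosed to a target exposure rather than to body size, via the
Calvert relation

    Dose (mg) = target AUC · (GFR + 25)        [AUC in mg·min/mL, GFR in mL/min]

where 25 mL/min is the non-renal clearance term. In practice GFR is replaced
by an estimate — Cockcroft–Gault creatinine clearance (CrCL) or CKD-EPI eGFR
de-normalized by body surface area (eGFR_abs = eGFR·BSA/1.73) — and the
choice matters: the two estimators can disagree substantially in women with
near-normal renal function. This package quantifies that disagreement in
exposure terms. Doses from

1. `Dose = AUC·(CrCL + 25)`
2. `Dose = AUC·(eGFR_abs + 25)`
3. `Dose = AUC·(eGFR_abs + 25 + α)`, α ∈ [−25, 25] mL/min

are pushed through a two-compartment model (central volume V1, exchange
k12/k21, elimination CL/V1) at meta-analytically pooled typical values — a
single 3 h infusion, AUC over 24 h — and each predicted AUC is classified as
under-exposed (< 4), on target (4–6), in the 6–7 gap, or over-exposed
(≥ 7 mg·min/mL). The α sweep then asks whether any additive correction to
the non-renal term improves on the eGFR-based formula. Because the source
hospital cohorts are not public, a seeded synthetic-cohort generator
reproduces their published subgroup structure (2/58/57/37 patients by
source × target AUC, with the printed eGFR mean/SD/range summaries) so the
whole pipeline runs end-to-end from the repository alone.

## Worked example

```
$ carbodose pool --out pooled.json
pooling configuration: scale=linear, tau2=REML, se_mode=sd_over_sqrt_n (assumed_n=100 when study N missing)
  CL: 7.897 [7.001, 8.793] (k=3, I2=99.4%)
  K12: 0.1197 [0.08936, 0.1501] (k=2, I2=98.3%)
  K21: 0.1938 [0.1507, 0.2369] (k=2, I2=96.3%)
  Q: 1.22 [0.6908, 1.749] (k=1, I2=n/a)
  V1: 15.34 [14.28, 16.4] (k=3, I2=98.1%)
  V2: 24.8 [24.71, 24.89] (k=1, I2=n/a)
```

Each line is a pooled typical value with its 95% CI, the number of
contributing studies and the between-study heterogeneity I². Clearance pools
to 7.897 L/h (131.6 mL/min after unit standardization) — the effective
denominator of every exposure prediction. V2 and Q come from a single study,
pass through un-pooled, and are not used in simulation (the model runs on
CL, V1 and the directly reported K12/K21).

```
$ carbodose run-all --out-dir run
crcl_conventional: under 27.3%  target 57.8%  gap 7.8%  over 7.1%
egfr_conventional: under 12.3%  target 85.1%  gap 2.6%  over 0.0%
egfr_modified: under 11.7%  target 85.1%  gap 3.2%  over 0.0%
selected alpha: 1
outputs in run
```

On the packaged 154-patient synthetic reference cohort, CrCL-based dosing
leaves 27.3% of patients under-exposed and only 57.8% on target; switching
the same patients to BSA-readjusted eGFR raises attainment to 85.1% and
cuts under-exposure to 12.3%. Sweeping α selects α = 1 — i.e.
`Dose = AUC·(eGFR_abs + 26)` — which trims under-exposure further (11.7%)
without worsening attainment or over-exposure. The run directory contains
`pooled.json`, `cohort.csv`, `doses.csv`, `exposures.csv`, the per-α curve
table `sweep.csv`, a markdown report, and the full configuration for
provenance. Exact percentages are properties of the seeded synthetic cohort
(default seed 398), not estimates for any real population; see
`docs/methods.md` for what the generator does and does not emulate.

The same stages are available individually (`pool`, `generate-cohort`,
`dose`, `simulate`, `sweep`, `report`) and as library functions
(`carbodose.pool_study_table`, `default_cohort`, `cohort_proportions`,
`alpha_sweep`, …).

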