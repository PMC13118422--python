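# Subgroup structure of the pooled retrospective carboplatin cohorts
# (two sources, female breast-cancer patients, first treatment cycle).
# eGFR moments and ranges are the published subgroup summaries; the
# demographic distributions are documented assumptions (the sources print
# no age/weight/height summaries) — see docs/methods.md.
crcl_min: 55.0
default_seed: 398
subgroups:
  - dataset_label: dataset1
    target_auc: 5.0
    n: 2
    egfr_mean: 104.36
    egfr_sd: 17.03
    egfr_range: [92.31, 116.40]
  - dataset_label: dataset1
    target_auc: 6.0
    n: 58
    egfr_mean: 102.0
    egfr_sd: 9.11
    egfr_range: [79.38, 121.27]
  - dataset_label: dataset2
    target_auc: 5.0
    n: 57
    egfr_mean: 98.3
    egfr_sd: 13.3
    egfr_range: [61.0, 120.0]
  - dataset_label: dataset2
    target_auc: 6.0
    n: 37
    egfr_mean: 97.6
    egfr_sd: 14.2
    egfr_range: [66.0, 119.0]
demographics:
  age: {mean: 57.0, sd: 10.0, range: [30.0, 79.0]}
  height_cm: {mean: 157.0, sd: 6.0, range: [140.0, 175.0]}
  weight_kg: {mean: 57.0, sd: 9.0, range: [38.0, 90.0]}
  female_fraction: 1.0
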