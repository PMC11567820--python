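{
  "description": "Integer counts printed in the source study, used as inputs for summary arithmetic. Family-class counts do not exactly partition the printed family totals (a known internal inconsistency of the published tallies); they are used only as numerator/denominator pairs.",
  "cohorts": {
    "AD-FBS": {
      "n_families_recruited": 251,
      "n_individuals_recruited": 1055,
      "n_families": 197,
      "n_individuals": 926,
      "n_affected": 545,
      "n_unaffected": 381,
      "onset_mean": 75.21,
      "onset_sd": 8.04,
      "n_families_rare_explained": 38,
      "n_families_apoe_only": 64,
      "n_families_unexplained": 99
    },
    "EFIGA": {
      "n_families_recruited": 271,
      "n_individuals_recruited": 1481,
      "n_families": 214,
      "n_individuals": 1340,
      "n_affected": 793,
      "n_unaffected": 547,
      "onset_mean": 71.2,
      "onset_sd": 9.9,
      "n_families_rare_explained": 34,
      "n_families_apoe_only": 29,
      "n_families_unexplained": 149
    }
  },
  "combined": {
    "n_families": 411,
    "n_individuals": 2266,
    "n_families_rare_explained": 72,
    "n_families_apoe_only": 93,
    "n_families_unexplained": 248,
    "n_segregating_variants": 86
  },
  "ld": {
    "n_variants_considered": 76,
    "n_in_ld": 33
  }
}
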