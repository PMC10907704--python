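{
  "drug_groups": [
    "CDOX",
    "DOXIL",
    "MYOCET"
  ],
  "n_deduplicated_reports": 200,
  "n_demo_rows": 262,
  "n_dropped_onset_intervals": 0,
  "n_duplicate_versions_removed": 62,
  "n_reports_in_window": 200,
  "n_unmatched_drug_names": 268,
  "orphan_rows": {
    "DRUG": 0,
    "INDI": 0,
    "OUTC": 0,
    "REAC": 0,
    "THER": 0
  },
  "unmatched_drug_names_top": {
    "CARBOPLATIN": 53,
    "CYCLOPHOSPHAMIDE": 43,
    "PACLITAXEL": 51,
    "PREDNISONE": 42,
    "RITUXIMAB": 48,
    "VINCRISTINE": 31
  }
}
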