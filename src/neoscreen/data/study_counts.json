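{
  "description": "Published counts from a 309,102-newborn regional screening program comparing a cutoff (reference-interval) scheme against a machine-learning risk-score scheme. These counts are inputs: every percentage, rate and ratio is recomputed from them by the evaluation module.",
  "n_screened": 309102,
  "initial_positive": {"reference_interval": 3608, "ml_system": 1029},
  "secondary_abnormal": 398,
  "ngs_tested": 180,
  "confirmed_positive": 152,
  "confirmed_affected": 72,
  "confirmed_carriers": 80,
  "confusion": {
    "ml_system": {"tp": 142, "tn": 22, "fn": 10, "fp": 6},
    "reference_interval": {"tp": 144, "tn": 2, "fn": 8, "fp": 26}
  },
  "per_disease": [
    {"disease": "PAHD",   "total": 23, "ml_detected": 20, "ri_detected": 20},
    {"disease": "BH4D",   "total": 1,  "ml_detected": 1,  "ri_detected": 1},
    {"disease": "PCD",    "total": 30, "ml_detected": 30, "ri_detected": 29},
    {"disease": "MMA",    "total": 6,  "ml_detected": 6,  "ri_detected": 5},
    {"disease": "SCADD",  "total": 8,  "ml_detected": 8,  "ri_detected": 8},
    {"disease": "IBDD",   "total": 9,  "ml_detected": 9,  "ri_detected": 9},
    {"disease": "3-MCCD", "total": 41, "ml_detected": 38, "ri_detected": 40},
    {"disease": "3-HMGD", "total": 4,  "ml_detected": 4,  "ri_detected": 4},
    {"disease": "NICCD",  "total": 3,  "ml_detected": 3,  "ri_detected": 2},
    {"disease": "CIT-I",  "total": 8,  "ml_detected": 8,  "ri_detected": 7},
    {"disease": "HMET",   "total": 9,  "ml_detected": 6,  "ri_detected": 9},
    {"disease": "2-MBDD", "total": 4,  "ml_detected": 4,  "ri_detected": 4},
    {"disease": "MCADD",  "total": 3,  "ml_detected": 2,  "ri_detected": 3},
    {"disease": "GA-II",  "total": 1,  "ml_detected": 1,  "ri_detected": 1},
    {"disease": "OTCD",   "total": 1,  "ml_detected": 1,  "ri_detected": 1},
    {"disease": "HARG",   "total": 1,  "ml_detected": 1,  "ri_detected": 1}
  ],
  "zygosity_tp": [
    {"disease": "PAHD",   "zygosity": "affected", "detected": 15, "total": 16},
    {"disease": "PAHD",   "zygosity": "carrier",  "detected": 5,  "total": 7},
    {"disease": "BH4D",   "zygosity": "carrier",  "detected": 1,  "total": 1},
    {"disease": "PCD",    "zygosity": "affected", "detected": 14, "total": 14},
    {"disease": "PCD",    "zygosity": "carrier",  "detected": 16, "total": 16},
    {"disease": "MMA",    "zygosity": "affected", "detected": 5,  "total": 5},
    {"disease": "MMA",    "zygosity": "carrier",  "detected": 1,  "total": 1},
    {"disease": "SCADD",  "zygosity": "affected", "detected": 5,  "total": 5},
    {"disease": "SCADD",  "zygosity": "carrier",  "detected": 3,  "total": 3},
    {"disease": "IBDD",   "zygosity": "affected", "detected": 8,  "total": 8},
    {"disease": "IBDD",   "zygosity": "carrier",  "detected": 1,  "total": 1},
    {"disease": "3-MCCD", "zygosity": "affected", "detected": 12, "total": 12},
    {"disease": "3-MCCD", "zygosity": "carrier",  "detected": 26, "total": 29},
    {"disease": "3-HMGD", "zygosity": "carrier",  "detected": 4,  "total": 4},
    {"disease": "NICCD",  "zygosity": "affected", "detected": 3,  "total": 3},
    {"disease": "CIT-I",  "zygosity": "affected", "detected": 3,  "total": 3},
    {"disease": "CIT-I",  "zygosity": "carrier",  "detected": 5,  "total": 5},
    {"disease": "HMET",   "zygosity": "affected", "detected": 1,  "total": 1},
    {"disease": "HMET",   "zygosity": "carrier",  "detected": 5,  "total": 8},
    {"disease": "2-MBDD", "zygosity": "affected", "detected": 4,  "total": 4},
    {"disease": "MCADD",  "zygosity": "affected", "detected": 2,  "total": 2},
    {"disease": "MCADD",  "zygosity": "carrier",  "detected": 0,  "total": 1},
    {"disease": "GA-II",  "zygosity": "affected", "detected": 1,  "total": 1},
    {"disease": "OTCD",   "zygosity": "affected", "detected": 1,  "total": 1},
    {"disease": "HARG",   "zygosity": "carrier",  "detected": 1,  "total": 1}
  ],
  "pooled_zygosity_tp": {
    "affected": {"detected": 70, "total": 72},
    "carrier": {"detected": 71, "total": 80}
  },
  "incidence": {
    "all_imd": {"cases": 152, "screened": 309102},
    "3-MCCD": {"cases": 41, "screened": 309102}
  }
}
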