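{
  "description": "Externally reported base-case summary statistics for the six regimens (means as printed: USD, years, QALYs). Shipped for arithmetic consistency checks; not produced by this package.",
  "wtp": 12728,
  "base_case": {
    "exenatide": {"cost": 42114, "life_years": 23.87, "qaly": 12.56, "nmb": 117736},
    "liraglutide": {"cost": 47026, "life_years": 23.86, "qaly": 12.58, "nmb": 113069},
    "loxenatide": {"cost": 42092, "life_years": 24.01, "qaly": 12.65, "nmb": 118865},
    "dulaglutide": {"cost": 42763, "life_years": 23.67, "qaly": 12.5, "nmb": 116325},
    "semaglutide": {"cost": 46414, "life_years": 23.74, "qaly": 12.56, "nmb": 113442},
    "lixisenatide": {"cost": 44016, "life_years": 23.79, "qaly": 12.52, "nmb": 116029,
                     "note": "printed cost lies outside its own interval; excluded from identity checks"}
  },
  "complication_breakdown": {
    "categories": ["amputation", "cataract", "mi", "pvd", "retinopathy",
                   "heart_failure", "ihd", "renal_failure", "stroke",
                   "neuropathy", "ulcer", "hypoglycemia"],
    "cost": {
      "dulaglutide": {"components": [93.3, 286.9, 465.01, 138.49, 46.74, 930.87, 702.91, 5890.51, 750.11, 140.23, 228.73, 67.422], "sum": 9741.24},
      "liraglutide": {"components": [96.96, 289.22, 467.37, 139.2, 50.39, 1641.47, 700.97, 5919.25, 724.05, 125.95, 245.51, 67.296], "sum": 10467.62},
      "loxenatide": {"components": [84.71, 278.21, 445.44, 150.14, 43.25, 907.02, 715.82, 6040.8, 715.51, 291.81, 239.05, 68.091], "sum": 9979.85},
      "semaglutide": {"components": [79.59, 271.93, 451.15, 136.21, 41.86, 888.99, 687.61, 5598.65, 698.56, 136.03, 198.93, 67.049], "sum": 9256.56},
      "exenatide": {"components": [122.61, 299.34, 487.43, 156.71, 55.9, 946.97, 717.78, 6608.31, 746.22, 145.34, 252.77, 67.671], "sum": 10607.06},
      "lixisenatide": {"components": [135.67, 300.39, 480.52, 150.71, 57.1, 950.71, 685.6, 6314.71, 754.29, 153.94, 275.2, 67.346], "sum": 10326.18}
    },
    "disutility": {
      "dulaglutide": {"components": [0.012, 0.027, 0.079, 0.003, 0.001, 0.078, 0.021, 0.067, 0.11, 0.003, 0.014, 0.0], "sum": 0.42},
      "liraglutide": {"components": [0.013, 0.027, 0.08, 0.003, 0.001, 0.078, 0.021, 0.067, 0.106, 0.003, 0.016, 0.0], "sum": 0.41},
      "loxenatide": {"components": [0.011, 0.026, 0.076, 0.004, 0.001, 0.076, 0.022, 0.068, 0.105, 0.003, 0.015, 0.0], "sum": 0.41},
      "semaglutide": {"components": [0.01, 0.025, 0.075, 0.003, 0.001, 0.075, 0.021, 0.063, 0.102, 0.003, 0.012, 0.0], "sum": 0.39},
      "exenatide": {"components": [0.016, 0.028, 0.083, 0.004, 0.001, 0.079, 0.022, 0.075, 0.11, 0.003, 0.016, 0.0], "sum": 0.44},
      "lixisenatide": {"components": [0.018, 0.028, 0.081, 0.004, 0.001, 0.08, 0.021, 0.071, 0.111, 0.003, 0.017, 0.0], "sum": 0.44}
    }
  }
}
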