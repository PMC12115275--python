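{
  "_comment": "Measured batch outcomes: mean weight / hardness / diameter for all sixteen formulations, and the full QC row (Hausner ratio of the blend, friability, disintegration) for the R=3.5 series.",
  "batch_summary": {
    "F1":  {"target_R": 5.0, "mean_weight_mg": 187.6, "mean_hardness_N": 147.7, "diameter_mm": 9},
    "F2":  {"target_R": 5.0, "mean_weight_mg": 172.9, "mean_hardness_N": 159.9, "diameter_mm": 9},
    "F3":  {"target_R": 5.0, "mean_weight_mg": 697.6, "mean_hardness_N": 331.8, "diameter_mm": 13},
    "F4":  {"target_R": 5.0, "mean_weight_mg": 250.0, "mean_hardness_N": 230.5, "diameter_mm": 9},
    "F5":  {"target_R": 4.5, "mean_weight_mg": 160.9, "mean_hardness_N": 121.9, "diameter_mm": 8},
    "F6":  {"target_R": 4.5, "mean_weight_mg": 112.0, "mean_hardness_N": 113.4, "diameter_mm": 8},
    "F7":  {"target_R": 4.5, "mean_weight_mg": 172.7, "mean_hardness_N": 48.0, "diameter_mm": 8},
    "F8":  {"target_R": 4.5, "mean_weight_mg": 131.3, "mean_hardness_N": 78.3, "diameter_mm": 8},
    "F9":  {"target_R": 4.0, "mean_weight_mg": 83.0, "mean_hardness_N": 77.0, "diameter_mm": 6},
    "F10": {"target_R": 4.0, "mean_weight_mg": 82.7, "mean_hardness_N": 73.2, "diameter_mm": 6},
    "F11": {"target_R": 4.0, "mean_weight_mg": 101.5, "mean_hardness_N": 55.4, "diameter_mm": 6},
    "F12": {"target_R": 4.0, "mean_weight_mg": 88.4, "mean_hardness_N": 21.2, "diameter_mm": 6},
    "F13": {"target_R": 3.5, "mean_weight_mg": 67.0, "mean_hardness_N": 62.5, "diameter_mm": 5},
    "F14": {"target_R": 3.5, "mean_weight_mg": 62.8, "mean_hardness_N": 24.8, "diameter_mm": 5},
    "F15": {"target_R": 3.5, "mean_weight_mg": 69.9, "mean_hardness_N": 27.6, "diameter_mm": 5},
    "F16": {"target_R": 3.5, "mean_weight_mg": 68.1, "mean_hardness_N": 37.4, "diameter_mm": 5}
  },
  "qc_r35": {
    "F13": {"hausner_ratio": 1.36, "mean_hardness_N": 62.5, "friability_pct": 0.89,
            "disintegration_s": 50, "diameter_mm": 5},
    "F14": {"hausner_ratio": 1.32, "mean_hardness_N": 24.8, "friability_pct": 0.38,
            "disintegration_s": 45, "diameter_mm": 5},
    "F15": {"hausner_ratio": 1.19, "mean_hardness_N": 27.6, "friability_pct": 0.89,
            "disintegration_s": 103, "diameter_mm": 5},
    "F16": {"hausner_ratio": 1.23, "mean_hardness_N": 37.4, "friability_pct": 1.00,
            "disintegration_s": 420, "diameter_mm": 5}
  }
}
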