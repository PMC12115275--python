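{
  "_comment": "Published 12-radius SeDeM profiles, printed incidence means and printed IGC for the API and the four candidate disintegrants, plus the two optimized blends (F13/F14). Radius order keys are the canonical parameter ids.",
  "carbamazepine": {
    "radii": {"Da": 5.84, "Dc": 7.02, "Ie": 2.39, "IC": 3.36, "Icd": 3.00,
              "IH": 8.99, "alpha": 4.69, "t_flow": 8.17, "HR": 9.67, "H": 9.95,
              "Pf": 7.80, "Itheta": 1.25},
    "printed_incidences": {"dimensions": 6.44, "compressibility": 2.92,
                           "flowability": 7.28, "lubricity_stability": 9.81,
                           "lubricity_dosage": 4.53},
    "printed_igc": 5.72,
    "role": "API"
  },
  "L-HPC LH11": {
    "radii": {"Da": 3.84, "Dc": 5.52, "Ie": 6.61, "IC": 6.09, "Icd": 4.99,
              "IH": 7.81, "alpha": 1.19, "t_flow": 0.00, "HR": 3.10, "H": 4.77,
              "Pf": 0.00, "Itheta": 6.00},
    "printed_incidences": {"dimensions": 4.68, "compressibility": 5.90,
                           "flowability": 3.00, "lubricity_stability": 4.93,
                           "lubricity_dosage": 3.00},
    "printed_igc": 4.12,
    "role": "corrective-excipient",
    "igc_path": "printed_incidences"
  },
  "L-HPC NBD022": {
    "radii": {"Da": 3.52, "Dc": 5.51, "Ie": 8.55, "IC": 7.22, "Icd": 2.22,
              "IH": 7.18, "alpha": 3.10, "t_flow": 0.00, "HR": 6.02, "H": 3.89,
              "Pf": 0.00, "Itheta": 7.65},
    "printed_incidences": {"dimensions": 4.52, "compressibility": 6.00,
                           "flowability": 3.42, "lubricity_stability": 4.95,
                           "lubricity_dosage": 3.83},
    "printed_igc": 4.35,
    "role": "corrective-excipient",
    "igc_path": "printed_incidences"
  },
  "PARTECK ODT": {
    "radii": {"Da": 5.28, "Dc": 6.20, "Ie": 2.34, "IC": 2.97, "Icd": 9.42,
              "IH": 9.13, "alpha": 4.60, "t_flow": 8.17, "HR": 8.12, "H": 9.69,
              "Pf": 7.40, "Itheta": 1.85},
    "printed_incidences": {"dimensions": 5.74, "compressibility": 4.91,
                           "flowability": 7.30, "lubricity_stability": 8.90,
                           "lubricity_dosage": 4.63},
    "printed_igc": 5.96,
    "role": "corrective-excipient",
    "backsolved_compressibility_radius": 5.25
  },
  "PROSOLV ODT": {
    "radii": {"Da": 6.19, "Dc": 7.82, "Ie": 2.81, "IC": 4.17, "Icd": 10.00,
              "IH": 8.69, "alpha": 5.09, "t_flow": 8.00, "HR": 6.18, "H": 9.78,
              "Pf": 2.57, "Itheta": 4.75},
    "printed_incidences": {"dimensions": 7.01, "compressibility": 5.66,
                           "flowability": 7.26, "lubricity_stability": 7.98,
                           "lubricity_dosage": 3.66},
    "printed_igc": 6.03,
    "role": "corrective-excipient"
  },
  "F13": {
    "radii": {"Da": 4.84, "Dc": 6.59, "Ie": 4.58, "IC": 5.31, "Icd": 10.00,
              "IH": 8.19, "alpha": 3.30, "t_flow": 3.67, "HR": 7.63, "H": 8.24,
              "Pf": 2.69, "Itheta": 1.85},
    "printed_incidences": {"dimensions": 5.72, "compressibility": 6.63,
                           "flowability": 5.05, "lubricity_stability": 7.94,
                           "lubricity_dosage": 2.27},
    "printed_igc": 5.31,
    "role": "blend"
  },
  "F14": {
    "radii": {"Da": 4.73, "Dc": 6.49, "Ie": 4.78, "IC": 5.42, "Icd": 10.00,
              "IH": 8.14, "alpha": 3.76, "t_flow": 0.00, "HR": 7.77, "H": 8.55,
              "Pf": 0.62, "Itheta": 1.95},
    "printed_incidences": {"dimensions": 5.61, "compressibility": 6.73,
                           "flowability": 3.97, "lubricity_stability": 8.16,
                           "lubricity_dosage": 1.28},
    "printed_igc": 4.94,
    "role": "blend"
  }
}
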