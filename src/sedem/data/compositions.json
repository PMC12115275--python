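{
  "_comment": "Published formulation compositions (percent) for the 4x4 sweep of corrective excipients over target compressibility radii; 50 mg dose throughout.",
  "target_radii": {"5.0": ["F1", "F2", "F3", "F4"],
                   "4.5": ["F5", "F6", "F7", "F8"],
                   "4.0": ["F9", "F10", "F11", "F12"],
                   "3.5": ["F13", "F14", "F15", "F16"]},
  "excipient_by_formulation": {
    "F1": "L-HPC LH11", "F5": "L-HPC LH11", "F9": "L-HPC LH11", "F13": "L-HPC LH11",
    "F2": "L-HPC NBD022", "F6": "L-HPC NBD022", "F10": "L-HPC NBD022", "F14": "L-HPC NBD022",
    "F3": "PARTECK ODT", "F7": "PARTECK ODT", "F11": "PARTECK ODT", "F15": "PARTECK ODT",
    "F4": "PROSOLV ODT", "F8": "PROSOLV ODT", "F12": "PROSOLV ODT", "F16": "PROSOLV ODT"
  },
  "carbamazepine_pct": {
    "F1": 26.70, "F2": 28.97, "F3": 7.23, "F4": 20.59,
    "F5": 43.48, "F6": 45.20, "F7": 28.69, "F8": 38.84,
    "F9": 60.26, "F10": 61.44, "F11": 50.15, "F12": 57.08,
    "F13": 77.04, "F14": 77.67, "F15": 71.61, "F16": 75.33
  },
  "excipient_pct": {
    "F1": 69.80, "F2": 67.53, "F3": 89.27, "F4": 75.91,
    "F5": 53.02, "F6": 51.30, "F7": 67.81, "F8": 57.66,
    "F9": 36.24, "F10": 35.06, "F11": 46.35, "F12": 39.42,
    "F13": 19.46, "F14": 18.83, "F15": 24.89, "F16": 21.17
  },
  "lubricants_pct": {"talc": 2.36, "colloidal_silicon_dioxide": 0.14,
                     "magnesium_stearate": 1.00}
}
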