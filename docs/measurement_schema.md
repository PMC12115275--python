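# Measurement CSV column dictionary

One file per material; UTF-8, comma-separated, header row mandatory.
Each row is one instrument record, selected by `record_kind`. List-valued
cells pack their entries with semicolons (`95;84;83.2`). The optional
`replicate` column (integer, default 1) groups rows into replicate
campaigns; a replicate needs all six record kinds before the twelve
parameters can be computed.

| record_kind | required columns | optional columns | units / notes |
|-------------|------------------|------------------|---------------|
| `density`   | `mass_g`, `volume_initial_mL`, `tap_counts`, `tap_volumes_mL` | | tap counts typically `10;500;1250` (add `2500` when the 500- vs 1250-tap volumes differ by more than 2 mL); volumes non-increasing, ≤ initial volume |
| `cone`      | `height_cm`, `base_radii_cm` | | exactly four base radii |
| `flow`      | `times_s` | `nonflow` (0/1) | three stopwatch times, s per 100 g; `nonflow=1` means the powder did not flow (no times needed) |
| `moisture`  | `wet_weight_g`, `dry_weight_g`, `humid_weight_g` | | dry after 105 °C to constant weight; humid after 24 h at 76 % RH |
| `sieve`     | `retained_pct` | `apertures_mm` (default `0.355;0.212;0.1;0.05`), `top_bound_mm` (default `0.5`) | one percentage per sieve plus the pan, summing to 100 ± 0.01 |
| `hardness`  | `forces_N` | `lubricated` (0/1) | per-tablet breaking forces; flag set when the 3.5 % standardized lubricant mixture was added |

Example:

```csv
record_kind,replicate,mass_g,volume_initial_mL,tap_counts,tap_volumes_mL,height_cm,base_radii_cm,times_s,nonflow,wet_weight_g,dry_weight_g,humid_weight_g,retained_pct,forces_N,lubricated
density,1,58.4,100,10;500;1250,95;84;83.2,,,,,,,,,,
cone,1,,,,,2.5,5;5;5;5,,,,,,,,
flow,1,,,,,,,3.6;3.7;3.7,0,,,,,,
moisture,1,,,,,,,,,100,99.67,100.1,,,
sieve,1,,,,,,,,,,,,"36.5;0;45;7.5;11",,
hardness,1,,,,,,,,,,,,,60;62;58,1
```

Malformed rows raise an error citing the line number. Parsing yields one
`PowderDataset` per replicate; `sedem characterize` averages parameters
across replicates before the radius transform.
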