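# sedem — SeDeM expert-system toolkit for direct-compression preformulation

`sedem` implements the SeDeM diagram methodology used in pharmaceutical
preformulation: it turns raw powder-characterization measurements into the
twelve standardized SeDeM parameters, maps them onto a 12-axis radar
profile, computes the suitability indices (IPP, reliability factor *f*,
Good Compression Index), doses a corrective excipient with the
CP = 100 − 100·(RE − R)/(RE − RP) equation, and evaluates tablet batches
against a QTPP/CQA rule set. It ships the reference dataset of a
50 mg carbamazepine orally disintegrating mini-tablet development
(API + four disintegrants + the two optimized blends) and a seeded
synthetic-measurement generator so the whole pipeline is testable without
any instrument.

Audience: formulation scientists and method developers who want the SeDeM
arithmetic reproducible, scriptable and unit-tested instead of living in a
spreadsheet.

## The model in brief

Twelve parameters — bulk/tapped density (`Da`, `Dc`), interparticle
porosity `Ie = (Dc−Da)/(Dc·Da)`, Carr index `IC = 100(Dc−Da)/Dc`, cohesion
index `Icd` (mean breaking force), Hausner ratio `IH = Dc/Da`, angle of
repose `α = atan(h/r̄)`, flow time `t″`, loss on drying `%HR`,
hygroscopicity `%H`, fines `%Pf`, homogeneity index `Iθ` — are each mapped
by an affine rule onto a radius in [0, 10] (10 = favorable). Radii are
grouped into five incidence factors (dimensions, compressibility,
flowability, lubricity/stability, lubricity/dosage); the mean radius is
the parametric profile index IPP, and

    IGC = IPP × f        (f = 0.952 for 12 axes)

with IGC > 5 indicating suitability for direct compression. A
compressibility-deficient API is corrected by blending in an excipient
percentage CP from the equation above, plus a fixed lubricant trio
(talc 2.36 %, colloidal SiO₂ 0.14 %, Mg stearate 1.00 %). See
`docs/methods.md` for the full model, conventions and limitations.

## Worked example

```python
from sedem import fixtures
from sedem.design import r_sweep
from sedem.profile import good_compression_index, round_half_away

profiles = fixtures.material_profiles()
api = profiles["carbamazepine"]

gc = good_compression_index(api)
print(round_half_away(gc["igc"]))                     # 5.72  -> suitable overall
print(round_half_away(api.incidence_means()["compressibility"]))  # 2.92 -> deficient

outcomes = r_sweep(
    fixtures.compressibility_material("carbamazepine"),   # RP = 2.92
    fixtures.compressibility_material("L-HPC LH11"),      # RE = 5.90
)
for o in outcomes:
    print(o.target_R, round_half_away(o.design.cp_pct),
          round_half_away(o.design.tablet_weight_mg))
# 5.0 69.8 187.26
# 4.5 53.02 115.0
# 4.0 36.24 82.98
# 3.5 19.46 64.9
```

Reading: carbamazepine's global index (5.72) clears the direct-compression
bar but its compressibility incidence (2.92 < 5) does not, so a
corrective disintegrant is dosed. Relaxing the target compressibility
radius from 5.0 to 3.5 cuts the excipient from 69.8 % to 19.5 % and the
50 mg-dose tablet weight from 187 mg to 65 mg — the step that makes a
5 mm pediatric mini-tablet possible.

The numbered scripts under `analysis/` run the full study narrative and
write their tables to `results/`:

```bash
python analysis/01_characterize_materials.py   # indices + SVG diagrams for 7 materials
python analysis/02_design_formulations.py      # the 16-formulation composition sweep
python analysis/03_qc_tablets.py               # QTPP/CQA verdicts for the R=3.5 batches
python analysis/04_simulation_recovery.py      # simulator closure + noise recovery
```

There is also a CLI (`sedem characterize | profile | design | qc |
simulate | report | pipeline`); the measurement CSV dialect is documented
in `docs/measurement_schema.md`.

## Layout

```
src/sedem/        library: types, powder, profile, design, qc, simulate,
                  fixtures (+ bundled reference tables), io, pipeline, cli
analysis/         numbered study drivers (write to results/)
tests/            pytest suite incl. property tests and the end-to-end
                  reproduction of the reference tables
docs/             methods note and measurement-file schema
scripts/          acceptance script
```
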