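# Methods

This package implements the SeDeM expert-system workflow for deciding
whether a powder — an active pharmaceutical ingredient (API), an excipient,
or a blend — can be tableted by direct compression, and for dosing a
corrective excipient when it cannot. The worked system is the development
of 50 mg carbamazepine orally disintegrating mini-tablets for pediatric
use, but every stage accepts new inputs.

## The SeDeM model

Twelve rheological and galenic parameters are measured per material and
grouped into five *incidence factors*:

| incidence factor     | parameters                                   |
|----------------------|----------------------------------------------|
| dimensions           | bulk density `Da`, tapped density `Dc`       |
| compressibility      | interparticle porosity `Ie`, Carr index `IC`, cohesion index `Icd` |
| flowability          | Hausner ratio `IH`, angle of repose `α`, flow time `t″` |
| lubricity/stability  | loss on drying `%HR`, hygroscopicity `%H`    |
| lubricity/dosage     | fines `%Pf` (< 50 µm), homogeneity index `Iθ` |

with

- `Da = m/V0`, `Dc = m/V1250` (or `m/V2500` when the 500- vs 1250-tap
  volumes differ by more than 2 mL; Ph. Eur. 2.9.34),
- `Ie = (Dc − Da)/(Dc·Da)`, `IC = 100 (Dc − Da)/Dc`, `IH = Dc/Da`,
- `α = atan(h/r̄)` from the cone height and the mean of four base radii,
- `Icd` = mean breaking force (N) of tablets compressed from the powder
  (with the standardized 3.5 % lubricant trio when the raw powder will not
  compress),
- `%HR` and `%H` = percent weight change on drying at 105 °C and after
  24 h at 76 % relative humidity,
- `Iθ = Fm / (100 + Σ_j |d_m − d_j| F_j)` over the sieve fractions, where
  `Fm` is the majority fraction's percentage and `d` are fraction mean
  diameters in µm.

Each parameter value `v` is mapped onto a **radius** `r ∈ [0, 10]` by an
affine rule (e.g. Carr index `v/5`, Hausner `(30 − 10v)/2`, homogeneity
`500 v`) that sends the favorable end of its acceptable range to 10 and the
unfavorable end to 0, clamped outside. The mean of the twelve radii is the
parametric profile index `IPP`; the **Good Compression Index** is

    IGC = IPP × f ,   f = polygon area / circle area ,

where `f` defaults to the conventional 0.952 for twelve axes. `IGC > 5`
marks a powder as directly compressible; an incidence factor below 5 marks
a correctable deficiency.

A compressibility-deficient API (radius `RP`) is corrected with an
excipient of compressibility incidence `RE > RP`; the excipient percentage
needed to bring the pair to a target incidence `R` is

    CP = 100 − 100 (RE − R)/(RE − RP) ,

the linear interpolation between `RP` (CP = 0) and `RE` (CP = 100). `CP`
is increasing in `R` and decreasing in `RP`. The standardized lubricant
trio (talc 2.36 %, colloidal silicon dioxide 0.14 %, magnesium stearate
1.00 %) is layered on afterwards, so API % = 100 − CP − 3.5 and the tablet
weight for dose `D` is `D/(API %/100)`.

## Numerical and design choices

**Interparticle-porosity formula.** Two printed variants of the `Ie`
formula circulate; `(Dc − Da)/(Dc·Da)` is implemented, as it is the only
form whose forward transform lands on the reference carbamazepine radius
(2.39–2.40).

**Reliability factor.** `f = 0.952` is the default because it reproduces
every reference IGC exactly (e.g. 6.011 × 0.952 = 5.72); the exact
regular-polygon ratio `(n/2π)·sin(2π/n) = 0.9549` is available via
`reliability_factor(12, "geometric")`.

**Rounding.** Radii and indices are carried at full precision internally;
comparisons with published values round to 2 decimals, half away from
zero. The dose equation consumes incidence radii **rounded to 2 decimals**
(`RE = 5.90`, `RP = 2.92`, …): that is the precision at which profiles are
reported and the only convention that regenerates the published
composition table digit for digit (full precision gives e.g. 69.91 %
instead of 69.80 % for the first L-HPC LH11 design).

**Sieve fraction diameters.** Fraction mean diameters are midpoints of the
bounding apertures in µm (pan: 25 µm; coarsest fraction bounded above by a
configurable 500 µm, consistent with 0.6 mm pre-sieving of blends). A tie
for the majority fraction resolves to the coarser fraction with a warning.

**Degenerate inputs.** `Da = Dc` gives `Ie = IC = 0`, `IH = 1` exactly; a
powder that does not flow carries `t_flow = +inf` and maps to radius 0; a
flat cone (`h = 0`) gives `α = 0`; negative hygroscopicity (weight loss at
76 % RH) is floored at 0 with a warning, since the transform range 20–0
presumes non-negative uptake.

**Inconsistent reference tables.** The transcribed L-HPC LH11 table is
internally inconsistent: its per-parameter radii give a
lubricity/stability incidence of 3.94 versus the printed 4.93, and a
radius-path IGC of 3.96 versus the published 4.12. For such profiles the
IGC is recomputed from the printed incidence means (count-weighted by
group sizes 2/3/3/2/2), the path is recorded, and the discrepancy is
surfaced by `check_incidence_consistency` — never silently edited.
Similarly the published PARTECK ODT composition column back-solves to a
compressibility incidence of 5.25, not the printed 4.91 (under which the
R = 5.0 design is infeasible, since `R > RE`); both values are stored and
the infeasibility is flagged rather than extrapolated past CP = 100 %.

**Replicates.** When a material is characterized in replicate, parameters
are computed per replicate and averaged before the radius transform (the
reporting default); per-replicate profiles remain available.

## Quality control rules

The QTPP for pediatric orally disintegrating mini-tablets is encoded as
machine-readable limits: diameter < 7 mm, disintegration ≤ 180 s, dose
50 mg, friability ≤ 1.0 % ("not more than": exactly 1.00 % passes at the
limit, with a note), and weight variation per Ph. Eur. 2.9.5 (band 10 %
below 80 mg mean weight, 7.5 % for 80–250 mg, 5 % above; at most two units
beyond the band, none beyond twice it). Hardness uses a 25–60 N window
taken as **advisory**: a batch outside it is flagged, not failed, because
a slightly harder tablet can still meet every disintegration and
friability target (the 62.5 N reference batch does). Missing attributes
are reported as not assessed and make the overall verdict indeterminate.

## Synthetic measurement generator

The generator inverts a target radius profile to a physically consistent
raw campaign: cylinder volumes at a poured volume of 100 mL, cone height
on a 5 cm mean base radius, three stopwatch flow times, 100 g moisture
weights, ten breaking forces at the target mean, and a five-fraction sieve
composition. Because `Ie`, `IC` and `IH` are functions of the densities, a
ground truth is fully specified by nine independent quantities; the
dependent three follow, so recovered radii can differ from a rounded
published column by up to ~0.009 (within the ±0.01 closure tolerance used
throughout).

The sieve composition hitting a target `(Iθ, %Pf)` pair is found by a
deterministic search: the pan is fixed at `%Pf`; for every choice of
majority fraction and a 0.1 %-step grid on its share, the remaining mass
is split between a pair of other fractions by solving the (linear)
denominator equation of `Iθ` exactly. The best candidate must match the
target within 2 × 10⁻⁵ in `Iθ` (0.01 on the radius scale) or an
infeasible-truth error is raised.

Noise is multiplicative Gaussian on every raw reading (relative SD is the
single dial), truncated to preserve the type invariants: tap volumes are
re-monotonized, the dry weight capped at the wet weight, sieve masses
renormalized to 100 %. Each replicate consumes a fixed-length block of 32
standard-normal draws regardless of noise level, so recovery experiments
at different noise levels share common random numbers and their RMSE
curves are directly comparable; at zero noise the factors are exactly 1
and the campaign closes on the ground truth.

What the generator does **not** emulate: real inter-replicate powder
heterogeneity (segregation, electrostatics), correlated instrument errors,
operator effects, or any mechanistic link from composition to hardness or
disintegration. Passing recovery tests therefore demonstrate that the
computational pipeline is self-consistent and noise-stable, not that the
measurement model captures every real-world failure mode; the measured
batch outcomes in the bundled tables are observational fixtures, never
predictions.

## Problem sizes

All index arithmetic is desk scale (twelve numbers per material). The
recovery study in `analysis/04_simulation_recovery.py` uses 100 Monte
Carlo replicates per noise level at 0 / 1 / 2 / 5 % relative SD with a
fixed seed — enough for stable two-digit RMSE estimates while keeping the
whole analysis suite under a minute on one CPU.

## Known limitations

- Tablet diameter is tooling-dependent and is consumed as a measured
  input, never computed from the composition.
- The dose equation treats the blend incidence as exactly linear in the
  excipient mass fraction; real blends can deviate (the reference blends'
  measured compressibility incidences, 6.63 and 6.73, exceed their linear
  targets of 3.5).
- The weight-variation bands are the compendial uncoated-tablet bands;
  other dosage forms need different rules.
- `f` for diagrams with a parameter count other than 12 is only available
  in geometric mode.
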