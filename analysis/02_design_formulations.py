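#!/usr/bin/env python
"""Design the 16-formulation sweep with the corrective-excipient equation.

For each disintegrant the dose equation CP = 100 - 100 (RE - R)/(RE - RP)
is evaluated over the decreasing target-radius series (5.0, 4.5, 4.0, 3.5)
at a fixed 50 mg dose, layering on the standardized lubricant trio (talc
2.36%, colloidal silicon dioxide 0.14%, magnesium stearate 1.00%). The
recomputed percentages are compared with the published composition table.

Findings reproduced here:

* the three recomputable excipients match the published sweep exactly
  (e.g. L-HPC LH11: 69.80 / 53.02 / 36.24 / 19.46 % excipient);
* PARTECK ODT is infeasible at R = 5.0 under its printed compressibility
  incidence of 4.91 (a target above RE cannot be blended); the published
  column back-solves to RE = 5.25 exactly, under which it reproduces;
* tablet weight falls along the sweep (less excipient, fixed dose): the
  R = 3.5 designs weigh 64.9-69.8 mg, enabling 5 mm pediatric tablets.

Writes results/table_compositions.csv.
"""

from pathlib import Path

import pandas as pd

from sedem import fixtures
from sedem.design import r_sweep
from sedem.profile import round_half_away

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    api = fixtures.compressibility_material("carbamazepine")
    published = fixtures.composition_table().set_index("formulation")

    rows = []
    for name in fixtures.MATERIALS[1:]:
        for variant, backsolved in (("printed", False), ("backsolved", True)):
            exc = fixtures.compressibility_material(name, use_backsolved=backsolved)
            if variant == "backsolved" and exc.compressibility_radius == round_half_away(
                fixtures.material_profiles()[name].incidence_means()["compressibility"]
            ):
                continue  # no separate back-solved value for this excipient
            for o in r_sweep(api, exc):
                row = {
                    "excipient": name,
                    "RE_source": variant,
                    "RE": exc.compressibility_radius,
                    "target_R": o.target_R,
                    "feasible": o.feasible,
                }
                if o.feasible:
                    row.update(
                        cp_pct=round_half_away(o.design.cp_pct),
                        api_pct=round_half_away(o.design.api_pct),
                        tablet_weight_mg=round_half_away(o.design.tablet_weight_mg),
                    )
                else:
                    row["reason"] = o.reason
                rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "table_compositions.csv", index=False)
    print(df.to_string(index=False))

    # compare against the published table, using the back-solved RE variant
    # where one exists (it is the one that reproduces the printed column)
    has_backsolved = set(df.loc[df.RE_source == "backsolved", "excipient"])
    checked, mismatches = 0, []
    for _, row in df[df.feasible].iterrows():
        wanted = "backsolved" if row.excipient in has_backsolved else "printed"
        if row.RE_source != wanted:
            continue
        pub = published[
            (published.excipient == row.excipient)
            & (published.target_R == row.target_R)
        ].iloc[0]
        checked += 1
        if row.cp_pct != pub.excipient_pct or row.api_pct != pub.api_pct:
            mismatches.append((row.excipient, row.target_R))
    print(f"\nChecked {checked} recomputed compositions against the published "
          f"table; mismatches: {mismatches or 'none'}")


if __name__ == "__main__":
    main()
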