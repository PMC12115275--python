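"""End-to-end pipeline: characterize -> profile -> design -> QC -> report.

A :class:`RunConfig` names the measurement files and design choices; the
pipeline writes parameter-set JSONs, radius-profile JSONs and SVG diagrams,
the composition sweep CSV, QC verdict JSONs and a markdown summary into the
output directory. Hard errors abort the stage that raised them; results of
completed stages are preserved on disk.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import fixtures
from .design import DesignOutcome, MaterialProfile, r_sweep
from .io import characterize, parameter_set_to_json, parse_measurements
from .profile import (
    RadiusProfile,
    diagram,
    good_compression_index,
    igc_from_incidences,
    reliability_factor,
    round_half_away,
)
from .qc import QTPPRules, TabletBatch, evaluate_cqa


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run (one material set)."""

    api_csv: Optional[str] = None
    excipient_csvs: dict[str, str] = Field(default_factory=dict)
    qc_batches: dict[str, dict] = Field(default_factory=dict)
    f_mode: Literal["printed", "geometric"] = "printed"
    target_radii: tuple[float, ...] = (5.0, 4.5, 4.0, 3.5)
    dose_mg: float = Field(default=50.0, gt=0)
    output_dir: str = "sedem_output"
    seed: int = 0


def _profile_for(csv_path: str, f: float) -> RadiusProfile:
    datasets = parse_measurements(csv_path)
    params, _prov = characterize(datasets)
    return RadiusProfile.from_parameters(params, name=datasets[0].name, f=f)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the report bundle as a dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    f = reliability_factor(12, config.f_mode)
    bundle: dict = {"f": f, "profiles": {}, "designs": {}, "qc": {}}

    profiles: dict[str, RadiusProfile] = {}
    api_profile: Optional[RadiusProfile] = None
    if config.api_csv:
        datasets = parse_measurements(config.api_csv)
        params, prov = characterize(datasets)
        parameter_set_to_json(params, out / "api_parameters.json", prov)
        api_profile = RadiusProfile.from_parameters(params, name=datasets[0].name, f=f)
        profiles[api_profile.name] = api_profile
    for name, csv_path in config.excipient_csvs.items():
        prof = _profile_for(csv_path, f)
        prof = prof.model_copy(update={"name": name})
        profiles[name] = prof

    for name, prof in profiles.items():
        slug = name.replace(" ", "_").replace("/", "-")
        prof.to_json(out / f"profile_{slug}.json")
        diagram(prof, out / f"diagram_{slug}.svg")
        bundle["profiles"][name] = good_compression_index(prof)

    if api_profile is not None and config.excipient_csvs:
        rp = api_profile.incidence_means()["compressibility"]
        api_mat = MaterialProfile(
            name=api_profile.name, role="API",
            compressibility_radius=round_half_away(rp),
        )
        rows = []
        for name in config.excipient_csvs:
            re_val = profiles[name].incidence_means()["compressibility"]
            exc_mat = MaterialProfile(
                name=name, role="corrective-excipient",
                compressibility_radius=round_half_away(re_val),
            )
            outcomes = r_sweep(api_mat, exc_mat, config.target_radii, config.dose_mg)
            bundle["designs"][name] = [o.model_dump() for o in outcomes]
            rows.extend(_design_rows(name, outcomes))
        pd.DataFrame(rows).to_csv(out / "compositions.csv", index=False)

    rules = QTPPRules(dose_mg=config.dose_mg)
    for name, fields in config.qc_batches.items():
        batch = TabletBatch(name=name, **fields)
        report = evaluate_cqa(batch, rules)
        (out / f"qc_{name}.json").write_text(report.model_dump_json(indent=2))
        bundle["qc"][name] = report.model_dump()

    _write_summary(bundle, out / "summary.md")
    return bundle


def _design_rows(excipient: str, outcomes: list[DesignOutcome]) -> list[dict]:
    rows = []
    for o in outcomes:
        row: dict = {"excipient": excipient, "target_R": o.target_R, "feasible": o.feasible}
        if o.feasible and o.design is not None:
            row.update(
                {
                    "api_pct": round_half_away(o.design.api_pct),
                    "excipient_pct": round_half_away(o.design.cp_pct),
                    "tablet_weight_mg": round_half_away(o.design.tablet_weight_mg),
                }
            )
        else:
            row["reason"] = o.reason
        rows.append(row)
    return rows


def _write_summary(bundle: dict, path: Path) -> None:
    lines = ["# SeDeM pipeline summary", ""]
    if bundle["profiles"]:
        lines += ["## Profiles", "",
                  "| material | IPP | IGC | suitable (IGC > 5) |", "|---|---|---|---|"]
        for name, gc in bundle["profiles"].items():
            lines.append(
                f"| {name} | {gc['ipp']:.2f} | {gc['igc']:.2f} | {gc['suitable']} |"
            )
        lines.append("")
    if bundle["designs"]:
        lines += ["## Corrective-excipient designs", ""]
        for name, outcomes in bundle["designs"].items():
            for o in outcomes:
                if o["feasible"]:
                    d = o["design"]
                    api_pct = 100.0 - d["cp_pct"] - 3.5
                    lines.append(
                        f"- {name} at R={o['target_R']}: CP={d['cp_pct']:.2f}%, "
                        f"API={api_pct:.2f}%"
                    )
                else:
                    lines.append(f"- {name} at R={o['target_R']}: infeasible ({o['reason']})")
        lines.append("")
    if bundle["qc"]:
        lines += ["## QC verdicts", ""]
        for name, rep in bundle["qc"].items():
            lines.append(f"- {name}: {rep['overall']}")
        lines.append("")
    path.write_text("\n".join(lines))


def fixtures_report(output_dir: str | Path) -> dict:
    """Fixtures-only pipeline over the bundled published tables.

    Recomputes every profile's incidence means, IPP and IGC (via the
    printed-incidence path where a table is internally inconsistent), the
    corrective-excipient sweep for each excipient, and the QC verdicts of
    the R=3.5 batches; writes CSV/JSON artifacts plus a summary.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = fixtures.material_profiles()

    profile_rows = []
    for name, prof in profiles.items():
        gc = good_compression_index(prof)
        igc = gc["igc"]
        if fixtures.igc_path(name) == "printed_incidences":
            igc = igc_from_incidences(prof.printed_incidences)
        profile_rows.append(
            {
                "material": name,
                **{f"incidence_{g}": round_half_away(v)
                   for g, v in prof.incidence_means().items()},
                "ipp": round_half_away(gc["ipp"]),
                "igc": round_half_away(igc),
                "printed_igc": fixtures.printed_igc(name),
            }
        )
        diagram(prof, out / f"diagram_{name.replace(' ', '_')}.svg")
    profile_df = pd.DataFrame(profile_rows)
    profile_df.to_csv(out / "profiles_recomputed.csv", index=False)

    api = fixtures.compressibility_material("carbamazepine")
    design_rows = []
    for name in fixtures.MATERIALS[1:]:
        exc = fixtures.compressibility_material(name, use_backsolved=True)
        outcomes = r_sweep(api, exc)
        design_rows.extend(_design_rows(name, outcomes))
    design_df = pd.DataFrame(design_rows)
    design_df.to_csv(out / "compositions_recomputed.csv", index=False)

    qc_rows = []
    for name, batch in fixtures.qc_batches().items():
        report = evaluate_cqa(batch)
        (out / f"qc_{name}.json").write_text(report.model_dump_json(indent=2))
        qc_rows.append({"batch": name, "overall": report.overall})
    qc_df = pd.DataFrame(qc_rows)

    bundle = {
        "profiles": profile_df.to_dict(orient="records"),
        "designs": design_df.to_dict(orient="records"),
        "qc": qc_df.to_dict(orient="records"),
    }
    (out / "fixtures_report.json").write_text(json.dumps(bundle, indent=2))
    return bundle


__all__ = ["RunConfig", "run_pipeline", "fixtures_report"]
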