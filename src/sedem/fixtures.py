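"""Loaders for the bundled reference profiles, compositions and QC rows.

The JSON files under ``sedem/data`` transcribe published characterization
tables for carbamazepine, four candidate disintegrants and the two
optimized blends (F13/F14), the sixteen-formulation composition sweep, and
the measured tablet-batch outcomes. They serve as ground truth for tests
and as ready-made inputs for the report and acceptance pipelines.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Any

import pandas as pd

from .design import MaterialProfile
from .profile import RadiusProfile, round_half_away
from .qc import TabletBatch

MATERIALS = (
    "carbamazepine",
    "L-HPC LH11",
    "L-HPC NBD022",
    "PARTECK ODT",
    "PROSOLV ODT",
)
BLENDS = ("F13", "F14")


@lru_cache(maxsize=None)
def _load(name: str) -> dict[str, Any]:
    path = resources.files("sedem.data").joinpath(name)
    return json.loads(path.read_text())


def material_profiles() -> dict[str, RadiusProfile]:
    """All bundled 12-radius profiles (materials and blends) by name."""
    raw = _load("material_profiles.json")
    return {
        name: RadiusProfile(
            name=name,
            radii=entry["radii"],
            printed_incidences=entry.get("printed_incidences"),
        )
        for name, entry in raw.items()
        if not name.startswith("_")
    }


def printed_igc(name: str) -> float:
    return _load("material_profiles.json")[name]["printed_igc"]


def igc_path(name: str) -> str:
    """Which recomputation path reproduces the published IGC for a profile:
    ``radii`` (default) or ``printed_incidences`` (transcription-inconsistent
    profiles)."""
    return _load("material_profiles.json")[name].get("igc_path", "radii")


def compressibility_material(
    name: str, use_backsolved: bool = False
) -> MaterialProfile:
    """Material reduced to its compressibility incidence radius for design.

    ``use_backsolved`` substitutes the compressibility radius that exactly
    back-solves the published composition sweep where it disagrees with the
    published incidence (PARTECK ODT: 5.25 vs printed 4.91).
    """
    entry = _load("material_profiles.json")[name]
    profile = material_profiles()[name]
    radius = profile.incidence_means()["compressibility"]
    if use_backsolved and "backsolved_compressibility_radius" in entry:
        radius = entry["backsolved_compressibility_radius"]
    role = "API" if entry.get("role") == "API" else "corrective-excipient"
    return MaterialProfile(
        name=name, role=role, compressibility_radius=round_half_away(radius)
    )


def composition_table() -> pd.DataFrame:
    """Published composition sweep as a tidy frame (one row per formulation)."""
    raw = _load("compositions.json")
    rows = []
    for target, forms in raw["target_radii"].items():
        for f in forms:
            rows.append(
                {
                    "formulation": f,
                    "target_R": float(target),
                    "excipient": raw["excipient_by_formulation"][f],
                    "api_pct": raw["carbamazepine_pct"][f],
                    "excipient_pct": raw["excipient_pct"][f],
                    **{k + "_pct": v for k, v in raw["lubricants_pct"].items()},
                }
            )
    return pd.DataFrame(rows)


def batch_summaries() -> pd.DataFrame:
    """Measured mean weight / hardness / diameter for all 16 formulations."""
    raw = _load("tablet_batches.json")["batch_summary"]
    return (
        pd.DataFrame.from_dict(raw, orient="index")
        .rename_axis("formulation")
        .reset_index()
    )


def qc_batches() -> dict[str, TabletBatch]:
    """The R=3.5 series QC rows as evaluable batches (50 mg dose)."""
    raw = _load("tablet_batches.json")["qc_r35"]
    return {
        name: TabletBatch(
            name=name,
            mean_hardness_N=row["mean_hardness_N"],
            friability_pct=row["friability_pct"],
            disintegration_s=(float(row["disintegration_s"]),),
            diameter_mm=float(row["diameter_mm"]),
            dose_mg=50.0,
        )
        for name, row in raw.items()
    }


__all__ = [
    "MATERIALS",
    "BLENDS",
    "material_profiles",
    "printed_igc",
    "igc_path",
    "compressibility_material",
    "composition_table",
    "batch_summaries",
    "qc_batches",
]
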