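"""Measurement-file parsing and JSON serialization.

The measurement CSV dialect (UTF-8, comma-separated, mandatory header) has
one typed row per instrument record. A ``record_kind`` column selects the
schema; list-valued cells pack their entries with semicolons. An optional
``replicate`` column groups rows into replicate campaigns. The full column
dictionary ships in ``docs/measurement_schema.md``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from .errors import SedemError
from .powder import tapped_density
from .types import (
    PARAMETER_ORDER,
    ConeMeasurement,
    DensityMeasurement,
    FlowMeasurement,
    HardnessSample,
    MoistureRecord,
    ParameterSet,
    PowderDataset,
    SieveAnalysis,
)

RECORD_KINDS = ("density", "cone", "flow", "moisture", "sieve", "hardness")

#: Units of each parameter, used in serialized parameter sets.
PARAMETER_UNITS = {
    "Da": "g/mL", "Dc": "g/mL", "Ie": "-", "IC": "%", "Icd": "N", "IH": "-",
    "alpha": "deg", "t_flow": "s/100g", "HR": "%", "H": "%", "Pf": "%",
    "Itheta": "-",
}


def _floats(cell: str) -> tuple[float, ...]:
    return tuple(float(x) for x in str(cell).split(";") if str(x).strip() != "")


def _flag(cell: Any) -> bool:
    text = str(cell).strip().lower()
    if text in {"", "0", "0.0", "false", "no"}:
        return False
    if text in {"1", "1.0", "true", "yes"}:
        return True
    raise ValueError(f"not a boolean flag: {cell!r}")


def _cell(row: pd.Series, column: str, line: int) -> Any:
    value = row.get(column)
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        # wrapped with the line number by _parse_row
        raise ValueError(f"missing required column {column!r}")
    return value


def _parse_row(row: pd.Series, line: int):
    kind = row.get("record_kind")
    if kind not in RECORD_KINDS:
        raise SedemError(f"line {line}: unknown record_kind {kind!r}")
    try:
        if kind == "density":
            counts = [int(float(c)) for c in str(_cell(row, "tap_counts", line)).split(";")]
            volumes = _floats(_cell(row, "tap_volumes_mL", line))
            if len(counts) != len(volumes):
                raise SedemError("tap_counts and tap_volumes_mL differ in length")
            return kind, DensityMeasurement(
                mass_g=float(_cell(row, "mass_g", line)),
                volume_initial_mL=float(_cell(row, "volume_initial_mL", line)),
                tap_volumes_mL=dict(zip(counts, volumes)),
            )
        if kind == "cone":
            return kind, ConeMeasurement(
                height_cm=float(_cell(row, "height_cm", line)),
                base_radii_cm=_floats(_cell(row, "base_radii_cm", line)),
            )
        if kind == "flow":
            nonflow = _flag(row.get("nonflow", ""))
            times = () if nonflow else _floats(_cell(row, "times_s", line))
            return kind, FlowMeasurement(times_s=times, nonflow_flag=nonflow)
        if kind == "moisture":
            return kind, MoistureRecord(
                wet_weight_g=float(_cell(row, "wet_weight_g", line)),
                dry_weight_g=float(_cell(row, "dry_weight_g", line)),
                humid_weight_g=float(_cell(row, "humid_weight_g", line)),
            )
        if kind == "sieve":
            kwargs: dict[str, Any] = {
                "retained_pct": _floats(_cell(row, "retained_pct", line))
            }
            if str(row.get("apertures_mm", "")).strip():
                kwargs["apertures_mm"] = _floats(row["apertures_mm"])
            if str(row.get("top_bound_mm", "")).strip():
                kwargs["top_bound_mm"] = float(row["top_bound_mm"])
            return kind, SieveAnalysis(**kwargs)
        # hardness
        lub = _flag(row.get("lubricated", ""))
        return kind, HardnessSample(
            breaking_forces_N=_floats(_cell(row, "forces_N", line)),
            lubricated_flag=lub,
        )
    except Exception as err:  # pydantic / domain error, with row context
        raise SedemError(f"line {line}: {err}") from err


def parse_measurements(path: str | Path, name: Optional[str] = None) -> list[PowderDataset]:
    """Read a measurement CSV into one :class:`PowderDataset` per replicate.

    Raises :class:`SedemError` with the offending line number on malformed
    rows, and when a replicate lacks one of the six record kinds.
    """
    path = Path(path)
    name = name or path.stem
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "record_kind" not in df.columns:
        raise SedemError(f"{path}: missing mandatory 'record_kind' column")
    replicates: dict[int, dict[str, Any]] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        rep = int(float(row["replicate"])) if str(row.get("replicate", "")).strip() else 1
        kind, record = _parse_row(row, line)
        bucket = replicates.setdefault(rep, {})
        if kind in bucket:
            raise SedemError(f"line {line}: duplicate {kind!r} record in replicate {rep}")
        bucket[kind] = record
    datasets = []
    for rep in sorted(replicates):
        bucket = replicates[rep]
        datasets.append(
            PowderDataset(
                name=name if len(replicates) == 1 else f"{name} (replicate {rep})",
                **bucket,
            )
        )
    return datasets


def write_measurements(datasets: list[PowderDataset], path: str | Path) -> None:
    """Serialize replicate datasets back to the measurement CSV dialect."""
    rows = []
    for rep, ds in enumerate(datasets, start=1):
        if ds.density is not None:
            counts = sorted(ds.density.tap_volumes_mL)
            rows.append({
                "record_kind": "density", "replicate": rep,
                "mass_g": ds.density.mass_g,
                "volume_initial_mL": ds.density.volume_initial_mL,
                "tap_counts": ";".join(str(c) for c in counts),
                "tap_volumes_mL": ";".join(repr(ds.density.tap_volumes_mL[c]) for c in counts),
            })
        if ds.cone is not None:
            rows.append({
                "record_kind": "cone", "replicate": rep,
                "height_cm": ds.cone.height_cm,
                "base_radii_cm": ";".join(repr(r) for r in ds.cone.base_radii_cm),
            })
        if ds.flow is not None:
            rows.append({
                "record_kind": "flow", "replicate": rep,
                "times_s": ";".join(repr(t) for t in ds.flow.times_s),
                "nonflow": int(ds.flow.nonflow_flag),
            })
        if ds.moisture is not None:
            rows.append({
                "record_kind": "moisture", "replicate": rep,
                "wet_weight_g": ds.moisture.wet_weight_g,
                "dry_weight_g": ds.moisture.dry_weight_g,
                "humid_weight_g": ds.moisture.humid_weight_g,
            })
        if ds.sieve is not None:
            rows.append({
                "record_kind": "sieve", "replicate": rep,
                "apertures_mm": ";".join(repr(a) for a in ds.sieve.apertures_mm),
                "retained_pct": ";".join(repr(p) for p in ds.sieve.retained_pct),
                "top_bound_mm": ds.sieve.top_bound_mm,
            })
        if ds.hardness is not None:
            rows.append({
                "record_kind": "hardness", "replicate": rep,
                "forces_N": ";".join(repr(x) for x in ds.hardness.breaking_forces_N),
                "lubricated": int(ds.hardness.lubricated_flag),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def characterize(datasets: list[PowderDataset]) -> tuple[ParameterSet, dict[str, Any]]:
    """Per-replicate parameters averaged into one set, with provenance
    (which tapped volume the 2 mL rule selected, lubrication, non-flow)."""
    from .powder import mean_parameter_set

    params = mean_parameter_set(datasets)
    provenance = {
        "n_replicates": len(datasets),
        "tapped_volume_used": [tapped_density(ds.density).volume_used for ds in datasets],
        "cohesion_lubricated": [ds.hardness.lubricated_flag for ds in datasets],
        "nonflow": [ds.flow.nonflow_flag for ds in datasets],
    }
    return params, provenance


def parameter_set_to_json(
    params: ParameterSet, path: str | Path, provenance: Optional[dict] = None
) -> None:
    payload = {
        "parameters": {
            pid: {
                "value": getattr(params, pid),
                "unit": PARAMETER_UNITS[pid],
            }
            for pid in PARAMETER_ORDER
        },
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def parameter_set_from_json(path: str | Path) -> ParameterSet:
    payload = json.loads(Path(path).read_text())
    return ParameterSet(
        **{pid: entry["value"] for pid, entry in payload["parameters"].items()}
    )


__all__ = [
    "RECORD_KINDS",
    "PARAMETER_UNITS",
    "parse_measurements",
    "write_measurements",
    "characterize",
    "parameter_set_to_json",
    "parameter_set_from_json",
]
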