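"""Tablet batch quality control against the QTPP / CQA rules.

Implements the compendial evaluations named in the product profile for
orally disintegrating mini-tablets: weight variation (Ph. Eur. 2.9.5 bands
by mean-weight class), friability 100 (W1 - W2) / W1 with a "not more than
1.0%" limit, disintegration against the 3-minute ODT target, tablet
diameter below 7 mm, and a hardness window treated as a flag rather than a
hard failure (the window is advisory: a batch slightly above it can still
be acceptable).
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .errors import (
    ImpossibleGainError,
    InsufficientSampleError,
    InvalidMeasurementError,
)

Status = Literal["pass", "fail", "flag", "not_assessed"]


class TabletBatch(BaseModel):
    """Measured attributes of one compressed batch.

    Raw per-tablet lists are preferred; summary values (mean hardness,
    friability percentage) may stand in when only aggregated results were
    recorded. Missing attributes are reported as not assessed.
    """

    name: str = "batch"
    weights_mg: Optional[tuple[float, ...]] = None
    hardness_N: Optional[tuple[float, ...]] = None
    mean_hardness_N: Optional[float] = None
    friability_W1_g: Optional[float] = None
    friability_W2_g: Optional[float] = None
    friability_pct: Optional[float] = None
    disintegration_s: Optional[tuple[float, ...]] = None
    diameter_mm: Optional[float] = None
    dose_mg: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "TabletBatch":
        for field in ("weights_mg", "hardness_N", "disintegration_s"):
            vals = getattr(self, field)
            if vals is not None and any(v <= 0 for v in vals):
                raise InvalidMeasurementError(f"{field} entries must be positive")
        if self.friability_W1_g is not None and self.friability_W2_g is not None:
            if self.friability_W2_g > self.friability_W1_g:
                raise ImpossibleGainError("tablets gained weight during friability")
        return self


class QTPPRules(BaseModel):
    """Machine-readable targets of the quality target product profile."""

    max_diameter_mm: float = Field(default=7.0, gt=0)
    max_disintegration_s: float = Field(default=180.0, gt=0)
    dose_mg: float = Field(default=50.0, gt=0)
    max_friability_pct: float = Field(default=1.0, gt=0)
    hardness_window_N: tuple[float, float] = (25.0, 60.0)


def friability(W1: float, W2: float) -> float:
    """Percent weight loss 100 (W1 - W2) / W1."""
    if W1 <= 0 or W2 <= 0:
        raise InvalidMeasurementError("friability weights must be positive")
    if W2 > W1:
        raise ImpossibleGainError("post-test weight exceeds pre-test weight")
    return 100.0 * (W1 - W2) / W1


class WeightVariationResult(BaseModel):
    mean_mg: float
    deviations_pct: tuple[float, ...]
    band_pct: float
    n_outside_band: int
    n_outside_double_band: int
    passed: bool


def weight_variation(weights_mg: tuple[float, ...] | list[float]) -> WeightVariationResult:
    """Uncoated-tablet weight variation (Ph. Eur. 2.9.5).

    Band by mean-weight class: 10% below 80 mg, 7.5% for 80-250 mg, 5%
    above 250 mg. At most two units may deviate beyond the band and none by
    more than twice it.
    """
    if len(weights_mg) < 20:
        raise InsufficientSampleError("weight variation needs at least 20 units")
    mean = sum(weights_mg) / len(weights_mg)
    if mean < 80.0:
        band = 10.0
    elif mean <= 250.0:
        band = 7.5
    else:
        band = 5.0
    devs = tuple(100.0 * (w - mean) / mean for w in weights_mg)
    n_out = sum(1 for d in devs if abs(d) > band)
    n_double = sum(1 for d in devs if abs(d) > 2.0 * band)
    return WeightVariationResult(
        mean_mg=mean,
        deviations_pct=devs,
        band_pct=band,
        n_outside_band=n_out,
        n_outside_double_band=n_double,
        passed=(n_out <= 2 and n_double == 0),
    )


class AttributeVerdict(BaseModel):
    value: Optional[float] = None
    status: Status
    note: Optional[str] = None


class CQAReport(BaseModel):
    batch: str
    attributes: dict[str, AttributeVerdict]
    overall: Literal["pass", "fail", "indeterminate"]


def _batch_friability(batch: TabletBatch) -> Optional[float]:
    if batch.friability_W1_g is not None and batch.friability_W2_g is not None:
        return friability(batch.friability_W1_g, batch.friability_W2_g)
    return batch.friability_pct


def _batch_hardness(batch: TabletBatch) -> Optional[float]:
    if batch.hardness_N:
        return sum(batch.hardness_N) / len(batch.hardness_N)
    return batch.mean_hardness_N


def evaluate_cqa(batch: TabletBatch, rules: Optional[QTPPRules] = None) -> CQAReport:
    """Per-attribute pass/fail verdicts and their conjunction.

    Hardness outside its window yields ``flag`` (advisory), not ``fail``.
    Friability exactly at the limit passes with a note ("not more than").
    Attributes with no data are ``not_assessed`` and make the overall
    verdict indeterminate.
    """
    rules = rules or QTPPRules()
    verdicts: dict[str, AttributeVerdict] = {}

    if batch.diameter_mm is None:
        verdicts["diameter"] = AttributeVerdict(status="not_assessed")
    else:
        ok = batch.diameter_mm < rules.max_diameter_mm
        verdicts["diameter"] = AttributeVerdict(
            value=batch.diameter_mm, status="pass" if ok else "fail",
            note=f"limit < {rules.max_diameter_mm} mm",
        )

    if batch.disintegration_s is None:
        verdicts["disintegration"] = AttributeVerdict(status="not_assessed")
    else:
        worst = max(batch.disintegration_s)
        ok = worst <= rules.max_disintegration_s
        verdicts["disintegration"] = AttributeVerdict(
            value=worst, status="pass" if ok else "fail",
            note=f"limit {rules.max_disintegration_s:.0f} s",
        )

    friab = _batch_friability(batch)
    if friab is None:
        verdicts["friability"] = AttributeVerdict(status="not_assessed")
    else:
        if friab < rules.max_friability_pct:
            verdicts["friability"] = AttributeVerdict(value=friab, status="pass")
        elif abs(friab - rules.max_friability_pct) < 1e-9:
            verdicts["friability"] = AttributeVerdict(
                value=friab, status="pass",
                note=f"at the {rules.max_friability_pct}% limit",
            )
        else:
            verdicts["friability"] = AttributeVerdict(value=friab, status="fail")

    hard = _batch_hardness(batch)
    if hard is None:
        verdicts["hardness"] = AttributeVerdict(status="not_assessed")
    else:
        lo, hi = rules.hardness_window_N
        in_window = lo <= hard <= hi
        verdicts["hardness"] = AttributeVerdict(
            value=hard, status="pass" if in_window else "flag",
            note=None if in_window else f"outside advisory window {lo}-{hi} N",
        )

    if batch.weights_mg is None:
        verdicts["weight_variation"] = AttributeVerdict(status="not_assessed")
    else:
        wv = weight_variation(batch.weights_mg)
        verdicts["weight_variation"] = AttributeVerdict(
            value=wv.mean_mg, status="pass" if wv.passed else "fail",
            note=f"band ±{wv.band_pct}%",
        )

    if batch.dose_mg is None:
        verdicts["dose"] = AttributeVerdict(status="not_assessed")
    else:
        ok = abs(batch.dose_mg - rules.dose_mg) < 1e-9
        verdicts["dose"] = AttributeVerdict(
            value=batch.dose_mg, status="pass" if ok else "fail",
            note=f"target {rules.dose_mg} mg",
        )

    statuses = {v.status for v in verdicts.values()}
    if "fail" in statuses:
        overall: Literal["pass", "fail", "indeterminate"] = "fail"
    elif "not_assessed" in statuses:
        overall = "indeterminate"
    else:
        overall = "pass"
    return CQAReport(batch=batch.name, attributes=verdicts, overall=overall)


__all__ = [
    "TabletBatch",
    "QTPPRules",
    "WeightVariationResult",
    "AttributeVerdict",
    "CQAReport",
    "friability",
    "weight_variation",
    "evaluate_cqa",
]
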