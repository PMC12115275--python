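"""Typed records for raw powder measurements and derived parameter sets.

The measurement types mirror what a preformulation lab actually writes down:
masses and graduated-cylinder volumes (Ph. Eur. 2.9.34), cone geometry
(2.9.36), stopwatch flow times per 100 g (2.9.16), drying / humidification
weights, sieve fractions (2.9.12) and tablet breaking forces. The
:class:`ParameterSet` holds the twelve SeDeM parameter values in their
physical units, before any transformation to diagram radii.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import (
    InconsistentDensitiesError,
    InvalidMeasurementError,
    NormalizationError,
)

#: Ordered canonical parameter identifiers (Table-2 row order).
PARAMETER_ORDER: tuple[str, ...] = (
    "Da", "Dc", "Ie", "IC", "Icd", "IH",
    "alpha", "t_flow", "HR", "H", "Pf", "Itheta",
)

#: Incidence factors: named groups partitioning the 12 parameters {2,3,3,2,2}.
INCIDENCE_GROUPS: dict[str, tuple[str, ...]] = {
    "dimensions": ("Da", "Dc"),
    "compressibility": ("Ie", "IC", "Icd"),
    "flowability": ("IH", "alpha", "t_flow"),
    "lubricity_stability": ("HR", "H"),
    "lubricity_dosage": ("Pf", "Itheta"),
}


class DensityMeasurement(BaseModel):
    """Graduated-cylinder record for bulk and tapped density."""

    mass_g: float = Field(gt=0)
    volume_initial_mL: float = Field(gt=0)
    #: tap count -> apparent volume (mL); counts 10, 500, 1250, optionally 2500
    tap_volumes_mL: dict[int, float]

    @model_validator(mode="after")
    def _check_volumes(self) -> "DensityMeasurement":
        prev = self.volume_initial_mL
        for count in sorted(self.tap_volumes_mL):
            v = self.tap_volumes_mL[count]
            if v <= 0:
                raise InvalidMeasurementError(f"tap volume at {count} taps must be > 0")
            if v > self.volume_initial_mL + 1e-9:
                raise InvalidMeasurementError(
                    f"tap volume at {count} taps exceeds the initial volume"
                )
            if v > prev + 1e-9:
                raise InvalidMeasurementError(
                    f"tap volumes must be non-increasing (violated at {count} taps)"
                )
            prev = v
        return self


class ConeMeasurement(BaseModel):
    """Cone height and the four base radii for the angle of repose."""

    height_cm: float = Field(ge=0)
    base_radii_cm: tuple[float, float, float, float]

    @model_validator(mode="after")
    def _check_radii(self) -> "ConeMeasurement":
        if any(r <= 0 for r in self.base_radii_cm):
            raise InvalidMeasurementError("all four base radii must be > 0")
        return self


class FlowMeasurement(BaseModel):
    """Three stopwatch times (s / 100 g), or a did-not-flow flag."""

    times_s: tuple[float, ...] = ()
    nonflow_flag: bool = False

    @model_validator(mode="after")
    def _check_times(self) -> "FlowMeasurement":
        if self.nonflow_flag:
            return self
        if len(self.times_s) != 3:
            raise InvalidMeasurementError("exactly three flow times required unless nonflow")
        if any(t < 0 for t in self.times_s):
            raise InvalidMeasurementError("flow times must be >= 0")
        return self


class MoistureRecord(BaseModel):
    """Weights before/after 105 degC drying and after 76% RH / 24 h exposure."""

    wet_weight_g: float = Field(gt=0)
    dry_weight_g: float = Field(gt=0)
    humid_weight_g: float = Field(gt=0)


class SieveAnalysis(BaseModel):
    """Percent retained on each sieve of a descending stack, plus the pan."""

    apertures_mm: tuple[float, ...] = (0.355, 0.212, 0.100, 0.05)
    retained_pct: tuple[float, ...] = ()
    top_bound_mm: float = 0.500

    @model_validator(mode="after")
    def _check(self) -> "SieveAnalysis":
        if list(self.apertures_mm) != sorted(self.apertures_mm, reverse=True):
            raise InvalidMeasurementError("sieve apertures must be strictly descending")
        if self.top_bound_mm <= self.apertures_mm[0]:
            raise InvalidMeasurementError("top_bound_mm must exceed the coarsest aperture")
        if len(self.retained_pct) != len(self.apertures_mm) + 1:
            raise InvalidMeasurementError(
                "retained_pct needs one entry per sieve plus the pan"
            )
        if any(p < 0 for p in self.retained_pct):
            raise InvalidMeasurementError("retained percentages must be >= 0")
        if abs(sum(self.retained_pct) - 100.0) > 0.01:
            raise NormalizationError(
                f"retained percentages sum to {sum(self.retained_pct):.4f}, not 100"
            )
        return self

    def fraction_mean_diameters_um(self) -> tuple[float, ...]:
        """Mean particle diameter per fraction (um), coarsest first.

        Each fraction's mean diameter is the midpoint of its bounding
        apertures; the coarsest fraction is bounded above by ``top_bound_mm``
        and the pan below by 0 (so the default pan midpoint is 25 um).
        """
        bounds = (self.top_bound_mm, *self.apertures_mm, 0.0)
        return tuple(
            1000.0 * (bounds[i] + bounds[i + 1]) / 2.0 for i in range(len(bounds) - 1)
        )


class HardnessSample(BaseModel):
    """Per-tablet breaking forces for the cohesion index."""

    breaking_forces_N: tuple[float, ...]
    lubricated_flag: bool = False

    @model_validator(mode="after")
    def _check(self) -> "HardnessSample":
        if not self.breaking_forces_N:
            raise InvalidMeasurementError("at least one breaking force required")
        if any(f < 0 for f in self.breaking_forces_N):
            raise InvalidMeasurementError("breaking forces must be >= 0")
        return self


class PowderDataset(BaseModel):
    """One material's raw characterization (a single replicate).

    Records may be absent while a campaign is incomplete; computing the
    full parameter set requires all six.
    """

    name: str = "unnamed"
    density: Optional[DensityMeasurement] = None
    cone: Optional[ConeMeasurement] = None
    flow: Optional[FlowMeasurement] = None
    moisture: Optional[MoistureRecord] = None
    sieve: Optional[SieveAnalysis] = None
    hardness: Optional[HardnessSample] = None

    def missing_records(self) -> list[str]:
        return [
            kind
            for kind in ("density", "cone", "flow", "moisture", "sieve", "hardness")
            if getattr(self, kind) is None
        ]


class ParameterSet(BaseModel):
    """The twelve SeDeM parameter values in physical units.

    ``t_flow`` may be ``+inf`` for a powder that does not flow at all; every
    other value is finite and non-negative. ``Ie``, ``IC`` and ``IH`` are
    functions of the densities, so ``Da <= Dc`` (hence ``IH >= 1``) is
    enforced.
    """

    Da: float = Field(ge=0, description="bulk density, g/mL")
    Dc: float = Field(ge=0, description="tapped density, g/mL")
    Ie: float = Field(ge=0, description="interparticle porosity")
    IC: float = Field(ge=0, description="Carr index, %")
    Icd: float = Field(ge=0, description="cohesion index (mean hardness), N")
    IH: float = Field(ge=1, description="Hausner ratio")
    alpha: float = Field(ge=0, description="angle of repose, degrees")
    t_flow: float = Field(ge=0, description="flow time, s/100 g (inf = does not flow)")
    HR: float = Field(ge=0, description="loss on drying, %")
    H: float = Field(ge=0, description="hygroscopicity, %")
    Pf: float = Field(ge=0, description="particles < 50 um, %")
    Itheta: float = Field(ge=0, description="relative homogeneity index")

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        if self.Da > self.Dc + 1e-12:
            raise InconsistentDensitiesError("bulk density exceeds tapped density")
        for pid in PARAMETER_ORDER:
            v = getattr(self, pid)
            if pid != "t_flow" and not math.isfinite(v):
                raise InvalidMeasurementError(f"{pid} must be finite")
        return self

    def as_dict(self) -> dict[str, float]:
        return {pid: getattr(self, pid) for pid in PARAMETER_ORDER}


__all__ = [
    "PARAMETER_ORDER",
    "INCIDENCE_GROUPS",
    "DensityMeasurement",
    "ConeMeasurement",
    "FlowMeasurement",
    "MoistureRecord",
    "SieveAnalysis",
    "HardnessSample",
    "PowderDataset",
    "ParameterSet",
]
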