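"""Computation of the twelve SeDeM parameters from raw measurements.

Bulk density Da = m/V0 and tapped density Dc = m/V1250 (or m/V2500 when the
500-vs-1250 tap volumes differ by more than 2 mL) follow Ph. Eur. 2.9.34.
From the two densities follow the interparticle porosity
Ie = (Dc - Da)/(Dc * Da), the Carr index IC = 100 (Dc - Da)/Dc and the
Hausner ratio IH = Dc/Da. The angle of repose is atan(h / mean radius); the
cohesion index is the mean tablet breaking force; moisture gives loss on
drying and hygroscopicity as percent weight changes; the sieve test gives
the fines percentage (< 50 um) and the relative homogeneity index

    Itheta = Fm / (100 + sum_j |dm - dj| * Fj)

where Fm is the majority fraction's percentage, dm its mean particle
diameter (um) and the sum runs over every other fraction j.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import (
    DegenerateConeError,
    IncompleteTapSeriesError,
    InconsistentDensitiesError,
    MeasurementOrderError,
    NoDataError,
    TapRuleViolationError,
)
from .types import (
    ConeMeasurement,
    DensityMeasurement,
    FlowMeasurement,
    HardnessSample,
    MoistureRecord,
    ParameterSet,
    PowderDataset,
    SieveAnalysis,
)

#: Volume difference (mL) between 500 and 1250 taps beyond which the
#: series must be extended to 2500 taps (Ph. Eur. 2.9.34).
TAP_RULE_THRESHOLD_ML = 2.0


def bulk_density(d: DensityMeasurement) -> float:
    """Bulk density Da = m / V0 in g/mL."""
    return d.mass_g / d.volume_initial_mL


@dataclass(frozen=True)
class TappedDensityResult:
    """Tapped density plus which tap volume the 2 mL rule selected."""

    value: float  # g/mL
    volume_used: str  # "V1250" or "V2500"

    def __float__(self) -> float:
        return self.value


def tapped_density(d: DensityMeasurement) -> TappedDensityResult:
    """Tapped density Dc = m/V1250, or m/V2500 when the 2 mL rule fires."""
    taps = d.tap_volumes_mL
    for required in (500, 1250):
        if required not in taps:
            raise IncompleteTapSeriesError(f"tap count {required} missing from series")
    if abs(taps[500] - taps[1250]) > TAP_RULE_THRESHOLD_ML:
        if 2500 not in taps:
            raise TapRuleViolationError(
                "V500 - V1250 exceeds 2 mL: a 2500-tap volume is required"
            )
        return TappedDensityResult(d.mass_g / taps[2500], "V2500")
    return TappedDensityResult(d.mass_g / taps[1250], "V1250")


def density_derived(Da: float, Dc: float) -> dict[str, float]:
    """Interparticle porosity, Carr index and Hausner ratio from Da, Dc."""
    if Da <= 0 or Dc <= 0:
        raise InconsistentDensitiesError("densities must be positive")
    if Da > Dc + 1e-12:
        raise InconsistentDensitiesError(f"Da={Da} exceeds Dc={Dc}")
    return {
        "Ie": (Dc - Da) / (Dc * Da),
        "IC": 100.0 * (Dc - Da) / Dc,
        "IH": Dc / Da,
    }


def angle_of_repose(c: ConeMeasurement) -> float:
    """Angle of repose alpha = atan(h / mean of four base radii), degrees."""
    r = sum(c.base_radii_cm) / 4.0
    if r <= 0:
        raise DegenerateConeError("mean base radius is zero")
    return math.degrees(math.atan(c.height_cm / r))


def flow_time(f: FlowMeasurement) -> float:
    """Mean flow time (s / 100 g); +inf if the powder did not flow."""
    if f.nonflow_flag:
        return math.inf
    return sum(f.times_s) / len(f.times_s)


def homogeneity_index(s: SieveAnalysis) -> float:
    """Relative homogeneity index Itheta from the sieve fractions.

    The majority fraction is the one retaining the largest percentage; ties
    are broken toward the coarser fraction (with a warning). Diameters are
    fraction midpoints in micrometers.
    """
    diam = s.fraction_mean_diameters_um()
    pct = s.retained_pct
    best = max(pct)
    m = pct.index(best)  # index() takes the first (coarsest) on ties
    if sum(1 for p in pct if p == best) > 1:
        warnings.warn(
            "tie for the majority sieve fraction; using the coarser one",
            stacklevel=2,
        )
    denom = 100.0 + sum(
        abs(diam[m] - diam[j]) * pct[j] for j in range(len(pct)) if j != m
    )
    return pct[m] / denom


def moisture_params(m: MoistureRecord) -> dict[str, float]:
    """Loss on drying %HR and hygroscopicity %H as percent weight changes."""
    if m.dry_weight_g > m.wet_weight_g:
        raise MeasurementOrderError("dry weight exceeds pre-drying weight")
    hr = 100.0 * (m.wet_weight_g - m.dry_weight_g) / m.wet_weight_g
    h = 100.0 * (m.humid_weight_g - m.wet_weight_g) / m.wet_weight_g
    if h < 0:
        warnings.warn(
            "negative hygroscopicity (weight loss at 76% RH) floored to 0",
            stacklevel=2,
        )
        h = 0.0
    return {"HR": hr, "H": h}


def cohesion_index(h: HardnessSample) -> float:
    """Cohesion index: arithmetic mean breaking force (N)."""
    if not h.breaking_forces_N:
        raise NoDataError("no breaking forces recorded")
    return sum(h.breaking_forces_N) / len(h.breaking_forces_N)


def fines_fraction(s: SieveAnalysis) -> float:
    """Percentage of particles below 50 um (the pan fraction)."""
    return s.retained_pct[-1]


def parameter_set(ds: PowderDataset) -> ParameterSet:
    """Assemble the full twelve-parameter set for one replicate."""
    missing = ds.missing_records()
    if missing:
        raise NoDataError(f"{ds.name}: incomplete campaign, missing {missing}")
    Da = bulk_density(ds.density)
    Dc = tapped_density(ds.density).value
    derived = density_derived(Da, Dc)
    moist = moisture_params(ds.moisture)
    return ParameterSet(
        Da=Da,
        Dc=Dc,
        Ie=derived["Ie"],
        IC=derived["IC"],
        Icd=cohesion_index(ds.hardness),
        IH=derived["IH"],
        alpha=angle_of_repose(ds.cone),
        t_flow=flow_time(ds.flow),
        HR=moist["HR"],
        H=moist["H"],
        Pf=fines_fraction(ds.sieve),
        Itheta=homogeneity_index(ds.sieve),
    )


def mean_parameter_set(replicates: list[PowderDataset]) -> ParameterSet:
    """Per-replicate parameters averaged into one set (the reporting default
    when a material is characterized in replicate)."""
    if not replicates:
        raise NoDataError("no replicates given")
    sets = [parameter_set(ds) for ds in replicates]
    values = {}
    for pid in ParameterSet.model_fields:
        vals = [getattr(ps, pid) for ps in sets]
        values[pid] = sum(vals) / len(vals)
    return ParameterSet(**values)


__all__ = [
    "TAP_RULE_THRESHOLD_ML",
    "TappedDensityResult",
    "bulk_density",
    "tapped_density",
    "density_derived",
    "angle_of_repose",
    "flow_time",
    "homogeneity_index",
    "moisture_params",
    "cohesion_index",
    "fines_fraction",
    "parameter_set",
    "mean_parameter_set",
]
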