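"""Corrective-excipient dosing and blend composition design.

A powder whose compressibility incidence radius RP falls below the target R
is corrected by adding an excipient with a higher compressibility incidence
RE. The percentage of excipient in the binary API + excipient pair is

    CP = 100 - 100 * (RE - R) / (RE - RP)

which linearly interpolates the blend's compressibility incidence between
RP (CP = 0) and RE (CP = 100). The fixed lubricant trio (talc 2.36%,
colloidal silicon dioxide 0.14%, magnesium stearate 1.00%) is layered on
afterwards, so the API percentage in the final tablet is 100 - CP - 3.5 and
the tablet weight for a fixed dose D is D / (API% / 100).
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .errors import CompositionError, DegeneratePairError, InfeasibleTargetError
from .profile import round_half_away

#: Standardized lubricant mixture (percent of final composition).
LUBRICANTS: dict[str, float] = {
    "talc": 2.36,
    "colloidal_silicon_dioxide": 0.14,
    "magnesium_stearate": 1.00,
}
LUBRICANT_TOTAL_PCT = sum(LUBRICANTS.values())  # 3.50

#: Target compressibility radii swept in decreasing order.
DEFAULT_TARGET_RADII: tuple[float, ...] = (5.0, 4.5, 4.0, 3.5)


class MaterialProfile(BaseModel):
    """A material reduced to its compressibility incidence radius."""

    name: str
    role: Literal["API", "corrective-excipient"]
    compressibility_radius: float = Field(ge=0, le=10)


def corrective_excipient_pct(RE: float, R: float, RP: float) -> float:
    """Percent excipient CP in the binary pair for target radius R.

    Requires RP < RE (the excipient must be the better compressor) and
    RP <= R <= RE (otherwise no mixture of the two can reach R).
    """
    if abs(RE - RP) < 1e-12:
        raise DegeneratePairError("RE equals RP: no blend changes the radius")
    if RP > RE:
        raise DegeneratePairError(
            f"excipient radius RE={RE} below API radius RP={RP}: "
            "the excipient cannot correct the deficiency"
        )
    if R > RE + 1e-12:
        raise InfeasibleTargetError(
            f"target R={R} exceeds RE={RE}: even pure excipient falls short"
        )
    if R < RP - 1e-12:
        raise InfeasibleTargetError(
            f"target R={R} below RP={RP}: pure API already exceeds the target"
        )
    return 100.0 - (RE - R) / (RE - RP) * 100.0


def blend_radius_predict(cp_pct: float, RE: float, RP: float) -> float:
    """Compressibility radius of the binary pair at cp_pct % excipient
    (the algebraic inverse of :func:`corrective_excipient_pct`)."""
    if not (0.0 <= cp_pct <= 100.0):
        raise InfeasibleTargetError(f"cp_pct={cp_pct} outside [0, 100]")
    return (cp_pct * RE + (100.0 - cp_pct) * RP) / 100.0


class BlendDesign(BaseModel):
    """A full tablet composition for one target compressibility radius."""

    api: MaterialProfile
    excipient: MaterialProfile
    target_R: float
    cp_pct: float
    dose_mg: float = 50.0

    @model_validator(mode="after")
    def _check(self) -> "BlendDesign":
        if self.cp_pct < 0:
            raise CompositionError("cp_pct must be >= 0")
        if self.cp_pct > 100.0 - LUBRICANT_TOTAL_PCT:
            raise CompositionError(
                f"cp_pct={self.cp_pct:.2f} leaves no room for API plus the "
                f"{LUBRICANT_TOTAL_PCT}% lubricant mixture"
            )
        return self

    @property
    def api_pct(self) -> float:
        return 100.0 - self.cp_pct - LUBRICANT_TOTAL_PCT

    @property
    def tablet_weight_mg(self) -> float:
        return self.dose_mg / (self.api_pct / 100.0)

    def composition(self) -> dict[str, float]:
        """Component -> percent; always sums to 100."""
        return {
            self.api.name: self.api_pct,
            self.excipient.name: self.cp_pct,
            **LUBRICANTS,
        }


def build_composition(design: BlendDesign) -> dict[str, float]:
    """Composition row plus the tablet weight for the fixed dose."""
    row = {f"{name} %": pct for name, pct in design.composition().items()}
    row["tablet_weight_mg"] = design.tablet_weight_mg
    return row


class DesignOutcome(BaseModel):
    """One target radius of a sweep: a design, or a flagged infeasibility."""

    target_R: float
    feasible: bool
    design: Optional[BlendDesign] = None
    reason: Optional[str] = None


def r_sweep(
    api: MaterialProfile,
    excipient: MaterialProfile,
    targets: Sequence[float] = DEFAULT_TARGET_RADII,
    dose_mg: float = 50.0,
    round_inputs: bool = True,
) -> list[DesignOutcome]:
    """One design per target radius; infeasible targets are flagged, never
    silently dropped.

    ``round_inputs`` evaluates the dose equation on incidence radii rounded
    to two decimals, the reporting precision of published profiles.
    """
    RP = api.compressibility_radius
    RE = excipient.compressibility_radius
    if round_inputs:
        RP, RE = round_half_away(RP), round_half_away(RE)
    outcomes: list[DesignOutcome] = []
    for R in targets:
        try:
            cp = corrective_excipient_pct(RE, R, RP)
            design = BlendDesign(
                api=api, excipient=excipient, target_R=R, cp_pct=cp, dose_mg=dose_mg
            )
            outcomes.append(DesignOutcome(target_R=R, feasible=True, design=design))
        except (InfeasibleTargetError, DegeneratePairError, CompositionError) as err:
            outcomes.append(
                DesignOutcome(target_R=R, feasible=False, reason=str(err))
            )
    return outcomes


__all__ = [
    "LUBRICANTS",
    "LUBRICANT_TOTAL_PCT",
    "DEFAULT_TARGET_RADII",
    "MaterialProfile",
    "BlendDesign",
    "DesignOutcome",
    "corrective_excipient_pct",
    "blend_radius_predict",
    "build_composition",
    "r_sweep",
]
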