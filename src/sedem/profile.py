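"""SeDeM radius transforms, incidence factors, IPP / IGC, and diagram geometry.

Each of the twelve parameters v is mapped by an affine rule onto a radius
r in [0, 10], with 10 at the favorable end of its acceptable range and 0 at
the unfavorable end (values outside are clamped). The parametric profile
index IPP is the mean of the twelve radii; the Good Compression Index is

    IGC = IPP * f

where the reliability factor f is the ratio of the diagram polygon's area
to the circumscribing circle's area (0.952 for twelve parameters as used in
practice; the exact regular-polygon ratio is (n / 2 pi) sin(2 pi / n)).
An IGC above 5 marks a powder as suitable for direct compression.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, model_validator

from .errors import ConfigurationError, MissingRadiusError
from .types import INCIDENCE_GROUPS, PARAMETER_ORDER, ParameterSet

#: Reliability factor used for 12-parameter diagrams in the published method.
F_PRINTED_12 = 0.952

#: IPP / IGC acceptability limit for direct compression.
DIRECT_COMPRESSION_LIMIT = 5.0

#: Per-group radius counts, used for count-weighted means over incidences.
GROUP_SIZES = {name: len(members) for name, members in INCIDENCE_GROUPS.items()}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TransformSpec:
    """Affine radius rule r = slope * v + intercept, clamped to [0, 10]."""

    parameter_id: str
    unit: str
    v_range: tuple[float, float]  # (unfavorable end, favorable end)
    slope: float
    intercept: float = 0.0

    def forward(self, v: float) -> float:
        r = self.slope * v + self.intercept
        if math.isnan(r):
            raise ConfigurationError(f"{self.parameter_id}: value is NaN")
        return min(10.0, max(0.0, r))

    def inverse(self, r: float) -> float:
        """Parameter value whose (unclamped) radius is r."""
        return (r - self.intercept) / self.slope


#: The twelve transformation rules (acceptable range listed unfavorable ->
#: favorable; e.g. Hausner 3 -> 1, angle of repose 50 -> 0 degrees).
TRANSFORMS: dict[str, TransformSpec] = {
    "Da": TransformSpec("Da", "g/mL", (0.0, 1.0), 10.0),
    "Dc": TransformSpec("Dc", "g/mL", (0.0, 1.0), 10.0),
    "Ie": TransformSpec("Ie", "-", (0.0, 1.2), 10.0 / 1.2),
    "IC": TransformSpec("IC", "%", (0.0, 50.0), 1.0 / 5.0),
    "Icd": TransformSpec("Icd", "N", (0.0, 200.0), 1.0 / 20.0),
    "IH": TransformSpec("IH", "-", (3.0, 1.0), -5.0, 15.0),
    "alpha": TransformSpec("alpha", "deg", (50.0, 0.0), -1.0 / 5.0, 10.0),
    "t_flow": TransformSpec("t_flow", "s", (20.0, 0.0), -1.0 / 2.0, 10.0),
    "HR": TransformSpec("HR", "%", (10.0, 0.0), -1.0, 10.0),
    "H": TransformSpec("H", "%", (20.0, 0.0), -1.0 / 2.0, 10.0),
    "Pf": TransformSpec("Pf", "%", (50.0, 0.0), -1.0 / 5.0, 10.0),
    "Itheta": TransformSpec("Itheta", "-", (0.0, 0.02), 500.0),
}


def to_radius(parameter_id: str, v: float) -> float:
    """Map a parameter value to its SeDeM radius in [0, 10].

    ``+inf`` is accepted for downward transforms only (a powder that never
    flows maps to radius 0).
    """
    try:
        spec = TRANSFORMS[parameter_id]
    except KeyError:
        raise ConfigurationError(f"unknown parameter id: {parameter_id!r}") from None
    if math.isinf(v):
        if spec.slope < 0 and v > 0:
            return 0.0
        raise ConfigurationError(f"{parameter_id}: non-finite value {v}")
    return spec.forward(v)


def from_radius(parameter_id: str, r: float) -> float:
    """Inverse transform: parameter value for a given (unclamped) radius."""
    try:
        spec = TRANSFORMS[parameter_id]
    except KeyError:
        raise ConfigurationError(f"unknown parameter id: {parameter_id!r}") from None
    return spec.inverse(r)


def reliability_factor(
    n_params: int = 12, mode: Literal["printed", "geometric"] = "printed"
) -> float:
    """Polygon/circle area ratio f.

    ``printed`` returns the conventional 0.952 used for 12-parameter
    diagrams; ``geometric`` returns the exact regular-polygon ratio
    (n / 2 pi) sin(2 pi / n), which tends to 1 as n grows.
    """
    if n_params < 3:
        raise ConfigurationError("a polygon needs at least 3 vertices")
    if mode == "printed":
        if n_params != 12:
            raise ConfigurationError("the printed factor is defined for 12 parameters")
        return F_PRINTED_12
    if mode == "geometric":
        return (n_params / (2.0 * math.pi)) * math.sin(2.0 * math.pi / n_params)
    raise ConfigurationError(f"unknown reliability-factor mode: {mode!r}")


class RadiusProfile(BaseModel):
    """A material's twelve SeDeM radii plus the derived indices."""

    name: str = "unnamed"
    radii: dict[str, float]
    f: float = F_PRINTED_12
    #: Optional externally reported incidence means (e.g. transcribed from a
    #: published table). When present and inconsistent with the radii, IGC
    #: recomputation can be keyed to them via ``igc_from_incidences``.
    printed_incidences: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "RadiusProfile":
        missing = [p for p in PARAMETER_ORDER if p not in self.radii]
        if missing:
            raise MissingRadiusError(f"missing radii: {missing}")
        for pid, r in self.radii.items():
            if pid not in PARAMETER_ORDER:
                raise ConfigurationError(f"unknown parameter id: {pid!r}")
            if not (0.0 <= r <= 10.0):
                raise MissingRadiusError(f"radius {pid}={r} outside [0, 10]")
        return self

    @classmethod
    def from_parameters(
        cls, params: ParameterSet, name: str = "unnamed", f: float = F_PRINTED_12
    ) -> "RadiusProfile":
        radii = {pid: to_radius(pid, getattr(params, pid)) for pid in PARAMETER_ORDER}
        return cls(name=name, radii=radii, f=f)

    def radius_vector(self) -> tuple[float, ...]:
        return tuple(self.radii[p] for p in PARAMETER_ORDER)

    def incidence_means(self) -> dict[str, float]:
        """Mean radius of each of the five incidence factors."""
        return {
            group: sum(self.radii[p] for p in members) / len(members)
            for group, members in INCIDENCE_GROUPS.items()
        }

    @property
    def ipp(self) -> float:
        """Parametric profile index: mean of the twelve radii."""
        return sum(self.radius_vector()) / len(PARAMETER_ORDER)

    @property
    def igc(self) -> float:
        """Good Compression Index = IPP * f."""
        return self.ipp * self.f

    @property
    def suitable_for_direct_compression(self) -> bool:
        return self.igc > DIRECT_COMPRESSION_LIMIT

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "radii": {p: self.radii[p] for p in PARAMETER_ORDER},
            "incidence_means": self.incidence_means(),
            "ipp": self.ipp,
            "f": self.f,
            "igc": self.igc,
            "suitable_for_direct_compression": self.suitable_for_direct_compression,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def incidence_means(profile: RadiusProfile) -> dict[str, float]:
    return profile.incidence_means()


def good_compression_index(
    profile: RadiusProfile, f: Optional[float] = None
) -> dict[str, object]:
    """IPP, IGC and the suitability verdict for a complete profile."""
    factor = profile.f if f is None else f
    ipp = profile.ipp
    igc = ipp * factor
    return {
        "ipp": ipp,
        "f": factor,
        "igc": igc,
        "suitable": igc > DIRECT_COMPRESSION_LIMIT,
    }


def igc_from_incidences(
    incidences: Mapping[str, float], f: float = F_PRINTED_12
) -> float:
    """IGC via the count-weighted mean of the five incidence means.

    Equivalent to the radius path when the incidences are exact means of the
    radii; used directly when a transcribed table reports incidence means
    that disagree with its own radii.
    """
    total = sum(GROUP_SIZES[g] * incidences[g] for g in INCIDENCE_GROUPS)
    return f * total / sum(GROUP_SIZES.values())


def check_incidence_consistency(
    profile: RadiusProfile, tol: float = 0.02
) -> dict[str, float]:
    """Compare radius-derived incidence means with printed ones, warning on
    disagreement beyond ``tol``. Returns the per-group discrepancies."""
    if profile.printed_incidences is None:
        return {}
    computed = profile.incidence_means()
    delta = {
        g: computed[g] - profile.printed_incidences[g]
        for g in profile.printed_incidences
    }
    bad = {g: d for g, d in delta.items() if abs(d) > tol}
    if bad:
        warnings.warn(
            f"{profile.name}: printed incidence means inconsistent with radii: "
            + ", ".join(f"{g} (off by {d:+.2f})" for g, d in bad.items()),
            stacklevel=2,
        )
    return delta


# ---------------------------------------------------------------------------
# Diagram geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagramGeometry:
    """Polar geometry of the 12-axis radar polygon."""

    vertex_angles: tuple[float, ...]  # radians, axis directions
    polygon_vertices: tuple[tuple[float, float], ...]  # cartesian (x, y)
    polygon_area: float
    circle_area: float


def _shoelace(points: Sequence[tuple[float, float]]) -> float:
    n = len(points)
    acc = 0.0
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        acc += x1 * y2 - x2 * y1
    return abs(acc) / 2.0


def diagram_geometry(profile: RadiusProfile) -> DiagramGeometry:
    """Vertices, polygon area (shoelace) and circle area for a profile.

    Axes follow the canonical parameter order, starting at 12 o'clock and
    proceeding clockwise, one every 30 degrees.
    """
    radii = profile.radius_vector()
    n = len(radii)
    angles = tuple(math.pi / 2 - 2.0 * math.pi * i / n for i in range(n))
    vertices = tuple(
        (r * math.cos(a), r * math.sin(a)) for r, a in zip(radii, angles)
    )
    return DiagramGeometry(
        vertex_angles=angles,
        polygon_vertices=vertices,
        polygon_area=_shoelace(vertices),
        circle_area=math.pi * 10.0**2,
    )


def diagram(
    profile: RadiusProfile, path: Optional[str | Path] = None
) -> DiagramGeometry:
    """Render the SeDeM radar diagram (SVG via matplotlib) and return its
    geometry. With ``path=None`` only the geometry is computed."""
    geom = diagram_geometry(profile)
    if path is None:
        return geom

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = ["Da", "Dc", "Ie", "IC", "Icd", "IH", "α", "t″", "%HR", "%H", "%Pf", "Iθ"]
    n = len(labels)
    theta = [math.pi / 2 - 2.0 * math.pi * i / n for i in range(n)]
    radii = list(profile.radius_vector())

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5.5, 5.5))
    closed_theta = theta + theta[:1]
    closed_r = radii + radii[:1]
    ax.plot(closed_theta, closed_r, lw=1.5, color="tab:blue")
    ax.fill(closed_theta, closed_r, alpha=0.25, color="tab:blue")
    # shade the incidence groups at the rim
    group_colors = {
        "dimensions": "#8dd3c7",
        "compressibility": "#ffffb3",
        "flowability": "#bebada",
        "lubricity_stability": "#fb8072",
        "lubricity_dosage": "#80b1d3",
    }
    idx = 0
    for group, members in INCIDENCE_GROUPS.items():
        k = len(members)
        start = math.pi / 2 - 2.0 * math.pi * (idx - 0.5) / n
        width = 2.0 * math.pi * k / n
        ax.bar(
            [start - width / 2.0], [0.6], width=width, bottom=10.0,
            color=group_colors[group], edgecolor="none", align="center",
        )
        idx += k
    ax.set_xticks(theta)
    ax.set_xticklabels(labels)
    ax.set_ylim(0, 10.6)
    ax.set_yticks(range(0, 11, 2))
    ax.set_title(
        f"{profile.name}  (IPP={profile.ipp:.2f}, IGC={profile.igc:.2f})", pad=22
    )
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return geom


__all__ = [
    "F_PRINTED_12",
    "DIRECT_COMPRESSION_LIMIT",
    "TRANSFORMS",
    "TransformSpec",
    "RadiusProfile",
    "DiagramGeometry",
    "round_half_away",
    "to_radius",
    "from_radius",
    "reliability_factor",
    "incidence_means",
    "good_compression_index",
    "igc_from_incidences",
    "check_incidence_consistency",
    "diagram_geometry",
    "diagram",
]
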