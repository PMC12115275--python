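"""Synthetic measurement generator with known ground-truth parameters.

Given a target twelve-parameter set, this module constructs a physically
consistent raw measurement campaign — cylinder volumes, cone geometry, flow
times, drying / humidification weights, a sieve composition and tablet
breaking forces — that reproduces the targets exactly at zero noise, and
with configurable multiplicative Gaussian noise on every raw reading
otherwise. Because the interparticle porosity, Carr index and Hausner
ratio are functions of the two densities, a ground truth is specified by
the nine independent quantities (Da, Dc, Icd, alpha, t_flow, HR, H, Pf,
Itheta); the dependent three follow.

The sieve composition matching the (Itheta, Pf) pair is found by a
deterministic search: for every choice of majority fraction and a fine grid
on its percentage, the remaining mass is split between a pair of other
fractions by solving the (linear) homogeneity-index denominator equation
exactly; the best candidate by achieved Itheta is taken.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import InfeasibleTruthError
from .powder import density_derived, parameter_set
from .profile import RadiusProfile, from_radius, to_radius
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

#: |Itheta_achieved - Itheta_target| accepted by the sieve search
#: (2e-5 in Itheta is 0.01 on the radius scale).
SIEVE_SEARCH_TOL = 2e-5

#: Number of standard-normal draws consumed per simulated replicate. Fixed
#: so that runs at different noise levels share the same random stream
#: (common random numbers).
_DRAWS_PER_REPLICATE = 32


class GroundTruth(BaseModel):
    """Target parameter set plus the simulation noise model."""

    name: str = "synthetic"
    parameters: ParameterSet
    noise_rel: float = Field(default=0.0, ge=0, description="relative SD on raw readings")
    n_replicates: int = Field(default=1, ge=1)
    seed: int = 0

    def target_radii(self) -> dict[str, float]:
        return {
            pid: to_radius(pid, getattr(self.parameters, pid))
            for pid in PARAMETER_ORDER
        }


def ground_truth_from_radii(
    radii: dict[str, float], name: str = "synthetic", **kwargs
) -> GroundTruth:
    """Invert a radius profile to a physically consistent parameter set.

    Da, Dc, Icd, alpha, t_flow, HR, H, Pf and Itheta are inverted directly
    (radii at a clamp boundary invert to the boundary value of the
    acceptable range); Ie, IC and IH are recomputed from the densities, so
    their radii may differ from the input in the last rounded digit.
    """
    Da = from_radius("Da", radii["Da"])
    Dc = from_radius("Dc", radii["Dc"])
    if Da > Dc:
        raise InfeasibleTruthError(f"radii imply Da={Da} > Dc={Dc}")
    derived = density_derived(Da, Dc)
    params = ParameterSet(
        Da=Da,
        Dc=Dc,
        Ie=derived["Ie"],
        IC=derived["IC"],
        IH=derived["IH"],
        Icd=from_radius("Icd", radii["Icd"]),
        alpha=from_radius("alpha", radii["alpha"]),
        t_flow=from_radius("t_flow", radii["t_flow"]),
        HR=from_radius("HR", radii["HR"]),
        H=from_radius("H", radii["H"]),
        Pf=from_radius("Pf", radii["Pf"]),
        Itheta=from_radius("Itheta", radii["Itheta"]),
    )
    return GroundTruth(name=name, parameters=params, **kwargs)


def find_sieve_composition(
    itheta: float,
    pf_pct: float,
    apertures_mm: Sequence[float] = (0.355, 0.212, 0.100, 0.05),
    top_bound_mm: float = 0.500,
    fm_step: float = 0.1,
    tol: float = SIEVE_SEARCH_TOL,
) -> SieveAnalysis:
    """A five-fraction sieve composition with the given fines percentage
    whose homogeneity index matches ``itheta`` to within ``tol``."""
    bounds = (top_bound_mm, *apertures_mm, 0.0)
    diam = [1000.0 * (bounds[i] + bounds[i + 1]) / 2.0 for i in range(len(bounds) - 1)]
    nfrac = len(diam)
    pan = nfrac - 1
    others_all = [j for j in range(nfrac) if j != pan]
    S_total = 100.0 - pf_pct
    if S_total < -1e-9:
        raise InfeasibleTruthError("fines percentage exceeds 100")

    def evaluate(pct: list[float]) -> float:
        best_val = max(pct)
        m = pct.index(best_val)
        denom = 100.0 + sum(
            abs(diam[m] - diam[j]) * pct[j] for j in range(nfrac) if j != m
        )
        return pct[m] / denom

    best_pct: Optional[list[float]] = None
    best_err = math.inf

    def consider(pct: list[float]) -> None:
        nonlocal best_pct, best_err
        if any(p < -1e-9 for p in pct):
            return
        pct = [max(p, 0.0) for p in pct]
        err = abs(evaluate(pct) - itheta)
        if err < best_err:
            best_err = err
            best_pct = pct

    # Candidate majorities: the pan (its share is fixed at pf_pct) or any
    # sieve fraction with its share on a fine grid.
    majorities: list[tuple[int, list[float]]] = []
    if pf_pct > 0:
        majorities.append((pan, [pf_pct]))
    for m in others_all:
        lo = max(fm_step, pf_pct)  # must not be beaten by the pan
        grid = np.arange(lo, S_total + fm_step / 2, fm_step)
        majorities.append((m, [float(v) for v in grid]))

    for m, fm_values in majorities:
        rest = [j for j in others_all if j != m]
        for Fm in fm_values:
            S = S_total - (0.0 if m == pan else Fm)
            if S < -1e-9:
                continue
            S = max(S, 0.0)
            target_denom = Fm / itheta if itheta > 0 else math.inf
            w_pan = abs(diam[m] - diam[pan]) * pf_pct if m != pan else 0.0
            W = target_denom - 100.0 - w_pan
            cap = Fm  # no other fraction may exceed the majority
            if S == 0.0:
                pct = [0.0] * nfrac
                pct[pan] = pf_pct
                pct[m] = Fm if m != pan else pf_pct
                consider(pct)
                continue
            for j in rest:
                for k in rest:
                    if j >= k:
                        continue
                    wj = abs(diam[m] - diam[j])
                    wk = abs(diam[m] - diam[k])
                    if abs(wj - wk) < 1e-12:
                        continue
                    a = (W - S * wk) / (wj - wk)
                    b = S - a
                    if not (-1e-9 <= a <= min(S, cap) + 1e-9):
                        continue
                    if b > cap + 1e-9:
                        continue
                    pct = [0.0] * nfrac
                    pct[pan] = pf_pct
                    if m != pan:
                        pct[m] = Fm
                    pct[j] = max(a, 0.0)
                    pct[k] = max(b, 0.0)
                    consider(pct)
                # single-fraction fallback: everything in j
                pct = [0.0] * nfrac
                pct[pan] = pf_pct
                if m != pan:
                    pct[m] = Fm
                if S <= cap + 1e-9:
                    pct[j] = S
                    consider(pct)

    if best_pct is None or best_err > tol:
        raise InfeasibleTruthError(
            f"no sieve composition reaches Itheta={itheta} with Pf={pf_pct}% "
            f"(best error {best_err:.2e}, tolerance {tol:.0e})"
        )
    return SieveAnalysis(
        apertures_mm=tuple(apertures_mm),
        retained_pct=tuple(best_pct),
        top_bound_mm=top_bound_mm,
    )


def _noise_factors(rng: Optional[np.random.Generator], noise: float) -> np.ndarray:
    """Fixed-length block of multiplicative factors (1 at zero noise)."""
    if rng is None:
        z = np.zeros(_DRAWS_PER_REPLICATE)
    else:
        z = rng.standard_normal(_DRAWS_PER_REPLICATE)
    return np.clip(1.0 + noise * z, 0.05, None)


def simulate_powder_dataset(
    gt: GroundTruth,
    noise: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> PowderDataset:
    """One synthetic replicate of the full characterization campaign.

    At ``noise=0`` (or ``rng=None`` and ``gt.noise_rel=0``) the recomputed
    parameter set equals the ground truth up to the sieve-search tolerance.
    """
    p = gt.parameters
    noise = gt.noise_rel if noise is None else noise
    f = _noise_factors(rng, noise)
    i = iter(range(_DRAWS_PER_REPLICATE))

    # Densities: pour V0 = 100 mL at the target bulk density.
    V0_base = 100.0
    m_base = p.Da * V0_base
    V1250_base = m_base / p.Dc if p.Dc > 0 else V0_base
    V500_base = min(V1250_base + 1.0, V0_base)
    V10_base = (V0_base + V500_base) / 2.0

    mass = m_base * f[next(i)]
    V0 = V0_base * f[next(i)]
    V10 = min(V10_base * f[next(i)], V0)
    V500 = min(V500_base * f[next(i)], V10)
    V1250 = min(V1250_base * f[next(i)], V500)
    # The 2500-tap volume is always recorded so the record stays complete
    # when noise pushes |V500 - V1250| past the 2 mL extension rule.
    V2500 = min(V1250_base * f[next(i)], V1250)
    density = DensityMeasurement(
        mass_g=mass,
        volume_initial_mL=V0,
        tap_volumes_mL={10: V10, 500: V500, 1250: V1250, 2500: V2500},
    )

    # Cone: 5 cm mean base radius, height from the target angle.
    h_base = 5.0 * math.tan(math.radians(p.alpha))
    h = max(h_base * f[next(i)], 0.0)
    radii = tuple(max(5.0 * f[next(i)], 0.01) for _ in range(4))
    cone = ConeMeasurement(height_cm=h, base_radii_cm=radii)

    # Flow: three stopwatch repeats (draws consumed even for non-flowing
    # powders to keep the stream aligned).
    t_factors = [f[next(i)] for _ in range(3)]
    if math.isinf(p.t_flow):
        flow = FlowMeasurement(nonflow_flag=True)
    else:
        flow = FlowMeasurement(times_s=tuple(max(p.t_flow * tf, 0.0) for tf in t_factors))

    # Moisture: 100 g sample before drying.
    wet = 100.0 * f[next(i)]
    dry = min((100.0 - p.HR) / 100.0 * wet * f[next(i)], wet)
    humid = (100.0 + p.H) / 100.0 * wet * f[next(i)]
    moisture = MoistureRecord(wet_weight_g=wet, dry_weight_g=dry, humid_weight_g=humid)

    # Sieve: exact composition for the (Itheta, Pf) pair, then perturb the
    # per-fraction masses and renormalize.
    base_sieve = find_sieve_composition(p.Itheta, p.Pf)
    masses = [pct * f[next(i)] for pct in base_sieve.retained_pct]
    total = sum(masses)
    sieve = SieveAnalysis(
        apertures_mm=base_sieve.apertures_mm,
        retained_pct=tuple(100.0 * mm / total for mm in masses),
        top_bound_mm=base_sieve.top_bound_mm,
    )

    # Hardness: ten tablets at the target mean breaking force.
    forces = tuple(max(p.Icd * f[next(i)], 0.0) for _ in range(10))
    hardness = HardnessSample(breaking_forces_N=forces, lubricated_flag=True)

    return PowderDataset(
        name=gt.name,
        density=density,
        cone=cone,
        flow=flow,
        moisture=moisture,
        sieve=sieve,
        hardness=hardness,
    )


def simulate_replicates(gt: GroundTruth) -> list[PowderDataset]:
    """``gt.n_replicates`` datasets from the seeded noise model."""
    rng = np.random.default_rng(gt.seed)
    return [
        simulate_powder_dataset(gt, noise=gt.noise_rel, rng=rng)
        for _ in range(gt.n_replicates)
    ]


def recovery_report(
    gt: GroundTruth,
    n_replicates: int = 100,
    noise: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo recovery of the radius profile under measurement noise.

    Returns one row per parameter (bias and RMSE on the radius scale) plus
    an ``IGC`` row. The random stream depends only on ``seed`` and the
    replicate index, so runs at different noise levels use common random
    numbers and RMSE is comparable across levels.
    """
    if n_replicates < 2:
        raise InfeasibleTruthError("recovery needs at least 2 replicates")
    rng = np.random.default_rng(seed)
    truth = RadiusProfile.from_parameters(gt.parameters, name=gt.name)
    true_radii = truth.radius_vector()
    true_igc = truth.igc

    radii_err = np.zeros((n_replicates, len(PARAMETER_ORDER)))
    igc_err = np.zeros(n_replicates)
    for rep in range(n_replicates):
        ds = simulate_powder_dataset(gt, noise=noise, rng=rng)
        prof = RadiusProfile.from_parameters(parameter_set(ds), name=gt.name)
        radii_err[rep] = np.asarray(prof.radius_vector()) - np.asarray(true_radii)
        igc_err[rep] = prof.igc - true_igc

    rows = []
    for j, pid in enumerate(PARAMETER_ORDER):
        rows.append(
            {
                "quantity": pid,
                "true_radius": true_radii[j],
                "bias": float(radii_err[:, j].mean()),
                "rmse": float(np.sqrt((radii_err[:, j] ** 2).mean())),
            }
        )
    rows.append(
        {
            "quantity": "IGC",
            "true_radius": true_igc,
            "bias": float(igc_err.mean()),
            "rmse": float(np.sqrt((igc_err**2).mean())),
        }
    )
    return pd.DataFrame(rows)


__all__ = [
    "SIEVE_SEARCH_TOL",
    "GroundTruth",
    "ground_truth_from_radii",
    "find_sieve_composition",
    "simulate_powder_dataset",
    "simulate_replicates",
    "recovery_report",
]
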