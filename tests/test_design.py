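"""Corrective-excipient dose equation, compositions and the radius sweep."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedem import fixtures
from sedem.design import (
    DEFAULT_TARGET_RADII,
    LUBRICANT_TOTAL_PCT,
    BlendDesign,
    MaterialProfile,
    blend_radius_predict,
    build_composition,
    corrective_excipient_pct,
    r_sweep,
)
from sedem.errors import CompositionError, DegeneratePairError, InfeasibleTargetError
from sedem.profile import round_half_away


@pytest.mark.parametrize(
    "RE, R, RP, expected",
    [
        (5.90, 5.0, 2.92, 69.80),
        (5.90, 2.92, 2.92, 0.0),
        (5.90, 5.90, 2.92, 100.0),
        (5.66, 3.5, 2.92, 21.17),
    ],
)
def test_corrective_excipient_pct(RE, R, RP, expected):
    assert round_half_away(corrective_excipient_pct(RE, R, RP)) == expected


def test_corrective_excipient_errors():
    with pytest.raises(DegeneratePairError):
        corrective_excipient_pct(5.0, 4.0, 5.0)
    with pytest.raises(DegeneratePairError):
        corrective_excipient_pct(2.0, 2.5, 3.0)  # excipient worse than API
    with pytest.raises(InfeasibleTargetError):
        corrective_excipient_pct(4.91, 5.0, 2.92)  # target beyond pure excipient
    with pytest.raises(InfeasibleTargetError):
        corrective_excipient_pct(5.9, 2.0, 2.92)  # target below pure API


@pytest.mark.parametrize(
    "cp, RE, RP, expected",
    [(19.46, 5.90, 2.92, 3.50), (0.0, 5.9, 2.92, 2.92), (100.0, 5.9, 2.92, 5.9),
     (67.53, 6.00, 2.92, 5.00)],
)
def test_blend_radius_predict(cp, RE, RP, expected):
    assert blend_radius_predict(cp, RE, RP) == pytest.approx(expected, abs=0.005)


@given(
    RP=st.floats(0.0, 9.0),
    gap=st.floats(1e-3, 10.0),
    frac=st.floats(0.0, 1.0),
)
@settings(max_examples=300, derandomize=True)
def test_dose_equation_round_trip(RP, gap, frac):
    RE = min(RP + gap, 10.0)
    if RE - RP < 1e-6:
        return
    R = RP + frac * (RE - RP)
    cp = corrective_excipient_pct(RE, R, RP)
    assert 0.0 <= cp <= 100.0
    assert blend_radius_predict(cp, RE, RP) == pytest.approx(R, abs=1e-9)


@given(RP=st.floats(0.0, 5.0), a=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0))
@settings(max_examples=200, derandomize=True)
def test_cp_monotone_in_target_and_api_radius(RP, a, b):
    """Raising the target radius demands more excipient (CP = 100 at R=RE);
    a better-compressing API (higher RP) demands less."""
    RE = 8.0
    lo, hi = sorted((RP + a * (RE - RP), RP + b * (RE - RP)))
    if hi - lo < 1e-9:
        return
    assert corrective_excipient_pct(RE, hi, RP) > corrective_excipient_pct(RE, lo, RP)
    if lo > RP + 1e-9 and RP + 0.5 < lo:
        assert corrective_excipient_pct(RE, lo, RP + 0.5) < corrective_excipient_pct(
            RE, lo, RP
        )


class TestComposition:
    def test_f13_design(self):
        d = BlendDesign(
            api=MaterialProfile(name="carbamazepine", role="API", compressibility_radius=2.92),
            excipient=MaterialProfile(name="L-HPC LH11", role="corrective-excipient",
                                      compressibility_radius=5.90),
            target_R=3.5, cp_pct=19.46, dose_mg=50.0,
        )
        assert d.api_pct == pytest.approx(77.04)
        assert d.tablet_weight_mg == pytest.approx(64.90, abs=0.005)
        assert sum(d.composition().values()) == pytest.approx(100.0, abs=1e-9)

    def test_lubricants_only(self):
        d = BlendDesign(
            api=MaterialProfile(name="api", role="API", compressibility_radius=5.0),
            excipient=MaterialProfile(name="exc", role="corrective-excipient",
                                      compressibility_radius=6.0),
            target_R=5.0, cp_pct=0.0, dose_mg=50.0,
        )
        assert d.api_pct == pytest.approx(96.50)
        assert d.tablet_weight_mg == pytest.approx(51.81, abs=0.005)

    def test_no_room_for_api(self):
        with pytest.raises(CompositionError):
            BlendDesign(
                api=MaterialProfile(name="a", role="API", compressibility_radius=2.0),
                excipient=MaterialProfile(name="e", role="corrective-excipient",
                                          compressibility_radius=9.0),
                target_R=8.9, cp_pct=98.0,
            )

    def test_build_composition_row(self):
        d = BlendDesign(
            api=MaterialProfile(name="carbamazepine", role="API", compressibility_radius=2.92),
            excipient=MaterialProfile(name="PROSOLV ODT", role="corrective-excipient",
                                      compressibility_radius=5.66),
            target_R=5.0, cp_pct=75.91,
        )
        row = build_composition(d)
        assert row["carbamazepine %"] == pytest.approx(20.59)
        assert row["talc %"] == 2.36


PUBLISHED_SWEEPS = {
    "L-HPC LH11": (69.80, 53.02, 36.24, 19.46),
    "L-HPC NBD022": (67.53, 51.30, 35.06, 18.83),
    "PROSOLV ODT": (75.91, 57.66, 39.42, 21.17),
    "PARTECK ODT": (89.27, 67.81, 46.35, 24.89),  # needs the back-solved RE
}


@pytest.mark.parametrize("excipient", list(PUBLISHED_SWEEPS))
def test_r_sweep_reproduces_published_compositions(excipient):
    api = fixtures.compressibility_material("carbamazepine")
    exc = fixtures.compressibility_material(excipient, use_backsolved=True)
    outcomes = r_sweep(api, exc)
    got = tuple(round_half_away(o.design.cp_pct) for o in outcomes)
    assert got == PUBLISHED_SWEEPS[excipient]
    weights = [o.design.tablet_weight_mg for o in outcomes]
    assert weights == sorted(weights, reverse=True)  # lighter along the sweep
    for o in outcomes:
        assert sum(o.design.composition().values()) == pytest.approx(100, abs=1e-9)


def test_parteck_infeasible_at_printed_incidence():
    api = fixtures.compressibility_material("carbamazepine")
    exc = fixtures.compressibility_material("PARTECK ODT", use_backsolved=False)
    assert exc.compressibility_radius == 4.91
    outcomes = r_sweep(api, exc)
    flags = {o.target_R: o.feasible for o in outcomes}
    assert flags == {5.0: False, 4.5: True, 4.0: True, 3.5: True}
    infeasible = next(o for o in outcomes if not o.feasible)
    assert "exceeds RE" in infeasible.reason


def test_equal_radii_sweep_all_flagged():
    m = MaterialProfile(name="x", role="API", compressibility_radius=4.0)
    e = MaterialProfile(name="y", role="corrective-excipient", compressibility_radius=4.0)
    outcomes = r_sweep(m, e, DEFAULT_TARGET_RADII)
    assert all(not o.feasible for o in outcomes)
    assert len(outcomes) == len(DEFAULT_TARGET_RADII)


def test_api_percent_accounts_for_lubricant_trio():
    assert LUBRICANT_TOTAL_PCT == pytest.approx(3.50)
    table = fixtures.composition_table()
    # every published row: API% + excipient% + lubricants = 100
    totals = table.api_pct + table.excipient_pct + LUBRICANT_TOTAL_PCT
    assert (abs(totals - 100.0) < 0.015).all()
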