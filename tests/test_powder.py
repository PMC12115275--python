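"""Unit and property tests for the twelve parameter computations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedem.errors import (
    IncompleteTapSeriesError,
    InconsistentDensitiesError,
    MeasurementOrderError,
    NoDataError,
    TapRuleViolationError,
)
from sedem.powder import (
    angle_of_repose,
    bulk_density,
    cohesion_index,
    density_derived,
    fines_fraction,
    homogeneity_index,
    moisture_params,
    parameter_set,
    tapped_density,
)
from sedem.profile import to_radius
from sedem.types import (
    ConeMeasurement,
    DensityMeasurement,
    HardnessSample,
    MoistureRecord,
    PowderDataset,
    SieveAnalysis,
)


def _density(m, v0, taps):
    return DensityMeasurement(mass_g=m, volume_initial_mL=v0, tap_volumes_mL=taps)


@pytest.mark.parametrize(
    "m, v0, expected",
    [(100.0, 100.0, 1.000), (58.4, 100.0, 0.584), (61.9, 100.0, 0.619)],
)
def test_bulk_density(m, v0, expected):
    d = _density(m, v0, {10: v0, 500: v0, 1250: v0})
    assert bulk_density(d) == pytest.approx(expected)


@pytest.mark.parametrize(
    "m, taps, expected, used",
    [
        (70.2, {10: 103, 500: 101, 1250: 100}, 0.702, "V1250"),
        (100.0, {10: 110, 500: 108, 1250: 105, 2500: 104}, 100 / 104, "V2500"),
        (100.0, {10: 100, 500: 100, 1250: 100}, 1.000, "V1250"),
    ],
)
def test_tapped_density_two_ml_rule(m, taps, expected, used):
    result = tapped_density(_density(m, 120.0, taps))
    assert result.value == pytest.approx(expected, abs=1e-4)
    assert result.volume_used == used


def test_tapped_density_errors():
    with pytest.raises(IncompleteTapSeriesError):
        tapped_density(_density(100, 120, {10: 110, 1250: 105}))
    # 3 mL gap between 500 and 1250 taps but no 2500-tap reading
    with pytest.raises(TapRuleViolationError):
        tapped_density(_density(100, 120, {10: 110, 500: 108, 1250: 105}))


@pytest.mark.parametrize(
    "Da, Dc, Ie, IC, IH",
    [
        (0.584, 0.702, 0.2878, 16.81, 1.2021),  # API densities
        (0.5, 0.5, 0.0, 0.0, 1.0),
        (0.473, 0.649, 0.5733, 27.12, 1.3721),  # optimized blend F14
    ],
)
def test_density_derived(Da, Dc, Ie, IC, IH):
    out = density_derived(Da, Dc)
    assert out["Ie"] == pytest.approx(Ie, abs=5e-4)
    assert out["IC"] == pytest.approx(IC, abs=5e-3)
    assert out["IH"] == pytest.approx(IH, abs=5e-4)


def test_density_derived_radii_match_published_column():
    # forward transforms of the derived indices land on the published radii
    out = density_derived(0.584, 0.702)
    assert to_radius("Ie", out["Ie"]) == pytest.approx(2.40, abs=0.01)
    assert to_radius("IC", out["IC"]) == pytest.approx(3.36, abs=0.01)
    assert to_radius("IH", out["IH"]) == pytest.approx(8.99, abs=0.01)
    out = density_derived(0.473, 0.649)
    assert to_radius("Ie", out["Ie"]) == pytest.approx(4.78, abs=0.02)
    assert to_radius("IC", out["IC"]) == pytest.approx(5.42, abs=0.02)
    assert to_radius("IH", out["IH"]) == pytest.approx(8.14, abs=0.02)


def test_density_derived_rejects_inverted_densities():
    with pytest.raises(InconsistentDensitiesError):
        density_derived(0.7, 0.6)


@given(
    Da=st.floats(0.05, 1.5),
    delta1=st.floats(0.0, 1.0),
    delta2=st.floats(1e-6, 0.5),
)
@settings(max_examples=200, derandomize=True)
def test_density_indices_increase_with_tapped_density(Da, delta1, delta2):
    lo = density_derived(Da, Da + delta1)
    hi = density_derived(Da, Da + delta1 + delta2)
    assert hi["Ie"] > lo["Ie"]
    assert hi["IC"] > lo["IC"]
    assert hi["IH"] > lo["IH"]
    assert lo["Ie"] >= 0 and lo["IC"] >= 0 and lo["IH"] >= 1


@pytest.mark.parametrize(
    "h, radii, expected",
    [
        (3.0, (5, 5, 5, 5), 30.96),
        (0.0, (5, 5, 5, 5), 0.0),
        (5.0, (4, 5, 5, 6), 45.00),
    ],
)
def test_angle_of_repose(h, radii, expected):
    cone = ConeMeasurement(height_cm=h, base_radii_cm=radii)
    assert angle_of_repose(cone) == pytest.approx(expected, abs=0.01)


class TestHomogeneityIndex:
    def test_single_fraction_powder(self):
        s = SieveAnalysis(retained_pct=(0, 0, 100, 0, 0))
        assert homogeneity_index(s) == pytest.approx(1.0)

    def test_two_fraction_hand_expansion(self):
        # 50% in 100-212 um (d=156) and 50% in 50-100 um (d=75), coarser
        # fraction wins the tie: 50 / (100 + (156-75)*50)
        with pytest.warns(UserWarning, match="tie"):
            s = SieveAnalysis(retained_pct=(0, 0, 50, 50, 0))
            assert homogeneity_index(s) == pytest.approx(50 / 4150, rel=1e-9)

    def test_bounds_and_majority_shift(self):
        near = SieveAnalysis(retained_pct=(0, 30, 60, 10, 0))
        far = SieveAnalysis(retained_pct=(0, 30, 60, 0, 10))  # mass moved farther
        assert 0 < homogeneity_index(far) < homogeneity_index(near) <= 1

    @given(
        pcts=st.lists(st.floats(0.0, 100.0), min_size=5, max_size=5).filter(
            lambda xs: sum(xs) > 1.0
        )
    )
    @settings(max_examples=300, derandomize=True)
    def test_against_literal_expansion(self, pcts):
        total = sum(pcts)
        pcts = tuple(100.0 * p / total for p in pcts)
        s = SieveAnalysis(retained_pct=pcts)
        # independent oracle: literal neighbor-by-neighbor expansion
        d = s.fraction_mean_diameters_um()
        m = max(range(5), key=lambda j: (pcts[j], -j))
        denom = 100.0
        for n in range(1, 5):
            if m - n >= 0:
                denom += (d[m - n] - d[m]) * pcts[m - n]
            if m + n <= 4:
                denom += (d[m] - d[m + n]) * pcts[m + n]
        expected = pcts[m] / denom
        assert homogeneity_index(s) == pytest.approx(expected, rel=1e-12)
        assert 0 < homogeneity_index(s) <= 1 + 1e-9


@pytest.mark.parametrize(
    "wet, dry, humid, hr, h",
    [
        (100.0, 99.67, 100.01, 0.33, 0.01),
        (100.0, 100.0, 100.0, 0.0, 0.0),
        (100.0, 93.98, 103.10, 6.02, 3.10),
    ],
)
def test_moisture_params(wet, dry, humid, hr, h):
    out = moisture_params(
        MoistureRecord(wet_weight_g=wet, dry_weight_g=dry, humid_weight_g=humid)
    )
    assert out["HR"] == pytest.approx(hr, abs=1e-9)
    assert out["H"] == pytest.approx(h, abs=1e-9)


def test_moisture_negative_hygroscopicity_floored():
    with pytest.warns(UserWarning, match="floored"):
        out = moisture_params(
            MoistureRecord(wet_weight_g=100, dry_weight_g=99, humid_weight_g=99.5)
        )
    assert out["H"] == 0.0


def test_moisture_order_error():
    with pytest.raises(MeasurementOrderError):
        moisture_params(
            MoistureRecord(wet_weight_g=100, dry_weight_g=101, humid_weight_g=100)
        )


@pytest.mark.parametrize(
    "forces, expected_mean, expected_radius",
    [
        ((60, 60, 60), 60.0, 3.0),
        ((195, 205, 200), 200.0, 10.0),
        ((44.4,), 44.4, 2.22),
    ],
)
def test_cohesion_index(forces, expected_mean, expected_radius):
    mean = cohesion_index(HardnessSample(breaking_forces_N=forces))
    assert mean == pytest.approx(expected_mean)
    assert to_radius("Icd", mean) == pytest.approx(expected_radius)


@pytest.mark.parametrize(
    "pan, expected_radius",
    [(0.0, 10.0), (11.0, 7.80), (50.0, 0.0)],
)
def test_fines_fraction_and_radius(pan, expected_radius):
    s = SieveAnalysis(retained_pct=(100 - pan, 0, 0, 0, pan))
    assert fines_fraction(s) == pan
    assert to_radius("Pf", pan) == pytest.approx(expected_radius)


def test_parameter_set_requires_complete_campaign():
    ds = PowderDataset(name="partial", density=_density(58.4, 100, {10: 95, 500: 90, 1250: 88}))
    with pytest.raises(NoDataError, match="missing"):
        parameter_set(ds)
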