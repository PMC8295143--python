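"""Material property curves, bounds and the perfusion term."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ireplan as ip
from ireplan.tissue import SIGMA_MAX, SIGMA_MIN, PropertyCurve


class TestSigmaOfField:
    def test_floor_ceiling_and_midpoint(self, liver):
        assert ip.sigma_of_field(liver, 0.0) == pytest.approx(0.0650)
        assert ip.sigma_of_field(liver, 1e9) == pytest.approx(0.1483)
        # default curve is symmetric about the ramp midpoint (40 kV/m)
        assert ip.sigma_of_field(liver, 4.0e4) == pytest.approx((0.0650 + 0.1483) / 2)

    def test_negative_field_rejected(self, liver):
        with pytest.raises(ValueError):
            ip.sigma_of_field(liver, -1.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1e7, allow_nan=False))
    def test_bounded_by_floor_and_ceiling(self, e):
        liver = ip.bovine_liver()
        s = float(ip.sigma_of_field(liver, e))
        assert SIGMA_MIN <= s <= SIGMA_MAX

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=2e5, allow_nan=False),
        st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
    )
    def test_monotone_non_decreasing(self, e, de):
        liver = ip.bovine_liver()
        assert ip.sigma_of_field(liver, e + de) >= ip.sigma_of_field(liver, e)

    def test_continuity_at_knots(self, liver):
        eps = 1e-6
        for xk in liver.electrical_conductivity.x:
            lo = ip.sigma_of_field(liver, max(xk - eps, 0.0))
            hi = ip.sigma_of_field(liver, xk + eps)
            assert abs(hi - lo) < 1e-8

    def test_curve_declared_nondecreasing(self):
        with pytest.raises(ValueError):
            ip.TissueProperties(
                electrical_conductivity=PropertyCurve(
                    [(0.0, 0.1), (1e4, 0.05)], abscissa="field_magnitude"
                )
            )


class TestKOfTemperature:
    def test_default_single_knot(self, liver):
        assert ip.k_of_temperature(liver, 37.0) == pytest.approx(0.52)
        # clamp below the first knot
        assert ip.k_of_temperature(liver, 0.0) == pytest.approx(0.52)

    def test_two_knot_interpolation(self):
        props = ip.TissueProperties(
            thermal_conductivity=PropertyCurve([(37.0, 0.5), (57.0, 0.6)])
        )
        assert ip.k_of_temperature(props, 47.0) == pytest.approx(0.55)
        assert ip.k_of_temperature(props, 20.0) == pytest.approx(0.5)
        assert ip.k_of_temperature(props, 90.0) == pytest.approx(0.6)

    def test_non_finite_rejected(self, liver):
        with pytest.raises(ValueError):
            ip.k_of_temperature(liver, float("nan"))


class TestPerfusion:
    def test_blood_defaults_exact(self, blood):
        assert (
            blood.density,
            blood.heat_capacity,
            blood.perfusion_rate,
            blood.blood_temperature,
            blood.metabolic_heat,
        ) == (1000.0, 3640.0, 5e-4, 37.0, 0.0)

    def test_zero_at_blood_temperature(self, blood):
        assert ip.perfusion_sink(blood, 37.0) == 0.0

    def test_antisymmetric_about_blood_temperature(self, blood):
        assert ip.perfusion_sink(blood, 47.0) == pytest.approx(-18200.0)
        assert ip.perfusion_sink(blood, 27.0) == pytest.approx(18200.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=-20.0, max_value=120.0, allow_nan=False))
    def test_sign_matches_temperature_deficit(self, t):
        blood = ip.blood_defaults()
        assert np.sign(ip.perfusion_sink(blood, t)) == np.sign(37.0 - t)


class TestPropertyCurve:
    def test_knots_must_increase(self):
        with pytest.raises(ValueError):
            PropertyCurve([(1.0, 0.5), (1.0, 0.6)])

    def test_csv_round_trip(self, tmp_path, liver):
        path = tmp_path / "sigma.csv"
        liver.electrical_conductivity.to_csv(path)
        back = PropertyCurve.from_csv(path)
        assert back.abscissa == "field_magnitude"
        np.testing.assert_allclose(back.x, liver.electrical_conductivity.x)
        np.testing.assert_allclose(back.values, liver.electrical_conductivity.values)

    def test_shipped_curves_match_defaults(self):
        import importlib.resources as resources

        liver = ip.bovine_liver()
        with resources.as_file(
            resources.files("ireplan") / "data" / "sigma_vs_field.csv"
        ) as p:
            shipped = PropertyCurve.from_csv(p)
        np.testing.assert_allclose(shipped.values, liver.electrical_conductivity.values)
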