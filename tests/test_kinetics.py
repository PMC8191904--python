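"""Temperature responses, uptake kinetics, inhibition and speciation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slurrygas.kinetics import (
    CardinalParams,
    InhibitionConstants,
    KSTemperatureParams,
    MicrobialGroup,
    cardinal_rate,
    h2s_pka1,
    inhibition_product,
    ks_at_temperature,
    methanogen_uptake_rate,
    nh4_pka,
    qmax_opt_from_linear_rule,
    speciate_sulfide,
    speciate_tan,
    sulfate_reduction_rate,
)


class TestCardinalRate:
    @pytest.mark.parametrize(
        "T, expected",
        [
            (50.0, 0.02),        # rate_opt at the optimum
            (0.0, 0.0),          # zero at T_min
            (60.0, 0.0),         # zero at T_max
            (20.0, 0.0045714),   # hand-evaluated interior point
        ],
    )
    def test_reference_points(self, T, expected):
        p = CardinalParams(T_min=0.0, T_opt=50.0, T_max=60.0, rate_opt=0.02)
        assert cardinal_rate(T, p) == pytest.approx(expected, abs=1e-6)

    def test_clamped_outside_cardinal_interval(self):
        p = CardinalParams(T_min=5.0, T_opt=35.0, T_max=45.0, rate_opt=1.0)
        assert cardinal_rate(-10.0, p) == 0.0
        assert cardinal_rate(80.0, p) == 0.0

    def test_maximum_attained_exactly_at_optimum(self):
        p = CardinalParams(T_min=0.0, T_opt=37.0, T_max=45.0, rate_opt=2.5)
        grid = np.linspace(-5.0, 60.0, 20001)
        vals = cardinal_rate(grid, p)
        assert np.all(vals >= 0.0)
        assert np.all(vals <= p.rate_opt + 1e-12)
        assert abs(grid[np.argmax(vals)] - p.T_opt) < 0.01
        # continuity on the open interval: no jumps on a fine grid
        inner = vals[(grid > p.T_min) & (grid < p.T_max)]
        assert np.max(np.abs(np.diff(inner))) < 0.01

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError, match="T_min < T_opt < T_max"):
            CardinalParams(T_min=40.0, T_opt=30.0, T_max=50.0, rate_opt=1.0)


class TestKSTemperature:
    def test_at_zero_celsius_equals_coef_times_k1(self):
        p = KSTemperatureParams(k1=0.8, k2=0.04)
        assert ks_at_temperature(0.0, 2.5, p) == pytest.approx(2.5 * 0.8)

    def test_default_coef_of_one_gives_bare_exponential(self):
        p = KSTemperatureParams(k1=1.0, k2=0.05)
        T = np.array([0.0, 10.0, 25.0])
        np.testing.assert_allclose(
            ks_at_temperature(T, 1.0, p), np.exp(-0.05 * T), rtol=1e-12
        )

    def test_decade_ratio_independent_of_temperature(self):
        p = KSTemperatureParams(k1=0.6, k2=0.07)
        for T in (-5.0, 0.0, 13.0, 40.0):
            ratio = ks_at_temperature(T + 10.0, 1.0, p) / ks_at_temperature(T, 1.0, p)
            assert ratio == pytest.approx(np.exp(-10.0 * 0.07), rel=1e-12)

    def test_strictly_decreasing_and_log_affine(self):
        p = KSTemperatureParams(k1=1.3, k2=0.06)
        T = np.linspace(-10.0, 60.0, 300)
        ks = ks_at_temperature(T, 1.0, p)
        assert np.all(np.diff(ks) < 0)
        slope = np.diff(np.log(ks)) / np.diff(T)
        np.testing.assert_allclose(slope, -0.06, rtol=1e-9)

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ValueError):
            KSTemperatureParams(k1=0.0, k2=0.05)
        with pytest.raises(ValueError):
            KSTemperatureParams(k1=1.0, k2=-0.1)


class TestLinearQmaxRule:
    @pytest.mark.parametrize("t_opt, expected", [(40.0, 8.0), (0.0, 0.0), (20.0, 4.0),
                                                 (50.0, 10.0)])
    def test_line_through_origin(self, t_opt, expected):
        assert qmax_opt_from_linear_rule(t_opt) == pytest.approx(expected)

    def test_negative_optimum_rejected(self):
        with pytest.raises(ValueError):
            qmax_opt_from_linear_rule(-1.0)


class TestUptakeRates:
    def test_monod_limits(self):
        assert methanogen_uptake_rate(0.0, 0.5, 2.0, 100.0) == 0.0
        assert methanogen_uptake_rate(0.5, 0.5, 2.0, 100.0) == pytest.approx(100.0)
        assert methanogen_uptake_rate(1e9, 0.5, 2.0, 100.0) == pytest.approx(
            200.0, rel=1e-6)

    def test_homogeneous_in_biomass(self, rng):
        for _ in range(20):
            c, ks, q, x = rng.uniform(0.01, 10.0, 4)
            r1 = methanogen_uptake_rate(c, ks, q, x)
            r2 = methanogen_uptake_rate(c, ks, q, 3.0 * x)
            assert r2 == pytest.approx(3.0 * r1)
            assert r1 >= 0.0

    def test_double_monod_limits(self):
        assert sulfate_reduction_rate(1.0, 0.0, 0.5, 0.05, 2.0, 100.0) == 0.0
        quarter = sulfate_reduction_rate(0.5, 0.05, 0.5, 0.05, 2.0, 100.0)
        assert quarter == pytest.approx(2.0 * 100.0 / 4.0)
        # sulfate saturation reduces to the single-Monod form
        sat = sulfate_reduction_rate(0.7, 1e9, 0.5, 0.05, 2.0, 100.0)
        assert sat == pytest.approx(methanogen_uptake_rate(0.7, 0.5, 2.0, 100.0),
                                    rel=1e-6)

    def test_inhibition_product_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            methanogen_uptake_rate(1.0, 0.5, 2.0, 100.0, I_product=1.5)
        with pytest.raises(ValueError):
            sulfate_reduction_rate(1.0, 1.0, 0.5, 0.05, 2.0, 100.0, I_product=-0.1)


class TestInhibition:
    def test_unity_without_inhibitors_at_ph_optimum(self, mesophile):
        pH_opt = mesophile.inhibition.pH_opt
        assert inhibition_product(pH_opt, 0.0, 0.0, 0.0, mesophile) == pytest.approx(1.0)

    def test_vanishes_at_extreme_sulfide(self, mesophile):
        assert inhibition_product(7.0, 0.0, 0.0, 1e9, mesophile) < 1e-6

    def test_acidification_reduces_activity(self, mesophile):
        assert (inhibition_product(5.5, 0.0, 0.0, 0.0, mesophile)
                < inhibition_product(7.0, 0.0, 0.0, 0.0, mesophile))

    def test_monotone_nonincreasing_in_each_inhibitor(self, mesophile):
        grid = np.linspace(0.0, 5.0, 50)
        for make in (
            lambda c: inhibition_product(7.25, c, 0.0, 0.0, mesophile),
            lambda c: inhibition_product(7.25, 0.0, c, 0.0, mesophile),
            lambda c: inhibition_product(7.25, 0.0, 0.0, c, mesophile),
        ):
            vals = np.array([make(c) for c in grid])
            assert np.all(np.diff(vals) <= 1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        pH=st.floats(0.0, 14.0),
        nh3=st.floats(0.0, 100.0),
        nh4=st.floats(0.0, 100.0),
        h2s=st.floats(0.0, 100.0),
    )
    def test_bounded_on_admissible_inputs(self, pH, nh3, nh4, h2s):
        g = MicrobialGroup(
            id="g", cardinal=CardinalParams(0.0, 30.0, 40.0, 5.0),
            inhibition=InhibitionConstants(pH_LL=6.0, pH_UL=8.0),
        )
        val = inhibition_product(pH, nh3, nh4, h2s, g)
        assert 0.0 <= val <= 1.0


class TestSpeciation:
    def test_tan_conserved_and_split_at_pka(self):
        T = 25.0
        nh3, nh4 = speciate_tan(10.0, nh4_pka(T), T)
        assert nh3 + nh4 == pytest.approx(10.0)
        assert nh3 == pytest.approx(5.0)

    def test_tan_limits(self):
        nh3, nh4 = speciate_tan(10.0, 0.0, 20.0)
        assert nh3 == pytest.approx(0.0, abs=1e-8)
        assert speciate_tan(0.0, 7.0, 20.0) == (0.0, 0.0)

    def test_free_ammonia_increases_with_ph_and_temperature(self):
        low, _ = speciate_tan(10.0, 7.0, 20.0)
        high, _ = speciate_tan(10.0, 8.5, 20.0)
        warm, _ = speciate_tan(10.0, 7.0, 35.0)
        assert high > low
        assert warm > low

    def test_sulfide_half_unionized_at_pka(self):
        T = 25.0
        conc = speciate_sulfide(10.0, h2s_pka1(T), T, slurry_mass=5.0)
        assert conc == pytest.approx(0.5 * 10.0 / 5.0)

    def test_sulfide_limits_and_errors(self):
        # alkaline limit: unionized fraction vanishes
        assert speciate_sulfide(10.0, 13.0, 20.0, 1.0) < 1e-4 * speciate_sulfide(
            10.0, 4.0, 20.0, 1.0)
        assert speciate_sulfide(0.0, 7.0, 20.0, 1.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            speciate_sulfide(1.0, 7.0, 20.0, 0.0)
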