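import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from limnogas import (
    diffusive_flux,
    enhancement_factor,
    equilibrium_concentration,
    flux_table,
    k600_model,
    oxygen_saturation,
    schmidt_number,
    station_pressure,
    transfer_velocity,
)
from limnogas.gas_exchange import (
    K600_MODELS,
    co2_diffusivity,
    hydration_rate,
    hydroxylation_rate,
    schmidt_exponent,
)
from limnogas.carbonate_isotope import freshwater_constants


class TestSchmidtNumber:
    def test_values_at_21c(self):
        assert schmidt_number("CO2", 21.0) == pytest.approx(635.86, abs=0.01)
        assert schmidt_number("CH4", 21.0) == pytest.approx(654.26, abs=0.01)

    def test_constant_term_at_zero_c(self):
        assert schmidt_number("CO2", 0.0) == pytest.approx(2116.8)

    def test_matches_independent_polynomial_evaluation(self):
        # oracle: a second, explicit power-sum evaluation of the same fits
        for t in np.linspace(0.0, 40.0, 41):
            ref_co2 = (2116.8 - 136.25 * t + 4.7353 * t**2
                       - 0.09231 * t**3 + 0.0007555 * t**4)
            ref_ch4 = (2101.2 - 131.54 * t + 4.4931 * t**2
                       - 0.08676 * t**3 + 0.00070663 * t**4)
            assert schmidt_number("CO2", t) == pytest.approx(ref_co2, rel=1e-9)
            assert schmidt_number("CH4", t) == pytest.approx(ref_ch4, rel=1e-9)

    def test_out_of_range_behaviour(self):
        with pytest.raises(ValueError):
            schmidt_number("CO2", 45.0)
        with pytest.warns(UserWarning):
            schmidt_number("CO2", 45.0, out_of_range="warn")

    def test_unknown_gas(self):
        with pytest.raises(KeyError):
            schmidt_number("N2", 21.0)


class TestK600Registry:
    @pytest.mark.parametrize(
        "model,u10,expected",
        [
            ("cole_caraco", 0.0, 2.07),
            ("crusius_wanninkhof", 2.0, 1.44),
            ("cole_caraco", 2.0, 0.215 * 2**1.7 + 2.07),
            ("nightingale", 2.0, 1.12),
        ],
    )
    def test_printed_relations(self, model, u10, expected):
        assert k600_model(model, u10) == pytest.approx(expected, rel=1e-12)

    def test_unknown_model_lists_valid_ids(self):
        with pytest.raises(KeyError, match="cole_caraco"):
            k600_model("liss_merlivat", 2.0)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            k600_model("cole_caraco", -1.0)


class TestTransferVelocity:
    def test_normalization_at_sc_600(self):
        for u10 in (0.5, 2.0, 8.0):
            assert transfer_velocity(3.3, 600.0, u10) == pytest.approx(3.3)

    def test_smooth_surface_scaling(self):
        got = transfer_velocity(1.44, 654.26, 2.0)
        assert got == pytest.approx(1.44 * (654.26 / 600) ** -0.67, rel=1e-12)
        assert got == pytest.approx(1.359, abs=2e-3)
        assert transfer_velocity(1.44, 635.86, 2.0) == pytest.approx(1.385, abs=2e-3)

    def test_wind_rule_boundary(self):
        assert schmidt_exponent(2.99) == -0.67
        assert schmidt_exponent(3.0) == -0.5
        assert schmidt_exponent(8.0) == -0.5


class TestEquilibriumConcentration:
    def test_zero_mole_fraction(self):
        assert equilibrium_concentration("CO2", 21.0, 0.0) == 0.0

    def test_co2_at_altitude(self):
        p = station_pressure(1884.0)
        c = equilibrium_concentration("CO2", 21.0, 410e-6, p)
        assert c == pytest.approx(12.44, abs=0.01)
        assert 12.0 < c < 13.0  # ~0.038 mol/L/atm x ~328 uatm

    def test_ch4_is_negligible_vs_lake_water(self):
        p = station_pressure(1884.0)
        c = equilibrium_concentration("CH4", 21.0, 1.87e-6, p)
        assert c == pytest.approx(2.26e-3, rel=0.02)
        assert c < 0.01 * 151.0

    def test_station_pressure_sea_level(self):
        assert station_pressure(0.0) == 1.0


class TestEnhancementFactor:
    def test_diffusivity_power_law_at_21c(self):
        ref = 14.6836e-5 * ((273.15 + 21.0) / 217.2056 - 1.0) ** 1.997
        assert co2_diffusivity(21.0) == pytest.approx(ref, rel=1e-12)
        assert co2_diffusivity(21.0) == pytest.approx(1.84e-5, abs=0.01e-5)

    def test_no_enhancement_limit_fast_transfer(self):
        res = enhancement_factor(21.0, 9.5, k_co2_cm_h=1e9)
        assert res.beta == pytest.approx(1.0, abs=1e-6)

    def test_prescribed_rate_constants_hand_case(self):
        # r = 0.3 1/s, tau ~ 1.0006 at pH 9.5: Q and beta both near 6.1
        consts = freshwater_constants(21.0)
        res = enhancement_factor(21.0, 9.5, 1.385, constants=consts, r1=0.3, r2=0.0)
        d = res.diffusivity_cm2_s
        q = math.sqrt(0.3 * res.tau / d) * d / (1.385 / 3600.0)
        assert q == pytest.approx(6.1, abs=0.1)
        assert res.beta == pytest.approx(res.tau / ((res.tau - 1) + math.tanh(q) / q),
                                         rel=1e-12)
        assert res.beta == pytest.approx(6.1, abs=0.15)

    def test_matches_brute_force_formula_on_grid(self):
        # oracle: independent evaluation of the reaction-diffusion expression
        for t in (5.0, 15.0, 25.0, 35.0):
            for ph in (7.0, 8.5, 9.5, 10.5):
                for k in (0.5, 1.44, 5.0, 50.0):
                    res = enhancement_factor(t, ph, k)
                    consts = freshwater_constants(t)
                    a_h = 10.0 ** -ph
                    r = hydration_rate(t) + hydroxylation_rate(t) * consts.Kw / a_h
                    tau = 1 + a_h**2 / (consts.K1 * consts.K2 + consts.K1 * a_h)
                    d = 14.6836e-5 * ((273.15 + t) / 217.2056 - 1) ** 1.997
                    q = math.sqrt(r * tau / d) * d / (k / 3600.0)
                    beta = tau / ((tau - 1) + math.tanh(q) / q)
                    assert res.beta == pytest.approx(beta, rel=1e-12)
                    assert res.beta >= 1.0

    def test_beta_monotone_nonincreasing_in_k(self):
        ks = np.logspace(-1, 4, 40)
        betas = [enhancement_factor(21.0, 9.5, k).beta for k in ks]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(betas, betas[1:]))
        assert betas[-1] == pytest.approx(1.0, abs=1e-3)

    def test_zero_transfer_velocity_rejected(self):
        with pytest.raises(ValueError):
            enhancement_factor(21.0, 9.5, 0.0)


class TestDiffusiveFlux:
    def test_equilibrium_means_zero_flux(self):
        res = diffusive_flux("CO2", 12.4, 12.4, 1.385)
        assert res.flux_mg_c_m2_d == 0.0

    def test_methane_efflux_across_the_model_registry(self):
        # surface CH4 151 umol/L, 21 degC, U10 = 2 m/s, atmospheric CH4
        # 1.87 ppm at 1884 m elevation
        p = station_pressure(1884.0)
        c_eq = equilibrium_concentration("CH4", 21.0, 1.87e-6, p)
        sc = schmidt_number("CH4", 21.0)
        expected = {"crusius_wanninkhof": 591.0, "cole_caraco": 1137.0,
                    "nightingale": 460.0}
        for model, target in expected.items():
            k = transfer_velocity(k600_model(model, 2.0), sc, 2.0)
            res = diffusive_flux("CH4", 151.0, c_eq, k, model=model)
            assert res.flux_mg_c_m2_d == pytest.approx(target, rel=0.01)

    def test_enhancement_restricted_to_co2(self):
        with pytest.raises(ValueError, match="CO2 only"):
            diffusive_flux("CH4", 151.0, 0.0, 1.36, beta=1.5)

    @given(
        dc=st.floats(-500.0, 500.0),
        k=st.floats(0.1, 20.0),
        scale=st.floats(1.1, 4.0),
    )
    def test_flux_linear_in_disequilibrium_and_velocity(self, dc, k, scale):
        base = diffusive_flux("CO2", dc, 0.0, k).flux_mg_c_m2_d
        in_dc = diffusive_flux("CO2", dc * scale, 0.0, k).flux_mg_c_m2_d
        in_k = diffusive_flux("CO2", dc, 0.0, k * scale).flux_mg_c_m2_d
        assert in_dc == pytest.approx(scale * base, rel=1e-9, abs=1e-9)
        assert in_k == pytest.approx(scale * base, rel=1e-9, abs=1e-9)

    def test_flux_ratios_equal_k600_ratios_at_fixed_beta(self):
        table = flux_table({"CH4": 151.0}, elevation_m=1884.0)
        by_model = table.set_index("model")
        r_flux = (by_model.loc["cole_caraco", "flux_mgC_m2_d"]
                  / by_model.loc["crusius_wanninkhof", "flux_mgC_m2_d"])
        r_k600 = (K600_MODELS["cole_caraco"](2.0)
                  / K600_MODELS["crusius_wanninkhof"](2.0))
        assert r_flux == pytest.approx(r_k600, rel=1e-12)
        assert r_flux == pytest.approx(1137.0 / 591.0, rel=1e-3)

    def test_flux_table_enhanced_mode_boosts_co2_only(self):
        plain = flux_table({"CO2": 1.0, "CH4": 151.0}, elevation_m=1884.0)
        enhanced = flux_table(
            {"CO2": 1.0, "CH4": 151.0}, elevation_m=1884.0,
            ph=9.5, enhancement="hoover_berkshire",
        )
        co2_plain = plain[plain.gas == "CO2"].set_index("model")["flux_mgC_m2_d"]
        co2_enh = enhanced[enhanced.gas == "CO2"].set_index("model")["flux_mgC_m2_d"]
        assert (co2_enh < co2_plain).all()  # influx is negative and amplified
        ch4_enh = enhanced[enhanced.gas == "CH4"]["beta"]
        assert (ch4_enh == 1.0).all()


class TestOxygenSaturation:
    def test_freshwater_sea_level_at_21c(self):
        assert oxygen_saturation(21.0) == pytest.approx(8.9, abs=0.1)

    @given(s=st.floats(0.0, 35.0), t=st.floats(0.0, 35.0))
    def test_salting_out_monotonicity(self, s, t):
        assert oxygen_saturation(t, s + 1.0) < oxygen_saturation(t, s)

    def test_pressure_linearity(self):
        full = oxygen_saturation(21.0, 0.0, 1.0)
        half = oxygen_saturation(21.0, 0.0, 0.5)
        assert half == pytest.approx(full / 2, rel=1e-12)
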