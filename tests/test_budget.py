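"""Salinity normalization, anomaly decomposition and the box-model budget."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baycarb.budget import (
    BayGeometry,
    CarbonBudgetModel,
    EndMember,
    box_model_rates,
    correct_for_gas_exchange,
    decompose_ta_dic,
    diel_average,
    normalize_salinity,
    surface_density,
)
from baycarb.synth import BayScenario, generate_bay

GEOM = BayGeometry(
    residence_time_days=71.0, mean_depth_m=18.0,
    reference_salinity=33.02, seawater_density=1021.0,
)


class TestPrimitives:
    def test_normalization_identity_and_hand_value(self):
        assert normalize_salinity(2200.0, 33.02, 33.02) == 2200.0
        assert normalize_salinity(2200.0, 33.52, 33.02) == pytest.approx(
            2200.0 * 33.02 / 33.52
        )

    def test_normalization_round_trip(self):
        n = normalize_salinity(2200.0, 33.52, 33.02)
        assert normalize_salinity(n, 33.02, 33.52) == pytest.approx(2200.0, rel=1e-15)

    def test_normalization_rejects_bad_salinity(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_salinity(2200.0, 0.0, 33.02)

    def test_diel_midpoint(self):
        assert diel_average(2000.0, 2100.0) == 2050.0
        assert diel_average(1987.3, 1987.3) == 1987.3
        with pytest.raises(ValueError, match="both day and night"):
            diel_average(2000.0, float("nan"))

    def test_surface_density_plausible(self):
        rho = surface_density(33.02, 30.0)
        assert 1019 < rho < 1022
        assert surface_density(35, 25) > surface_density(33, 30)


class TestDecomposition:
    def test_zero_anomaly(self):
        d = decompose_ta_dic(2250.0, 1930.0, EndMember(2250.0, 1930.0))
        assert d.dTA == d.dDIC == d.dDIC_calc == d.dDIC_org == 0.0

    def test_pure_calcification_slope_two(self):
        d = decompose_ta_dic(2150.0, 1880.0, EndMember(2250.0, 1930.0))
        assert (d.dTA, d.dDIC) == (-100.0, -50.0)
        assert d.dDIC_calc == -50.0 and d.dDIC_org == 0.0

    def test_bay_anomaly_hand_arithmetic(self):
        """dTA = -175.4, dDIC = -60.9 split into -87.7 calcification and
        +26.8 organic umol kg-1."""
        d = decompose_ta_dic(2250.0 - 175.4, 1930.0 - 60.9, EndMember(2250.0, 1930.0))
        assert d.dDIC_calc == pytest.approx(-87.7)
        assert d.dDIC_org == pytest.approx(26.8)

    @given(dta=st.floats(-300, 100), ddic=st.floats(-200, 200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additivity_exact(self, dta, ddic):
        d = decompose_ta_dic(2250.0 + dta, 1930.0 + ddic, EndMember(2250.0, 1930.0))
        assert d.dDIC_calc + d.dDIC_org == d.dDIC


class TestBoxModel:
    def test_no_anomaly_no_flux(self):
        assert box_model_rates(0.0, 0.0, GEOM) == (0.0, 0.0)

    def test_headline_rates_hand_arithmetic(self):
        """dTA = -175.4, dDIC = -60.9 over tau = 71 d, d = 18 m, rho = 1021
        give net calcification ~22.7 mmol CaCO3 m-2 d-1 and net production
        ~-6.9 mmol C m-2 d-1."""
        gn, pn = box_model_rates(-175.4, -60.9, GEOM)
        assert gn == pytest.approx(87.7 * 1021.0 * 18.0 / 71.0 / 1000.0)
        assert gn == pytest.approx(22.7, abs=0.05)
        assert pn == pytest.approx(-6.9, abs=0.05)

    def test_doubling_residence_time_halves_rates(self):
        slow = BayGeometry(142.0, 18.0, 33.02, seawater_density=1021.0)
        gn1, pn1 = box_model_rates(-175.4, -60.9, GEOM)
        gn2, pn2 = box_model_rates(-175.4, -60.9, slow)
        assert gn2 == pytest.approx(gn1 / 2) and pn2 == pytest.approx(pn1 / 2)

    @given(c=st.floats(-3, 3), dta=st.floats(-200, 50), ddic=st.floats(-150, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c, dta, ddic):
        gn, pn = box_model_rates(dta, ddic, GEOM)
        gnc, pnc = box_model_rates(c * dta, c * ddic, GEOM)
        assert gnc == pytest.approx(c * gn, rel=1e-9, abs=1e-9)
        assert pnc == pytest.approx(c * pn, rel=1e-9, abs=1e-9)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError, match="residence time"):
            BayGeometry(-1.0, 18.0, 33.02)
        with pytest.raises(ValueError, match="depth"):
            BayGeometry(71.0, 0.0, 33.02)


class TestGasCorrection:
    def test_worked_example(self):
        """Efflux of 5.6 shifts Pn from -6.9 to -12.5 mmol C m-2 d-1."""
        assert correct_for_gas_exchange(-6.9, 5.6) == pytest.approx(-12.5)

    def test_degenerate_cases(self):
        assert correct_for_gas_exchange(3.2, 0.0) == 3.2
        assert correct_for_gas_exchange(0.0, 5.6) == -5.6


class TestCarbonBudgetModel:
    def test_noiseless_recovery_machine_precision(self):
        sc = BayScenario(seed=11)
        res = CarbonBudgetModel(generate_bay(sc), sc.geometry).fit()
        assert res.Gn == pytest.approx(sc.true_Gn, abs=1e-9)
        assert res.Pn == pytest.approx(sc.true_Pn, abs=1e-9)

    def test_diel_and_salinity_variation_do_not_bias(self):
        """Antisymmetric diel swings and per-station salinity spread are
        removed exactly by midpointing and normalization."""
        sc = BayScenario(
            diel_amplitude_TA=15.0, diel_amplitude_DIC=20.0,
            salinity_spread=0.3, seed=5,
        )
        res = CarbonBudgetModel(generate_bay(sc), sc.geometry).fit()
        assert res.Gn == pytest.approx(sc.true_Gn, abs=1e-9)
        assert res.Pn == pytest.approx(sc.true_Pn, abs=1e-9)

    def test_station_missing_phase_dropped_and_reported(self):
        sc = BayScenario(seed=2)
        df = generate_bay(sc)
        df = df[~((df.site_id == "N01") & (df.phase == "night"))]
        res = CarbonBudgetModel(df, sc.geometry).fit()
        assert res.bay["dropped_sites"] == ["N01"]
        assert res.bay["n"] == sc.n_interior_sites - 1
        assert res.Gn == pytest.approx(sc.true_Gn, abs=1e-9)

    def test_gas_flux_correction_wired_through(self):
        sc = BayScenario(seed=1)
        res = CarbonBudgetModel(generate_bay(sc), sc.geometry, gas_flux=5.6).fit()
        assert res.result.Pn_corrected == pytest.approx(res.Pn - 5.6)

    def test_pooled_mode_equivalent_for_balanced_table(self):
        """With every site sampled in both phases, pooling all samples and
        midpointing per site give the same group means."""
        sc = BayScenario(diel_amplitude_TA=15.0, seed=4)
        df = generate_bay(sc)
        a = CarbonBudgetModel(df, sc.geometry, pooling="midpoint").fit()
        b = CarbonBudgetModel(df, sc.geometry, pooling="pooled").fit()
        assert a.Gn == pytest.approx(b.Gn, abs=1e-9)
        assert a.Pn == pytest.approx(b.Pn, abs=1e-9)

    def test_validation_errors(self):
        sc = BayScenario(seed=1)
        df = generate_bay(sc)
        with pytest.raises(ValueError, match="missing columns"):
            CarbonBudgetModel(df.drop(columns=["phase"]), sc.geometry)
        bad = df.copy()
        bad.loc[0, "station_role"] = "mystery"
        with pytest.raises(ValueError, match="unknown station roles"):
            CarbonBudgetModel(bad, sc.geometry)

    def test_summary_reports_rates_and_geometry(self):
        sc = BayScenario(seed=1)
        text = CarbonBudgetModel(generate_bay(sc), sc.geometry, gas_flux=5.6).fit().summary()
        assert "tau = 71" in text and "Gn" in text and "Pn_corrected" in text

    def test_noisy_recovery_within_three_se(self):
        """With titrator-grade noise (sigma = 3 umol kg-1) on 74 interior
        samples, the recovered rates fall within 3 SE of truth in >=95% of
        500 replicates."""
        ok_gn = ok_pn = 0
        n_rep = 500
        for rep in range(n_rep):
            sc = BayScenario(noise_sd_TA=3.0, noise_sd_DIC=3.0, seed=1000 + rep)
            res = CarbonBudgetModel(generate_bay(sc), sc.geometry).fit()
            if res.se_Gn > 0 and abs(res.Gn - sc.true_Gn) <= 3 * res.se_Gn:
                ok_gn += 1
            if res.se_Pn > 0 and abs(res.Pn - sc.true_Pn) <= 3 * res.se_Pn:
                ok_pn += 1
        assert ok_gn / n_rep >= 0.95
        assert ok_pn / n_rep >= 0.95
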