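"""Buoyant-weight calcimetry and closed-chamber O2 incubation rates."""

import math

import numpy as np
import pytest

from baycarb.metabolism import (
    IncubationSeries,
    NubbinRecord,
    TransplantExperiment,
    buoyant_to_dry_weight,
    calcification_rate,
    gross_photosynthesis,
    incubation_rate,
    o2_slope,
)
from baycarb.synth import DEFAULT_GROUP_RATES, generate_transplant


def make_series(readings, phase="light", v_chamber=400.0, v_coral=20.0, **kw):
    return IncubationSeries(
        nubbin_id="x", phase=phase, chamber_volume_ml=v_chamber,
        coral_volume_ml=v_coral, readings=tuple(readings), **kw,
    )


class TestBuoyantWeight:
    def test_hand_value(self):
        assert buoyant_to_dry_weight(1.0, 1.023, 2.94) == pytest.approx(
            1.0 / (1.0 - 1.023 / 2.94)
        )
        assert buoyant_to_dry_weight(1.0, 1.023, 2.94) == pytest.approx(1.5337, abs=1e-4)

    def test_vacuum_limit_and_linearity(self):
        assert buoyant_to_dry_weight(1.0, 1e-12, 2.94) == pytest.approx(1.0)
        assert buoyant_to_dry_weight(2.0, 1.023, 2.94) == pytest.approx(
            2 * buoyant_to_dry_weight(1.0, 1.023, 2.94)
        )

    def test_density_ordering_enforced(self):
        with pytest.raises(ValueError, match="skeletal density"):
            buoyant_to_dry_weight(1.0, 2.94, 1.023)


class TestCalcification:
    def rec(self, w0, w1, sa=10.0, days=18.0):
        return NubbinRecord(
            nubbin_id="n1", colony_id="c1", origin_site="M1",
            transplant_site="N5", buoyant_weight_initial=w0,
            buoyant_weight_final=w1, duration_days=days, surface_area=sa,
        )

    def test_no_change_zero_rate(self):
        assert calcification_rate(self.rec(5.0, 5.0)) == 0.0

    def test_hand_value(self):
        """0.180 g dry-mass gain over 18 d on 10 cm2 is 1 mg cm-2 d-1."""
        factor = 1.0 - 1.023 / 2.94
        r = self.rec(5.0, 5.0 + 0.180 * factor)
        assert calcification_rate(r) == pytest.approx(1.0, rel=1e-12)

    def test_halving_area_doubles_rate(self):
        full = calcification_rate(self.rec(5.0, 5.2, sa=10.0))
        half = calcification_rate(self.rec(5.0, 5.2, sa=5.0))
        assert half == pytest.approx(2 * full)

    def test_net_dissolution_is_negative(self):
        assert calcification_rate(self.rec(5.0, 4.9)) < 0

    def test_invalid_record(self):
        with pytest.raises(ValueError, match="surface area"):
            self.rec(5.0, 5.1, sa=0.0)


class TestO2Slope:
    def test_exact_ols_on_collinear_points(self):
        s = make_series([(0, 200.0), (20, 210.0), (40, 220.0)])
        assert o2_slope(s) == pytest.approx(30.0, rel=1e-12)

    def test_blank_drift_fully_attributed(self):
        s = make_series([(0, 200.0), (20, 210.0), (40, 220.0)])
        blank = make_series([(0, 180.0), (20, 190.0), (40, 200.0)],
                            v_coral=0.0, is_blank=True)
        assert o2_slope(s, blank) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        up = make_series([(0, 200.0), (20, 205.0), (40, 214.0)])
        down = make_series([(0, 200.0), (20, 195.0), (40, 186.0)])
        assert o2_slope(down) == pytest.approx(-o2_slope(up) + 2 * 0.0, rel=1e-9)

    def test_endpoint_method_matches_ols_for_linear_data(self):
        s = make_series([(0, 200.0), (20, 210.0), (40, 220.0)])
        assert o2_slope(s, method="endpoint") == pytest.approx(
            o2_slope(s, method="ols"), rel=1e-12
        )

    def test_series_validation(self):
        with pytest.raises(ValueError, match="two O2 readings"):
            make_series([(0, 200.0)])
        with pytest.raises(ValueError, match="strictly increasing"):
            make_series([(0, 200.0), (0, 210.0)])
        with pytest.raises(ValueError, match="share a phase"):
            o2_slope(
                make_series([(0, 200.0), (40, 220.0)], phase="light"),
                make_series([(0, 200.0), (40, 220.0)], phase="dark"),
            )


class TestIncubationRate:
    def test_hand_value(self):
        """30 umol L-1 h-1 in a 400-20 ml chamber over 10 cm2 gives
        1.14 umol O2 cm-2 h-1."""
        assert incubation_rate(30.0, 400.0, 20.0, 10.0) == pytest.approx(1.14)

    def test_zero_slope_and_area_normalization(self):
        assert incubation_rate(0.0, 400.0, 20.0, 10.0) == 0.0
        assert incubation_rate(30.0, 400.0, 20.0, 20.0) == pytest.approx(
            incubation_rate(30.0, 400.0, 20.0, 10.0) / 2
        )

    def test_volume_ordering_enforced(self):
        with pytest.raises(ValueError, match="chamber volume"):
            incubation_rate(30.0, 400.0, 400.0, 10.0)


class TestGrossPhotosynthesis:
    def test_hand_values(self):
        pg, ratio = gross_photosynthesis(1.0, -0.5)
        assert (pg, ratio) == (1.5, 3.0)
        pg, ratio = gross_photosynthesis(0.0, -0.7)
        assert pg == pytest.approx(0.7) and ratio == pytest.approx(1.0)

    def test_pg_at_least_pn_when_r_negative(self):
        for pn, r in [(1.2, -0.3), (0.0, -0.1), (-0.2, -0.4)]:
            pg, _ = gross_photosynthesis(pn, r)
            assert pg >= pn

    def test_zero_respiration_flagged_nan_ratio(self):
        pg, ratio = gross_photosynthesis(1.0, 0.0)
        assert pg == 1.0 and math.isnan(ratio)


class TestTransplantExperiment:
    def test_noiseless_recovery_exact(self):
        """All four generating group rates are recovered exactly from the
        noiseless synthetic tables, and Pg = Pn - R holds per nubbin."""
        nub, inc = generate_transplant(seed=7)
        res = TransplantExperiment(nub, inc).fit()
        df = res.to_frame()
        for (origin, site), true in DEFAULT_GROUP_RATES.items():
            g = df[(df.origin_site == origin) & (df.transplant_site == site)]
            assert np.allclose(g.calcification_mg_cm2_d, true["calcification"],
                               atol=1e-10)
            sub = g.dropna(subset=["pn_umol_cm2_h"])
            assert len(sub) == 9
            assert np.allclose(sub.pn_umol_cm2_h, true["Pn"], atol=1e-10)
            assert np.allclose(sub.r_umol_cm2_h, true["R"], atol=1e-10)
        sub = df.dropna(subset=["pg_umol_cm2_h"])
        assert np.allclose(sub.pg_umol_cm2_h,
                           sub.pn_umol_cm2_h - sub.r_umol_cm2_h, atol=1e-12)

    def test_blank_correction_needed_when_drift_present(self):
        """Skipping the control-chamber correction biases Pn by the drift."""
        nub, inc = generate_transplant(seed=7, blank_drift_umol_l_h=1.5)
        on = TransplantExperiment(nub, inc, blank_correction=True).fit().to_frame()
        off = TransplantExperiment(nub, inc, blank_correction=False).fit().to_frame()
        pn_on = on.dropna(subset=["pn_umol_cm2_h"]).pn_umol_cm2_h
        pn_off = off.dropna(subset=["pn_umol_cm2_h"]).pn_umol_cm2_h
        assert (pn_off > pn_on).all()

    def test_noisy_group_mean_recovery(self):
        """With balance noise (0.1 mg) and O2 sensor noise at n = 12
        colonies, group-mean calcification lies within 3 SE of truth in
        >=95% of replicates."""
        n_rep = 200
        hits = total = 0
        for rep in range(n_rep):
            nub, _ = generate_transplant(
                weight_noise_g=0.0001, o2_noise_umol_l=0.5,
                n_incubated=0, seed=5000 + rep,
            )
            res = TransplantExperiment(nub, None).fit()
            gm = res.group_means()
            for (origin, site), true in DEFAULT_GROUP_RATES.items():
                m = gm.loc[(origin, site), ("calcification_mg_cm2_d", "mean")]
                se = gm.loc[(origin, site), ("calcification_mg_cm2_d", "se")]
                total += 1
                if abs(m - true["calcification"]) <= 3 * se:
                    hits += 1
        assert hits / total >= 0.95

    def test_missing_columns_rejected(self):
        nub, _ = generate_transplant(seed=1)
        with pytest.raises(ValueError, match="missing columns"):
            TransplantExperiment(nub.drop(columns=["surface_area_cm2"]))
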