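import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specyield.water import (
    DailyMet,
    IrrigationPlan,
    KyRecord,
    SoilProfile,
    WaterBalanceInputs,
    deep_percolation,
    ky_pooled,
    ky_single,
    penman_monteith_eto,
    seasonal_et,
    seasonal_etc,
    soil_water_storage,
    volumetric_water_storage,
    wue,
)


def reference_eto(met: DailyMet) -> float:
    """Independent evaluation of the FAO-56 reference form, arranged
    differently from the library path (denominator distributed)."""
    den = met.delta + met.gamma * (1 + 0.34 * met.u2)
    radiation_term = 0.408 * met.delta * (met.rn - met.g) / den
    aero_term = (
        met.gamma * 900.0 * met.u2 * (met.es - met.ea) / ((met.t_mean + 273.0) * den)
    )
    return max(0.0, radiation_term + aero_term)


class TestPenmanMonteith:
    def test_vanishing_forcing_gives_zero(self):
        met = DailyMet(rn=5.0, g=5.0, t_mean=20, t_max=26, t_min=14, u2=2.0, rh=100)
        assert penman_monteith_eto(met) == 0.0

    def test_monotone_in_vapour_deficit(self):
        base = dict(rn=14.0, t_mean=20, t_max=27, t_min=13, u2=2.0)
        dry = DailyMet(rh=30, **base)
        humid = DailyMet(rh=80, **base)
        assert penman_monteith_eto(dry) > penman_monteith_eto(humid)

    def test_monotone_in_net_radiation(self):
        lo = DailyMet(rn=8.0, t_mean=20, t_max=27, t_min=13, u2=2.0, rh=45)
        hi = DailyMet(rn=18.0, t_mean=20, t_max=27, t_min=13, u2=2.0, rh=45)
        assert penman_monteith_eto(hi) > penman_monteith_eto(lo)

    @given(
        rn=st.floats(0.0, 30.0),
        t=st.floats(5.0, 40.0),
        spread=st.floats(1.0, 15.0),
        u2=st.floats(0.1, 8.0),
        rh=st.floats(10.0, 100.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_independent_form(self, rn, t, spread, u2, rh):
        met = DailyMet(
            rn=rn, t_mean=t, t_max=t + spread / 2, t_min=t - spread / 2,
            u2=u2, rh=rh, gamma=0.0643,
        )
        assert penman_monteith_eto(met) == pytest.approx(
            reference_eto(met), abs=1e-10
        )
        assert penman_monteith_eto(met) >= 0

    def test_validation(self):
        with pytest.raises(ValueError):
            DailyMet(rn=10, t_mean=20, t_max=15, t_min=18, u2=2, rh=50)
        with pytest.raises(ValueError):
            DailyMet(rn=10, t_mean=20, t_max=25, t_min=15, u2=2, rh=150)


class TestSeasonalEtc:
    def test_deficit_scaling_is_exact(self):
        rng = np.random.default_rng(4)
        eto = rng.uniform(2, 8, size=140)
        kc = np.interp(np.arange(140), [0, 40, 100, 140], [0.3, 1.15, 1.15, 0.4])
        full = seasonal_etc(IrrigationPlan(eto, kc, deficit_factor=1.0))
        half = seasonal_etc(IrrigationPlan(eto, kc, deficit_factor=0.5))
        three_q = seasonal_etc(IrrigationPlan(eto, kc, deficit_factor=0.75))
        assert half == pytest.approx(0.5 * full, rel=1e-15)
        assert three_q == pytest.approx(0.75 * full, rel=1e-15)

    def test_zero_length_season(self):
        assert seasonal_etc(IrrigationPlan(np.array([]), 1.0)) == 0.0

    def test_calibrated_full_season_scales(self):
        """A season calibrated to 558 mm at full irrigation gives exactly
        418.5 mm at the 0.75 deficit factor."""
        eto = np.full(124, 4.5)
        kc = 558.0 / np.sum(eto)  # constant Kc closing the 558 mm budget
        full = seasonal_etc(IrrigationPlan(eto, kc, 1.0))
        assert full == pytest.approx(558.0)
        assert seasonal_etc(IrrigationPlan(eto, kc, 0.75)) == pytest.approx(418.5)


class TestWaterBalance:
    def test_only_etc(self):
        assert seasonal_et(WaterBalanceInputs(etc=400.0)) == 400.0

    def test_signed_arithmetic(self):
        inputs = WaterBalanceInputs(
            etc=400, precipitation=20, deep_percolation=10, storage_change=-5
        )
        assert seasonal_et(inputs) == pytest.approx(405.0)

    def test_nonpositive_et_rejected(self):
        with pytest.raises(ValueError):
            seasonal_et(WaterBalanceInputs(etc=10, deep_percolation=50))

    @given(
        etc=st.floats(100, 700),
        p=st.floats(0, 100),
        cr=st.floats(0, 50),
        r=st.floats(0, 50),
        d=st.floats(0, 50),
        ds=st.floats(-50, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_affine_sign_structure(self, etc, p, cr, r, d, ds):
        """ET is affine in each component with coefficients +1 +1 +1 -1 -1 +1."""
        base = seasonal_et(
            WaterBalanceInputs(etc, p, cr, r, d, ds)
        )
        assert base == pytest.approx(etc + p + cr - r - d + ds, abs=1e-9)
        bumped = seasonal_et(WaterBalanceInputs(etc, p, cr, r + 1.0, d, ds))
        assert bumped == pytest.approx(base - 1.0, abs=1e-9)


class TestSoilStorage:
    def test_zero_content(self):
        assert soil_water_storage(0.0, SoilProfile()) == 0.0

    def test_site_constants(self):
        # gravimetric 0.10 over 0.9 m of 1.49 g cm-3 soil
        assert soil_water_storage(0.10, SoilProfile()) == pytest.approx(134.1)

    def test_field_capacity_storage(self):
        assert volumetric_water_storage(0.151, 0.9) == pytest.approx(135.9)
        assert SoilProfile().capacity_mm == pytest.approx(135.9)

    def test_deep_percolation_overflow_rule(self):
        soil = SoilProfile()
        assert deep_percolation(100.0, 20.0, soil) == 0.0
        assert deep_percolation(120.0, 40.0, soil) == pytest.approx(24.1)


class TestKy:
    def test_printed_worked_examples(self):
        """Two reference rows: deficit 0.217/decrease 0.145 -> 0.67 and
        deficit 0.437/decrease 0.624 -> 1.43 (2 dp)."""
        rec = ky_single(ETa=1 - 0.217, ETm=1.0, GYa=1 - 0.145, GYm=1.0)
        assert round(rec.ky, 2) == pytest.approx(0.67, abs=0.005)
        rec = ky_single(ETa=1 - 0.437, ETm=1.0, GYa=1 - 0.624, GYm=1.0)
        assert round(rec.ky, 2) == pytest.approx(1.43, abs=0.005)

    def test_no_yield_loss_gives_zero(self):
        assert ky_single(ETa=300, ETm=400, GYa=500, GYm=500).ky == 0.0

    def test_zero_deficit_flagged(self):
        rec = ky_single(ETa=400, ETm=400, GYa=450, GYm=500)
        assert rec.ky is None and not rec.defined

    def test_single_record_pooled_equals_single(self):
        rec = ky_single(ETa=300, ETm=400, GYa=350, GYm=500)
        assert ky_pooled([rec]) == pytest.approx(rec.ky)

    def test_records_on_line(self):
        pts = [(x, 1.3 * x) for x in (0.1, 0.2, 0.3, 0.45)]
        assert ky_pooled(pts, "through_origin") == pytest.approx(1.3)
        assert ky_pooled(pts, "free_intercept") == pytest.approx(1.3)

    def test_pooled_recovery_from_noisy_generator(self, coarse_grid):
        """Pooled ky over 50 seeded synthetic experiments recovers the
        generator's noise-free pooled value within +/-0.1."""
        from specyield.pipeline import _ky_table
        from specyield.synthetic import SyntheticConfig, generate_experiment

        ref_cfg = SyntheticConfig(
            grid=coarse_grid, seed=0, seasons=1, agronomic_cv=0.0,
            spectral_noise_sd=0.0, et_noise_sd_mm=0.0,
        )
        _, agro0, _ = generate_experiment(ref_cfg)
        ref = _ky_table(agro0)
        ref_ky = float(ref.loc[ref.density.isna(), "ky"].iloc[0])
        est = []
        for seed in range(50):
            cfg = SyntheticConfig(grid=coarse_grid, seed=seed, seasons=1)
            _, agro, _ = generate_experiment(cfg)
            kt = _ky_table(agro)
            est.append(float(kt.loc[kt.density.isna(), "ky"].iloc[0]))
        assert np.mean(est) == pytest.approx(ref_ky, abs=0.1)

    def test_all_zero_deficits_rejected(self):
        with pytest.raises(ValueError):
            ky_pooled([(0.0, 0.1), (0.0, 0.2)])


class TestWue:
    def test_examples(self):
        assert wue(0.0, 300.0) == 0.0
        assert wue(600.0, 400.0) == pytest.approx(1.5)
        with pytest.raises(ValueError):
            wue(500.0, 0.0)

    def test_generator_consistency(self, small_experiment):
        """Stored WUE equals GY / ET to machine precision in every record."""
        _, _, agronomy, _ = small_experiment
        np.testing.assert_array_equal(
            agronomy["WUE"].to_numpy(),
            agronomy["GY"].to_numpy() / agronomy["ET"].to_numpy(),
        )
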