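"""Surface concentration, vapour pressures, availability dynamics,
double-exponential fitting and gap-filled cumulation."""

import math

import numpy as np
import pandas as pd
import pytest

from pestivol.micromet import ResistancePair
from pestivol.surface_vapour import (AvailabilityFit, ClausiusClapeyron,
                                     availability_ratio, fit_availability,
                                     gapfill_and_cumulate, modelled_flux,
                                     resistance_flux, saturation_pressure,
                                     surface_concentration, vapour_pressure)


class TestResistanceScheme:
    def test_zero_flux_means_no_gradient(self):
        res = ResistancePair(50.0, 30.0)
        assert surface_concentration(42.0, 0.0, res) == 42.0

    def test_direct_arithmetic(self):
        res = ResistancePair(60.0, 40.0)
        assert surface_concentration(50.0, 10.0, res) == pytest.approx(1050.0)

    def test_mutual_inverse_round_trip(self):
        """Surface concentration and resistance flux are exact algebraic
        inverses at any state."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            res = ResistancePair(*rng.uniform(5, 400, 2))
            c_ref, f = rng.uniform(0, 500), rng.uniform(-50, 50)
            c_z0 = surface_concentration(c_ref, f, res)
            assert resistance_flux(c_z0, c_ref, res) == pytest.approx(
                f, rel=1e-12, abs=1e-12)


class TestVapourPressure:
    def test_zero_concentration_zero_pressure(self):
        assert vapour_pressure(0.0, 25.0) == 0.0

    def test_ideal_gas_hand_value(self):
        # C = M ng/m3 at 25 C: p = 1e-9 * R * 298.15
        expected = 1e-9 * 8.314 * 298.15
        assert vapour_pressure(265.9, 25.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.48e-6, rel=1e-2)

    def test_linear_in_concentration(self):
        assert vapour_pressure(200.0, 10.0) == pytest.approx(
            2.0 * vapour_pressure(100.0, 10.0))


class TestSaturationPressure:
    def test_reference_point(self):
        assert saturation_pressure(25.0) == pytest.approx(7.6e-5, rel=1e-12)

    def test_zero_activation_is_constant(self):
        cc = ClausiusClapeyron(activation=0.0)
        for t in (-10.0, 5.0, 40.0):
            assert saturation_pressure(t, cc) == pytest.approx(7.6e-5)

    def test_hand_value_at_35C(self):
        expected = 7.6e-5 * math.exp(
            95000.0 / 8.3 * (1.0 / 298.15 - 1.0 / 308.15))
        assert saturation_pressure(35.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.6416e-4, rel=1e-3)

    def test_strictly_increasing_and_loglinear_in_inverse_T(self):
        t = np.linspace(-5.0, 40.0, 50)
        p = saturation_pressure(t)
        assert np.all(np.diff(p) > 0)
        inv_tk = 1.0 / (t + 273.15)
        slope, intercept = np.polyfit(inv_tk, np.log(p), 1)
        resid = np.log(p) - (slope * inv_tk + intercept)
        assert np.max(np.abs(resid)) < 1e-10
        assert slope == pytest.approx(-95000.0 / 8.3, rel=1e-9)


class TestAvailabilityRatio:
    def test_saturated_surface(self):
        assert availability_ratio(7.6e-5, 7.6e-5) == 1.0

    def test_clean_surface(self):
        assert availability_ratio(0.0, 7.6e-5) == 0.0

    def test_rejects_nonpositive_saturation(self):
        with pytest.raises(ValueError):
            availability_ratio(1.0, 0.0)


class TestAvailabilityFit:
    COEFFS = (57.0, 0.61, 43.0, 0.012)

    def test_noiseless_recovery_to_four_significant_digits(self):
        a1, k1, a2, k2 = self.COEFFS
        t = np.arange(0.0, 22.0, 1.0)
        y = a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)
        fit = fit_availability(t, y)
        for got, true in zip((fit.a1, fit.k1, fit.a2, fit.k2), self.COEFFS):
            assert got == pytest.approx(true, rel=5e-4)

    def test_single_exponential_nested_case(self):
        t = np.arange(0.0, 15.0, 1.0)
        y = 80.0 * np.exp(-0.4 * t)
        fit = fit_availability(t, y)
        assert fit.k1 == pytest.approx(0.4, rel=1e-3)
        assert fit.a2 * math.exp(-fit.k2 * t[-1]) < 1.0   # vanishing 2nd term

    def test_plateau_variant_fixes_second_rate(self):
        t = np.arange(0.0, 22.0, 1.0)
        y = 22.0 * np.exp(-0.20 * t) + 78.0
        fit = fit_availability(t, y, fix_k2_zero=True)
        assert fit.k2 == 0.0
        assert fit.k1 == pytest.approx(0.20, rel=1e-4)
        assert fit.a2 == pytest.approx(78.0, rel=1e-4)

    def test_noise_bias_on_fast_rate_is_small(self):
        """5% multiplicative noise, 22 daily points, 200 replicates:
        median k1 bias below 10% of k1."""
        rng = np.random.default_rng(12)
        a1, k1, a2, k2 = self.COEFFS
        t = np.arange(0.0, 22.0, 1.0)
        clean = a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)
        k1_hats = []
        for _ in range(200):
            y = clean * (1.0 + rng.normal(0, 0.05, len(t)))
            try:
                k1_hats.append(fit_availability(t, y).k1)
            except RuntimeError:
                continue
        assert len(k1_hats) > 180
        assert abs(np.median(k1_hats) - k1) < 0.1 * k1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_availability(np.arange(5.0), np.ones(5))


class TestModelledFlux:
    def test_zero_availability_and_background_gives_zero(self):
        fit = AvailabilityFit(0.0, 0.5, 0.0, 0.0)
        ts = pd.date_range("2018-04-17", periods=4, freq="30min", tz="UTC")
        out = modelled_flux(fit, ts, np.arange(4) / 48.0, [20.0] * 4,
                            [ResistancePair(50.0, 30.0)] * 4, c_ref=0.0)
        assert np.allclose(out["flux"], 0.0)

    def test_warm_step_emits_more_than_cold_step(self):
        fit = AvailabilityFit(50.0, 0.0, 50.0, 0.0)
        ts = pd.date_range("2018-04-17", periods=2, freq="30min", tz="UTC")
        out = modelled_flux(fit, ts, np.zeros(2), [25.0, 5.0],
                            [ResistancePair(50.0, 30.0)] * 2, c_ref=0.0)
        assert out["flux"].iloc[0] > out["flux"].iloc[1]

    def test_correlates_with_generating_truth(self, clean_campaign):
        from conftest import run_lite_pipeline
        truth = clean_campaign["truth"]
        _, modelled, _ = run_lite_pipeline(clean_campaign)
        post = truth["t_days"].to_numpy() >= 0
        a = truth.loc[post, "flux"].to_numpy()
        b = modelled.loc[post, "flux"].to_numpy()
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        assert r2 > 0.9


class TestGapfillAndCumulate:
    @staticmethod
    def _frame(flux, start="2018-04-17", freq_min=30):
        ts = pd.date_range(start, periods=len(flux), freq=f"{freq_min}min",
                           tz="UTC")
        return pd.DataFrame({"flux": np.asarray(flux, dtype=float),
                             "method": "inversion"}, index=ts)

    def test_constant_flux_day_integrates_to_ten_percent(self):
        """11.574 ng/m2/s over one day on a 100 g/ha dose ~ 10%."""
        n = 49   # spans exactly 24 h on the 30-min grid
        measured = self._frame([11.574] * n)
        modelled = self._frame([11.574] * n)
        out = gapfill_and_cumulate(measured, modelled, dose_g_ha=100.0)
        assert out["cumulative_pct"].iloc[-1] == pytest.approx(10.0, rel=5e-3)

    def test_no_gaps_identical_with_and_without_filling(self):
        rng = np.random.default_rng(3)
        flux = rng.uniform(0, 30, 200)
        measured = self._frame(flux)
        modelled = self._frame(flux * 0.8)
        out = gapfill_and_cumulate(measured, modelled, dose_g_ha=544.0)
        t = (measured.index - measured.index[0]).total_seconds().to_numpy()
        direct = np.trapezoid(flux, t) / (544.0 * 1e5) * 100.0
        assert out["cumulative_pct"].iloc[-1] == pytest.approx(direct, rel=1e-12)
        assert (out["method"] == "inversion").all()

    def test_gaps_filled_with_rescaled_model(self):
        flux = np.full(300, 20.0)
        flux[100:150] = np.nan
        measured = self._frame(flux)
        modelled = self._frame(np.full(300, 10.0))   # model is half as large
        out = gapfill_and_cumulate(measured, modelled, dose_g_ha=544.0)
        filled = out["flux"].to_numpy()[100:150]
        np.testing.assert_allclose(filled, 20.0, rtol=1e-9)
        assert (out["method"].to_numpy()[100:150] == "gapfilled").all()

    def test_cumulative_nondecreasing_for_nonnegative_flux(self, noisy_campaign):
        from conftest import run_lite_pipeline
        measured, modelled, _ = run_lite_pipeline(noisy_campaign)
        measured = measured.copy()
        measured["flux"] = measured["flux"].clip(lower=0.0)
        modelled = modelled.copy()
        modelled["flux"] = modelled["flux"].clip(lower=0.0)
        out = gapfill_and_cumulate(measured, modelled, 544.0)
        assert np.all(np.diff(out["cumulative_pct"].to_numpy()) >= -1e-12)

    def test_rejects_nonpositive_dose(self):
        f = self._frame([1.0] * 10)
        with pytest.raises(ValueError):
            gapfill_and_cumulate(f, f, dose_g_ha=0.0)
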