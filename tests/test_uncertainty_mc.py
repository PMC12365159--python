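"""Monte-Carlo propagation: parameter sampling, per-step flux bands and
cumulative-loss bounds."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import circstd
from shapely.geometry import box

from pestivol.dispersion import SourceMap, SourcePolygon, polygon_dispersion
from pestivol.flux_inference import ConcSeries
from pestivol.micromet import MetRecord
from pestivol.uncertainty_mc import (McParameterSpec, mc_cumulative, mc_flux,
                                     sample_parameters)

NEUTRAL_L = 1e9
RECEPTOR = (410.0, 410.0, 1.9)


def _met(n=1, wd=200.0):
    return [MetRecord(ustar=0.3, L=NEUTRAL_L, wd=wd, sigma_w=0.35,
                      t_air=18.0, z0=0.0035, d=0.33,
                      timestamp=pd.Timestamp("2018-04-18", tz="UTC")
                      + i * pd.Timedelta("30min"))
            for i in range(n)]


def _sources():
    return SourceMap([SourcePolygon("A", box(0, 0, 450, 450), 544.0)])


def _conc(values, c_bgd=5.7):
    ts = pd.DatetimeIndex([pd.Timestamp("2018-04-18", tz="UTC")
                           + i * pd.Timedelta("30min")
                           for i in range(len(values))])
    return ConcSeries(timestamps=ts, conc=np.asarray(values, float),
                      z_ref=1.9, c_bgd=c_bgd)


class TestSampleParameters:
    def test_zero_variance_draws_equal_means(self):
        spec = McParameterSpec(seed=1).zero_variance()
        rng = np.random.default_rng(0)
        met = _met()[0]
        met_p, rec_p, cf, cb = sample_parameters(spec, met, RECEPTOR, rng)
        assert met_p.z0 == pytest.approx(met.z0 if False else spec.z0_mean)
        assert met_p.ustar == met.ustar
        assert met_p.wd == met.wd
        assert rec_p == RECEPTOR
        assert cf == 1.0
        assert cb == spec.c_bgd_mean

    def test_lognormal_roughness_mean_recovered(self):
        """1e5 draws of z0: sample mean within 1% of 0.0035 m (the
        log-normal is parameterised by its arithmetic moments)."""
        spec = McParameterSpec(seed=1)
        rng = np.random.default_rng(42)
        met = _met()[0]
        z0s = np.array([sample_parameters(spec, met, RECEPTOR, rng)[0].z0
                        for _ in range(100_000)])
        assert z0s.mean() == pytest.approx(0.0035, rel=0.01)
        assert z0s.std(ddof=1) == pytest.approx(0.0004, rel=0.05)
        assert np.all(z0s > 0)

    def test_wind_direction_circular_spread(self):
        spec = McParameterSpec(seed=1)
        rng = np.random.default_rng(7)
        met = _met(wd=350.0)[0]   # near the 0/360 wrap
        wds = np.array([sample_parameters(spec, met, RECEPTOR, rng)[0].wd
                        for _ in range(20_000)])
        sd = np.degrees(circstd(np.radians(wds)))
        assert sd == pytest.approx(12.5, rel=0.05)

    def test_obukhov_perturbation_preserves_sign(self):
        spec = McParameterSpec(seed=1)
        rng = np.random.default_rng(9)
        for L in (-30.0, 50.0):
            met = MetRecord(ustar=0.3, L=L, z0=0.0035, d=0.33)
            Ls = [sample_parameters(spec, met, RECEPTOR, rng)[0].L
                  for _ in range(500)]
            assert all(np.sign(l) == np.sign(L) for l in Ls)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            McParameterSpec(n_draws=1)
        with pytest.raises(ValueError):
            McParameterSpec(ustar_rel_sd=-0.1)


class TestMcFlux:
    def test_zero_variance_bands_collapse_on_deterministic_flux(self):
        met = _met(4)
        conc = _conc([50.0, 60.0, 55.0, 45.0])
        spec = McParameterSpec(n_draws=20, seed=3,
                               c_bgd_mean=5.7).zero_variance()
        bands = mc_flux(conc, _sources(), met, spec, receptor=RECEPTOR)
        d0 = polygon_dispersion(RECEPTOR, _sources(), met[0]).d_total
        expected = (conc.conc - 5.7) / np.array(
            [polygon_dispersion(RECEPTOR, _sources(), m).d_total for m in met])
        np.testing.assert_allclose(bands["p05"], expected, rtol=1e-9)
        np.testing.assert_allclose(bands["p95"], expected, rtol=1e-9)
        assert d0 > 0

    def test_percentiles_ordered(self):
        met = _met(6)
        conc = _conc([50.0] * 6)
        spec = McParameterSpec(n_draws=60, seed=5, c_bgd_mean=5.7)
        bands = mc_flux(conc, _sources(), met, spec, receptor=RECEPTOR)
        ok = bands["method"] == "inversion"
        assert (bands.loc[ok, "p05"] <= bands.loc[ok, "p50"]).all()
        assert (bands.loc[ok, "p50"] <= bands.loc[ok, "p95"]).all()

    def test_seeded_runs_bit_reproducible(self):
        met = _met(3)
        conc = _conc([50.0, 60.0, 55.0])
        spec = McParameterSpec(n_draws=25, seed=11, c_bgd_mean=5.7)
        b1 = mc_flux(conc, _sources(), met, spec, receptor=RECEPTOR)
        b2 = mc_flux(conc, _sources(), met, spec, receptor=RECEPTOR)
        pd.testing.assert_frame_equal(b1, b2)

    def test_concentration_only_uncertainty_matches_delta_method(self):
        """With only the +/-14% concentration error active, the flux
        spread on one step matches the closed-form linear propagation
        sd(F) = 0.14 C / D."""
        met = _met(1)
        conc = _conc([80.0], c_bgd=5.7)
        spec = McParameterSpec(n_draws=4000, seed=21,
                               c_bgd_mean=5.7).zero_variance()
        spec = McParameterSpec(**{**spec.__dict__, "conc_rel_sd": 0.14,
                                  "n_draws": 4000, "seed": 21})
        d0 = polygon_dispersion(RECEPTOR, _sources(), met[0]).d_total
        bands = mc_flux(conc, _sources(), met, spec, receptor=RECEPTOR)
        half_width = (bands["p95"].iloc[0] - bands["p05"].iloc[0]) / 2.0
        sd_expected = 0.14 * 80.0 / d0
        assert half_width == pytest.approx(1.645 * sd_expected, rel=0.10)

    def test_doubling_spreads_widens_bands(self):
        met = _met(4)
        conc = _conc([60.0] * 4)
        base = McParameterSpec(n_draws=150, seed=13, c_bgd_mean=5.7)
        wide = McParameterSpec(
            n_draws=150, seed=13, c_bgd_mean=5.7,
            z0_sd=2 * base.z0_sd, d_sd=2 * base.d_sd,
            sensor_sd=tuple(2 * s for s in base.sensor_sd),
            ustar_rel_sd=2 * base.ustar_rel_sd, wd_sd_deg=2 * base.wd_sd_deg,
            L_rel_sd=2 * base.L_rel_sd, sigma_w_rel_sd=2 * base.sigma_w_rel_sd,
            conc_rel_sd=2 * base.conc_rel_sd, c_bgd_sd=2 * base.c_bgd_sd)
        b1 = mc_flux(conc, _sources(), met, base, receptor=RECEPTOR)
        b2 = mc_flux(conc, _sources(), met, wide, receptor=RECEPTOR)
        w1 = (b1["p95"] - b1["p05"]).to_numpy()
        w2 = (b2["p95"] - b2["p05"]).to_numpy()
        assert np.all(w2 > w1)


class TestMcCumulative:
    def _modelled(self, n):
        ts = pd.DatetimeIndex([pd.Timestamp("2018-04-18", tz="UTC")
                               + i * pd.Timedelta("30min") for i in range(n)])
        return pd.DataFrame({"flux": np.full(n, 10.0)}, index=ts)

    def test_deterministic_flux_has_degenerate_bounds(self):
        n = 8
        met = _met(n)
        conc = _conc([60.0] * n)
        spec = McParameterSpec(n_draws=15, seed=2,
                               c_bgd_mean=5.7).zero_variance()
        cum = mc_cumulative(conc, _sources(), met, spec, self._modelled(n),
                            dose_g_ha=544.0, receptor=RECEPTOR)
        assert cum["p05"] == pytest.approx(cum["mean"], rel=1e-9)
        assert cum["p95"] == pytest.approx(cum["mean"], rel=1e-9)

    def test_doubling_dose_halves_percentages(self):
        n = 8
        met = _met(n)
        conc = _conc([60.0] * n)
        spec = McParameterSpec(n_draws=15, seed=2, c_bgd_mean=5.7)
        c1 = mc_cumulative(conc, _sources(), met, spec, self._modelled(n),
                           dose_g_ha=544.0, receptor=RECEPTOR)
        c2 = mc_cumulative(conc, _sources(), met, spec, self._modelled(n),
                           dose_g_ha=1088.0, receptor=RECEPTOR)
        assert c2["mean"] == pytest.approx(c1["mean"] / 2.0, rel=1e-9)
        assert c2["p95"] == pytest.approx(c1["p95"] / 2.0, rel=1e-9)

    def test_truth_covered_by_bounds_across_seeds(self, cumulative_coverage):
        """Over 20 seeded synthetic campaigns the generating cumulative
        loss falls inside the Monte-Carlo 5-95% band at least 90% of the
        time."""
        hits, details = cumulative_coverage
        assert sum(hits) >= 0.9 * len(hits), details
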