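"""Shared fixtures: canonical met states, a small synthetic campaign, and
the two expensive oracles (numerical advection-diffusion solution and the
Monte-Carlo cumulative-coverage simulation), computed once per session."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pestivol.micromet import MetRecord, resistances
from pestivol.dispersion import powerlaw_profile_params, _strip_D
from pestivol.flux_inference import invert_flux
from pestivol.surface_vapour import (daily_availability, fit_availability,
                                     gapfill_and_cumulate, modelled_flux)
from pestivol.synthetic_data import CampaignConfig, generate_campaign
from pestivol.uncertainty_mc import McParameterSpec, mc_cumulative


NEUTRAL_L = 1e9


@pytest.fixture
def neutral_met():
    """Wheat-field neutral state: u*=0.3, z0=3.5 mm, d=0.33 m."""
    return MetRecord(ustar=0.3, L=NEUTRAL_L, wd=270.0, sigma_w=0.3,
                     t_air=15.0, z0=0.0035, d=0.33, h_c=0.5)


@pytest.fixture
def stable_met():
    return MetRecord(ustar=0.15, L=50.0, wd=270.0, sigma_w=0.15,
                     t_air=8.0, z0=0.0035, d=0.33, h_c=0.5)


@pytest.fixture
def unstable_met():
    return MetRecord(ustar=0.4, L=-30.0, wd=270.0, sigma_w=0.5,
                     t_air=24.0, z0=0.0035, d=0.33, h_c=0.5)


@pytest.fixture(scope="session")
def clean_campaign():
    """Noise-free, outage-free 12-day campaign (exact round trips)."""
    cfg = CampaignConfig(n_days=12, conc_rel_noise=0.0,
                         gradient_rel_noise=0.0, outages_days=(), seed=7)
    return generate_campaign(cfg)


@pytest.fixture(scope="session")
def noisy_campaign():
    """Default-noise 12-day campaign with a half-day outage."""
    cfg = CampaignConfig(n_days=12, outages_days=((3.0, 3.5),), seed=11)
    return generate_campaign(cfg)


def solve_advection_diffusion(prof, fetch, z_receptor, nz=350, nx=900,
                              z_max=150.0, z_min=1e-3):
    """Numerical oracle: implicit finite-volume march of
    d(u c)/dx = d/dz (K dc/dz) with unit ground flux over 0 < x < fetch.

    Independent of the analytical route: same power-law u, K, but a
    direct tridiagonal discretisation.  Returns c(fetch, z_receptor).
    """
    from scipy.linalg import solve_banded

    z_f = np.geomspace(z_min, z_max, nz + 1)          # faces
    z_c = np.sqrt(z_f[:-1] * z_f[1:])                 # cell centres
    dz = np.diff(z_f)
    u = prof.u(z_c)
    K_f = prof.K(z_f)

    x_f = np.geomspace(fetch * 1e-4, fetch, nx)
    dx = np.diff(np.concatenate(([0.0], x_f)))

    c = np.zeros(nz)
    # interior face conductances K/dz between adjacent centres
    g = K_f[1:-1] / np.diff(z_c)
    for step in range(nx):
        r = u * dz / dx[step]
        lower = np.zeros(nz)
        diag = r.copy()
        upper = np.zeros(nz)
        rhs = r * c
        # diffusive coupling
        diag[:-1] += g
        upper[1:] -= g
        diag[1:] += g
        lower[:-1] -= g
        # bottom face: prescribed unit surface flux entering the domain
        rhs[0] += 1.0
        # top face: c = 0 beyond the domain (Dirichlet via conductance)
        diag[-1] += K_f[-1] / (z_f[-1] - z_c[-1])
        ab = np.zeros((3, nz))
        ab[0, 1:] = upper[1:]
        ab[1] = diag
        ab[2, :-1] = lower[:-1]
        c = solve_banded((1, 1), ab, rhs)
    return float(np.interp(z_receptor, z_c, c))


@pytest.fixture(scope="session")
def pde_oracle_case():
    """Neutral strip case (u*=0.3, z0=3.5 mm, d=0.33 m, z=1.9 m, 200 m
    fetch): analytical D vs the numerical solution."""
    met = MetRecord(ustar=0.3, L=NEUTRAL_L, z0=0.0035, d=0.33)
    z, fetch = 1.9, 200.0
    prof = powerlaw_profile_params(met, z)
    d_analytic = float(_strip_D(fetch, z - met.d, prof))
    d_numeric = solve_advection_diffusion(prof, fetch, z - met.d)
    return d_analytic, d_numeric


def run_lite_pipeline(camp):
    """Inversion -> surface state -> availability fit -> modelled flux,
    without Monte Carlo (shared by the coverage experiments)."""
    from pestivol.surface_vapour import (availability_ratio,
                                         saturation_pressure,
                                         surface_concentration,
                                         vapour_pressure)

    cfg, met, conc = camp["config"], camp["met"], camp["conc"]
    truth = camp["truth"]
    d_coeff = truth["d_coeff"].to_numpy()
    measured = invert_flux(conc, d_coeff)
    res = [resistances(cfg.z_ref, m) for m in met]
    t_air = np.array([m.t_air for m in met])
    flux = measured["flux"].to_numpy()
    c_z0 = np.array([surface_concentration(c, f, r) if np.isfinite(f) else np.nan
                     for c, f, r in zip(conc.conc, flux, res)])
    r_series = availability_ratio(vapour_pressure(c_z0, t_air),
                                  saturation_pressure(t_air))
    t_days = truth["t_days"].to_numpy()
    post = t_days >= 0
    ts = conc.timestamps
    daily = daily_availability(ts[post], r_series[post])
    day_t = (daily.index - ts[post][0]).total_seconds() / 86400.0
    fit = fit_availability(day_t, daily.to_numpy() * 100.0 / daily.iloc[0])
    modelled = modelled_flux(fit, ts, np.maximum(t_days, 0.0), t_air, res,
                             c_ref=conc.c_bgd, r_scale=daily.iloc[0] / 100.0)
    modelled.loc[t_days < 0, "flux"] = 0.0
    return measured, modelled, fit


@pytest.fixture(scope="session")
def cumulative_coverage():
    """20 seeded noisy campaigns with a 3-day outage: is the true
    cumulative loss inside the Monte-Carlo 5-95% band?  Returns the list
    of per-seed hits plus (truth, band) pairs."""
    hits, details = [], []
    for seed in range(20):
        cfg = CampaignConfig(n_days=12, outages_days=((4.0, 7.0),),
                             seed=100 + seed)
        camp = generate_campaign(cfg)
        truth = camp["truth"]
        _, modelled, _ = run_lite_pipeline(camp)
        spec = McParameterSpec(n_draws=40, seed=200 + seed,
                               c_bgd_mean=camp["conc"].c_bgd,
                               c_bgd_sd=max(camp["conc"].c_bgd_sd, 0.5))
        cum = mc_cumulative(camp["conc"], camp["sources"], camp["met"], spec,
                            modelled, cfg.dose_g_ha, receptor=cfg.receptor)
        t_sec = (truth.index - truth.index[0]).total_seconds().to_numpy()
        true_cum = float(np.trapezoid(truth["flux"].to_numpy(), t_sec)
                         / (cfg.dose_g_ha * 1e5) * 100.0)
        hits.append(cum["p05"] <= true_cum <= cum["p95"])
        details.append((true_cum, cum["p05"], cum["p95"]))
    return hits, details
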