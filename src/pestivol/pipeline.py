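"""End-to-end campaign pipeline.

Orchestrates simulate (or load) -> dispersion -> inversion ->
surface/availability fit -> Monte Carlo -> gap-fill + cumulate, writing
reproducible artefacts (flux CSV, surface-state CSV, fit JSON,
cumulative summary JSON) carrying a provenance block (seed, package
version, config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .dispersion import polygon_dispersion
from .flux_inference import ConcSeries, D_FLOOR, invert_flux
from .micromet import resistances
from .surface_vapour import (availability_ratio, daily_availability,
                             fit_availability, gapfill_and_cumulate,
                             modelled_flux, surface_concentration,
                             vapour_pressure, saturation_pressure)
from .synthetic_data import CampaignConfig, generate_campaign
from .uncertainty_mc import McParameterSpec, mc_cumulative, mc_flux

log = logging.getLogger("pestivol")

__all__ = ["RunConfig", "ConfigError", "InputError", "run_pipeline"]


class ConfigError(ValueError):
    """The run configuration is inconsistent or incomplete."""


class InputError(ValueError):
    """Input files are missing columns or time grids do not match."""


class EmptyCampaignError(RuntimeError):
    """No usable (unmasked) steps remain in the campaign."""


@dataclasses.dataclass
class RunConfig:
    """Flat run configuration.

    Exactly one of ``simulate`` (a CampaignConfig block) or the observed
    input paths (``met_csv`` + ``conc_csv`` + ``sources_geojson``) must
    be present.
    """

    out_dir: str = "run_out"
    seed: int = 0
    simulate: dict | None = None
    met_csv: str | None = None
    conc_csv: str | None = None
    sources_geojson: str | None = None
    z_ref: float = 1.9
    dose_g_ha: float = 544.0
    mc: dict = dataclasses.field(default_factory=dict)
    fit_daytime_hours: tuple = (9, 17)
    fit_fix_k2_zero: bool = False
    window_days: float = 7.0
    run_mc: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        observed = all(x is not None for x in
                       (self.met_csv, self.conc_csv, self.sources_geojson))
        if bool(self.simulate is not None) == observed:
            raise ConfigError(
                "exactly one of a 'simulate' block or observed inputs "
                "(met_csv + conc_csv + sources_geojson) must be given")
        if self.mc.get("n_draws", 100) < 2:
            raise ConfigError("mc.n_draws must be >= 2")
        if self.dose_g_ha <= 0:
            raise ConfigError("dose_g_ha must be > 0")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {"package": "pestivol", "version": __version__,
            "seed": cfg.seed, "config_hash": cfg.config_hash()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full chain and write artefacts under ``cfg.out_dir``.

    Returns a summary dict with the fit, the cumulative loss (mean,
    p05, p95 in % of dose) and the paths of the written files.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    header = "\n".join(f"{k}: {v}" for k, v in prov.items())

    # --- inputs -----------------------------------------------------------
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        camp_cfg = CampaignConfig(**sim_kwargs)
        camp = generate_campaign(camp_cfg)
        met, sources, conc = camp["met"], camp["sources"], camp["conc"]
        receptor = camp_cfg.receptor
        dose = camp_cfg.dose_g_ha
        t_days = camp["truth"]["t_days"].to_numpy()
        pio.write_met_csv(out / "met.csv", met, header)
        pio.write_conc_csv(out / "conc.csv", conc, header)
        pio.write_sources_geojson(out / "fields.geojson", sources)
        camp["truth"].to_csv(out / "truth.csv")
        if len(camp["gradient"]):
            camp["gradient"].to_csv(out / "gradient.csv")
    else:
        met = pio.read_met_csv(cfg.met_csv)
        conc = pio.read_conc_csv(cfg.conc_csv, z_ref=cfg.z_ref)
        sources = pio.read_sources_geojson(cfg.sources_geojson)
        receptor = (0.0, 0.0, cfg.z_ref)
        dose = cfg.dose_g_ha
        ts = pd.DatetimeIndex([m.timestamp for m in met])
        if not ts.equals(conc.timestamps):
            raise InputError("met and concentration time grids do not match")
        t_days = (conc.timestamps - conc.timestamps[0]
                  ).total_seconds().to_numpy() / 86400.0

    ts = conc.timestamps
    if len(met) != len(conc.conc):
        raise InputError("met and concentration series length mismatch")

    # --- dispersion + inversion ------------------------------------------
    d_coeff = np.array([polygon_dispersion(receptor, sources, m).d_total
                        for m in met])
    measured = invert_flux(conc, d_coeff)
    if not np.isfinite(measured["flux"]).any():
        raise EmptyCampaignError("every step is masked (calm or wrong sector)")

    # --- surface state and availability fit -------------------------------
    res = [resistances(conc.z_ref, m) for m in met]
    t_air = np.array([m.t_air for m in met])
    c_z0 = np.array([surface_concentration(c, f, r) if np.isfinite(f) else np.nan
                     for c, f, r in zip(conc.conc, measured["flux"], res)])
    p_vap_z0 = vapour_pressure(np.nan_to_num(c_z0, nan=np.nan), t_air)
    p_sat = saturation_pressure(t_air)
    r_series = availability_ratio(p_vap_z0, p_sat)
    surface = pd.DataFrame(
        {"c_z0": c_z0, "p_vap_z0": p_vap_z0, "p_sat": p_sat, "r": r_series,
         "r_a": [x.r_a for x in res], "r_b": [x.r_b for x in res]}, index=ts)
    pio.write_surface_csv(out / "surface.csv", surface, header)

    post = t_days >= 0
    daily = daily_availability(ts[post], r_series[post],
                               day_hours=cfg.fit_daytime_hours)
    day_t = (daily.index - ts[post][0]).total_seconds() / 86400.0
    norm = 100.0 / daily.iloc[0]
    fit = fit_availability(day_t, daily.to_numpy() * norm,
                           fix_k2_zero=cfg.fit_fix_k2_zero)
    r_scale = daily.iloc[0] / 100.0
    with open(out / "fit.json", "w") as fh:
        json.dump({**prov, "fit": fit.to_dict(),
                   "r_scale": float(r_scale)}, fh, indent=1)

    modelled = modelled_flux(fit, ts, np.maximum(t_days, 0.0), t_air, res,
                             c_ref=conc.c_bgd, r_scale=r_scale)
    modelled.loc[t_days < 0, "flux"] = 0.0

    filled = gapfill_and_cumulate(measured, modelled, dose,
                                  window_days=cfg.window_days)

    # --- Monte Carlo ------------------------------------------------------
    summary = {**prov, "cumulative_pct": {
        "mean": float(filled["cumulative_pct"].iloc[-1])}}
    mc_kwargs = dict(cfg.mc)
    mc_kwargs.setdefault("seed", cfg.seed)
    mc_kwargs.setdefault("c_bgd_mean", conc.c_bgd)
    mc_kwargs.setdefault("c_bgd_sd", conc.c_bgd_sd)
    spec = McParameterSpec(**mc_kwargs)
    if cfg.run_mc:
        bands = mc_flux(conc, sources, met, spec, receptor=receptor)
        flux_out = measured.join(bands[["p05", "p95", "n_mc"]])
        cum = mc_cumulative(conc, sources, met, spec, modelled, dose,
                            receptor=receptor, window_days=cfg.window_days)
        summary["cumulative_pct"].update(
            {k: cum[k] for k in ("mean", "p05", "p50", "p95")})
        summary["n_draws"] = cum["n_draws"]
    else:
        flux_out = measured.assign(p05=np.nan, p95=np.nan, n_mc=0)

    pio.write_flux_csv(out / "flux.csv", flux_out, header)
    filled.assign(timestamp=ts).to_csv(out / "flux_gapfilled.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    log.info("cumulative volatilisation: %.1f%% of dose",
             summary["cumulative_pct"]["mean"])
    return {"summary": summary, "fit": fit, "measured": measured,
            "filled": filled, "surface": surface, "out_dir": str(out)}
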