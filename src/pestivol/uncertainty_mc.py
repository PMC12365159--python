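"""Monte-Carlo propagation of input and parameter uncertainty through the
dispersion + inversion chain.

Every input of the inversion (roughness length, displacement height,
sensor position, friction velocity, wind direction, Obukhov length,
lateral wind spread, measured and background concentration) carries an
independent distribution.  Per-step flux bands redraw the joint
parameter set at every 30-min step ("the model is re-run n times at each
time step"); cumulative-loss bounds instead draw one joint parameter set
per Monte-Carlo replicate and hold it over the whole campaign
(trajectory mode), so that systematic parameter errors do not average
out over the time integral, and the percentiles are taken over the
per-replicate cumulative trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from .dispersion import SourceMap, polygon_dispersion
from .flux_inference import ConcSeries, D_FLOOR
from .micromet import MetRecord
from .surface_vapour import gapfill_and_cumulate

__all__ = ["McParameterSpec", "McFactors", "sample_factors",
           "sample_parameters", "mc_flux", "mc_cumulative"]


@dataclass
class McParameterSpec:
    """Per-parameter uncertainty (means come from the data; sds below).

    Percentages are relative sds applied multiplicatively; absolute sds
    are in the parameter's own units.  z0 is log-normal (its arithmetic
    mean and sd are converted to log-space parameters internally); all
    other parameters are normal.  Multiplicative factors are truncated
    to be positive, which preserves the sign (stability regime) of the
    Obukhov length and the positivity of u* and sigma_w.
    """

    z0_mean: float = 0.0035
    z0_sd: float = 0.0004
    d_sd: float = 0.03
    sensor_sd: tuple[float, float, float] = (1.0, 1.0, 0.1)
    ustar_rel_sd: float = 0.14
    wd_sd_deg: float = 12.5
    L_rel_sd: float = 0.40
    sigma_w_rel_sd: float = 0.14
    conc_rel_sd: float = 0.14
    c_bgd_mean: float = 5.7
    c_bgd_sd: float = 2.2
    n_draws: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        sds = (self.z0_sd, self.d_sd, *self.sensor_sd, self.ustar_rel_sd,
               self.wd_sd_deg, self.L_rel_sd, self.sigma_w_rel_sd,
               self.conc_rel_sd, self.c_bgd_sd)
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be >= 0")

    def zero_variance(self) -> "McParameterSpec":
        """Degenerate copy with every sd set to 0 (bands collapse)."""
        return _dc_replace(self, z0_sd=0.0, d_sd=0.0, sensor_sd=(0.0,) * 3,
                           ustar_rel_sd=0.0, wd_sd_deg=0.0, L_rel_sd=0.0,
                           sigma_w_rel_sd=0.0, conc_rel_sd=0.0, c_bgd_sd=0.0)


@dataclass
class McFactors:
    """One joint draw of the perturbations, separated from the means so a
    single draw can be held over a whole campaign (trajectory mode)."""

    z0: float
    d_offset: float
    sensor_offset: tuple[float, float, float]
    ustar_factor: float
    wd_offset: float
    L_factor: float
    sigma_w_factor: float
    conc_factor: float
    c_bgd: float


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """log-space (mu, sigma) of a log-normal with given arithmetic mean/sd."""
    if sd == 0.0:
        return math.log(mean), 0.0
    var = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - var / 2.0, math.sqrt(var)


def _positive_factor(rng, rel_sd: float, max_redraws: int = 50) -> float:
    """Multiplicative 1 + N(0, rel_sd) truncated to > 0 by redrawing."""
    if rel_sd == 0.0:
        return 1.0
    for _ in range(max_redraws):
        f = 1.0 + float(rng.normal(0.0, rel_sd))
        if f > 0.0:
            return f
    return 1.0


def sample_factors(spec: McParameterSpec, rng) -> McFactors:
    """Draw one joint set of perturbation factors/offsets."""
    mu, sig = _lognormal_params(spec.z0_mean, spec.z0_sd)
    return McFactors(
        z0=float(rng.lognormal(mu, sig)),
        d_offset=float(rng.normal(0.0, spec.d_sd)),
        sensor_offset=tuple(float(rng.normal(0.0, s)) for s in spec.sensor_sd),
        ustar_factor=_positive_factor(rng, spec.ustar_rel_sd),
        wd_offset=float(rng.normal(0.0, spec.wd_sd_deg)),
        L_factor=_positive_factor(rng, spec.L_rel_sd),
        sigma_w_factor=_positive_factor(rng, spec.sigma_w_rel_sd),
        conc_factor=_positive_factor(rng, spec.conc_rel_sd),
        c_bgd=float(rng.normal(spec.c_bgd_mean, spec.c_bgd_sd)),
    )


def _apply_factors(fac: McFactors, met: MetRecord, receptor):
    """Perturbed met state and receptor position from one factor draw."""
    z0 = fac.z0
    d = min(max(met.d + fac.d_offset, 0.0), receptor[2] - 2 * z0)
    met_p = MetRecord(ustar=met.ustar * fac.ustar_factor,
                      L=met.L * fac.L_factor,
                      wd=(met.wd + fac.wd_offset) % 360.0,
                      sigma_w=met.sigma_w * fac.sigma_w_factor,
                      t_air=met.t_air, z0=z0, d=d, h_c=met.h_c,
                      timestamp=met.timestamp)
    receptor_p = (receptor[0] + fac.sensor_offset[0],
                  receptor[1] + fac.sensor_offset[1],
                  max(receptor[2] + fac.sensor_offset[2], d + 2 * z0))
    return met_p, receptor_p


def sample_parameters(spec: McParameterSpec, met: MetRecord,
                      receptor: tuple[float, float, float], rng):
    """One joint draw of the perturbed inversion inputs.

    Returns (met', receptor', conc_factor, c_bgd').
    """
    fac = sample_factors(spec, rng)
    met_p, rec_p = _apply_factors(fac, met, receptor)
    return met_p, rec_p, fac.conc_factor, fac.c_bgd


def _factor_flux(conc_val: float, fac: McFactors, met: MetRecord,
                 receptor, sources: SourceMap,
                 d_floor: float = D_FLOOR) -> float:
    met_p, rec_p = _apply_factors(fac, met, receptor)
    disp = polygon_dispersion(rec_p, sources, met_p)
    if disp.d_total < d_floor:
        return np.nan
    return (conc_val * fac.conc_factor - fac.c_bgd) / disp.d_total


def mc_flux(conc: ConcSeries, sources: SourceMap, met_series: list[MetRecord],
            spec: McParameterSpec, receptor=None,
            d_floor: float = D_FLOOR) -> pd.DataFrame:
    """Per-step Monte-Carlo flux percentiles.

    At each step ``spec.n_draws`` joint parameter draws re-run the
    dispersion model and the inversion; the returned frame holds the
    empirical 5th/50th/95th percentiles, the valid-draw count ``n_mc``
    and a method tag.  A step fails (all-NaN) when more than half of its
    draws are masked by the D floor.
    """
    rng = np.random.default_rng(spec.seed)
    receptor = receptor or (0.0, 0.0, conc.z_ref)
    rows = []
    for met, c in zip(met_series, conc.conc):
        if not np.isfinite(c):
            rows.append((np.nan, np.nan, np.nan, 0, "gap"))
            continue
        draws = np.array([
            _factor_flux(c, sample_factors(spec, rng), met, receptor,
                         sources, d_floor) for _ in range(spec.n_draws)])
        ok = np.isfinite(draws)
        if ok.sum() <= spec.n_draws / 2:
            rows.append((np.nan, np.nan, np.nan, int(ok.sum()), "masked"))
            continue
        p05, p50, p95 = np.percentile(draws[ok], [5, 50, 95])
        rows.append((p05, p50, p95, int(ok.sum()), "inversion"))
    return pd.DataFrame(rows, columns=["p05", "p50", "p95", "n_mc", "method"],
                        index=conc.timestamps)


def mc_cumulative(conc: ConcSeries, sources: SourceMap,
                  met_series: list[MetRecord], spec: McParameterSpec,
                  modelled: pd.DataFrame, dose_g_ha: float,
                  receptor=None, d_floor: float = D_FLOOR,
                  window_days: float = 7.0) -> dict:
    """Cumulative volatilised fraction with Monte-Carlo bounds.

    Trajectory mode: each replicate holds one joint parameter draw over
    the whole campaign, re-inverts every step, is gap-filled against the
    modelled flux and integrated; percentiles are then taken over the
    per-replicate cumulative trajectories.

    Returns a dict with final-value ``mean``/``p05``/``p50``/``p95``
    (% of dose) and the percentile trajectories in ``trajectories``.
    """
    rng = np.random.default_rng(spec.seed)
    receptor = receptor or (0.0, 0.0, conc.z_ref)
    ts = conc.timestamps
    finals = np.empty(spec.n_draws)
    cums = np.empty((spec.n_draws, len(ts)))
    for j in range(spec.n_draws):
        fac = sample_factors(spec, rng)
        flux = np.full(len(ts), np.nan)
        for i, (met, c) in enumerate(zip(met_series, conc.conc)):
            if np.isfinite(c):
                flux[i] = _factor_flux(c, fac, met, receptor, sources, d_floor)
        measured = pd.DataFrame({"flux": flux, "method": "inversion"}, index=ts)
        filled = gapfill_and_cumulate(measured, modelled, dose_g_ha,
                                      window_days=window_days)
        cums[j] = filled["cumulative_pct"].to_numpy()
        finals[j] = cums[j, -1]
    p05, p50, p95 = np.percentile(cums, [5, 50, 95], axis=0)
    traj = pd.DataFrame({"p05": p05, "p50": p50, "p95": p95,
                         "mean": cums.mean(axis=0)}, index=ts)
    return {"mean": float(finals.mean()),
            "p05": float(np.percentile(finals, 5)),
            "p50": float(np.percentile(finals, 50)),
            "p95": float(np.percentile(finals, 95)),
            "n_draws": int(spec.n_draws),
            "trajectories": traj}
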