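"""Canopy-surface concentration and vapour-pressure dynamics.

The big-leaf resistance scheme relates the measured flux and
concentration at a reference height to the concentration at the
notional leaf surface (height z0):

    F = (C(z0) - C(z_ref)) / (R_b + R_a(z_ref))          (resistance form)
    C(z0) = C(z_ref) + F (R_b + R_a(z_ref))              (its inverse)

Concentrations convert to partial pressures by the ideal gas law,
p_vap = C * 1e-9 * R T_K / M, and the pure-compound saturation pressure
follows a Clausius-Clapeyron form anchored at a laboratory reference
point.  The ratio r = p_vap(z0)/p_sat(T_air) is interpreted as the
fraction of the canopy and ground surface covered by unbound (hence
volatilisable) compound; its decay over days after application is
summarised by a double-exponential fit, which in turn drives a modelled
flux used to gap-fill the measured series before cumulating the loss as
a percentage of the applied dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import M_CHLOROTHALONIL, NG_M2_PER_G_HA, R_GAS, T0_K
from .micromet import ResistancePair

__all__ = [
    "ClausiusClapeyron",
    "AvailabilityFit",
    "surface_concentration",
    "vapour_pressure",
    "concentration_from_pressure",
    "saturation_pressure",
    "availability_ratio",
    "fit_availability",
    "modelled_flux",
    "gapfill_and_cumulate",
]


@dataclass
class ClausiusClapeyron:
    """Saturation vapour-pressure curve anchored at (t_ref, p_ref).

    Defaults are chlorothalonil laboratory values: 7.6e-5 Pa at 25 degC
    with an activation energy of 95 kJ mol^-1; the gas constant retains
    the rounded 8.3 J mol^-1 K^-1 of the published parameterisation so
    the curve reproduces it exactly.
    """

    p_ref: float = 7.6e-5
    t_ref: float = 25.0
    activation: float = 95000.0
    gas_const_fit: float = 8.3

    def __post_init__(self):
        if self.p_ref <= 0:
            raise ValueError("p_ref must be > 0")


def surface_concentration(c_ref: float, flux: float,
                          res: ResistancePair) -> float:
    """Concentration at the canopy surface, C(z0) = C(z_ref) + F (R_a + R_b)."""
    return c_ref + flux * (res.r_a + res.r_b)


def resistance_flux(c_z0, c_ref, res: ResistancePair):
    """Big-leaf flux F = (C(z0) - C(z_ref))/(R_b + R_a); emission positive."""
    return (np.asarray(c_z0) - np.asarray(c_ref)) / (res.r_a + res.r_b)


def vapour_pressure(conc, t_air, molar_mass: float = M_CHLOROTHALONIL):
    """Partial pressure (Pa) of a trace gas at concentration ``conc`` (ng m^-3)
    and air temperature ``t_air`` (degC), by the ideal gas law."""
    conc = np.asarray(conc, dtype=float)
    return conc * 1e-9 * R_GAS * (np.asarray(t_air) + T0_K) / molar_mass


def concentration_from_pressure(p_vap, t_air,
                                molar_mass: float = M_CHLOROTHALONIL):
    """Inverse of :func:`vapour_pressure`: Pa -> ng m^-3."""
    return np.asarray(p_vap) * molar_mass / (
        1e-9 * R_GAS * (np.asarray(t_air) + T0_K))


def saturation_pressure(t_air, cc: ClausiusClapeyron | None = None):
    """Pure-compound saturation vapour pressure p_sat(T_air), Pa."""
    cc = cc or ClausiusClapeyron()
    t_air = np.asarray(t_air, dtype=float)
    expo = cc.activation / cc.gas_const_fit * (
        1.0 / (cc.t_ref + T0_K) - 1.0 / (t_air + T0_K))
    out = cc.p_ref * np.exp(expo)
    return out if out.ndim else float(out)


def availability_ratio(p_vap_z0, p_sat):
    """r = p_vap(z0) / p_sat(T_air), the unbound-surface-coverage proxy."""
    p_sat = np.asarray(p_sat, dtype=float)
    if np.any(p_sat <= 0):
        raise ValueError("p_sat must be > 0")
    out = np.asarray(p_vap_z0, dtype=float) / p_sat
    return out if out.ndim else float(out)


def daily_availability(timestamps: pd.DatetimeIndex, r: np.ndarray,
                       day_hours: tuple[int, int] = (9, 17)) -> pd.Series:
    """Daily availability ratio from daytime steps (nighttime resistances
    are noisiest); the daytime window is configurable."""
    s = pd.Series(np.asarray(r, dtype=float), index=timestamps)
    day = s[(s.index.hour >= day_hours[0]) & (s.index.hour < day_hours[1])]
    return day.resample("1D").mean().dropna()


@dataclass
class AvailabilityFit:
    """Double-exponential decay fit y(t) = a1 e^(-k1 t) + a2 e^(-k2 t).

    Amplitudes in % of the initial value (a1 + a2 ~ 100 for normalised
    series), rates in day^-1 with k1 >= k2 >= 0; ``se`` holds the
    standard errors in the same order (a1, k1, a2, k2).
    """

    a1: float
    k1: float
    a2: float
    k2: float
    se: tuple[float, float, float, float] = (np.nan,) * 4
    converged: bool = True
    message: str = ""

    def __call__(self, t_days):
        t = np.asarray(t_days, dtype=float)
        return (self.a1 * np.exp(-self.k1 * t)
                + self.a2 * np.exp(-self.k2 * t))

    def to_dict(self) -> dict:
        return {
            "a1": self.a1, "k1": self.k1, "a2": self.a2, "k2": self.k2,
            "se": list(np.asarray(self.se, dtype=float)),
            "converged": self.converged, "message": self.message,
        }


def _double_exp(t, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def fit_availability(t_days, y, fix_k2_zero: bool = False,
                     p0: tuple | None = None) -> AvailabilityFit:
    """Nonlinear least-squares double-exponential fit of an availability
    (or remaining-content) series.

    Parameters
    ----------
    t_days, y : sampling times (days since application) and values
        (typically % of initial); at least 8 points.
    fix_k2_zero : fit the plateau variant a1 e^(-k1 t) + a2 (the second
        rate pinned to 0).

    Raises
    ------
    RuntimeError
        On non-convergence, with the optimiser diagnostics in the message.
    """
    t = np.asarray(t_days, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 8:
        raise ValueError(f"need >= 8 points to fit, got {len(t)}")

    y0 = y[np.argmin(t)]
    tail = float(np.median(y[t >= np.percentile(t, 75)]))
    if p0 is None:
        p0 = (max(y0 - tail, 0.1 * y0), 0.5, tail, 0.01)

    try:
        if fix_k2_zero:
            popt, pcov = curve_fit(
                lambda tt, a1, k1, a2: _double_exp(tt, a1, k1, a2, 0.0),
                t, y, p0=p0[:3],
                bounds=([0, 0, 0], [np.inf, np.inf, np.inf]), maxfev=20000)
            a1, k1, a2 = popt
            k2, se_k2 = 0.0, 0.0
            se = np.sqrt(np.diag(pcov))
            se = (se[0], se[1], se[2], se_k2)
        else:
            popt, pcov = curve_fit(
                _double_exp, t, y, p0=p0,
                bounds=([0, 0, 0, 0], [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000)
            a1, k1, a2, k2 = popt
            se = tuple(np.sqrt(np.diag(pcov)))
    except RuntimeError as err:
        raise RuntimeError(
            f"availability fit did not converge: {err}; n={len(t)}, "
            f"t range=({t.min():.3g},{t.max():.3g}), p0={p0}") from err

    # order the components so the fast rate comes first
    if k2 > k1:
        a1, a2, k1, k2 = a2, a1, k2, k1
        se = (se[2], se[3], se[0], se[1])
    return AvailabilityFit(float(a1), float(k1), float(a2), float(k2),
                           se=tuple(float(v) for v in se))


def modelled_flux(fit: AvailabilityFit, timestamps: pd.DatetimeIndex,
                  t_days: np.ndarray, t_air: np.ndarray,
                  resistances: list[ResistancePair],
                  c_ref: np.ndarray | float = 0.0,
                  r_scale: float = 0.01,
                  cc: ClausiusClapeyron | None = None,
                  molar_mass: float = M_CHLOROTHALONIL) -> pd.DataFrame:
    """Flux modelled from the fitted availability dynamics.

    The surface concentration is C(z0) = r(t) p_sat(T_air) M/(R T_K) 1e9
    with r(t) = ``r_scale`` * fit(t) (the fit is in % of the initial
    ratio; ``r_scale`` maps % back to the absolute ratio, default
    0.01 * r(0) with r(0)=1 -- pass ``r_scale=r0/100`` for an absolute
    initial ratio r0).  F = (C(z0) - C(z_ref))/(R_b + R_a).
    """
    t_days = np.asarray(t_days, dtype=float)
    r_t = r_scale * fit(t_days)
    p_sat = saturation_pressure(np.asarray(t_air, dtype=float), cc)
    c_z0 = concentration_from_pressure(r_t * p_sat, t_air, molar_mass)
    c_ref = np.broadcast_to(np.asarray(c_ref, dtype=float), t_days.shape)
    rtot = np.array([rp.total for rp in resistances], dtype=float)
    flux = (c_z0 - c_ref) / rtot
    return pd.DataFrame(
        {"flux": flux, "c_z0": c_z0, "p_sat": p_sat, "r": r_t,
         "method": "modelled"},
        index=timestamps)


def gapfill_and_cumulate(measured: pd.DataFrame, modelled: pd.DataFrame,
                         dose_g_ha: float, window_days: float = 7.0,
                         min_overlap: float = 0.5,
                         through_origin: bool = True) -> pd.DataFrame:
    """Gap-fill the measured flux with rescaled modelled flux and cumulate.

    For every step, the modelled flux is linearly rescaled to the
    measured flux over a centred moving window (default 7 days); gaps in
    the measured series are then filled with the rescaled model, and the
    cumulative volatilised fraction is computed by trapezoidal
    integration on the 30-min grid, in % of the applied dose
    (1 g ha^-1 = 1e5 ng m^-2).

    Windows whose measured/modelled overlap is below ``min_overlap`` of
    the window fall back to the nearest window with a valid fit (noted in
    ``.attrs["fallback_steps"]``).

    Returns a DataFrame with columns ``flux`` (filled series),
    ``method`` ("inversion"/"gapfilled"), ``cumulative_pct`` and
    ``scale`` (per-step rescale slope).
    """
    if dose_g_ha <= 0:
        raise ValueError("dose must be > 0")
    idx = measured.index
    if not idx.equals(modelled.index):
        modelled = modelled.reindex(idx)
    fm = measured["flux"].to_numpy(dtype=float)
    fmod = modelled["flux"].to_numpy(dtype=float)
    n = len(idx)
    t_sec = (idx - idx[0]).total_seconds().to_numpy(dtype=float)
    half = window_days * 86400.0 / 2.0

    slope = np.full(n, np.nan)
    valid_pair = np.isfinite(fm) & np.isfinite(fmod)
    for i in range(n):
        in_win = np.abs(t_sec - t_sec[i]) <= half
        pair = in_win & valid_pair
        if pair.sum() < max(2, min_overlap * in_win.sum()):
            continue
        x, ymeas = fmod[pair], fm[pair]
        if through_origin:
            denom = float(x @ x)
            slope[i] = float(x @ ymeas) / denom if denom > 0 else np.nan
        else:
            slope[i] = np.polyfit(x, ymeas, 1)[0]

    fallback = np.where(~np.isfinite(slope))[0]
    good = np.where(np.isfinite(slope))[0]
    if len(good) == 0:
        raise ValueError("no window has enough measured/modelled overlap")
    for i in fallback:
        slope[i] = slope[good[np.argmin(np.abs(good - i))]]

    filled = np.where(np.isfinite(fm), fm, slope * fmod)
    method = np.where(np.isfinite(fm), measured.get(
        "method", pd.Series("inversion", index=idx)), "gapfilled")

    cum_ng_m2 = np.concatenate(
        ([0.0], np.cumsum(np.diff(t_sec) * 0.5 * (filled[1:] + filled[:-1]))))
    cum_pct = cum_ng_m2 / (dose_g_ha * NG_M2_PER_G_HA) * 100.0

    out = pd.DataFrame(
        {"flux": filled, "method": method, "cumulative_pct": cum_pct,
         "scale": slope},
        index=idx)
    out.attrs["fallback_steps"] = int(len(fallback))
    out.attrs["dose_g_ha"] = float(dose_g_ha)
    return out
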