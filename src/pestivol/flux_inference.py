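"""Volatilisation-flux retrieval from concentration measurements.

Two independent routes are implemented:

* **Inversion** of the forward dispersion relation C = D F + C_bgd,
  i.e. F = (C - C_bgd)/D, per 30-min step, masking steps whose
  dispersion coefficient is below a floor (calm periods / wrong wind
  sector, where the inversion variance explodes as 1/D).
* The **aerodynamic gradient method**: F = -u* C*, with the scaling
  concentration C* obtained from the least-squares slope of the
  concentration against ln(z - d) - Psi_H over the sampling heights.

Sign convention: emission positive, deposition negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import VON_KARMAN
from .dispersion import SourceMap, polygon_dispersion
from .micromet import MetRecord, psi_h, NEUTRAL_L

__all__ = [
    "ConcSeries",
    "D_FLOOR",
    "invert_flux",
    "gradient_flux",
    "attribute_sources",
]

#: steps with D below this floor (s m^-1) are masked, not zero-filled
D_FLOOR = 1.0e-3


@dataclass
class ConcSeries:
    """Receptor concentration time series at a single height.

    conc is in ng m^-3 at height ``z_ref``; ``c_bgd``/``c_bgd_sd`` hold the
    background estimated from a pre-application window (its hourly and
    daily variations are neglected).
    """

    timestamps: pd.DatetimeIndex
    conc: np.ndarray
    z_ref: float
    rel_uncertainty: float = 0.14
    c_bgd: float = 0.0
    c_bgd_sd: float = 0.0

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        if len(self.conc) != len(self.timestamps):
            raise ValueError("conc and timestamps length mismatch")
        if self.z_ref <= 0:
            raise ValueError("z_ref must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"conc": self.conc}, index=self.timestamps)


def invert_flux(conc: ConcSeries, d_coeff: np.ndarray,
                d_floor: float = D_FLOOR) -> pd.DataFrame:
    """Invert concentrations to fluxes, F = (C - C_bgd)/D.

    Parameters
    ----------
    d_coeff : per-step dispersion coefficient aligned with ``conc`` (s m^-1).
    d_floor : steps with D < floor are returned as NaN with method "masked".

    Returns
    -------
    DataFrame indexed by timestamp with columns ``flux`` (ng m^-2 s^-1,
    emission positive), ``d_coeff`` and ``method``.
    """
    d_coeff = np.asarray(d_coeff, dtype=float)
    if d_coeff.shape != conc.conc.shape:
        raise ValueError("d_coeff must align with the concentration series")
    usable = np.isfinite(d_coeff) & (d_coeff >= d_floor) & np.isfinite(conc.conc)
    flux = np.full_like(d_coeff, np.nan)
    flux[usable] = (conc.conc[usable] - conc.c_bgd) / d_coeff[usable]
    method = np.where(usable, "inversion", "masked")
    return pd.DataFrame(
        {"flux": flux, "d_coeff": d_coeff, "method": method},
        index=conc.timestamps,
    )


def gradient_flux(levels: list[tuple[float, float]], met: MetRecord) -> float:
    """Aerodynamic-gradient flux from >= 2 concentration levels.

    ``levels`` is a list of (z, conc) pairs (m, ng m^-3), all z > d.  The
    scaling concentration is C* = k * dC/dX with X = ln(z - d) - Psi_H,
    estimated by ordinary least squares over the available levels, and
    F = -u* C* (emission positive).
    """
    pts = [(z, c) for z, c in levels if np.isfinite(c)]
    if len(pts) < 2:
        raise ValueError("gradient flux needs at least 2 valid levels")
    z = np.array([p[0] for p in pts], dtype=float)
    c = np.array([p[1] for p in pts], dtype=float)
    if np.any(z <= met.d):
        raise ValueError("all sampling heights must exceed d")
    zeta = (z - met.d) / met.L if abs(met.L) < NEUTRAL_L else np.zeros_like(z)
    x = np.log(z - met.d) - psi_h(zeta)
    slope = np.polyfit(x, c, 1)[0]
    c_star = VON_KARMAN * slope
    return float(-met.ustar * c_star)


def attribute_sources(sources: SourceMap, met_series: list[MetRecord],
                      receptor: tuple[float, float, float],
                      lateral: str = "strip") -> pd.DataFrame:
    """Per-step fractional contribution of each source to the modelled
    concentration at the receptor (emission-factor weighted), plus the
    campaign mean in ``.attrs["campaign_mean"]``.

    Steps where no source is upwind carry zero for every source and are
    excluded from the campaign mean.
    """
    rows = []
    for met in met_series:
        res = polygon_dispersion(receptor, sources, met, lateral=lateral)
        rows.append(res.contributions)
    frame = pd.DataFrame(rows, index=[m.timestamp for m in met_series])
    seen = frame.sum(axis=1) > 0
    frame.attrs["campaign_mean"] = (
        frame[seen].mean().to_dict() if seen.any() else {n: np.nan for n in frame}
    )
    return frame
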