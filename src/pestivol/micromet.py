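"""Monin-Obukhov surface-layer similarity: stability corrections and the
two transfer resistances used by both the flux-gradient method and the
big-leaf surface exchange scheme.

The aerodynamic resistance between the roughness height z0 and a reference
height z_ref is

    R_a(z_ref) = (ln((z_ref - d)/z0) - Psi_H) / (k u*)

and the quasi-laminar boundary-layer resistance of the canopy is

    R_b = 2/(k u*) (Sc/Pr)^(2/3)

with k the von Karman constant, u* the friction velocity, d the zero-plane
displacement, Sc/Pr the Schmidt/Prandtl numbers of the transported scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .constants import VON_KARMAN

__all__ = [
    "MetRecord",
    "ResistancePair",
    "psi_h",
    "psi_m",
    "phi_h",
    "aerodynamic_resistance",
    "boundary_layer_resistance",
    "schmidt_number_graham",
    "displacement_height",
]

#: |L| at or above this value is treated as neutral stratification
NEUTRAL_L = 1.0e5

#: default clamp on the stability parameter zeta = (z - d)/L
ZETA_BOUNDS = (-5.0, 2.0)

#: coefficient of the linear stable-branch correction Psi_H = -beta * zeta
BETA_STABLE = 5.2

#: Prandtl number of air (heat)
PRANDTL_AIR = 0.72

#: kinematic viscosity of air near 15 degC, m2 s^-1
NU_AIR = 1.46e-5

#: molecular diffusivity of water vapour in air near 15 degC, m2 s^-1
D_H2O = 2.4e-5

M_H2O = 18.015


def displacement_height(h_c: float) -> float:
    """Zero-plane displacement from canopy height, d = (2/3) h_c."""
    return 2.0 / 3.0 * h_c


def schmidt_number_graham(molar_mass: float, nu: float = NU_AIR,
                          d_h2o: float = D_H2O) -> float:
    """Schmidt number of a trace gas with no measured diffusivity.

    The molecular diffusivity is estimated from the water-vapour
    diffusivity scaled by the inverse square-root molar-mass ratio
    (Graham's-law scaling): D = D_H2O * sqrt(M_H2O / M).
    """
    d_gas = d_h2o * np.sqrt(M_H2O / molar_mass)
    return nu / d_gas


#: default Schmidt number for chlorothalonil under Graham's-law scaling
SC_CHLOROTHALONIL = schmidt_number_graham(265.9)


@dataclass
class MetRecord:
    """One 30-min micrometeorological state of the surface layer.

    Parameters
    ----------
    ustar : friction velocity, m s^-1 (> 0)
    L : Obukhov length, m (never 0; neutral encoded as ``|L| >= 1e5``)
    wd : wind direction, degrees from North (direction the wind comes FROM)
    sigma_w : lateral wind-component standard deviation, m s^-1
    t_air : air temperature, degC
    z0 : roughness length, m (> 0)
    d : zero-plane displacement, m
    h_c : canopy height, m
    """

    ustar: float
    L: float
    wd: float = 0.0
    sigma_w: float = 0.3
    t_air: float = 15.0
    z0: float = 0.0035
    d: float = 0.33
    h_c: float = 0.5
    timestamp: object = None

    def __post_init__(self):
        if self.ustar <= 0:
            raise ValueError(f"ustar must be > 0, got {self.ustar}")
        if self.z0 <= 0:
            raise ValueError(f"z0 must be > 0, got {self.z0}")
        if self.L == 0:
            raise ValueError("Obukhov length L must be nonzero")
        self.wd = float(self.wd) % 360.0


@dataclass
class ResistancePair:
    """Aerodynamic (r_a) and quasi-boundary-layer (r_b) resistances, s m^-1."""

    r_a: float
    r_b: float

    @property
    def total(self) -> float:
        return self.r_a + self.r_b


def _clamp_zeta(zeta, bounds=ZETA_BOUNDS):
    return np.clip(zeta, bounds[0], bounds[1])


def psi_h(zeta):
    """Integrated stability correction for scalars.

    Unstable branch (zeta < 0), Businger-Dyer:
        Psi_H = 2 ln((1 + x^2)/2),  x = (1 - 16 zeta)^(1/4)
    Stable branch (zeta >= 0), linear:
        Psi_H = -5.2 zeta

    Returns 0 at neutrality; positive (resistance-reducing) when unstable,
    negative when stable.  zeta is clamped to [-5, 2].
    """
    zeta = _clamp_zeta(np.asarray(zeta, dtype=float))
    x = (1.0 - 16.0 * np.minimum(zeta, 0.0)) ** 0.25
    unstable = 2.0 * np.log((1.0 + x**2) / 2.0)
    stable = -BETA_STABLE * zeta
    out = np.where(zeta < 0.0, unstable, stable)
    return out if out.ndim else float(out)


def psi_m(zeta):
    """Integrated stability correction for momentum (Businger-Dyer).

    Used only to build the wind-speed profile feeding the dispersion
    power laws; the stable branch is kept linear with the same
    coefficient as ``psi_h`` for consistency.
    """
    zeta = _clamp_zeta(np.asarray(zeta, dtype=float))
    x = (1.0 - 16.0 * np.minimum(zeta, 0.0)) ** 0.25
    unstable = (np.log((1.0 + x) ** 2 * (1.0 + x**2) / 8.0)
                - 2.0 * np.arctan(x) + np.pi / 2.0)
    stable = -BETA_STABLE * zeta
    out = np.where(zeta < 0.0, unstable, stable)
    return out if out.ndim else float(out)


def phi_h(zeta):
    """Dimensionless scalar gradient function phi_H = dC+/d ln z.

    phi_H = (1 - 16 zeta)^(-1/2) unstable, 1 + 5.2 zeta stable; the
    derivative counterpart of :func:`psi_h`.
    """
    zeta = _clamp_zeta(np.asarray(zeta, dtype=float))
    unstable = (1.0 - 16.0 * np.minimum(zeta, 0.0)) ** (-0.5)
    stable = 1.0 + BETA_STABLE * zeta
    out = np.where(zeta < 0.0, unstable, stable)
    return out if out.ndim else float(out)


def _zeta(z_above_d: float, L: float) -> float:
    if abs(L) >= NEUTRAL_L:
        return 0.0
    return z_above_d / L


def aerodynamic_resistance(z_ref: float, met: MetRecord) -> float:
    """Aerodynamic resistance R_a(z_ref) between z0 and z_ref, s m^-1.

    Raises
    ------
    ValueError
        If ``z_ref <= d + z0`` (receptor below the roughness sublayer,
        a geometry misconfiguration).
    """
    dz = z_ref - met.d
    if dz <= met.z0:
        raise ValueError(
            f"z_ref={z_ref} must exceed d + z0 = {met.d + met.z0}")
    zeta = _zeta(dz, met.L)
    ra = (np.log(dz / met.z0) - psi_h(zeta)) / (VON_KARMAN * met.ustar)
    return float(max(ra, 0.0))


def boundary_layer_resistance(met: MetRecord,
                              schmidt: float = SC_CHLOROTHALONIL,
                              prandtl: float = PRANDTL_AIR) -> float:
    """Quasi-laminar boundary-layer resistance R_b, s m^-1."""
    if schmidt <= 0 or prandtl <= 0:
        raise ValueError("Schmidt and Prandtl numbers must be > 0")
    return float(2.0 / (VON_KARMAN * met.ustar) * (schmidt / prandtl) ** (2.0 / 3.0))


def resistances(z_ref: float, met: MetRecord,
                schmidt: float = SC_CHLOROTHALONIL,
                prandtl: float = PRANDTL_AIR) -> ResistancePair:
    """Convenience: both transfer resistances for one met state."""
    return ResistancePair(
        r_a=aerodynamic_resistance(z_ref, met),
        r_b=boundary_layer_resistance(met, schmidt, prandtl),
    )
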