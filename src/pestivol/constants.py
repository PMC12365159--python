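"""Physical constants and unit conversions shared across the package.

Flux sign convention everywhere: emission from the surface to the
atmosphere is positive, deposition negative.
"""

#: von Karman constant
VON_KARMAN = 0.4

#: ideal gas constant, J mol^-1 K^-1
R_GAS = 8.314

#: chlorothalonil (C8Cl4N2) molar mass, g mol^-1
M_CHLOROTHALONIL = 265.9

#: 1 g ha^-1 expressed in ng m^-2
NG_M2_PER_G_HA = 1.0e5

#: 0 degC in K
T0_K = 273.15

#: reference pressure for mixing-ratio conversions, hPa
P_STD_HPA = 1013.25


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + T0_K


def g_ha_to_ng_m2(dose_g_ha: float) -> float:
    """Convert an areal dose from g ha^-1 to ng m^-2."""
    return dose_g_ha * NG_M2_PER_G_HA


def ng_m2_to_g_ha(dose_ng_m2: float) -> float:
    """Convert an areal dose from ng m^-2 to g ha^-1."""
    return dose_ng_m2 / NG_M2_PER_G_HA
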