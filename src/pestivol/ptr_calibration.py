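"""PTR-TOF quantification utilities for polychlorinated analytes.

Chlorothalonil (C8Cl4N2) carries four chlorine atoms, so its protonated
ion and its water cluster each show a chlorine isotope envelope
(35Cl/37Cl ~ 3:1): the instrument signal is taken as the sum of the
peaks that rise above a relative-abundance threshold in both envelopes.
The summed count rate is calibrated against a reference concentration
series (zero-intercept slope), converted between ng m^-3 and ppt
sensitivities through the molar volume, and translated into detection
limits either by ion-counting statistics or from measured zero-air noise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass

from .constants import P_STD_HPA, R_GAS, T0_K

__all__ = [
    "IsotopeEnvelope",
    "CalibrationFit",
    "isotope_envelope",
    "sum_peaks",
    "calibrate",
    "sensitivity_to_ppt",
    "lod",
    "ng_m3_per_ppt",
]

#: proton mass used for the +H adduct, Da
PROTON = 1.00727646677

#: peaks at least this fraction of the envelope maximum count as significant
SIGNIFICANT_FRACTION = 0.20


@dataclass
class IsotopeEnvelope:
    """Isotopologue envelope of one ion species.

    ``peaks`` is a list of (exact m/z, relative abundance) with the
    abundances summing to 1; ``species`` tags the adduct.
    """

    species: str
    peaks: list[tuple[float, float]]

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    @property
    def base_mz(self) -> float:
        """m/z of the lightest (monoisotopic) peak."""
        return float(self.mz.min())

    def significant(self, fraction: float = SIGNIFICANT_FRACTION
                    ) -> "IsotopeEnvelope":
        """Sub-envelope of peaks with abundance >= fraction * max."""
        amax = self.abundance.max()
        kept = [(m, a) for m, a in self.peaks if a >= fraction * amax]
        return IsotopeEnvelope(self.species, kept)


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not el:
            continue
        if el not in _ptmass.nist_mass:
            raise ValueError(f"unknown element {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if not counts:
        raise ValueError(f"could not parse formula {formula!r}")
    return counts


def _element_isotopes(el: str) -> list[tuple[float, float]]:
    """(mass, abundance) of the naturally occurring isotopes of ``el``."""
    return [(m, ab) for iso, (m, ab) in _ptmass.nist_mass[el].items()
            if iso != 0 and ab > 0]


def _convolve(counts: dict[str, int],
              prune: float = 1e-10) -> dict[int, tuple[float, float]]:
    """Convolve per-element isotope distributions into nominal-mass bins.

    Each element contributes an independent multinomial over its
    isotopes; the molecular envelope is their convolution.  Peaks are
    aggregated by nominal (integer) mass, keeping the
    abundance-weighted exact mass of each bin.
    """
    # state: nominal bin -> (probability, expected exact mass)
    state: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for el, n in counts.items():
        isotopes = _element_isotopes(el)
        for _ in range(n):
            nxt: dict[int, list[float]] = {}
            for nom, (prob, em) in state.items():
                for miso, ab in isotopes:
                    key = nom + int(round(miso))
                    p = prob * ab
                    if p < prune:
                        continue
                    acc = nxt.setdefault(key, [0.0, 0.0])
                    acc[0] += p
                    acc[1] += p * (em + miso)
            state = {k: (v[0], v[1] / v[0]) for k, v in nxt.items()}
    total = sum(p for p, _ in state.values())
    return {k: (p / total, em) for k, (p, em) in state.items()}


def isotope_envelope(formula: str, adduct: str = "H") -> IsotopeEnvelope:
    """Natural-abundance isotopologue envelope of a protonated molecule.

    Parameters
    ----------
    formula : element counts, e.g. ``"C8Cl4N2"``.
    adduct : ``"H"`` (protonated) or ``"H.H2O"``/``"H+H2O"`` (protonated
        water cluster) -- the adduct adds its exact mass to every peak.

    Returns the full envelope; use :meth:`IsotopeEnvelope.significant`
    for the peaks above the relative-abundance threshold.
    """
    counts = _parse_formula(formula)
    adduct_norm = adduct.replace("+", ".").replace(" ", "")
    if adduct_norm == "H":
        shift, label = PROTON, "protonated"
    elif adduct_norm in ("H.H2O", "H.h2o", "h.h2o"):
        h2o = (_ptmass.nist_mass["H"][1][0] * 2 + _ptmass.nist_mass["O"][16][0])
        shift, label = PROTON + h2o, "protonated+H2O"
    else:
        raise ValueError(f"unknown adduct {adduct!r}")
    bins = _convolve(counts)
    peaks = sorted((em + shift, p) for _, (p, em) in bins.items())
    return IsotopeEnvelope(label, peaks)


def chlorothalonil_envelopes(fraction: float = SIGNIFICANT_FRACTION
                             ) -> tuple[IsotopeEnvelope, IsotopeEnvelope]:
    """Significant-peak envelopes of the two chlorothalonil ion series
    (protonated near m/z 265 and mono-hydrated near m/z 283)."""
    return (isotope_envelope("C8Cl4N2", "H").significant(fraction),
            isotope_envelope("C8Cl4N2", "H.H2O").significant(fraction))


def sum_peaks(spectrum: np.ndarray, envelopes, tolerance: float = 0.2,
              fraction: float = SIGNIFICANT_FRACTION) -> float:
    """Total count rate in windows around the significant envelope peaks.

    Parameters
    ----------
    spectrum : (n, 2) array of (m/z, cps).
    envelopes : one envelope or an iterable of envelopes (for
        chlorothalonil, the protonated + hydrated pair gives 3 + 3 = 6
        windows).
    tolerance : half-width of each m/z window.

    Overlapping windows are collapsed (each spectral point is counted
    once); a warning is emitted when that happens.
    """
    import warnings

    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 2 or spectrum.shape[1] != 2:
        raise ValueError("spectrum must be an (n, 2) array of (mz, cps)")
    if isinstance(envelopes, IsotopeEnvelope):
        envelopes = [envelopes]
    centres = np.sort(np.concatenate(
        [env.significant(fraction).mz for env in envelopes]))
    if len(centres) > 1 and np.any(np.diff(centres) < 2 * tolerance):
        warnings.warn("overlapping m/z windows collapsed", stacklevel=2)
    if len(spectrum) == 0:
        return 0.0
    mz, cps = spectrum[:, 0], spectrum[:, 1]
    inside = np.zeros(len(mz), dtype=bool)
    for c in centres:
        inside |= np.abs(mz - c) <= tolerance
    return float(cps[inside].sum())


@dataclass
class CalibrationFit:
    """Zero-intercept calibration of instrument signal to a reference.

    ``slope`` is reference units per instrument unit; ``slope_range``
    the bootstrap (or half-range) spread; ``rel_uncertainty`` the 1-sigma
    relative uncertainty assigned to calibrated concentrations.
    """

    slope: float
    slope_range: tuple[float, float]
    rel_uncertainty: float
    n: int


def calibrate(signal, reference, n_boot: int = 500,
              method: str = "bootstrap", rng=None) -> CalibrationFit:
    """Least-squares zero-intercept calibration slope with uncertainty.

    ``method="bootstrap"`` resamples the pairs and reports the slope's
    relative standard deviation; ``method="half-range"`` reports
    half the bootstrap slope range over the mean (the estimator used
    when only a slope interval is quoted).
    """
    x = np.asarray(signal, dtype=float)
    y = np.asarray(reference, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired calibration points")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate reference: all values equal")
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("degenerate signal: all zero")
    slope = float(x @ y) / denom

    rng = np.random.default_rng(rng)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        xb, yb = x[idx], y[idx]
        d = float(xb @ xb)
        boots[i] = float(xb @ yb) / d if d > 0 else np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = float(boots.min()), float(boots.max())
    if np.allclose(y, slope * x):
        rel = 0.0
    elif method == "half-range":
        rel = (hi - lo) / 2.0 / slope
    elif method == "bootstrap":
        rel = float(np.std(boots, ddof=1)) / slope
    else:
        raise ValueError(f"unknown method {method!r}")
    return CalibrationFit(slope=slope, slope_range=(lo, hi),
                          rel_uncertainty=rel, n=len(x))


def ng_m3_per_ppt(molar_mass: float, t: float = 25.0,
                  p: float = P_STD_HPA) -> float:
    """Mass concentration of a 1-ppt mixing ratio, ng m^-3.

    1 ppt = 1e-12 mole fraction; at (t, p) the molar volume is
    R T_K / p, so 1 ppt corresponds to 1e-12 * M / V_m * 1e9 ng m^-3.
    """
    if molar_mass <= 0 or p <= 0:
        raise ValueError("molar mass and pressure must be > 0")
    v_m = R_GAS * (t + T0_K) / (p * 100.0)   # m^3 mol^-1
    return 1e-12 * molar_mass / v_m * 1e9


def sensitivity_to_ppt(sens_ng: float, molar_mass: float,
                       t: float = 25.0, p: float = P_STD_HPA) -> float:
    """Convert a sensitivity from cps (ng m^-3)^-1 to cps ppt^-1."""
    if sens_ng <= 0:
        raise ValueError("sensitivity must be > 0")
    return sens_ng * ng_m3_per_ppt(molar_mass, t, p)


def lod(sens: float, averaging_s: float = 1.0, noise_cps: float | None = None
        ) -> float:
    """Limit of detection, ng m^-3.

    Counting mode (``noise_cps`` is None): the concentration producing
    one total ion count over the averaging window, 1/(sens * t).
    Noise mode: the concentration matching the measured zero-air noise
    count rate, noise_cps / sens.
    """
    if sens <= 0 or averaging_s <= 0:
        raise ValueError("sensitivity and averaging time must be > 0")
    if noise_cps is None:
        return 1.0 / (sens * averaging_s)
    if noise_cps <= 0:
        raise ValueError("noise must be > 0")
    return noise_cps / sens
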