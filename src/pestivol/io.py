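"""Readers and writers for the campaign file formats.

All CSVs are RFC-4180 UTF-8 with ISO-8601 UTC timestamps; gaps are empty
fields.  Source polygons travel as GeoJSON in local planar metres with
per-feature properties ``name``, ``dose_g_per_ha`` and
``application_date``.  Every written file starts with comment headers
recording the flux sign convention and, when available, the run
provenance (seed, config hash).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape, mapping

from .dispersion import SourceMap, SourcePolygon
from .flux_inference import ConcSeries
from .micromet import MetRecord, displacement_height

SIGN_NOTE = "# sign convention: emission positive, deposition negative"


def read_met_csv(path, z0: float = 0.0035, h_c: float = 0.5,
                 d: float | None = None) -> list[MetRecord]:
    """Met input CSV with columns timestamp, ustar, obukhov_L, wd_deg,
    sigma_w, t_air_c (empty fields = gaps -> steps are dropped)."""
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    d = displacement_height(h_c) if d is None else d
    recs = []
    for _, r in df.dropna().iterrows():
        recs.append(MetRecord(ustar=r["ustar"], L=r["obukhov_L"],
                              wd=r["wd_deg"], sigma_w=r["sigma_w"],
                              t_air=r["t_air_c"], z0=z0, d=d, h_c=h_c,
                              timestamp=r["timestamp"]))
    return recs


def write_met_csv(path, met: list[MetRecord], header: str = "") -> None:
    df = pd.DataFrame({
        "timestamp": [m.timestamp for m in met],
        "ustar": [m.ustar for m in met],
        "obukhov_L": [m.L for m in met],
        "wd_deg": [m.wd for m in met],
        "sigma_w": [m.sigma_w for m in met],
        "t_air_c": [m.t_air for m in met],
    })
    _write_csv(path, df, header)


def read_conc_csv(path, z_ref: float, c_bgd: float = 0.0,
                  c_bgd_sd: float = 0.0,
                  rel_uncertainty: float = 0.14) -> ConcSeries:
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    return ConcSeries(timestamps=pd.DatetimeIndex(df["timestamp"]),
                      conc=df["conc_ng_m3"].to_numpy(dtype=float),
                      z_ref=z_ref, rel_uncertainty=rel_uncertainty,
                      c_bgd=c_bgd, c_bgd_sd=c_bgd_sd)


def write_conc_csv(path, conc: ConcSeries, header: str = "") -> None:
    df = pd.DataFrame({"timestamp": conc.timestamps,
                       "conc_ng_m3": conc.conc})
    _write_csv(path, df, header)


def read_sources_geojson(path) -> SourceMap:
    with open(path) as fh:
        gj = json.load(fh)
    sources = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        sources.append(SourcePolygon(
            name=props.get("name", f"src{len(sources)}"),
            polygon=shape(feat["geometry"]),
            dose_g_per_ha=float(props.get("dose_g_per_ha", 0.0)),
            rel_dose_factor=float(props.get("rel_dose_factor", 1.0)),
            application_date=props.get("application_date")))
    return SourceMap(sources)


def write_sources_geojson(path, sources: SourceMap) -> None:
    feats = []
    for s in sources:
        feats.append({
            "type": "Feature",
            "geometry": mapping(s.polygon),
            "properties": {"name": s.name,
                           "dose_g_per_ha": s.dose_g_per_ha,
                           "rel_dose_factor": s.rel_dose_factor,
                           "application_date": str(s.application_date or "")},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh,
                  indent=1)


def write_flux_csv(path, flux: pd.DataFrame, header: str = "") -> None:
    """Flux output: timestamp, flux_ng_m2_s, p05, p95, method, d_coeff, n_mc."""
    out = pd.DataFrame({"timestamp": flux.index})
    out["flux_ng_m2_s"] = flux.get("flux", np.nan).to_numpy() \
        if "flux" in flux else np.nan
    for col in ("p05", "p95"):
        out[col] = flux[col].to_numpy() if col in flux else np.nan
    out["method"] = flux["method"].to_numpy() if "method" in flux else ""
    out["d_coeff"] = flux["d_coeff"].to_numpy() if "d_coeff" in flux else np.nan
    out["n_mc"] = flux["n_mc"].to_numpy() if "n_mc" in flux else 0
    _write_csv(path, out, header)


def write_surface_csv(path, surface: pd.DataFrame, header: str = "") -> None:
    """Surface-state output: timestamp, c_z0, p_vap_z0, p_sat, r, r_a, r_b."""
    cols = ["c_z0", "p_vap_z0", "p_sat", "r", "r_a", "r_b"]
    out = pd.DataFrame({"timestamp": surface.index})
    for c in cols:
        out[c] = surface[c].to_numpy() if c in surface else np.nan
    _write_csv(path, out, header)


def _write_csv(path, df: pd.DataFrame, header: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(SIGN_NOTE + "\n")
        if header:
            for line in header.strip().splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
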