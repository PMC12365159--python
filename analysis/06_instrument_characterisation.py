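#!/usr/bin/env python
"""PTR-TOF quantification chain for chlorothalonil.

Chlorine isotope envelopes of the protonated and hydrated ions, the
6-peak summing windows, a synthetic calibration against co-located
reference samples, the ng m-3 <-> ppt sensitivity conversion and the
two detection-limit estimates.  Writes results/instrument.json.
"""

import json
from pathlib import Path

import numpy as np

from pestivol.ptr_calibration import (calibrate, chlorothalonil_envelopes,
                                      isotope_envelope, lod,
                                      sensitivity_to_ppt, sum_peaks)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    rng = np.random.default_rng(SEED)
    env_h, env_w = chlorothalonil_envelopes()
    full_h = isotope_envelope("C8Cl4N2", "H")
    full_w = isotope_envelope("C8Cl4N2", "H.H2O")

    # synthetic co-location calibration: 12 paired samples, 14% scatter
    ref = rng.uniform(10.0, 120.0, 12)                  # ng m-3 (reference)
    cps = 0.7 * ref * (1.0 + rng.normal(0, 0.14, 12))   # instrument signal
    fit = calibrate(cps, ref, n_boot=500, rng=SEED)

    sens_ppt = sensitivity_to_ppt(0.7, 265.9)
    report = {
        "protonated": {"monoisotopic_mz": full_h.base_mz,
                       "significant_peaks": len(env_h.peaks)},
        "hydrated": {"monoisotopic_mz": full_w.base_mz,
                     "significant_peaks": len(env_w.peaks)},
        "summed_windows": len(env_h.peaks) + len(env_w.peaks),
        "calibration": {"slope": fit.slope,
                        "rel_uncertainty": fit.rel_uncertainty},
        "sensitivity_cps_per_ng_m3": 0.7,
        "sensitivity_cps_per_ppt": sens_ppt,
        "lod_counting_1s_ng_m3": lod(0.7, averaging_s=1.0),
        "lod_noise_30min_ng_m3": lod(0.7, noise_cps=0.1),
    }
    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "instrument.json", "w") as fh:
        json.dump(report, fh, indent=1)

    # demonstrate peak summing on an envelope-shaped synthetic spectrum
    mz = np.concatenate([env_h.mz, env_w.mz])
    ab = np.concatenate([env_h.abundance, env_w.abundance])
    spectrum = np.column_stack([mz, 350.0 * ab / ab.sum()])
    total = sum_peaks(spectrum, (env_h, env_w))

    print(f"protonated massif at m/z {full_h.base_mz:.3f} "
          f"({len(env_h.peaks)} significant peaks)")
    print(f"hydrated massif at m/z {full_w.base_mz:.3f} "
          f"({len(env_w.peaks)} significant peaks)")
    print(f"summed {len(mz)} windows recover {total:.0f} cps of 350")
    print(f"calibration slope {fit.slope:.2f} "
          f"(+/- {fit.rel_uncertainty * 100.0:.0f}%)")
    print(f"sensitivity {sens_ppt:.1f} cps/ppt; LOD ~"
          f"{report['lod_counting_1s_ng_m3']:.1f} ng m-3 at 1 s (counting), "
          f"~{report['lod_noise_30min_ng_m3']:.2f} ng m-3 over 30 min "
          "(zero-air noise)")


if __name__ == "__main__":
    main()
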