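"""Paired-architecture light propagation: how much more light does the
multi-chromocenter ONL send beyond 30 degrees than the inverted ONL,
on identical nucleus geometry?

Also runs the forced chromocenter-count sweep {1, 2, 4, 8, 12} and an
averaged point-stimulus (PSF) transmission comparison, and reports both
honestly: at this desk scale the paired inequality is strong and stable,
while the forced-count trend and the PSF peak ordering are dominated by
an N-independent envelope term and geometry speckle respectively.

Writes results/compare_architectures.json and results/angular_spectra.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from onloptics.bpm import compare_models, paired_psf_comparison
from onloptics.phantom import ChromatinParams, generate_packed_nuclei

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 11
params = ChromatinParams()
labels = generate_packed_nuclei(
    40, (128, 256, 256), voxel_size_um=0.166, radius_um=(2.8, 0.3), seed=SEED
)

report = compare_models(labels, params, seed=SEED + 1)
print(f"large-angle (>30 deg) fraction, inverted:     {report.fraction_inverted:.3e}")
print(f"large-angle (>30 deg) fraction, chromocenter: {report.fraction_chromocenter:.3e}")
print(f"ratio chromocenter/inverted:                  {report.ratio_chromocenter_over_inverted:.1f}x")

pd.DataFrame(
    {
        "theta_deg": report.spectrum_inverted.theta_deg,
        "power_inverted": report.spectrum_inverted.power,
        "power_chromocenter": report.spectrum_chromocenter.power,
    }
).to_csv(RESULTS / "angular_spectra.csv", index=False, float_format="%.10g")

sweep = {}
for n_cc in (1, 2, 4, 8, 12):
    rep = compare_models(labels, params, seed=SEED + 1, n_cc_override=n_cc)
    sweep[n_cc] = rep.fraction_chromocenter
print("forced chromocenter-count sweep (>30 deg fraction):")
for n_cc, frac in sweep.items():
    print(f"  N={n_cc:2d}: {frac:.3e}")
monotone = all(b >= a for a, b in zip(list(sweep.values()), list(sweep.values())[1:]))
print(f"  non-decreasing in N: {monotone} "
      "(the >30 deg signal is dominated by heterochromatin-envelope contact, "
      "which does not vary with N in this model family)")

psf = paired_psf_comparison(labels, params, seed=SEED + 1, n_positions=16)
print("averaged point-stimulus transmission (16 probe positions):")
for name in ("inverted", "chromocenter"):
    m = psf[name]["psf"]
    print(f"  {name:13s}: normalized peak {m.peak_intensity:.4g}, FWHM {m.fwhm_um:.2f} um, "
          f"power {psf[name]['total_power']:.1f}")

out = {
    "paired": report.to_dict(),
    "forced_count_sweep": {str(k): v for k, v in sweep.items()},
    "psf": {
        name: {
            "peak_intensity": psf[name]["psf"].peak_intensity,
            "fwhm_um": psf[name]["psf"].fwhm_um,
            "total_power": psf[name]["total_power"],
        }
        for name in ("inverted", "chromocenter")
    },
}
(RESULTS / "compare_architectures.json").write_text(json.dumps(out, indent=2))
print(f"wrote {RESULTS / 'compare_architectures.json'}")
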