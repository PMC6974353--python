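"""Image-quality pipeline on synthetic measurements with known ground truth:
MTF recovery from veiled stripe stacks under shot noise, Strehl ratios of
constructed pairs, PSF peak/veil dissociation, and the outer-segment vs
nuclear-layer MTF comparison.

Writes results/optical_quality.csv (one row per analysis with truth,
measurement and relative error).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from onloptics.mie import SphereSpec, mie_efficiencies
from onloptics.quality import (
    MTFCurve,
    diffuse_transmission,
    mtf_curve,
    psf_metrics,
    scattering_to_mtf,
    strehl_ratio,
)
from onloptics.synth import GeneratorSpec, make_psf_image, make_stripe_stack

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
rows = []


def row(analysis, truth, measured):
    rows.append(dict(analysis=analysis, truth=truth, measured=measured,
                     rel_error=abs(measured - truth) / abs(truth)))


freqs = np.array([0.02, 0.04, 0.08, 0.16])
for v in (0.3, 0.5):
    vals = [
        mtf_curve(*make_stripe_stack(
            freqs, 0.8, v, GeneratorSpec(seed=s, noise_model="poisson", noise_scale=5.0))[:2]).mtf
        for s in range(5)
    ]
    row(f"mtf_recovery_veil_{v}", 1 - v, float(np.mean(vals)))

f = np.linspace(0.0, 2.5, 26)
sr = strehl_ratio(MTFCurve(f, np.full_like(f, 0.8)), MTFCurve(f, np.full_like(f, 0.4)))
row("strehl_constructed_2x_pair", 2.0, sr.strehl)

img0, _ = make_psf_image(4.0, 0.0, GeneratorSpec(seed=20), 0.5)
img5, _ = make_psf_image(4.0, 0.5, GeneratorSpec(seed=20), 0.5)
m0, m5 = psf_metrics(img0, 0.5, 40.0), psf_metrics(img5, 0.5, 40.0)
row("psf_peak_ratio_half_veil", 2.0, m0.peak_intensity / m5.peak_intensity)
row("psf_fwhm_um", 4.0, m0.fwhm_um)
row("psf_fwhm_unchanged_by_veil", 1.0, m5.fwhm_um / m0.fwhm_um)
row("diffuse_transmission_veiled_point", 1.0, diffuse_transmission(img5, img0))

# outer segments vs nuclear layer: converted MTFs at behavioral frequencies
behav = np.linspace(1e-4, 0.5 / 31.0, 25)
v_cyl = np.pi * 0.8**2 * 25.0
d_os = (6 * v_cyl / np.pi) ** (1 / 3)
e_os = mie_efficiencies(SphereSpec(d_os, 1.42, 1.33, 500.0))
m_os = scattering_to_mtf(e_os.g, e_os.qsca, 0.01, d_os, 25.0, behav)
d_cc = 2.22
e_cc = mie_efficiencies(SphereSpec(d_cc, 1.382, 1.357, 500.0))
m_cc = scattering_to_mtf(e_cc.g, e_cc.qsca, 0.3351 / (np.pi / 6 * d_cc**3), d_cc, 55.0, behav)
rows.append(dict(analysis="mtf_min_outer_segments", truth=np.nan, measured=float(m_os.mtf.min()),
                 rel_error=np.nan))
rows.append(dict(analysis="mtf_min_nuclear_layer", truth=np.nan, measured=float(m_cc.mtf.min()),
                 rel_error=np.nan))

df = pd.DataFrame(rows)
df.to_csv(RESULTS / "optical_quality.csv", index=False, float_format="%.8g")
print(df.to_string(index=False))
print("outer segments leave the behavioral-band MTF near unity "
      f"({m_os.mtf.min():.3f}) while the nuclear layer costs visibly more "
      f"({m_cc.mtf.min():.3f})")
print(f"wrote {RESULTS / 'optical_quality.csv'}")
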