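# onloptics

Tissue optics of the retinal **outer nuclear layer (ONL)** — the layer of rod
photoreceptor nuclei that every projected image must cross before reaching the
light-sensitive outer segments.

In nocturnal mammals, rod nuclei are *inverted*: dense heterochromatin, which
in conventional nuclei is split among many discrete **chromocenters** and a
peripheral rim at the nuclear envelope, fuses into a single central body
wrapped in low-density euchromatin. This package models and quantifies the
optical consequence of that rearrangement: fewer, larger heterochromatin
bodies scatter less light into large angles per unit of chromatin, which
reduces the diffuse veil overlaid on retinal images and thereby preserves
image contrast — without changing total light transmission or resolution.

It is intended for researchers in tissue optics and nuclear architecture who
want a self-contained, CPU-only reimplementation of this analysis chain:

1. **Mie fusion model** (`onloptics.mie`) — scattering efficiencies of
   homogeneous spheres (Wiscombe-truncated series, downward-recurrence
   logarithmic derivative). For a chromocenter of diameter *d* fused from *N*
   sub-spheres at conserved volume (*d·N^(−1/3)* each), the figure of merit is
   the volume-specific, angle-weighted **hiding power**

   *H = Q_sca · (1 − g)*,

   the transport (reduced) scattering efficiency: the part of scattered power
   redirected away from the forward direction, which is what degrades
   transmitted contrast. An optional Percus–Yevick hard-sphere factor
   (1 − vf)⁴/(1 + 2 vf)² corrects for dependent scattering at volume fraction
   vf.
2. **ONL phantom builder** (`onloptics.phantom`) — packs non-overlapping
   ellipsoidal nuclei into a labeled 3-D volume and paints two refractive-index
   architectures on *identical* geometry: **inverted** (n₂ = 1.382 core,
   n₁ = 1.357 shell, equal volumes) and **chromocenter** (8–12 seeded
   heterochromatin bodies plus a border shell, grown to half the nucleus
   volume), in an n₀ = 1.33 surround, Gaussian-smoothed (σ = 2 px).
3. **Beam propagation** (`onloptics.bpm`) — scalar split-step propagation of a
   500 nm plane wave (phase screen + non-paraxial angular-spectrum
   propagator), far-field angular power spectra via
   sin θ = λf/n₀, and the **large-angle (>30°) scattered fraction** as the
   veil-generating quantity.
4. **Image-quality analytics** (`onloptics.quality`) — stripe-contrast sine
   fitting, MTF(ξ) = C_image(ξ)/C_object(ξ), relative Strehl ratio
   SR = ∫ξ·MTF dξ / ∫ξ·MTF_ref dξ (0–2 cycles/deg band), PSF peak/FWHM,
   diffuse transmission, (g, Q_sca) → MTF conversion, FACS volume-specific
   scattering (SSC/FSC), and the area under the log contrast-sensitivity
   curve (AULC).
5. **Synthetic data** (`onloptics.synth`) — seeded generators with embedded
   ground truth for every input above.

Everything is orchestrated either from Python, through the numbered scripts in
`analysis/`, or via the `onloptics` command line (`mie-series`, `build-onl`,
`propagate`, `compare-models`, `mtf`, `strehl`, `psf`, `transmission`,
`facs-vss`, `aulc`, `synth …`, `run`).

## Worked example

```python
import numpy as np
from onloptics.mie import fusion_series
from onloptics.phantom import ChromatinParams, generate_packed_nuclei
from onloptics.bpm import compare_models

# Fusing 12 chromocenters into one 2-um body at conserved volume:
fs = fusion_series(2.0, [1, 12])   # heterochromatin 1.04 vs euchromatin 1.02
ratio = fs.volume_specific_hiding_power[1] / fs.volume_specific_hiding_power[0]
print(f"unfused/fused hiding power per volume: {ratio:.2f}x")

# Paired wave-optical experiment on identical 40-nucleus geometry:
labels = generate_packed_nuclei(40, (128, 256, 256), voxel_size_um=0.166,
                                radius_um=(2.8, 0.3), seed=11)
rep = compare_models(labels, ChromatinParams(), seed=12)
print(f"large-angle (>30 deg) fraction, inverted:     {rep.fraction_inverted:.2e}")
print(f"large-angle (>30 deg) fraction, chromocenter: {rep.fraction_chromocenter:.2e}")
print(f"ratio: {rep.ratio_chromocenter_over_inverted:.1f}x")
```

prints

```
unfused/fused hiding power per volume: 1.66x
large-angle (>30 deg) fraction, inverted:     1.14e-06
large-angle (>30 deg) fraction, chromocenter: 1.35e-05
ratio: 11.9x
```

The Mie model says twelve dispersed chromocenters hide 1.66× more light per
unit chromatin than one fused body; the full wave-optical simulation of the
same comparison on identical nucleus geometry sends ~12× more light beyond
30° in the multi-chromocenter ONL — the diffuse veil that costs image
contrast. The `analysis/` scripts run the complete sweeps and write their
tables under `results/`.

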