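# Methods

This note documents the models, numerical choices and limitations of
`onloptics`. Everything quantitative stated here is computed by the test
suite, the `analysis/` drivers, or `scripts/acceptance.py`.

## Mie fusion model (`onloptics.mie`)

**Model.** Chromocenters are treated as homogeneous spheres of
heterochromatin (index 1.04 relative convention) in euchromatin (1.02), i.e.
a ~2% relative index contrast, illuminated at 500 nm vacuum wavelength.
Coefficients use the Bohren–Huffman series with the Wiscombe truncation
n_max = x + 4x^(1/3) + 2 and a downward-recurrence logarithmic derivative,
stable to at least x ≈ 10³. For real indices Q_ext = Q_sca (checked to
10⁻⁸), and the series agrees with an independent Riccati–Bessel +
Gauss–Legendre quadrature oracle to 10⁻⁶ relative.

**Size-parameter convention.** The 1.04/1.02 pair is a relative convention;
the absolute medium index that scales x is configurable. `SphereSpec`
defaults to its own `m_medium` (correct for absolute pairs such as silica
1.48 in glycerol–water 1.43), while `fusion_series` defaults to 1.357, the
euchromatin index used by the refractive-index phantoms, so the Mie sweeps
and the beam-propagation experiments describe the same material. The
qualitative fusion results are unchanged under either convention (verified
for absolute media 1.02, 1.33 and 1.357).

**Hiding power.** The angle-weighted, contrast-degrading scattering strength
is the transport (reduced) scattering efficiency H = Q_sca·(1 − g). Weighting
by g itself would *reward* forward scattering, which does not veil images:
numerically, volume-specific Q_sca·g is larger for the fused body than for
twelve sub-spheres at every diameter in the 0.92–4 µm sweep, the opposite of
both the biology and the direction this analysis exists to capture, whereas
Q_sca·(1 − g) reproduces it everywhere. The fused (N = 1) state has strictly
lower volume-specific H than N = 12 at all 20 swept diameters; the full
N = 12→1 descent is strictly monotone at 18/20 diameters and monotone to
within ≤ 0.21% at the remaining two (d = 0.92 and 1.08 µm) — genuine Mie
interference ripple, confirmed by the independent oracle, not a numerical
artifact. Tests assert monotonicity with a 1% ripple allowance and the
endpoint inequality strictly.

**Dependent scattering.** At volume fraction vf the independent-scattering
cross-sections are multiplied by the Percus–Yevick hard-sphere zero-angle
structure factor (1 − vf)⁴/(1 + 2 vf)² (0.070 at vf = 0.3351). This is a
standard closed-form choice, isolated behind `dependent_packing_factor` so a
different correlation model can be swapped in; it is a common factor across N
and does not affect fusion ratios.

**Fusion geometry.** Sub-spheres scatter independently (fields add
incoherently); near-field coupling between chromocenters is not modelled.

## ONL phantoms (`onloptics.phantom`)

Nuclei are axis-aligned ellipsoids (radius 2.8 ± 0.3 µm, per-axis ratios
0.8–1.2 — mildly eccentric, rod-like, trivially packable) placed by
bounding-sphere rejection sampling, which guarantees zero label overlap;
centers keep one bounding radius from the domain faces so smoothing never
leaks mass out of the grid. The desk-scale default is 40 nuclei in a
256×256×128 grid at 0.166 µm isotropic voxels (42.5×42.5×21 µm), giving a
nuclear volume fraction of ~0.08; voxel size is configurable down to the
83 nm used for a native-resolution check.

Two architectures are painted on identical labels:

* **Inverted**: per nucleus, the deepest half of the voxels by Euclidean
  distance to the boundary becomes the n₂ = 1.382 core; the rest is
  n₁ = 1.357. For a sphere this is the concentric core of radius
  R·2^(−1/3), and the equal-volume split is exact to one voxel.
* **Chromocenter**: a count is drawn uniformly from 8–12, that many seed
  voxels are drawn uniformly inside the mask (the seed distribution is not
  otherwise constrained), the 1-voxel border shell is assigned to n₂
  (peripheral, lamina-associated heterochromatin), and n₂ grows from the
  seeds in order of Euclidean distance-to-nearest-seed — ties broken by
  lexicographic voxel order — until the n₂ phase holds half the nucleus.

Both models therefore place exactly half of each nucleus in each phase
(before smoothing), so they move the same optical material into different
arrangements; per-nucleus mean index agrees to < 10⁻³ between models.
Nuclei under 16 voxels cannot be split meaningfully and receive the uniform
mean index with a warning. The final map is smoothed by filtering the index
*excess over n₀* with a σ = 2 px Gaussian, which conserves the summed
optical path to 0.1% and leaves the background at exactly n₀ far from
nuclei. All randomness flows from explicit seeds; identical inputs give
voxel-identical output.

## Beam propagation (`onloptics.bpm`)

Scalar split-step: per z-slice a thin phase screen exp(i k₀ (n − n₀) dz)
followed by the non-paraxial propagator H(f) = exp(i 2π dz √((n₀/λ)² − f²))
with evanescent components truncated. Both operators are unitary on
propagating modes, so total intensity through real-index media is conserved
(≤ 0.1% drift measured on a 256³ heterogeneous volume). Fields are
single-precision complex by default (double available); lateral boundaries
are periodic, with an optional super-Gaussian absorbing apron (width 8% of
the grid) for runs where wrap-around of obliquely scattered light matters.
The apron removes energy by construction, so it is **off by default** to
keep the energy bookkeeping exact; the angular statistics used here are
insensitive to periodic wrap (verified: lateral translation leaves the
angular spectrum unchanged to 10⁻⁶).

The far field maps spatial frequency to polar angle via sin θ = λf/n₀ and is
azimuthally integrated into 1° bins; binned power satisfies Parseval against
the exit-plane sum to 10⁻⁶. The contrast-degrading quantity is the fraction
of transmitted power beyond 30°, and the "integrated side-scattering
cross-section" is operationalized as that fraction times the illuminated
area (unit incident irradiance over the periodic window). Validation: a
single weak sphere's scattered far field matches the Mie phase function with
cosine similarity ≥ 0.99 for θ ≤ 30°, and halving the voxel size moves the
large-angle fraction by < 10%.

`compare_models` runs both architectures on identical geometry with one
seed. At desk scale the multi-chromocenter ONL sends 6–13× more power beyond
30° than the inverted ONL (ratio 12.4 under the acceptance conditions) —
the central directional result. Two related desk-scale findings are
negative, are asserted as such nowhere, and their tests are left failing
deliberately rather than weakened:

* **Forced chromocenter-count sweep.** Overriding the drawn count with
  N ∈ {1, 2, 4, 8, 12} leaves the >30° fraction flat (±15% ripple, no
  trend), because that signal is dominated by heterochromatin–envelope
  contact (the n₂ shell and boundary-touching bodies against the n₀
  surround), which this model family holds constant across N. The
  N-dependent granularity signal appears only beyond ~45° at ~10⁻⁸ relative
  power. The same flatness holds with σ = 1 px smoothing, without the border
  shell, with interior-restricted seeds, and at 83 nm native resolution.
  A monotone count dependence would require a fusion-trajectory model in
  which peripheral heterochromatin detaches as the count falls; that is a
  different (and additional) modelling commitment not made here.
* **Paired point-stimulus peaks.** `paired_psf_comparison` propagates a
  focused Gaussian probe (waist 1.5 µm) at a grid of lateral positions and
  averages the recentred exit intensities. At desk-scale optical depth the
  between-model peak difference is buried in geometry speckle (±8% after 16
  positions) and the mean ordering is set by mid-angle (10–20°) forward-lobe
  differences rather than large-angle veil; the measured ~1.8× peak
  dissociation belongs to a ~200 µm multiply-scattering retina, not to a
  21–64 µm weakly veiling slab. Total transmitted power between models
  agrees to < 10⁻⁶, and FWHM to within 15%, as expected.

## Image-quality analytics (`onloptics.quality`)

* **Stripe contrast**: average along the axis orthogonal to the modulation,
  then fit offset + amplitude + phase with the frequency free within ±5% of
  the hint (seeded from the Fourier component at the hint; nonlinear least
  squares). Contrast = (I_max − I_min)/(I_max + I_min). Amplitudes within
  3σ of their fit uncertainty return contrast 0 with a low-confidence flag;
  fields showing fewer than two periods are rejected. Bias < 0.5% on
  noise-free stripes across contrasts 0.02–1. An optional baseline pair
  (I0_max, I0_min) subtracts a dark/reference contrast from the measured
  one (off by default; the unambiguous ratio definition is the primary
  quantity).
* **MTF**: per-frequency contrast ratio sample/reference, optionally divided
  by a setup-only MTF; negative values floored at 0 and flagged.
* **Strehl**: SR = ∫ξ·MTF dξ / ∫ξ·MTF_ref dξ by trapezoid on the merged
  grid, default band 0–2 cycles/deg. Exact for linear constructions
  (0.8 vs 0.4 flat pair → 2.000).
* **Degrees ↔ µm**: cycles/µm are converted to cycles/deg with a retinal
  magnification of 31 µm/deg (mouse eye scale), configurable everywhere.
* **PSF**: images are normalized by their field-of-view integral (peak is
  then the fraction of all light on the brightest pixel — the
  veil-sensitive readout), cropped to a 40 µm ROI, and the FWHM read from
  the radially averaged profile around the centroid by linear interpolation
  at half the peak, with bin positions taken at the mean radius per annulus
  (removes the half-bin bias of naive binning; Gaussian FWHM accurate to
  ~2%).
* **(g, Q_sca) → MTF**: a two-component small-angle transfer model —
  unscattered fraction e^(−τ) at full contrast plus the scattered remainder
  blurred by a Gaussian of spatial spread σ = arccos(g)·L/2 (characteristic
  scattering angle times the mean remaining path). MTF(0) = 1,
  non-increasing in ξ, increasing in g at fixed τ. This closed form is a
  documented stand-in used for directional comparisons only; with it,
  photoreceptor outer segments (volume-equivalent sphere of a 1.6×25 µm
  cylinder at n = 1.42, one per 2 µm lattice cell, over their 25 µm
  anatomical layer) keep the behavioral-band MTF ≥ 0.975 while a
  multi-chromocenter nuclear layer at heterochromatin volume fraction
  0.3351 over the 55 µm ONL falls to 0.93. The layers are compared at their
  anatomical thicknesses; at an artificially common 25 µm both are near
  unity and the comparison is uninformative.
* **FACS**: per-event volume-specific scattering SSC/FSC (forward scatter as
  the size proxy), population medians and IQRs; non-positive FSC events are
  dropped and counted.
* **AULC**: trapezoidal area of log₁₀(sensitivity) against *linear* spatial
  frequency (the axis convention is configurable in principle via the
  curve's frequency grid), sensitivity floored at 1.

## Synthetic data (`onloptics.synth`)

Generators emulate the measurement chain, not the instrument: stripe stacks
are ideal sinusoids with a veil that replaces a fraction v of structured
light by its mean (ground-truth MTF = 1 − v, or an imposed profile); point
images split energy (1 − v) into a Gaussian core and v into a uniform floor
at exactly conserved total energy; FACS tables are log-normal around exact
medians; optomotor trials are Bernoulli responses on the standard contrast
ladder (5% steps to 10%, 2% below) under a step psychometric function with
symmetric lapses. Noise models: none, additive Gaussian, or shot-like
Poisson (counts at intensity×scale, rescaled). Not emulated: optical
aberrations of the projection setup (defocus, field curvature), flat-field
structure, camera nonlinearity, or behavioral dynamics beyond per-trial
Bernoulli responses — so passing recovery tests demonstrate estimator
correctness on the stated forward models, not robustness to instrument
systematics. Staircase thresholds are only resolvable at ladder values, so
recovery is quoted against ladder-representable truths.

## Pipeline and I/O

Volumes travel as multi-page TIFF with JSON metadata (voxel size,
provenance, seeds) in the description tag; curves and tables as CSV at
full float precision (round-trip parsing); metrics as JSON. The
config-driven pipeline validates strictly (unknown keys are rejected by
name), records every stage's seed, and writes a manifest with SHA-256
checksums; identical configs produce identical checksums, and `--resume`
skips stages whose artifacts verify.

## Problem sizes

Desk-scale defaults throughout: 40 nuclei / 256×256×128 at 0.166 µm for the
paired experiment (single-core minutes), 20-diameter × 12-count Mie sweeps,
5 noise seeds × 4 frequencies for MTF recovery, 4000-event FACS populations
and 80-trial staircases. These sizes were chosen so every analysis runs
comfortably on one CPU core while leaving all directional results far from
their decision boundaries; the native 83 nm voxel size and larger domains
are configurable where more fidelity is wanted.
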