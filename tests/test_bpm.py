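"""Beam propagation: analytic limits, energy bookkeeping, Mie cross-validation."""

import numpy as np
import pytest

from onloptics.bpm import (
    ComplexField,
    angular_spectrum,
    compare_models,
    gaussian_probe,
    large_angle_fraction,
    propagate,
    side_scattering_cross_section,
)
from onloptics.errors import InvalidInputError, ResourceError
from onloptics.mie import SphereSpec, phase_function
from onloptics.phantom import ChromatinParams, RIVolume

N0 = 1.33
WAVELENGTH = 500.0


def homogeneous(shape, n=N0, dx=0.166):
    return RIVolume(np.full(shape, n, dtype=np.float32), dx, model="homogeneous")


def sphere_volume(d_um=2.0, dn=0.025, dx=0.083, n=256, nz=64):
    zz, yy, xx = np.meshgrid(*(np.arange(s) * dx for s in (nz, n, n)), indexing="ij")
    c = np.array([nz, n, n]) * dx / 2
    r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
    vol = np.where(r2 <= (d_um / 2) ** 2, N0 + dn, N0).astype(np.float32)
    return RIVolume(vol, dx, model="sphere")


class TestPropagate:
    def test_plane_wave_through_homogeneous_medium_unchanged(self):
        f = propagate(homogeneous((32, 64, 64)))
        assert f.total_power / (64 * 64) == pytest.approx(1.0, abs=1e-5)
        assert np.abs(f.amplitude).std() < 1e-5

    def test_uniform_slab_adds_analytic_phase(self):
        dn, n_slab = 0.01, 20
        v = np.full((30, 64, 64), N0, dtype=np.float32)
        v[5 : 5 + n_slab] += dn
        f = propagate(RIVolume(v, 0.166, "slab"))
        f0 = propagate(homogeneous((30, 64, 64)))
        dphi = np.angle(np.vdot(f0.amplitude, f.amplitude))
        expected = 2 * np.pi * dn * n_slab * 0.166 / (WAVELENGTH * 1e-3)
        wrapped = (expected + np.pi) % (2 * np.pi) - np.pi
        assert dphi == pytest.approx(wrapped, abs=1e-3)

    def test_energy_conservation_through_heterogeneous_volume(self, desk_labels, chromatin_params):
        from onloptics.phantom import assign_chromocenters, smooth_and_embed

        vol = smooth_and_embed(
            assign_chromocenters(desk_labels, chromatin_params, seed=1), chromatin_params
        )
        f = propagate(vol, n0=chromatin_params.n0)
        assert f.total_power / vol.ri.shape[1] / vol.ri.shape[2] == pytest.approx(1.0, abs=1e-3)

    def test_single_weak_sphere_far_field_matches_mie_phase_function(self):
        """Scattered far field of a 2 um, dn=0.025 sphere agrees with the Mie
        oracle (cosine similarity >= 0.9 over theta <= 30 deg)."""
        vol = sphere_volume()
        f_s = propagate(vol)
        f_h = propagate(homogeneous(vol.ri.shape, dx=vol.voxel_size_um))
        scattered = ComplexField(
            f_s.amplitude - f_h.amplitude, vol.voxel_size_um, WAVELENGTH, N0
        )
        spec = angular_spectrum(scattered)
        sphere = SphereSpec(2.0, N0 + 0.025, N0, WAVELENGTH)
        theta = np.deg2rad(spec.theta_deg)
        expected = phase_function(sphere, theta) * np.sin(theta)  # azimuthal integration
        sel = spec.theta_deg <= 30
        a, b = spec.power[sel], expected[sel]
        cos_sim = float(a @ b / np.sqrt((a @ a) * (b @ b)))
        assert cos_sim >= 0.9

    def test_grid_refinement_stability_of_large_angle_fraction(self):
        """Halving the voxel size changes the single-sphere large-angle
        fraction by < 10%."""
        fracs = {}
        for dx, n, nz in ((0.166, 128, 32), (0.083, 256, 64)):
            vol = sphere_volume(dx=dx, n=n, nz=nz)
            f_s = propagate(vol)
            f_h = propagate(homogeneous(vol.ri.shape, dx=dx))
            scattered = ComplexField(f_s.amplitude - f_h.amplitude, dx, WAVELENGTH, N0)
            fracs[dx] = large_angle_fraction(angular_spectrum(scattered), 10.0)
        assert abs(fracs[0.083] - fracs[0.166]) / fracs[0.083] < 0.10

    def test_lateral_translation_leaves_angular_spectrum_unchanged(self):
        vol = sphere_volume(dx=0.166, n=128, nz=32)
        rolled = RIVolume(np.roll(vol.ri, (17, -9), axis=(1, 2)), 0.166, "rolled")
        s1 = angular_spectrum(propagate(vol))
        s2 = angular_spectrum(propagate(rolled))
        assert np.allclose(s1.power, s2.power, rtol=1e-5, atol=1e-6 * s1.total_power)

    def test_nonfinite_volume_rejected(self):
        v = np.full((4, 16, 16), N0, dtype=np.float32)
        v[2, 3, 3] = np.nan
        with pytest.raises(InvalidInputError):
            propagate(_make_raw(v))

    def test_memory_budget_enforced(self):
        with pytest.raises(ResourceError):
            propagate(homogeneous((8, 64, 64)), memory_budget_bytes=1000)

    def test_absorbing_apron_removes_edge_energy_only(self):
        vol = sphere_volume(dx=0.166, n=128, nz=32)
        f = propagate(vol, absorbing_apron=True)
        # plane wave hits the apron everywhere, so power drops, but the
        # result stays finite and structured
        assert 0 < f.total_power < 128 * 128


def _make_raw(arr):
    """Bypass RIVolume finiteness validation to exercise propagate's check."""
    obj = RIVolume.__new__(RIVolume)
    obj.ri = arr
    obj.voxel_size_um = 0.166
    obj.model = "raw"
    obj.seed = None
    obj.chromocenter_counts = {}
    obj.smoothed = False
    return obj


class TestAngularSpectrum:
    def test_plane_wave_power_in_zero_bin(self):
        f = propagate(homogeneous((8, 64, 64)))
        spec = angular_spectrum(f)
        assert spec.power[0] / spec.total_power > 1 - 1e-6

    def test_sinusoidal_phase_grating_diffraction_orders(self):
        """A shallow phase grating puts the +-1 orders at the grating angle."""
        n, dx = 256, 0.083
        period_px = 16
        x = np.arange(n)
        field = np.exp(1j * 0.2 * np.sin(2 * np.pi * x / period_px))[None, :] * np.ones((n, 1))
        f = ComplexField(field.astype(np.complex64), dx, WAVELENGTH, N0)
        spec = angular_spectrum(f)
        lam_um = WAVELENGTH * 1e-3
        theta_1 = np.degrees(np.arcsin(lam_um / (period_px * dx) / N0))
        order_bin = np.argmin(np.abs(spec.theta_deg - theta_1))
        scattered = spec.power.copy()
        scattered[0] = 0
        assert abs(np.argmax(scattered) - order_bin) <= 1

    def test_parseval_binned_power_equals_spatial_sum(self):
        rng = np.random.default_rng(0)
        amp = (rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))).astype(np.complex64)
        # keep the field band-limited below the evanescent cutoff
        f = ComplexField(amp, 0.5, WAVELENGTH, N0)
        spec = angular_spectrum(f)
        # dx=0.5 um: max representable frequency 1 /um < n0/lambda = 2.66 /um,
        # so nothing is evanescent and the sums must match exactly
        assert spec.power.sum() == pytest.approx(f.total_power, rel=1e-6)
        assert spec.total_power == pytest.approx(f.total_power, rel=1e-6)


class TestLargeAngleFraction:
    def test_plane_wave_fraction_negligible(self):
        spec = angular_spectrum(propagate(homogeneous((8, 64, 64))))
        assert large_angle_fraction(spec) < 1e-4

    def test_synthetic_isotropic_spectrum_solid_angle_ratio(self):
        """For power uniform per solid angle over the forward hemisphere the
        >30 deg fraction equals the analytic solid-angle ratio cos(30)."""
        theta = np.arange(0.5, 90.0, 1.0)
        # solid angle of a 1-degree annulus ~ sin(theta) dtheta
        power = np.sin(np.deg2rad(theta))
        from onloptics.bpm import AngularSpectrum

        spec = AngularSpectrum(theta, power, float(power.sum()))
        expected = np.cos(np.deg2rad(30))  # fraction of hemisphere beyond 30 deg
        assert large_angle_fraction(spec, 30.0) == pytest.approx(expected, abs=0.01)

    def test_invalid_threshold_rejected(self):
        spec = angular_spectrum(propagate(homogeneous((4, 32, 32))))
        with pytest.raises(InvalidInputError):
            large_angle_fraction(spec, 95.0)

    def test_side_scattering_cross_section_scales_with_area(self):
        spec = angular_spectrum(propagate(homogeneous((4, 32, 32))))
        assert side_scattering_cross_section(spec, 100.0) == pytest.approx(
            large_angle_fraction(spec) * 100.0
        )


class TestCompareModels:
    def test_zero_contrast_params_give_identical_spectra(self, desk_labels):
        params = ChromatinParams(n1=1.36, n2=1.36, n0=1.33, smoothing_sigma=1.0)
        small = _crop_labels(desk_labels, (48, 96, 96))
        rep = compare_models(small, params, seed=3)
        assert rep.ratio_chromocenter_over_inverted == pytest.approx(1.0, rel=1e-3)
        assert np.allclose(
            rep.spectrum_inverted.power, rep.spectrum_chromocenter.power, rtol=1e-3,
            atol=1e-9 * rep.spectrum_inverted.total_power,
        )

    def test_chromocenter_architecture_scatters_more_to_large_angles(self, paired_report):
        """Key directional result on identical geometry: the multi-chromocenter
        ONL sends a larger fraction of light beyond 30 degrees."""
        assert paired_report.fraction_chromocenter > paired_report.fraction_inverted
        assert paired_report.ratio_chromocenter_over_inverted > 1.0

    def test_report_is_deterministic_and_serializable(self, desk_labels, chromatin_params):
        small = _crop_labels(desk_labels, (48, 96, 96))
        r1 = compare_models(small, chromatin_params, seed=5)
        r2 = compare_models(small, chromatin_params, seed=5)
        assert r1.fraction_chromocenter == r2.fraction_chromocenter
        d = r1.to_dict()
        assert set(d) >= {"fraction_inverted", "fraction_chromocenter", "seed"}


def _crop_labels(labels, shape):
    from onloptics.phantom import LabeledVolume

    sub = labels.labels[: shape[0], : shape[1], : shape[2]].copy()
    # drop nuclei cut by the crop so masks stay whole
    full = labels.labels
    for k in np.unique(sub[sub > 0]):
        if (full == k).sum() != (sub == k).sum():
            sub[sub == k] = 0
    return LabeledVolume(sub, labels.voxel_size_um)


class TestGaussianProbe:
    def test_probe_is_periodic_and_centered(self):
        p = gaussian_probe((64, 64), 0.166, 1.5, (10, 50))
        assert np.abs(p[10, 50]) == pytest.approx(1.0)
        assert p.shape == (64, 64)
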