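"""Optical-quality analytics: contrast fitting, MTF, Strehl, PSF, FACS, AULC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onloptics.errors import InvalidInputError
from onloptics.mie import SphereSpec, mie_efficiencies
from onloptics.quality import (
    CSCurve,
    MTFCurve,
    StripeSeries,
    aulc,
    diffuse_transmission,
    mtf_curve,
    psf_metrics,
    scattering_to_mtf,
    strehl_ratio,
    stripe_contrast,
    volume_specific_scattering,
)


def stripe_image(contrast, freq_cpum, shape=(64, 256), pixel=1.0, mean=100.0, phase=0.3):
    x = np.arange(shape[1]) * pixel
    row = mean * (1 + contrast * np.sin(2 * np.pi * freq_cpum * x + phase))
    return np.broadcast_to(row, shape).copy()


class TestStripeContrast:
    def test_recovers_constructed_contrast(self):
        img = stripe_image(0.40, 0.05)
        fit = stripe_contrast(img, 1.0, 0.05)
        assert fit.contrast == pytest.approx(0.400, abs=0.004)
        assert not fit.low_confidence

    def test_uniform_veil_halves_modulation(self):
        img = stripe_image(0.40, 0.05)
        veiled = 0.5 * img + 0.5 * img.mean()
        fit = stripe_contrast(veiled, 1.0, 0.05)
        assert fit.contrast == pytest.approx(0.200, abs=0.004)

    def test_frequency_refines_near_hint(self):
        img = stripe_image(0.3, 0.0515)
        fit = stripe_contrast(img, 1.0, 0.05)  # 3% off hint
        assert fit.frequency_cpum == pytest.approx(0.0515, rel=1e-3)

    def test_flat_image_flagged_low_confidence(self):
        rng = np.random.default_rng(0)
        img = np.full((32, 256), 100.0) + rng.normal(0, 0.01, (32, 256))
        fit = stripe_contrast(img, 1.0, 0.05)
        assert fit.low_confidence and fit.contrast == 0.0

    def test_fewer_than_two_periods_rejected(self):
        img = stripe_image(0.4, 0.005, shape=(16, 128))
        with pytest.raises(InvalidInputError):
            stripe_contrast(img, 1.0, 0.005)

    def test_baseline_contrast_correction(self):
        img = stripe_image(0.40, 0.05)
        fit = stripe_contrast(img, 1.0, 0.05, baseline=(110.0, 90.0))  # baseline contrast 0.1
        assert fit.contrast == pytest.approx(0.30, abs=0.005)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        contrast=st.floats(0.02, 1.0),
        freq=st.floats(0.02, 0.2),
    )
    def test_unbiased_on_noise_free_stripes(self, contrast, freq):
        """MTF estimation bias < 0.5% across frequencies and contrasts."""
        fit = stripe_contrast(stripe_image(contrast, freq), 1.0, freq)
        assert fit.contrast == pytest.approx(contrast, rel=5e-3)


class TestMTFCurve:
    def freqs(self):
        return np.array([0.02, 0.05, 0.1, 0.2])

    def series(self, contrasts, freqs=None):
        freqs = self.freqs() if freqs is None else freqs
        imgs = np.stack([stripe_image(c, f) for c, f in zip(contrasts, freqs)])
        return StripeSeries(imgs, freqs, 1.0)

    def test_sample_equals_reference_gives_unity(self):
        s = self.series([0.4, 0.4, 0.4, 0.4])
        curve = mtf_curve(s, s)
        assert np.allclose(curve.mtf, 1.0, atol=1e-6)

    def test_ratio_and_setup_normalization_arithmetic(self):
        sample = self.series([0.4] * 4)
        reference = self.series([0.8] * 4)
        curve = mtf_curve(sample, reference)
        assert np.allclose(curve.mtf, 0.5, atol=1e-3)
        setup = MTFCurve(self.freqs() * 31.0, np.full(4, 0.8))
        curve2 = mtf_curve(sample, reference, setup=setup)
        assert np.allclose(curve2.mtf, 0.625, atol=2e-3)

    def test_frequency_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            mtf_curve(self.series([0.4] * 4), self.series([0.4] * 4, self.freqs() * 1.5))

    def test_recovers_exponential_mtf_profile(self):
        freqs = self.freqs()
        profile = np.exp(-freqs / 0.1)
        sample = self.series(0.8 * profile)
        reference = self.series([0.8] * 4)
        curve = mtf_curve(sample, reference)
        assert np.allclose(curve.mtf, profile, rtol=0.03)


class TestStrehl:
    def flat(self, value, hi=3.0):
        f = np.linspace(0.0, hi, 31)
        return MTFCurve(f, np.full_like(f, value))

    def test_identity(self):
        r = strehl_ratio(self.flat(0.7), self.flat(0.7))
        assert r.strehl == pytest.approx(1.0, abs=1e-12)

    def test_linearity(self):
        r = strehl_ratio(self.flat(0.35), self.flat(0.7))
        assert r.strehl == pytest.approx(0.5, abs=1e-12)

    def test_band_restriction_matches_integral_definition(self):
        """Hand-built curves: M(xi)=1-xi/4 vs flat reference over 0-2 cpd.
        SR = int_0^2 xi (1-xi/4) dxi / int_0^2 xi dxi = (2 - 2/3)/2 = 2/3."""
        f = np.linspace(0.0, 3.0, 301)
        m = MTFCurve(f, 1 - f / 4)
        ref = MTFCurve(f, np.ones_like(f))
        r = strehl_ratio(m, ref, band_cpd=(0.0, 2.0))
        assert r.strehl == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_band_outside_data_rejected(self):
        with pytest.raises(InvalidInputError):
            strehl_ratio(self.flat(1.0, hi=1.0), self.flat(1.0, hi=1.0), band_cpd=(0, 2))


class TestPSFMetrics:
    def gaussian_spot(self, sigma_px=2.0, shape=(128, 128), amplitude=1000.0):
        yy, xx = np.indices(shape)
        r2 = (yy - shape[0] // 2) ** 2 + (xx - shape[1] // 2) ** 2
        return amplitude * np.exp(-r2 / (2 * sigma_px**2))

    def test_gaussian_fwhm_analytic(self):
        m = psf_metrics(self.gaussian_spot(), pixel_size_um=1.0, roi_um=60.0)
        assert m.fwhm_um == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0, abs=0.1)

    def test_intensity_scale_invariance(self):
        a = psf_metrics(self.gaussian_spot(amplitude=1.0), 1.0, roi_um=60.0)
        b = psf_metrics(self.gaussian_spot(amplitude=5.0), 1.0, roi_um=60.0)
        assert a.peak_intensity == pytest.approx(b.peak_intensity, rel=1e-12)
        assert a.fwhm_um == b.fwhm_um

    def test_non_positive_integral_rejected(self):
        with pytest.raises(InvalidInputError):
            psf_metrics(np.zeros((32, 32)), 1.0)


class TestDiffuseTransmission:
    def test_identity_and_half(self):
        ref = np.full((16, 16), 200.0)
        assert diffuse_transmission(ref, ref) == pytest.approx(1.0)
        assert diffuse_transmission(0.5 * ref, ref) == pytest.approx(0.5)

    def test_dark_offset_invariance(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(50, 150, (16, 16))
        smp = 0.7 * ref
        t0 = diffuse_transmission(smp, ref, 0.0)
        t1 = diffuse_transmission(smp + 10.0, ref + 10.0, 10.0)
        assert t1 == pytest.approx(t0, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            diffuse_transmission(np.ones((4, 4)), np.ones((5, 5)))


class TestScatteringToMTF:
    BEHAVIORAL_CPUM = np.linspace(1e-4, 0.5 / 31.0, 25)  # 0-0.5 cycles/deg

    def test_zero_optical_depth_gives_unity(self):
        m = scattering_to_mtf(0.9, 1.0, 0.0, 2.0, 50.0, self.BEHAVIORAL_CPUM)
        assert np.allclose(m.mtf, 1.0)

    def test_monotone_non_increasing_in_frequency(self):
        m = scattering_to_mtf(0.95, 1.0, 0.05, 2.0, 50.0, np.linspace(1e-4, 0.2, 60))
        assert np.all(np.diff(m.mtf) <= 1e-12)
        assert m.mtf[0] == pytest.approx(1.0, abs=1e-4)

    def test_higher_anisotropy_preserves_more_contrast(self):
        """At fixed optical depth, more forward-directed scattering (larger g)
        gives a higher MTF at every nonzero frequency."""
        freqs = np.linspace(1e-3, 0.02, 40)  # below the saturation floor
        prev = None
        for g in [0.5, 0.8, 0.9, 0.95, 0.99]:
            m = scattering_to_mtf(g, 1.0, 0.05, 2.0, 50.0, freqs).mtf
            if prev is not None:
                assert np.all(m >= prev - 1e-12)
                assert m[-1] > prev[-1]
            prev = m

    def test_outer_segments_negligible_vs_nuclei(self):
        """Photoreceptor outer segments (modelled as the equal-volume sphere
        of a 1.6 x 25 um cylinder, core n=1.42, over their 25 um anatomical
        layer) barely touch the MTF at behavioral frequencies, while a
        multi-chromocenter nuclear layer over the 55 um ONL is visibly
        worse."""
        v_cyl = np.pi * 0.8**2 * 25.0
        d_os = (6 * v_cyl / np.pi) ** (1 / 3)
        e_os = mie_efficiencies(SphereSpec(d_os, 1.42, 1.33, 500.0))
        rho_os = 0.01  # one OS per (2 um)^2 lattice cell
        m_os = scattering_to_mtf(e_os.g, e_os.qsca, rho_os, d_os, 25.0, self.BEHAVIORAL_CPUM)
        # nuclei: chromocenters at the heterochromatin volume fraction 0.3351
        d_cc = 2.22  # one of 8 chromocenters holding half a 92 um^3 nucleus
        e_cc = mie_efficiencies(SphereSpec(d_cc, 1.382, 1.357, 500.0))
        v_cc = np.pi / 6 * d_cc**3
        rho_cc = 0.3351 / v_cc
        m_cc = scattering_to_mtf(e_cc.g, e_cc.qsca, rho_cc, d_cc, 55.0, self.BEHAVIORAL_CPUM)
        assert np.all(m_os.mtf >= 0.95)
        assert m_cc.mtf.min() < m_os.mtf.min()

    def test_negative_density_rejected(self):
        with pytest.raises(InvalidInputError):
            scattering_to_mtf(0.9, 1.0, -0.1, 2.0, 50.0, self.BEHAVIORAL_CPUM)


class TestVolumeSpecificScattering:
    def test_single_event_arithmetic(self):
        df = pd.DataFrame({"fsc_area": [100.0], "ssc_area": [200.0], "label": ["a"]})
        events, summary = volume_specific_scattering(df)
        assert events["vss"].iloc[0] == pytest.approx(2.0)

    def test_homogeneity_in_forward_scatter(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "fsc_area": rng.uniform(50, 150, 100),
                "ssc_area": rng.uniform(50, 150, 100),
                "label": "a",
            }
        )
        _, s1 = volume_specific_scattering(df)
        df2 = df.assign(fsc_area=2 * df["fsc_area"])
        _, s2 = volume_specific_scattering(df2)
        assert s2["median"].iloc[0] == pytest.approx(s1["median"].iloc[0] / 2, rel=1e-12)

    def test_nonpositive_fsc_dropped_and_counted(self):
        df = pd.DataFrame(
            {"fsc_area": [100.0, 0.0, -5.0], "ssc_area": [200.0, 1.0, 1.0], "label": "a"}
        )
        events, summary = volume_specific_scattering(df)
        assert len(events) == 1
        assert summary["n_dropped"].iloc[0] == 2


class TestAULC:
    def test_constant_sensitivity_rectangle(self):
        c = CSCurve(np.array([0.1, 0.3]), np.array([0.1, 0.1]))  # sensitivity 10
        assert aulc(c) == pytest.approx(np.log10(10) * 0.2, rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(factor=st.floats(1.5, 9.0))
    def test_log_linearity_under_sensitivity_scaling(self, factor):
        """Multiplying all sensitivities by k adds log10(k)*(f2-f1) to the AULC."""
        f = np.array([0.05, 0.15, 0.3])
        thr = np.array([0.5, 0.2, 0.4])
        base = aulc(CSCurve(f, thr))
        scaled = aulc(CSCurve(f, thr / factor))
        assert scaled - base == pytest.approx(np.log10(factor) * (f[-1] - f[0]), rel=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(InvalidInputError):
            aulc(CSCurve(np.array([0.1]), np.array([0.5])))

    def test_sensitivity_floored_at_one(self):
        c = CSCurve(np.array([0.1, 0.2]), np.array([1.0, 1.0]))  # sensitivity exactly 1
        assert aulc(c) == 0.0
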