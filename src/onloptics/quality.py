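"""Image-quality analytics: MTF, Strehl ratio, PSF, transmission, FACS, AULC.

The measurement concepts mirror an ex-vivo micro-projection experiment:
sinusoidal stripe stacks of increasing spatial frequency are projected
through a sample and the surviving modulation contrast is read out by a
sine fit; the ratio of transmitted to projected contrast per frequency is
the modulation transfer function (MTF); the frequency-weighted area under
the MTF over a behaviorally relevant band summarizes optical quality as a
relative Strehl ratio; point-stimulus images separate scattering-induced
veil (normalized peak intensity) from resolution (PSF FWHM).

Spatial frequencies are carried in cycles/um; conversion to cycles/degree
of visual angle uses a configurable retinal magnification (um per degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InvalidInputError

__all__ = [
    "StripeSeries",
    "MTFCurve",
    "StrehlResult",
    "PSFMetrics",
    "CSCurve",
    "ContrastFit",
    "stripe_contrast",
    "mtf_curve",
    "strehl_ratio",
    "psf_metrics",
    "diffuse_transmission",
    "scattering_to_mtf",
    "volume_specific_scattering",
    "aulc",
]

#: Retinal magnification used to convert cycles/um to cycles/degree of
#: visual angle (mouse eye scale, configurable per call).
DEFAULT_UM_PER_DEG = 31.0


@dataclass
class StripeSeries:
    """A stack of sinusoidal stripe images, one spatial frequency per image."""

    images: np.ndarray  # (n, ny, nx)
    frequencies_cpum: np.ndarray  # cycles/um per image
    pixel_size_um: float
    modulation_axis: int = -1  # image axis carrying the sinusoid

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.frequencies_cpum = np.asarray(self.frequencies_cpum, dtype=np.float64)
        if self.images.ndim != 3:
            raise InvalidInputError("images must be a (n, ny, nx) stack")
        if self.images.shape[0] != self.frequencies_cpum.size:
            raise InvalidInputError("one frequency per image required")
        if np.any(self.images < 0):
            raise InvalidInputError("intensities must be non-negative")

    def frequencies_cpd(self, um_per_deg: float = DEFAULT_UM_PER_DEG) -> np.ndarray:
        return self.frequencies_cpum * um_per_deg


@dataclass
class MTFCurve:
    """Contrast transfer vs spatial frequency."""

    frequencies_cpd: np.ndarray
    mtf: np.ndarray
    frequencies_cpum: np.ndarray | None = None
    ci95: np.ndarray | None = None  # optional (n, 2) per-frequency interval
    floored: np.ndarray | None = None  # True where a negative ratio was floored to 0

    def __post_init__(self):
        self.frequencies_cpd = np.asarray(self.frequencies_cpd, dtype=np.float64)
        self.mtf = np.asarray(self.mtf, dtype=np.float64)
        if np.any(np.diff(self.frequencies_cpd) <= 0):
            raise InvalidInputError("frequencies must be strictly increasing")
        if np.any(self.mtf < 0):
            raise InvalidInputError("mtf values must be >= 0")

    def to_dataframe(self) -> pd.DataFrame:
        d = {"frequency_cpd": self.frequencies_cpd, "mtf": self.mtf}
        if self.frequencies_cpum is not None:
            d["frequency_cpum"] = self.frequencies_cpum
        if self.ci95 is not None:
            d["ci_lo"] = self.ci95[:, 0]
            d["ci_hi"] = self.ci95[:, 1]
        return pd.DataFrame(d)


@dataclass(frozen=True)
class StrehlResult:
    strehl: float
    band_cpd: tuple[float, float]
    reference_id: str = ""


@dataclass(frozen=True)
class PSFMetrics:
    peak_intensity: float  # fraction of field-of-view intensity at the brightest pixel
    fwhm_um: float
    centroid_um: tuple[float, float]


@dataclass
class CSCurve:
    """Contrast-sensitivity curve: threshold contrast per spatial frequency."""

    frequencies_cpd: np.ndarray
    threshold_contrast: np.ndarray

    def __post_init__(self):
        self.frequencies_cpd = np.asarray(self.frequencies_cpd, dtype=np.float64)
        self.threshold_contrast = np.asarray(self.threshold_contrast, dtype=np.float64)
        if np.any((self.threshold_contrast <= 0) | (self.threshold_contrast > 1)):
            raise InvalidInputError("threshold contrasts must lie in (0, 1]")

    @property
    def sensitivity(self) -> np.ndarray:
        return 1.0 / self.threshold_contrast


@dataclass(frozen=True)
class ContrastFit:
    i_max: float
    i_min: float
    contrast: float
    frequency_cpum: float
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Stripe contrast and MTF
# ---------------------------------------------------------------------------

def stripe_contrast(
    image: np.ndarray,
    pixel_size_um: float,
    frequency_hint_cpum: float,
    modulation_axis: int = -1,
    baseline: tuple[float, float] | None = None,
) -> ContrastFit:
    """Michelson contrast of a sinusoidal stripe image by sine fitting.

    The image is averaged along the axis orthogonal to the modulation and
    the resulting 1D profile is fit to ``c + a sin(2 pi f x + phi)`` with
    the frequency allowed to refine within +-5% of the hint.  Contrast is
    ``(Imax - Imin) / (Imax + Imin)``.  If ``baseline`` (I0_max, I0_min)
    from a dark/reference frame is given, its contrast is subtracted
    (baseline-contrast correction); negative corrected values are floored
    at 0 and flagged.

    A fitted amplitude indistinguishable from the noise floor returns
    contrast 0 with ``low_confidence=True``; fewer than two full periods in
    the field raises ``InvalidInputError``.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise InvalidInputError("image must be 2D")
    if np.any(img < 0):
        raise InvalidInputError("intensities must be non-negative")
    if frequency_hint_cpum <= 0:
        raise InvalidInputError("frequency hint must be positive")
    axis = modulation_axis % 2
    profile = img.mean(axis=1 - axis)
    n = profile.size
    length_um = n * pixel_size_um
    if frequency_hint_cpum * length_um < 2.0:
        raise InvalidInputError(
            f"fewer than two stripe periods visible "
            f"({frequency_hint_cpum * length_um:.2f} at hint frequency)"
        )

    x = np.arange(n) * pixel_size_um
    offset0 = float(profile.mean())
    # seed amplitude/phase from the Fourier component at the hint frequency
    ph = np.exp(-2j * np.pi * frequency_hint_cpum * x)
    comp = 2.0 * np.mean((profile - offset0) * ph)
    amp0 = abs(comp)
    phi0 = np.angle(comp) + np.pi / 2  # sin convention

    def model(xx, c, a, f, phi):
        return c + a * np.sin(2 * np.pi * f * xx + phi)

    f_lo, f_hi = 0.95 * frequency_hint_cpum, 1.05 * frequency_hint_cpum
    try:
        popt, pcov = curve_fit(
            model,
            x,
            profile,
            p0=[offset0, amp0, frequency_hint_cpum, phi0],
            bounds=([0.0, 0.0, f_lo, -2 * np.pi], [np.inf, np.inf, f_hi, 2 * np.pi]),
            maxfev=10000,
        )
    except RuntimeError:
        return ContrastFit(offset0, offset0, 0.0, frequency_hint_cpum, low_confidence=True)
    c, a, f_fit, _ = popt
    a_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    if a <= 3.0 * a_err:
        # amplitude consistent with the noise floor
        return ContrastFit(c, c, 0.0, f_fit, low_confidence=True)
    i_max, i_min = c + a, max(c - a, 0.0)
    contrast = (i_max - i_min) / (i_max + i_min) if (i_max + i_min) > 0 else 0.0
    if baseline is not None:
        b_max, b_min = baseline
        if b_max + b_min > 0:
            contrast -= (b_max - b_min) / (b_max + b_min)
    low_conf = False
    if contrast < 0:
        contrast, low_conf = 0.0, True
    return ContrastFit(i_max, i_min, float(contrast), float(f_fit), low_conf)


def mtf_curve(
    sample: StripeSeries,
    reference: StripeSeries,
    setup: StripeSeries | MTFCurve | None = None,
    um_per_deg: float = DEFAULT_UM_PER_DEG,
) -> MTFCurve:
    """MTF as the per-frequency ratio of sample to reference stripe contrast.

    ``MTF(xi) = C_sample(xi) / C_reference(xi)``, optionally divided by the
    MTF of the optical setup alone (given either as a stripe series or a
    precomputed curve).  Negative ratios are floored at 0 and flagged.
    """
    if sample.frequencies_cpum.size != reference.frequencies_cpum.size or not np.allclose(
        sample.frequencies_cpum, reference.frequencies_cpum
    ):
        raise InvalidInputError("sample and reference frequency grids must match")
    freqs = sample.frequencies_cpum

    def contrasts(series: StripeSeries) -> np.ndarray:
        return np.array(
            [
                stripe_contrast(
                    series.images[i], series.pixel_size_um, freqs[i], series.modulation_axis
                ).contrast
                for i in range(freqs.size)
            ]
        )

    c_s = contrasts(sample)
    c_r = contrasts(reference)
    if np.any(c_r <= 0):
        raise InvalidInputError("reference contrast vanished at some frequency")
    mtf = c_s / c_r
    if setup is not None:
        if isinstance(setup, StripeSeries):
            if not np.allclose(setup.frequencies_cpum, freqs):
                raise InvalidInputError("setup frequency grid must match")
            c_setup = contrasts(setup) / np.ones_like(freqs)
            setup_mtf = c_setup
        else:
            setup_mtf = np.interp(freqs * um_per_deg, setup.frequencies_cpd, setup.mtf)
        if np.any(setup_mtf <= 0):
            raise InvalidInputError("setup MTF must be positive over the frequency grid")
        mtf = mtf / setup_mtf
    floored = mtf < 0
    mtf = np.where(floored, 0.0, mtf)
    return MTFCurve(
        frequencies_cpd=freqs * um_per_deg,
        mtf=mtf,
        frequencies_cpum=freqs,
        floored=floored,
    )


def strehl_ratio(
    mtf: MTFCurve,
    reference: MTFCurve,
    band_cpd: tuple[float, float] = (0.0, 2.0),
    reference_id: str = "",
) -> StrehlResult:
    """Relative Strehl ratio: frequency-weighted area under the MTF.

    ``SR = int xi M(xi) dxi / int xi M_ref(xi) dxi`` over ``band_cpd``
    (trapezoid on a merged grid).  Equals 1 when the curves coincide over
    the band and scales linearly in the sample MTF.
    """
    lo, hi = band_cpd
    if not (hi > lo >= 0):
        raise InvalidInputError("band must satisfy 0 <= lo < hi")
    for curve in (mtf, reference):
        if curve.frequencies_cpd[0] > lo + 1e-9 or curve.frequencies_cpd[-1] < hi - 1e-9:
            raise InvalidInputError(
                f"curve covers [{curve.frequencies_cpd[0]:.3g}, "
                f"{curve.frequencies_cpd[-1]:.3g}] cpd, not the band [{lo}, {hi}]"
            )
    grid = np.union1d(mtf.frequencies_cpd, reference.frequencies_cpd)
    grid = np.union1d(grid[(grid >= lo) & (grid <= hi)], [lo, hi])
    num = np.trapezoid(grid * np.interp(grid, mtf.frequencies_cpd, mtf.mtf), grid)
    den = np.trapezoid(grid * np.interp(grid, reference.frequencies_cpd, reference.mtf), grid)
    if den <= 0:
        raise InvalidInputError("reference MTF area vanishes over the band")
    return StrehlResult(strehl=float(num / den), band_cpd=(lo, hi), reference_id=reference_id)


# ---------------------------------------------------------------------------
# PSF and transmission
# ---------------------------------------------------------------------------

def psf_metrics(image: np.ndarray, pixel_size_um: float, roi_um: float = 40.0) -> PSFMetrics:
    """Peak and width of a point-stimulus image.

    The image is normalized by its integral over the full field of view
    (so ``peak_intensity`` is the fraction of all light landing on the
    brightest ROI pixel, the veil-sensitive quantity), then the central
    ``roi_um`` square is cropped and the FWHM read off the radially
    averaged profile around the intensity centroid by linear interpolation
    at half peak.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise InvalidInputError("image must be 2D")
    total = img.sum()
    if total <= 0:
        raise InvalidInputError("image integral must be positive")
    norm = img / total

    half_px = int(round(roi_um / (2 * pixel_size_um)))
    cy0, cx0 = np.array(img.shape) // 2
    sl = (
        slice(max(cy0 - half_px, 0), min(cy0 + half_px, img.shape[0])),
        slice(max(cx0 - half_px, 0), min(cx0 + half_px, img.shape[1])),
    )
    roi = norm[sl]
    peak = float(roi.max())

    yy, xx = np.indices(roi.shape)
    w = roi / roi.sum()
    cy = float((yy * w).sum())
    cx = float((xx * w).sum())
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    r_max = int(np.floor(r.max()))
    prof = np.empty(r_max)
    r_centers = np.empty(r_max)
    for k in range(r_max):
        sel = (r >= k) & (r < k + 1)
        prof[k] = roi[sel].mean()
        r_centers[k] = r[sel].mean()
    half = peak / 2.0
    below = np.nonzero(prof < half)[0]
    if below.size == 0:
        raise InvalidInputError("profile never falls below half peak inside the ROI")
    k = int(below[0])
    if k == 0:
        hwhm_px = 0.5 * r_centers[0]
    else:
        frac = (prof[k - 1] - half) / (prof[k - 1] - prof[k])
        hwhm_px = r_centers[k - 1] + frac * (r_centers[k] - r_centers[k - 1])
    return PSFMetrics(
        peak_intensity=peak,
        fwhm_um=float(2.0 * hwhm_px * pixel_size_um),
        centroid_um=(
            (sl[0].start + cy) * pixel_size_um,
            (sl[1].start + cx) * pixel_size_um,
        ),
    )


def diffuse_transmission(
    sample_img: np.ndarray, reference_img: np.ndarray, dark_img: np.ndarray | float = 0.0
) -> float:
    """Fractional diffuse transmission from integrated intensities.

    ``T = sum(sample - dark) / sum(reference - dark)`` after dark-frame
    subtraction; insensitive to a common additive offset.
    """
    s = np.asarray(sample_img, dtype=np.float64)
    r = np.asarray(reference_img, dtype=np.float64)
    if s.shape != r.shape:
        raise InvalidInputError("sample and reference shapes must match")
    d = np.asarray(dark_img, dtype=np.float64)
    denom = (r - d).sum()
    if denom <= 0:
        raise InvalidInputError("reference integral must be positive after dark subtraction")
    return float((s - d).sum() / denom)


# ---------------------------------------------------------------------------
# Scattering-parameters-to-MTF conversion
# ---------------------------------------------------------------------------

def scattering_to_mtf(
    g: float,
    qsca: float,
    number_density_per_um3: float,
    diameter_um: float,
    thickness_um: float,
    frequencies_cpum,
    um_per_deg: float = DEFAULT_UM_PER_DEG,
) -> MTFCurve:
    """Convert single-particle scattering parameters into a layer MTF.

    Small-angle transfer model: a fraction ``exp(-tau)`` of the light
    crosses unscattered (tau = rho Csca L, the scattering optical depth)
    and retains full contrast; the scattered remainder is blurred by a
    Gaussian kernel whose spatial spread is ``sigma = theta_g * L / 2``
    with ``theta_g = arccos(g)`` the characteristic scattering angle and
    ``L/2`` the mean remaining path after a scattering event:

        MTF(xi) = exp(-tau) + (1 - exp(-tau)) exp(-2 (pi sigma xi)^2)

    MTF(0) = 1, non-increasing in xi, and increasing in g at fixed tau.
    The kernel is a documented closed-form stand-in for a full
    small-angle-scattering transfer theory; it is used for directional
    comparisons (e.g. nuclei vs photoreceptor outer segments), not for
    absolute MTF prediction.
    """
    freqs = np.asarray(frequencies_cpum, dtype=np.float64)
    if not (-1.0 <= g <= 1.0):
        raise InvalidInputError("anisotropy g must lie in [-1, 1]")
    csca = qsca * np.pi * (diameter_um / 2.0) ** 2
    tau = number_density_per_um3 * csca * thickness_um
    if tau < 0:
        raise InvalidInputError("optical depth must be non-negative")
    theta_g = np.arccos(np.clip(g, -1.0, 1.0))
    sigma_um = theta_g * thickness_um / 2.0
    ballistic = np.exp(-tau)
    mtf = ballistic + (1.0 - ballistic) * np.exp(-2.0 * (np.pi * sigma_um * freqs) ** 2)
    return MTFCurve(frequencies_cpd=freqs * um_per_deg, mtf=mtf, frequencies_cpum=freqs)


# ---------------------------------------------------------------------------
# FACS and behavior
# ---------------------------------------------------------------------------

def volume_specific_scattering(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side scattering normalized by size for FACS-like event tables.

    Expects columns ``fsc_area``, ``ssc_area``, ``label``.  The per-event
    metric is ``ssc_area / fsc_area`` (forward scatter as the size/volume
    proxy).  Events with non-positive forward scatter are dropped and
    counted.  Returns (events with a ``vss`` column, per-label summary
    with median, IQR and dropped-event counts).
    """
    df = records.copy()
    for col in ("fsc_area", "ssc_area", "label"):
        if col not in df.columns:
            raise InvalidInputError(f"records must have a '{col}' column")
    bad = df["fsc_area"] <= 0
    dropped = df[bad].groupby("label").size()
    df = df[~bad].copy()
    if df.empty:
        raise InvalidInputError("no events with positive forward scatter")
    df["vss"] = df["ssc_area"] / df["fsc_area"]
    summary = df.groupby("label")["vss"].agg(
        median="median",
        iqr=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
        n="size",
    )
    summary["n_dropped"] = dropped.reindex(summary.index, fill_value=0)
    return df, summary.reset_index()


def aulc(curve: CSCurve, floor_sensitivity: float = 1.0) -> float:
    """Area under the log10 contrast-sensitivity curve.

    Trapezoidal integral of ``log10(max(1/threshold, floor))`` against
    spatial frequency (linear axis) over the measured range.  Requires at
    least two frequencies.
    """
    f = curve.frequencies_cpd
    if f.size < 2:
        raise InvalidInputError("AULC needs at least two frequencies")
    if np.any(np.diff(f) <= 0):
        raise InvalidInputError("frequencies must be strictly increasing")
    sens = np.maximum(curve.sensitivity, floor_sensitivity)
    return float(np.trapezoid(np.log10(sens), f))
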