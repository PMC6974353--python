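"""Seeded generators for every measurement-like input the analytics consume.

Each generator returns ``(data, ground_truth)`` so recovery can be tested
against construction: stripe stacks with known contrast and veil, point
images with a known core/veil energy partition, FACS-like scatter event
tables, and optomotor staircase trial tables.  All randomness flows from
an explicit seed; identical specs give identical output.

The "veil" parameter v emulates scattering-induced diffuse background: a
fraction v of the structured light is replaced by its spatial mean (for
stripes) or spread uniformly over the field (for point images), which is
exactly how large-angle scattering degrades contrast without moving
object edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .quality import CSCurve, StripeSeries

__all__ = [
    "GeneratorSpec",
    "make_stripe_stack",
    "make_psf_image",
    "make_facs_table",
    "make_cs_trials",
    "recover_thresholds",
    "staircase_contrasts",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed and noise model for a synthetic acquisition.

    noise_model: "none", "gaussian" (additive, sd = noise_scale) or
    "poisson" (shot-like: counts drawn at ``intensity * noise_scale`` and
    rescaled, so larger noise_scale means *less* relative noise, as for a
    brighter exposure).
    """

    seed: int = 0
    noise_model: str = "none"
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise InvalidInputError(f"unknown noise model '{self.noise_model}'")
        if self.noise_scale <= 0:
            raise InvalidInputError("noise_scale must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(img: np.ndarray, spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none":
        return img
    if spec.noise_model == "gaussian":
        return np.clip(img + rng.normal(0.0, spec.noise_scale, img.shape), 0.0, None)
    return rng.poisson(np.clip(img, 0, None) * spec.noise_scale).astype(np.float64) / spec.noise_scale


def make_stripe_stack(
    frequencies_cpum,
    contrast_in: float,
    veil_v: float,
    spec: GeneratorSpec,
    shape: tuple[int, int] = (96, 256),
    pixel_size_um: float = 1.0,
    mean_intensity: float = 100.0,
    mtf_profile=None,
) -> tuple[StripeSeries, StripeSeries, dict]:
    """Synthetic stripe projection pair (sample through a veiling layer, clean reference).

    reference[i] = I0 (1 + contrast_in sin(2 pi f_i x)); the sample applies
    a per-frequency transfer ``t_i`` (``1 - veil_v`` by default, or the
    supplied ``mtf_profile``) to the modulation and then the noise model:
    sample = (1 - v) reference + v mean(reference) for the flat veil case.
    Ground truth records the imposed MTF per frequency.
    """
    freqs = np.asarray(frequencies_cpum, dtype=np.float64)
    if not (0.0 < contrast_in <= 1.0):
        raise InvalidInputError("contrast_in must be in (0, 1]")
    if not (0.0 <= veil_v < 1.0):
        raise InvalidInputError("veil fraction must be in [0, 1)")
    ny, nx = shape
    x = np.arange(nx) * pixel_size_um
    rng = spec.rng()
    if mtf_profile is None:
        transfer = np.full(freqs.size, 1.0 - veil_v)
    else:
        transfer = np.asarray(mtf_profile, dtype=np.float64)
        if transfer.shape != freqs.shape:
            raise InvalidInputError("mtf_profile must match the frequency grid")
    ref = np.empty((freqs.size, ny, nx))
    smp = np.empty_like(ref)
    for i, (f, t) in enumerate(zip(freqs, transfer)):
        clean = mean_intensity * (1.0 + contrast_in * np.sin(2 * np.pi * f * x))[None, :]
        ref[i] = np.broadcast_to(clean, (ny, nx))
        veiled = mean_intensity * (1.0 + t * contrast_in * np.sin(2 * np.pi * f * x))[None, :]
        smp[i] = _apply_noise(np.broadcast_to(veiled, (ny, nx)).copy(), spec, rng)
    truth = {
        "contrast_in": contrast_in,
        "veil_v": veil_v,
        "mtf_true": transfer,
        "frequencies_cpum": freqs,
        "seed": spec.seed,
    }
    mk = lambda a: StripeSeries(a, freqs, pixel_size_um)
    return mk(smp), mk(ref), truth


def make_psf_image(
    fwhm_um: float,
    veil_v: float,
    spec: GeneratorSpec,
    pixel_size_um: float = 0.5,
    shape: tuple[int, int] = (160, 160),
    total_energy: float = 1e6,
) -> tuple[np.ndarray, dict]:
    """Point-stimulus image: Gaussian core plus uniform veil.

    A fraction ``1 - veil_v`` of ``total_energy`` goes into a Gaussian spot
    of the requested FWHM at the field centre and ``veil_v`` is spread
    uniformly (large-angle veil), so total energy is independent of v by
    construction.
    """
    if fwhm_um <= 0:
        raise InvalidInputError("fwhm must be positive")
    if not (0.0 <= veil_v < 1.0):
        raise InvalidInputError("veil fraction must be in [0, 1)")
    ny, nx = shape
    sigma_px = fwhm_um / (2 * np.sqrt(2 * np.log(2))) / pixel_size_um
    yy, xx = np.indices((ny, nx))
    r2 = (yy - (ny - 1) / 2) ** 2 + (xx - (nx - 1) / 2) ** 2
    core = np.exp(-r2 / (2 * sigma_px**2))
    core *= (1.0 - veil_v) * total_energy / core.sum()
    img = core + veil_v * total_energy / (ny * nx)
    rng = spec.rng()
    img = _apply_noise(img, spec, rng)
    truth = {
        "fwhm_um": fwhm_um,
        "veil_v": veil_v,
        "core_energy": (1.0 - veil_v) * total_energy,
        "total_energy": total_energy,
        "seed": spec.seed,
    }
    return img, truth


def make_facs_table(populations, spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """FACS-like event table with log-normal forward/side scatter spread.

    ``populations`` is a list of dicts with keys ``label``, ``n``,
    ``fsc_median``, ``ssc_median`` and ``spread`` (log-normal sigma; 0
    gives identical events).  Medians are preserved exactly by the
    log-normal construction, so population median ratios are the ground
    truth.
    """
    rng = spec.rng()
    rows = []
    truth = {"populations": [], "seed": spec.seed}
    for pop in populations:
        n = int(pop["n"])
        if n < 1 or pop["fsc_median"] <= 0 or pop["ssc_median"] <= 0 or pop["spread"] < 0:
            raise InvalidInputError(f"invalid population spec: {pop}")
        fsc = pop["fsc_median"] * np.exp(rng.normal(0.0, pop["spread"], n))
        ssc = pop["ssc_median"] * np.exp(rng.normal(0.0, pop["spread"], n))
        rows.append(pd.DataFrame({"label": pop["label"], "fsc_area": fsc, "ssc_area": ssc}))
        truth["populations"].append(
            {
                "label": pop["label"],
                "vss_median_true": pop["ssc_median"] / pop["fsc_median"],
                "n": n,
            }
        )
    return pd.concat(rows, ignore_index=True), truth


def staircase_contrasts() -> np.ndarray:
    """Descending contrast ladder (percent/100): 5%-steps down to 10%
    absolute contrast, 2%-steps below."""
    upper = np.arange(100, 9, -5)  # 100, 95, ..., 10
    lower = np.arange(8, 1, -2)  # 8, 6, 4, 2
    return np.concatenate([upper, lower]) / 100.0


def make_cs_trials(
    threshold_curve: CSCurve,
    lapse_rate: float,
    n_trials: int,
    spec: GeneratorSpec,
) -> tuple[pd.DataFrame, dict]:
    """Optomotor-style yes/no trials on the standard contrast staircase.

    For each frequency and each ladder contrast, ``n_trials`` Bernoulli
    responses are drawn: P(yes) = 1 - lapse_rate above threshold and
    lapse_rate below (a step psychometric function with symmetric lapses).
    """
    if not (0.0 <= lapse_rate < 0.5):
        raise InvalidInputError("lapse rate must be in [0, 0.5)")
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    rng = spec.rng()
    ladder = staircase_contrasts()
    rows = []
    for f, thr in zip(threshold_curve.frequencies_cpd, threshold_curve.threshold_contrast):
        for c in ladder:
            p_yes = (1.0 - lapse_rate) if c >= thr else lapse_rate
            yes = rng.random(n_trials) < p_yes
            for resp in yes:
                rows.append((f, c, bool(resp)))
    trials = pd.DataFrame(rows, columns=["frequency_cpd", "contrast", "response"])
    truth = {
        "frequencies_cpd": np.asarray(threshold_curve.frequencies_cpd),
        "thresholds": np.asarray(threshold_curve.threshold_contrast),
        "lapse_rate": lapse_rate,
        "seed": spec.seed,
    }
    return trials, truth


def recover_thresholds(trials: pd.DataFrame) -> CSCurve:
    """Estimate threshold contrast per frequency from staircase trials.

    The threshold is the lowest ladder contrast whose majority response is
    'yes' while all lower contrasts are majority 'no' (scanning the
    descending ladder for the last consistent transition).
    """
    freqs = np.sort(trials["frequency_cpd"].unique())
    thresholds = []
    for f in freqs:
        sub = trials[trials["frequency_cpd"] == f]
        ladder = np.sort(sub["contrast"].unique())[::-1]
        yes_rate = np.array(
            [sub[sub["contrast"] == c]["response"].mean() for c in ladder]
        )
        passing = yes_rate > 0.5
        if not passing.any():
            thresholds.append(1.0)
            continue
        # lowest contrast still detected before the first sustained failure
        idx = np.nonzero(~passing)[0]
        last = (idx[0] - 1) if idx.size else (ladder.size - 1)
        thresholds.append(float(ladder[max(last, 0)]))
    return CSCurve(np.asarray(freqs), np.asarray(thresholds))
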