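"""Synthetic outer-nuclear-layer phantoms: packed nuclei and chromatin models.

Builds 3D labeled volumes of non-overlapping ellipsoidal rod nuclei and
paints refractive-index maps onto them under two chromatin architectures
on *identical* geometry:

* ``inverted`` — the adult rod arrangement: a dense heterochromatin core
  (n2) surrounded by a euchromatin shell (n1), split at equal volume.
* ``chromocenter`` — the conventional/developing arrangement: several
  discrete heterochromatin bodies seeded inside the nucleus plus a thin
  peripheral heterochromatin shell, grown until the n2 phase occupies half
  the nucleus volume.

Both models assign exactly half of every nucleus to each refractive phase
(before smoothing), so they differ only in the spatial arrangement of the
same amount of optical material.  Grids are indexed (z, y, x) with z the
light-propagation axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, PackingError

__all__ = [
    "ChromatinParams",
    "LabeledVolume",
    "RIVolume",
    "generate_packed_nuclei",
    "assign_inverted",
    "assign_chromocenters",
    "smooth_and_embed",
]

#: Minimum nucleus size (voxels) for a meaningful equal-volume phase split.
MIN_SPLIT_VOXELS = 16


@dataclass(frozen=True)
class ChromatinParams:
    """Refractive indices and chromatin-model parameters.

    n1/n2 are the euchromatin/heterochromatin indices, n0 the surround;
    ``n_cc_range`` is the inclusive range of chromocenter counts drawn per
    nucleus, ``smoothing_sigma`` the Gaussian blur (in voxels) applied to
    the final index map.
    """

    n1: float = 1.357
    n2: float = 1.382
    n0: float = 1.33
    n_cc_range: tuple[int, int] = (8, 12)
    smoothing_sigma: float = 2.0

    def __post_init__(self):
        if not (self.n2 >= self.n1 >= self.n0):
            raise InvalidInputError("require n2 >= n1 >= n0")
        lo, hi = self.n_cc_range
        if not (1 <= lo <= hi <= 64):
            raise InvalidInputError("n_cc_range must satisfy 1 <= lo <= hi <= 64")
        if self.smoothing_sigma < 0:
            raise InvalidInputError("smoothing_sigma must be >= 0")


@dataclass
class LabeledVolume:
    """Integer nucleus labels on a regular grid (0 = background)."""

    labels: np.ndarray  # (z, y, x) int32
    voxel_size_um: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidInputError("labels must be a 3D array")
        if self.labels.min() < 0:
            raise InvalidInputError("labels must be non-negative")
        if not (self.voxel_size_um > 0):
            raise InvalidInputError("voxel size must be positive")

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    def volume_fraction(self) -> float:
        return float(np.count_nonzero(self.labels)) / self.labels.size


@dataclass
class RIVolume:
    """Real-valued refractive-index map painted on a LabeledVolume grid."""

    ri: np.ndarray  # (z, y, x) float32
    voxel_size_um: float
    model: str  # "inverted" | "chromocenter" | other provenance tag
    seed: int | None = None
    chromocenter_counts: dict[int, int] = field(default_factory=dict)
    smoothed: bool = False

    def __post_init__(self):
        self.ri = np.asarray(self.ri, dtype=np.float32)
        if self.ri.ndim != 3:
            raise InvalidInputError("ri must be a 3D array")
        if not np.all(np.isfinite(self.ri)):
            raise InvalidInputError("ri must be finite")


# ---------------------------------------------------------------------------
# Packing generator
# ---------------------------------------------------------------------------

def generate_packed_nuclei(
    n_nuclei: int,
    domain_shape: tuple[int, int, int],
    voxel_size_um: float = 0.166,
    radius_um: tuple[float, float] = (2.8, 0.3),
    max_volume_fraction: float = 0.55,
    axis_ratio_range: tuple[float, float] = (0.8, 1.2),
    seed: int = 0,
    max_attempts_per_nucleus: int = 500,
) -> LabeledVolume:
    """Pack non-overlapping ellipsoidal nuclei into a (z, y, x) domain.

    Nuclei are axis-aligned ellipsoids with semi-axes ``r * ratio`` where
    ``r ~ N(radius_um)`` and the per-axis ratios are drawn uniformly from
    ``axis_ratio_range`` (mild eccentricity, rod-nucleus-like).  Placement
    is by rejection sampling on bounding spheres, so labels can never
    overlap; centers stay at least one bounding radius from every face.
    Deterministic for a given seed.

    Raises
    ------
    PackingError
        If the requested count cannot be placed; carries ``achieved``.
    """
    if n_nuclei < 1:
        raise InvalidInputError("n_nuclei must be >= 1")
    shape = tuple(int(s) for s in domain_shape)
    if len(shape) != 3 or min(shape) < 4:
        raise InvalidInputError("domain_shape must be 3 positive dimensions")
    rng = np.random.default_rng(seed)

    mean_r, sd_r = radius_um
    expected_vf = n_nuclei * (4 / 3) * np.pi * mean_r**3 / (
        np.prod(shape) * voxel_size_um**3
    )
    if expected_vf > max_volume_fraction:
        raise InvalidInputError(
            f"requested packing fraction ~{expected_vf:.2f} exceeds the "
            f"achievable limit {max_volume_fraction}"
        )

    extent = np.array(shape, dtype=float) * voxel_size_um  # (z, y, x) um
    centers: list[np.ndarray] = []
    semiaxes: list[np.ndarray] = []
    bound_r: list[float] = []
    for k in range(n_nuclei):
        placed = False
        for _ in range(max_attempts_per_nucleus):
            r = float(np.clip(rng.normal(mean_r, sd_r), 0.3 * mean_r, 2.0 * mean_r))
            ratios = rng.uniform(*axis_ratio_range, size=3)
            semi = r * ratios
            rb = float(semi.max())
            if np.any(extent < 2 * rb):
                continue
            c = rng.uniform(rb, extent - rb)
            if all(np.linalg.norm(c - c2) >= rb + rb2 for c2, rb2 in zip(centers, bound_r)):
                centers.append(c)
                semiaxes.append(semi)
                bound_r.append(rb)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could only place {k} of {n_nuclei} nuclei "
                f"(domain too crowded for bounding-sphere rejection)",
                achieved=k,
            )

    labels = np.zeros(shape, dtype=np.int32)
    for k, (c, semi) in enumerate(zip(centers, semiaxes), start=1):
        _paint_ellipsoid(labels, k, c, semi, voxel_size_um)
    return LabeledVolume(labels=labels, voxel_size_um=voxel_size_um)


def _paint_ellipsoid(labels, k, center_um, semi_um, voxel):
    lo = np.maximum(np.floor((center_um - semi_um) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + semi_um) / voxel).astype(int) + 1, labels.shape)
    zz, yy, xx = np.meshgrid(
        *[(np.arange(lo[i], hi[i]) + 0.5) * voxel for i in range(3)], indexing="ij"
    )
    d2 = (
        ((zz - center_um[0]) / semi_um[0]) ** 2
        + ((yy - center_um[1]) / semi_um[1]) ** 2
        + ((xx - center_um[2]) / semi_um[2]) ** 2
    )
    sub = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[d2 <= 1.0] = k


# ---------------------------------------------------------------------------
# Chromatin architecture painters
# ---------------------------------------------------------------------------

def _iter_nuclei(labels: np.ndarray):
    """Yield (label, slices, local boolean mask) per nucleus."""
    objects = ndimage.find_objects(labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        yield k, sl, labels[sl] == k


def _uniform_fallback(ri_local, mask, params):
    ri_local[mask] = 0.5 * (params.n1 + params.n2)


def assign_inverted(labels: LabeledVolume, params: ChromatinParams) -> RIVolume:
    """Paint the inverted (adult rod) architecture: n2 core, n1 shell.

    The core is the deepest half of each nucleus by Euclidean distance to
    its boundary, so core and shell have equal volume to within one voxel.
    Nuclei below ``MIN_SPLIT_VOXELS`` get the uniform mean index with a
    warning.
    """
    ri = np.full(labels.labels.shape, params.n0, dtype=np.float32)
    for k, sl, mask in _iter_nuclei(labels.labels):
        n_vox = int(mask.sum())
        sub = ri[sl]
        if n_vox < MIN_SPLIT_VOXELS:
            warnings.warn(f"nucleus {k} too small to split ({n_vox} voxels); assigned mean index")
            _uniform_fallback(sub, mask, params)
            continue
        depth = _boundary_depth(mask)
        core = _deepest_half(mask, depth, n_vox // 2)
        sub[mask] = params.n1
        sub[core] = params.n2
    return RIVolume(ri=ri, voxel_size_um=labels.voxel_size_um, model="inverted")


def _boundary_depth(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance (voxels) from each mask voxel to the background."""
    padded = np.pad(mask, 1)
    return ndimage.distance_transform_edt(padded)[tuple(slice(1, -1) for _ in range(3))]


def _deepest_half(mask, depth, n_core):
    """Boolean mask of the n_core deepest voxels (ties broken lexicographically)."""
    idx = np.flatnonzero(mask.ravel())
    order = np.argsort(-depth.ravel()[idx], kind="stable")
    core = np.zeros(mask.size, dtype=bool)
    core[idx[order[:n_core]]] = True
    return core.reshape(mask.shape)


def assign_chromocenters(
    labels: LabeledVolume,
    params: ChromatinParams,
    seed: int,
    n_cc_override: int | None = None,
) -> RIVolume:
    """Paint the multi-chromocenter (conventional/developing) architecture.

    Per nucleus: draw a chromocenter count from ``params.n_cc_range``
    (or use ``n_cc_override``), pick that many seed voxels uniformly inside
    the mask, assign the 1-voxel border shell to n2, then grow n2 from the
    seeds in order of Euclidean distance-to-nearest-seed (ties broken
    lexicographically) until the n2 phase holds half the nucleus volume.
    Deterministic for a given seed; drawn counts are recorded on the result.
    """
    rng = np.random.default_rng(seed)
    ri = np.full(labels.labels.shape, params.n0, dtype=np.float32)
    counts: dict[int, int] = {}
    for k, sl, mask in _iter_nuclei(labels.labels):
        n_vox = int(mask.sum())
        sub = ri[sl]
        if n_vox < MIN_SPLIT_VOXELS:
            warnings.warn(f"nucleus {k} too small to split ({n_vox} voxels); assigned mean index")
            _uniform_fallback(sub, mask, params)
            continue
        if n_cc_override is not None:
            n_cc = int(n_cc_override)
            if n_cc < 1:
                raise InvalidInputError("n_cc_override must be >= 1")
        else:
            lo, hi = params.n_cc_range
            n_cc = int(rng.integers(lo, hi + 1))
        counts[k] = n_cc

        budget = n_vox // 2
        coords = np.argwhere(mask)  # lexicographic (z, y, x) order
        seed_idx = rng.choice(coords.shape[0], size=min(n_cc, coords.shape[0]), replace=False)
        seeds = coords[np.sort(seed_idx)]

        shell = mask & ~ndimage.binary_erosion(mask)
        # distance of every mask voxel to its nearest chromocenter seed
        diff = coords[:, None, :] - seeds[None, :, :]
        dist = np.sqrt((diff.astype(np.float64) ** 2).sum(axis=2)).min(axis=1)

        n2_local = np.zeros(mask.shape, dtype=bool)
        shell_flat = shell[tuple(coords.T)]
        n_shell = int(shell_flat.sum())
        if n_shell >= budget:
            # tiny budget: take the shell voxels closest to a seed
            order = np.argsort(dist[shell_flat], kind="stable")
            chosen = coords[shell_flat][order[:budget]]
            n2_local[tuple(chosen.T)] = True
        else:
            n2_local[shell] = True
            interior = ~shell_flat
            order = np.argsort(dist[interior], kind="stable")  # coords already lexicographic
            chosen = coords[interior][order[: budget - n_shell]]
            n2_local[tuple(chosen.T)] = True

        sub[mask] = params.n1
        sub[n2_local] = params.n2
    return RIVolume(
        ri=ri,
        voxel_size_um=labels.voxel_size_um,
        model="chromocenter",
        seed=seed,
        chromocenter_counts=counts,
    )


def smooth_and_embed(ri: RIVolume, params: ChromatinParams) -> RIVolume:
    """Gaussian-smooth the index contrast against the n0 surround.

    Filters ``ri - n0`` with ``sigma = params.smoothing_sigma`` voxels and
    adds n0 back, so smoothing redistributes optical path rather than
    creating it (the summed index excess is conserved up to boundary
    leakage).  ``sigma = 0`` is the identity.
    """
    sigma = params.smoothing_sigma
    if sigma == 0:
        out = ri.ri.copy()
    else:
        excess = ri.ri.astype(np.float64) - params.n0
        out = (ndimage.gaussian_filter(excess, sigma=sigma, mode="constant") + params.n0).astype(
            np.float32
        )
    return RIVolume(
        ri=out,
        voxel_size_um=ri.voxel_size_um,
        model=ri.model,
        seed=ri.seed,
        chromocenter_counts=dict(ri.chromocenter_counts),
        smoothed=sigma > 0,
    )
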