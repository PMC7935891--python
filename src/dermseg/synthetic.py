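"""Seeded synthetic skin-image generator with exact ground truth.

Skin is rendered through the same two-chromophore attenuation model the
decomposition stage assumes: per channel c,

    intensity_c = 256 * exp(-(d_m[c] * q_m + d_h[c] * q_h + noise)) - 1

where ``q_m`` and ``q_h`` are smooth non-negative melanin/hemoglobin quantity
fields and ``d_m``, ``d_h`` are fixed absorption (density) vectors. Erythema
lesions are blobs where ``q_h`` is raised by a constant boost, which makes
them darker and redder; the boolean mask records exactly those pixels. Class
identity is carried by a lesion phenotype (blob shape/texture), so a
downstream classifier has something real to learn.

Every output is a pure function of (params, seed): byte-identical across
calls.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import save_image, save_mask

# Default absorption vectors (unit norm). Melanin attenuates all channels
# nearly equally (brown); hemoglobin attenuates green/blue far more than red,
# which is why erythema looks red.
DEFAULT_D_MELANIN = np.array([0.55, 0.60, 0.58])
DEFAULT_D_HEMOGLOBIN = np.array([0.10, 0.75, 0.65])

PHENOTYPES = ("single", "annular", "textured")


class SyntheticParamsError(ValueError):
    """Raised when a SyntheticParams field is inconsistent."""


@dataclass(frozen=True)
class SyntheticParams:
    """Generation settings; defaults give a modest 96x96 three-class task."""

    height: int = 96
    width: int = 96
    n_classes: int = 3
    lesions_per_image: tuple[int, int] = (1, 3)
    lesion_radius: tuple[float, float] = (6.0, 12.0)
    hemoglobin_boost: float = 0.8
    noise_sd: float = 0.02
    background_fraction: float = 0.0
    seed: int = 0
    # base-field ranges (dimensionless chromophore quantities)
    q_m_range: tuple[float, float] = (0.2, 0.8)
    q_h_range: tuple[float, float] = (0.1, 0.5)
    bump_density: float = 0.013          # bumps per pixel in the base fields
    bump_sigma: tuple[float, float] = (2.0, 6.0)  # bump width range, pixels
    # per-image illumination variation: a neutral (channel-equal) optical-
    # density offset = global exposure shift + smooth shading field, sd in
    # OD units. 0 disables. Emulates the uncontrolled lighting of consumer
    # camera photographs, which the decomposition stage normalizes away.
    shading_sd: float = 0.0
    # per-image white-balance variation: a constant per-channel optical-
    # density offset, each channel ~ Normal(0, color_cast_sd). Confounds raw
    # color cues across images; removed exactly by the per-image offset
    # subtraction of the decomposition stage.
    color_cast_sd: float = 0.0
    # pigmented distractors: blobs of raised melanin (nevi/hyperpigmentation)
    # that mimic lesions in shape and darkness but not in chromophore; they
    # are NOT part of the abnormal-skin mask.
    melanin_blobs: tuple[int, int] = (0, 0)
    melanin_blob_boost: float = 0.8
    d_melanin: tuple[float, float, float] = tuple(DEFAULT_D_MELANIN)
    d_hemoglobin: tuple[float, float, float] = tuple(DEFAULT_D_HEMOGLOBIN)
    phenotype_map: tuple[str, ...] | None = None  # class index -> phenotype

    def __post_init__(self):
        if self.height < 32:
            raise SyntheticParamsError(f"height must be >= 32, got {self.height}")
        if self.width < 32:
            raise SyntheticParamsError(f"width must be >= 32, got {self.width}")
        if self.n_classes < 2:
            raise SyntheticParamsError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.noise_sd < 0:
            raise SyntheticParamsError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.lesions_per_image
        if not (0 <= lo <= hi):
            raise SyntheticParamsError(
                f"lesions_per_image must be an ordered non-negative range, got {self.lesions_per_image}")
        rlo, rhi = self.lesion_radius
        if not (0 < rlo <= rhi):
            raise SyntheticParamsError(
                f"lesion_radius must be an ordered positive range, got {self.lesion_radius}")
        if 2 * rhi >= min(self.height, self.width):
            raise SyntheticParamsError(
                f"lesion_radius {rhi} does not fit a {self.height}x{self.width} image")
        if not (0 <= self.background_fraction < 1):
            raise SyntheticParamsError(
                f"background_fraction must be in [0, 1), got {self.background_fraction}")
        if self.shading_sd < 0:
            raise SyntheticParamsError(
                f"shading_sd must be >= 0, got {self.shading_sd}")
        if self.color_cast_sd < 0:
            raise SyntheticParamsError(
                f"color_cast_sd must be >= 0, got {self.color_cast_sd}")
        if self.hemoglobin_boost < 0:
            raise SyntheticParamsError(
                f"hemoglobin_boost must be >= 0, got {self.hemoglobin_boost}")
        blo, bhi = self.melanin_blobs
        if not (0 <= blo <= bhi):
            raise SyntheticParamsError(
                f"melanin_blobs must be an ordered non-negative range, got {self.melanin_blobs}")
        if self.melanin_blob_boost < 0:
            raise SyntheticParamsError(
                f"melanin_blob_boost must be >= 0, got {self.melanin_blob_boost}")
        if self.phenotype_map is not None:
            for p in self.phenotype_map:
                if p not in PHENOTYPES:
                    raise SyntheticParamsError(f"unknown phenotype '{p}'")

    def phenotype_for(self, class_index: int) -> str:
        if self.phenotype_map is not None:
            return self.phenotype_map[class_index % len(self.phenotype_map)]
        return PHENOTYPES[class_index % len(PHENOTYPES)]

    @property
    def mixing_matrix(self) -> np.ndarray:
        """2x3 matrix stacking the unit-norm density vectors [d_m; d_h]."""
        dm = np.asarray(self.d_melanin, dtype=float)
        dh = np.asarray(self.d_hemoglobin, dtype=float)
        return np.stack([dm / np.linalg.norm(dm), dh / np.linalg.norm(dh)])


@dataclass
class SyntheticSample:
    image: np.ndarray          # (h, w, 3) uint8
    mask: np.ndarray           # (h, w) bool, True = lesion
    label: int
    q_m: np.ndarray            # (h, w) float, truth melanin quantity
    q_h: np.ndarray            # (h, w) float, truth hemoglobin quantity
    density: np.ndarray        # (2, 3) truth mixing matrix [d_m; d_h]
    background: np.ndarray | None = None  # (h, w) bool distractor region


def _base_field(rng, shape, params: SyntheticParams, lo, hi):
    """Sparse Gaussian-bump field rescaled to [lo, hi].

    Chromophore variation is modeled as scattered smooth spots (freckle-like
    melanin deposits, capillary hemoglobin patches) with exponentially
    distributed amplitudes. The heavy-tailed, spatially sparse structure
    makes the field strongly non-Gaussian, which blind source separation
    needs (at most one source may be Gaussian) — a spatially smoothed
    Gaussian field would leave the mixing directions unidentifiable.
    """
    n_bumps = max(20, int(round(params.bump_density * shape[0] * shape[1])))
    f = np.zeros(shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    s_lo, s_hi = params.bump_sigma
    for _ in range(n_bumps):
        cy = rng.uniform(0, shape[0])
        cx = rng.uniform(0, shape[1])
        amp = rng.exponential(1.0)
        s = rng.uniform(s_lo, s_hi)
        f += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return lo + (hi - lo) * f


def _shading_field(rng, shape, sd):
    """Neutral optical-density offset: global exposure shift plus smooth
    spatial shading, both with standard deviation ``sd``."""
    g = rng.normal(0.0, sd)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), min(shape) / 4.0)
    f_sd = f.std()
    if f_sd > 0:
        f = f / f_sd * sd
    return g + f


def _disc(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _place_centers(rng, shape, radii, margin, n, min_sep_factor=2.5, max_tries=500):
    """Rejection-sample n centers with pairwise separation; deterministic."""
    centers = []
    for i in range(n):
        r = radii[i]
        for _ in range(max_tries):
            cy = rng.uniform(margin + r, shape[0] - margin - r)
            cx = rng.uniform(margin + r, shape[1] - margin - r)
            ok = all(
                np.hypot(cy - y, cx - x) > min_sep_factor * (r + radii[j]) / 2 + 2
                for j, (y, x) in enumerate(centers)
            )
            if ok:
                centers.append((cy, cx))
                break
        else:
            centers.append((cy, cx))  # crowded image: accept the last draw
    return centers


def _lesion_mask_and_boost(rng, params: SyntheticParams, phenotype, center, radius):
    """One lesion site -> (mask, additive q_h boost field)."""
    shape = (params.height, params.width)
    if phenotype == "single":
        # uniformly filled disc
        m = _disc(shape, center, radius)
        boost = m * params.hemoglobin_boost
    elif phenotype == "annular":
        # ring-shaped erythema with a recovering pale center
        m = _disc(shape, center, radius) & ~_disc(shape, center, radius * 0.55)
        boost = m * params.hemoglobin_boost
    elif phenotype == "textured":
        # coarsely mottled disc: strong high-frequency internal variation
        m = _disc(shape, center, radius)
        speckle = ndimage.gaussian_filter(rng.standard_normal(shape), 1.2)
        patches = (speckle > 0).astype(float)
        boost = m * params.hemoglobin_boost * (0.25 + 1.5 * patches)
    else:  # pragma: no cover - guarded by SyntheticParams
        raise SyntheticParamsError(f"unknown phenotype '{phenotype}'")
    return m, boost


def render(q_m, q_h, density, noise=None):
    """Render quantity fields through the attenuation model to uint8 RGB."""
    od = q_m[..., None] * density[0] + q_h[..., None] * density[1]
    if noise is not None:
        od = od + noise
    img = 256.0 * np.exp(-np.maximum(od, 0.0)) - 1.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_sample(params: SyntheticParams, class_index: int, rng=None) -> SyntheticSample:
    """Generate one labeled sample; deterministic given (params, rng state)."""
    if not 0 <= class_index < params.n_classes:
        raise SyntheticParamsError(
            f"class_index must be in [0, {params.n_classes}), got {class_index}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shape = (params.height, params.width)
    density = params.mixing_matrix

    q_m = _base_field(rng, shape, params, *params.q_m_range)
    q_h = _base_field(rng, shape, params, *params.q_h_range)

    n_lesions = int(rng.integers(params.lesions_per_image[0],
                                 params.lesions_per_image[1] + 1))
    n_blobs = int(rng.integers(params.melanin_blobs[0],
                               params.melanin_blobs[1] + 1))
    phenotype = params.phenotype_for(class_index)
    mask = np.zeros(shape, bool)
    if n_lesions + n_blobs > 0:
        radii = [rng.uniform(*params.lesion_radius)
                 for _ in range(n_lesions + n_blobs)]
        centers = _place_centers(rng, shape, radii, margin=2,
                                 n=n_lesions + n_blobs)
        for center, radius in zip(centers[:n_lesions], radii[:n_lesions]):
            m, boost = _lesion_mask_and_boost(rng, params, phenotype, center, radius)
            mask |= m
            q_h = q_h + boost
        for center, radius in zip(centers[n_lesions:], radii[n_lesions:]):
            blob = _disc(shape, center, radius)
            q_m = q_m + blob * params.melanin_blob_boost

    background = None
    noise = rng.normal(0.0, params.noise_sd, shape + (3,)) if params.noise_sd > 0 else None
    if params.shading_sd > 0:
        shading = _shading_field(rng, shape, params.shading_sd)[..., None]
        noise = shading if noise is None else noise + shading
    if params.color_cast_sd > 0:
        cast = rng.normal(0.0, params.color_cast_sd, 3)
        noise = cast if noise is None else noise + cast
    image = render(q_m, q_h, density, noise)

    if params.background_fraction > 0:
        # dark non-skin band on the left: a distractor, excluded from the mask
        ncols = int(round(params.background_fraction * params.width))
        background = np.zeros(shape, bool)
        background[:, :ncols] = True
        bg_vals = np.clip(
            30 + 12 * ndimage.gaussian_filter(rng.standard_normal(shape + (3,)), 2.0),
            0, 70,
        ).astype(np.uint8)
        image = image.copy()
        image[background] = bg_vals[background]
        mask &= ~background

    return SyntheticSample(image=image, mask=mask, label=int(class_index),
                           q_m=q_m, q_h=q_h, density=density, background=background)


def generate_multilesion_sample(params: SyntheticParams, class_indices,
                                rng=None) -> SyntheticSample:
    """One image carrying one lesion per requested class (multi-disease
    case). The per-lesion class is recoverable from the per-site masks in
    ``sample.site_masks``; ``label`` is the first class."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    for ci in class_indices:
        if not 0 <= ci < params.n_classes:
            raise SyntheticParamsError(f"class_index {ci} out of range")
    shape = (params.height, params.width)
    density = params.mixing_matrix
    q_m = _base_field(rng, shape, params, *params.q_m_range)
    q_h = _base_field(rng, shape, params, *params.q_h_range)
    radii = [rng.uniform(*params.lesion_radius) for _ in class_indices]
    centers = _place_centers(rng, shape, radii, margin=2, n=len(class_indices),
                             min_sep_factor=3.5)
    mask = np.zeros(shape, bool)
    site_masks = []
    for ci, center, radius in zip(class_indices, centers, radii):
        m, boost = _lesion_mask_and_boost(rng, params, params.phenotype_for(ci), center, radius)
        mask |= m
        q_h = q_h + boost
        site_masks.append((int(ci), m))
    noise = rng.normal(0.0, params.noise_sd, shape + (3,)) if params.noise_sd > 0 else None
    if params.shading_sd > 0:
        shading = _shading_field(rng, shape, params.shading_sd)[..., None]
        noise = shading if noise is None else noise + shading
    if params.color_cast_sd > 0:
        cast = rng.normal(0.0, params.color_cast_sd, 3)
        noise = cast if noise is None else noise + cast
    image = render(q_m, q_h, density, noise)
    sample = SyntheticSample(image=image, mask=mask, label=int(class_indices[0]),
                             q_m=q_m, q_h=q_h, density=density)
    sample.site_masks = site_masks
    return sample


def generate_dataset(params: SyntheticParams, n_per_class: int, seed: int | None = None,
                     out_dir=None):
    """Balanced dataset of n_per_class samples per class.

    Returns (samples, manifest_rows). When out_dir is given, writes
    ``images/NNN.png``, ``masks/NNN.png`` and ``manifest.csv`` with header
    ``image,mask,label``.
    """
    if n_per_class < 1:
        raise SyntheticParamsError(f"n_per_class must be >= 1, got {n_per_class}")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    samples, rows = [], []
    i = 0
    for ci in range(params.n_classes):
        for _ in range(n_per_class):
            samples.append(generate_sample(params, ci, rng))
            rows.append((f"images/{i:04d}.png", f"masks/{i:04d}.png", ci))
            i += 1
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for (img_rel, mask_rel, _), s in zip(rows, samples):
            save_image(out / img_rel, s.image)
            save_mask(out / mask_rel, s.mask)
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image", "mask", "label"])
            w.writerows(rows)
    return samples, rows
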