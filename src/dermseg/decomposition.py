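"""Chromophore decomposition of skin images.

The visible appearance of skin is dominated by two absorbers, melanin and
hemoglobin. Under the attenuation (Beer–Lambert) model the per-pixel optical
density is a linear mixture

    L = d_m * q_m + d_h * q_h + residual

with channelwise density (absorption) vectors ``d_m``, ``d_h`` and scalar
quantity fields ``q_m``, ``q_h``. The mixing directions are blind-estimated
with a two-component ICA on the pixel cloud; quantity maps come from the
least-squares inverse of the stacked 2x3 density matrix, shifted by the
per-component minimum so they are non-negative with minimum exactly zero.
Rendering one constituent alone (``exp(-d * q)``) produces the hemoglobin or
melanin image fed to the segmenter.

``ChromophoreDecomposer`` is the estimator interface (fit on one image, or
fit once and apply to many); the module-level functions are thin wrappers
used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA

LOG256 = float(np.log(256.0))


class DecompositionError(RuntimeError):
    """Raised when the density matrix cannot be estimated."""


# ---------------------------------------------------------------------------
# optical density <-> intensity
# ---------------------------------------------------------------------------

def rgb_to_optical_density(image: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to optical density: L = -log((I + 1) / 256).

    The +1 shift keeps L finite at intensity 0 (L = log 256) and exactly 0 at
    intensity 255; the round trip through :func:`intensity_from_density` is
    the identity on the integer grid.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) RGB image, got shape {image.shape}")
    vals = image.astype(np.float64)
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return -np.log((vals + 1.0) / 256.0)


def intensity_from_density(density: np.ndarray) -> np.ndarray:
    """Inverse map: I = 256 * exp(-L) - 1, rounded and clipped to [0, 255]."""
    density = np.asarray(density, dtype=np.float64)
    if density.min() < 0:
        raise ValueError("optical density must be non-negative")
    return np.clip(np.rint(256.0 * np.exp(-density) - 1.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# density matrix estimation
# ---------------------------------------------------------------------------

@dataclass
class DensityMatrix:
    """Estimated unit-norm density vectors and the non-negativity offset."""

    d_m: np.ndarray            # (3,)
    d_h: np.ndarray            # (3,)
    offset: np.ndarray | None  # (2,) per-component minimum of the raw maps

    @property
    def stacked(self) -> np.ndarray:
        return np.stack([self.d_m, self.d_h])

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.stacked))


class ChromophoreDecomposer(BaseEstimator, TransformerMixin):
    """Estimate the melanin/hemoglobin mixing directions of a skin image.

    Parameters
    ----------
    random_state : int
        Seed for the fixed-point ICA; fits are deterministic per seed.
    max_iter : int
        ICA iteration cap.
    max_condition : float
        Reject fits whose stacked 2x3 density matrix is worse conditioned
        than this.
    labeling : {"red_transparency", "none"}
        How to assign the two unordered ICA components to chromophores.
        ``red_transparency`` calls the component that attenuates red least
        relative to green "hemoglobin" (erythema is red because hemoglobin
        absorbs green/blue); ``none`` keeps ICA order.

    Attributes
    ----------
    density_ : DensityMatrix
        Fitted unit-norm density vectors with the offset for this image.
    """

    def __init__(self, random_state=0, max_iter=500, max_condition=1e6,
                 labeling="red_transparency"):
        self.random_state = random_state
        self.max_iter = max_iter
        self.max_condition = max_condition
        self.labeling = labeling

    # -- core ---------------------------------------------------------------
    def fit(self, X, y=None, sample_mask=None):
        """Fit on one image. X: (h, w, 3) optical densities, or an (n, 3)
        pixel matrix. ``sample_mask`` restricts to usable (skin) pixels."""
        pixels = self._as_pixels(X, sample_mask)
        if pixels.shape[0] < 100:
            raise DecompositionError(
                f"need at least 100 usable pixels, got {pixels.shape[0]}")
        cov = np.cov(pixels, rowvar=False)
        evals = np.linalg.eigvalsh(cov)
        if evals[-2] <= max(1e-12, 1e-9 * evals[-1]) or evals[-1] <= 1e-12:
            raise DecompositionError(
                "pixel covariance is rank-deficient (fewer than 2 independent "
                "color directions); cannot separate two chromophores")
        mixing = self._run_ica(pixels)  # (3, 2): columns are density directions
        d = mixing.T.astype(np.float64)
        # fix sign (majority-positive: absorption vectors are non-negative)
        for i in range(2):
            if d[i].sum() < 0:
                d[i] = -d[i]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        if self.labeling == "red_transparency":
            # hemoglobin attenuates red least relative to green
            ratio = d[:, 0] / np.maximum(d[:, 1], 1e-12)
            h_idx = int(np.argmin(ratio))
        elif self.labeling == "none":
            h_idx = 1
        else:
            raise ValueError(f"unknown labeling '{self.labeling}'")
        m_idx = 1 - h_idx
        dm = DensityMatrix(d_m=d[m_idx], d_h=d[h_idx], offset=None)
        if dm.condition_number > self.max_condition:
            raise DecompositionError(
                f"estimated density vectors are nearly collinear "
                f"(condition number {dm.condition_number:.3g})")
        raw = pixels @ np.linalg.pinv(dm.stacked)
        dm.offset = raw.min(axis=0)
        self.density_ = dm
        return self

    def _run_ica(self, pixels):
        """Fixed-point ICA with restarts.

        FastICA occasionally stalls on near-Gaussian pixel clouds; we run a
        few seeded restarts and keep the converged solution whose recovered
        sources are most non-Gaussian (largest total excess kurtosis). The
        restart seeds derive from ``random_state``, so the whole procedure is
        deterministic per seed.
        """
        import warnings

        best, best_score = None, -np.inf
        ss = np.random.SeedSequence(self.random_state)
        for child in ss.spawn(4):
            seed = int(child.generate_state(1)[0] % (2 ** 31))
            ica = FastICA(n_components=2, random_state=seed, tol=1e-7,
                          max_iter=self.max_iter, whiten="unit-variance")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sources = ica.fit_transform(pixels)
            converged = ica.n_iter_ < self.max_iter
            z = (sources - sources.mean(0)) / np.maximum(sources.std(0), 1e-12)
            kurt = np.abs((z ** 4).mean(0) - 3.0).sum()
            score = kurt + (1e6 if converged else 0.0)
            if score > best_score:
                best, best_score = ica.mixing_, score
        return best

    def transform(self, X):
        """Quantity maps for an optical-density image: (h, w, 2) stacked
        [q_m, q_h], offset-shifted so each map has minimum exactly 0."""
        q = compute_quantity_maps(X, self.density_, offset="auto")
        return np.stack([q.q_m, q.q_h], axis=-1)

    @staticmethod
    def _as_pixels(X, sample_mask=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3 and X.shape[2] == 3:
            pixels = X.reshape(-1, 3)
            if sample_mask is not None:
                pixels = pixels[np.asarray(sample_mask).reshape(-1)]
            return pixels
        if X.ndim == 2 and X.shape[1] == 3:
            return X if sample_mask is None else X[np.asarray(sample_mask)]
        raise ValueError(f"expected (h, w, 3) or (n, 3) input, got shape {X.shape}")


def estimate_density_matrix(density_image, skin_pixels=None, rng_seed=0) -> DensityMatrix:
    """Functional wrapper over :class:`ChromophoreDecomposer`."""
    dec = ChromophoreDecomposer(random_state=rng_seed)
    dec.fit(density_image, sample_mask=skin_pixels)
    return dec.density_


def default_skin_mask(image: np.ndarray, threshold: float = 60.0) -> np.ndarray:
    """Crude non-skin exclusion: pixels darker than ``threshold`` mean
    intensity (shadow, clothing, dark background) are not skin. The
    two-chromophore mixing model only holds on skin, so density estimation
    should not see these pixels."""
    return np.asarray(image).astype(float).mean(axis=-1) >= threshold


def estimate_density_matrix_pooled(images, rng_seed=0, pixels_per_image=1500,
                                   skin_mask_fn=default_skin_mask) -> DensityMatrix:
    """Fit-once/apply-many estimation over a batch of RGB images.

    Skin pixels are subsampled from every image and their optical densities
    pooled; each image's cloud is centered first, which cancels per-image
    exposure and white-balance offsets that would otherwise swamp the
    within-image chromophore structure. The returned matrix carries no
    offset — quantity maps recompute the per-image minimum (``offset="auto"``).
    """
    rng = np.random.default_rng(rng_seed)
    pools = []
    for img in images:
        od = rgb_to_optical_density(img)
        sel = od[skin_mask_fn(img)] if skin_mask_fn is not None else od.reshape(-1, 3)
        if len(sel) == 0:
            continue
        sel = sel - sel.mean(axis=0)
        if len(sel) > pixels_per_image:
            sel = sel[rng.choice(len(sel), pixels_per_image, replace=False)]
        pools.append(sel)
    if not pools:
        raise DecompositionError("no usable skin pixels in any image")
    dec = ChromophoreDecomposer(random_state=rng_seed)
    dec.fit(np.concatenate(pools))
    dec.density_.offset = None
    return dec.density_


# ---------------------------------------------------------------------------
# quantity maps and rendering
# ---------------------------------------------------------------------------

@dataclass
class QuantityMaps:
    q_m: np.ndarray
    q_h: np.ndarray


def compute_quantity_maps(density_image, dm: DensityMatrix, offset="auto") -> QuantityMaps:
    """Least-squares projection of L onto span{d_m, d_h}, then offset shift.

    The 2-unknown/3-channel system is solved with the Moore–Penrose
    pseudo-inverse. ``offset="auto"`` recomputes the per-component minimum on
    this image (each returned field then has minimum exactly 0);
    ``offset="stored"`` reuses the offset recorded at fit time, for
    fit-once/apply-many batch consistency.
    """
    L = np.asarray(density_image, dtype=np.float64)
    if L.ndim != 3 or L.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) optical densities, got shape {L.shape}")
    raw = L @ np.linalg.pinv(dm.stacked)  # (h, w, 2)
    if offset == "auto":
        off = raw.reshape(-1, 2).min(axis=0)
    elif offset == "stored":
        if dm.offset is None:
            raise ValueError("density matrix carries no stored offset")
        off = dm.offset
    else:
        raise ValueError(f"offset must be 'auto' or 'stored', got {offset!r}")
    q = raw - off
    return QuantityMaps(q_m=q[..., 0], q_h=q[..., 1])


def render_constituent(q: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Render a single constituent: per channel, I = 256*exp(-d_c*q) - 1.

    Pixels with q = 0 render white (255); larger quantities only darken.
    """
    q = np.asarray(q, dtype=np.float64)
    if q.min() < 0:
        raise ValueError("quantity field must be non-negative")
    d = np.asarray(d, dtype=np.float64).reshape(3)
    # an estimated density vector may carry a slightly negative channel
    # entry; the clip to [0, 255] absorbs the resulting intensity > 255
    img = 256.0 * np.exp(-(q[..., None] * d)) - 1.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class DecomposedPair:
    hemoglobin_image: np.ndarray  # (h, w, 3) uint8
    melanin_image: np.ndarray     # (h, w, 3) uint8
    density: DensityMatrix
    quantities: QuantityMaps


def decompose(image: np.ndarray, rng_seed: int = 0,
              density: DensityMatrix | None = None) -> DecomposedPair:
    """Full per-image decomposition: estimate (or reuse) the density matrix,
    compute quantity maps, and render the two constituent images."""
    od = rgb_to_optical_density(image)
    if density is None:
        density = estimate_density_matrix(od, rng_seed=rng_seed)
    q = compute_quantity_maps(od, density, offset="auto")
    return DecomposedPair(
        hemoglobin_image=render_constituent(q.q_h, density.d_h),
        melanin_image=render_constituent(q.q_m, density.d_m),
        density=density,
        quantities=q,
    )
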