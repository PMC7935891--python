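"""Abnormal-skin segmentation with an encoder-decoder network.

The segmenter consumes three registered views of the scene — the original
photograph plus its hemoglobin and melanin constituent images — stacked
channelwise (3+3+3 = 9 channels by default), and emits a per-pixel
probability of abnormal skin, thresholded into a binary mask. The network
is U-Net-shaped: ``depth`` down-sampling stages, a mirrored decoder, skip
connections between same-resolution stages, and zero-padded convolutions so
the output resolution equals the input's.

``SkinSegmenter`` follows the scikit-learn estimator protocol: configure in
``__init__``, ``fit(X, y)`` on stacked inputs and masks, ``predict`` new
stacks. ``predict_mask`` runs the full geometry-aware path on one raw image
(resize + pad, infer, map the mask back to the original frame).

Two named profiles are provided: ``full_scale`` (304x304, depth 4), and ``miniature`` (96x96, depth 3, base 8
channels), the CPU-friendly profile exercised by the test-suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import transform as sktransform
from sklearn.base import BaseEstimator

from ._nn import SEGMENTATION_LOSSES, UNet, make_optimizer, scheduled_lr
from .decomposition import DecomposedPair, decompose
from .evaluation import pixel_confusion, rates


class SegmentationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# input stacking and geometry
# ---------------------------------------------------------------------------

@dataclass
class ResizeGeometry:
    """Records how an image was fitted into the square network frame."""

    original_shape: tuple[int, int]
    scaled_shape: tuple[int, int]
    input_size: int

    def to_original(self, mask: np.ndarray) -> np.ndarray:
        """Map a network-frame mask back to original coordinates
        (drop padding, nearest-neighbor un-resize)."""
        sh, sw = self.scaled_shape
        valid = mask[:sh, :sw]
        out = sktransform.resize(valid.astype(float), self.original_shape,
                                 order=0, preserve_range=True,
                                 anti_aliasing=False)
        return out >= 0.5


def _fit_to_square(image: np.ndarray, input_size: int):
    """Aspect-preserving resize + zero-pad (top-left anchored) to a square."""
    h, w = image.shape[:2]
    scale = input_size / max(h, w)
    sh, sw = max(1, round(h * scale)), max(1, round(w * scale))
    resized = sktransform.resize(image.astype(float), (sh, sw), order=1,
                                 preserve_range=True, anti_aliasing=False)
    out_shape = (input_size, input_size) + image.shape[2:]
    out = np.zeros(out_shape, dtype=float)
    out[:sh, :sw] = resized
    return out, (sh, sw)


def stack_inputs(original: np.ndarray, pair: DecomposedPair | None,
                 input_size: int):
    """Stack (original, hemoglobin, melanin) into one normalized tensor.

    Returns ``(stack, geometry)`` where stack is (input_size, input_size, C)
    in [0, 1]; C is 9 with a decomposed pair, 3 without (original only).
    """
    images = [np.asarray(original)]
    if pair is not None:
        if (pair.hemoglobin_image.shape != images[0].shape
                or pair.melanin_image.shape != images[0].shape):
            raise ValueError("original and constituent image dimensions differ")
        images += [pair.hemoglobin_image, pair.melanin_image]
    planes = []
    geometry = None
    for img in images:
        fitted, scaled = _fit_to_square(img, input_size)
        geometry = ResizeGeometry(img.shape[:2], scaled, input_size)
        planes.append(fitted / 255.0)
    return np.concatenate(planes, axis=-1), geometry


def resize_mask_to(mask: np.ndarray, input_size: int) -> np.ndarray:
    fitted, _ = _fit_to_square(mask.astype(float)[..., None], input_size)
    return fitted[..., 0] >= 0.5


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class SkinSegmenter(BaseEstimator):
    """Encoder-decoder segmentation estimator.

    Parameters mirror the training recipe: binary cross-entropy (or soft
    Dice) loss, Adam/RMSprop/SGD, a step learning-rate schedule that decays
    by ``lr_decay_factor`` every ``lr_decay_every`` epochs, and a
    binarization ``threshold`` on the output probabilities. Defaults are the
    full-scale recipe: BCE, Adam at 5e-4 with weight decay 5e-4, 60 epochs,
    decay 0.1 every 20.

    Attributes (after fit)
    ----------------------
    model_ : the trained network
    history_ : list of per-epoch records (lr, loss, val_dice)
    """

    def __init__(self, input_size=304, in_channels=9, depth=4,
                 base_channels=16, loss="bce", optimizer="adam",
                 learning_rate=5e-4, weight_decay=5e-4, momentum=0.9,
                 epochs=60, lr_decay_factor=0.1, lr_decay_every=20,
                 threshold=0.5, batch_size=8, validation_fraction=0.0,
                 seed=0):
        self.input_size = input_size
        self.in_channels = in_channels
        self.depth = depth
        self.base_channels = base_channels
        self.loss = loss
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.epochs = epochs
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.threshold = threshold
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.seed = seed

    @classmethod
    def full_scale_profile(cls, **overrides):
        return cls(**{**dict(input_size=304, depth=4, base_channels=16), **overrides})

    @classmethod
    def miniature_profile(cls, **overrides):
        kw = dict(input_size=96, depth=3, base_channels=8, epochs=15,
                  batch_size=8)
        kw.update(overrides)
        return cls(**kw)

    # -- validation ---------------------------------------------------------
    def _check_config(self):
        if self.input_size % (2 ** self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2 ** self.depth}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.loss not in SEGMENTATION_LOSSES:
            raise ValueError(f"unknown loss '{self.loss}'")

    def _build(self):
        self._check_config()
        return UNet(in_channels=self.in_channels, depth=self.depth,
                    base_channels=self.base_channels, seed=self.seed)

    @staticmethod
    def _as_nchw(X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"expected (n, h, w, c) input stacks, got {X.shape}")
        return X.transpose(0, 3, 1, 2)

    # -- training -----------------------------------------------------------
    def fit(self, X, y, log_sink=None):
        """X: (n, h, w, c) stacks in [0,1]; y: (n, h, w) boolean masks."""
        Xn = self._as_nchw(X)
        y = np.asarray(y)
        if len(Xn) == 0:
            raise ValueError("empty training dataset")
        if y.shape != Xn.shape[:1] + Xn.shape[2:]:
            raise ValueError(
                f"mask shape {y.shape} does not match inputs {Xn.shape}")
        yb = y.astype(np.float32)[:, None]
        self.model_ = self._build()
        # prior-initialized output bias: start the head at the foreground
        # rate instead of 0.5, which removes the early all-background
        # plateau BCE suffers under heavy class imbalance
        pos_rate = float(np.clip(yb.mean(), 1e-3, 1 - 1e-3))
        self.model_.head.b[:] = np.log(pos_rate / (1.0 - pos_rate))
        rng = np.random.default_rng(self.seed)
        loss_fn = SEGMENTATION_LOSSES[self.loss]

        n_val = int(round(self.validation_fraction * len(Xn)))
        idx = rng.permutation(len(Xn))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("validation split leaves no training samples")

        self.history_ = []
        params = self.model_.params()
        opt = make_optimizer(self.optimizer, params, self.learning_rate,
                             self.weight_decay, self.momentum)
        for epoch in range(self.epochs):
            opt.lr = scheduled_lr(self.learning_rate, epoch,
                                  self.lr_decay_factor, self.lr_decay_every)
            order = rng.permutation(tr_idx)
            losses = []
            for start in range(0, len(order), self.batch_size):
                b = order[start:start + self.batch_size]
                logits = self.model_.forward(Xn[b], train=True)
                loss, grad = loss_fn(logits, yb[b])
                if not np.isfinite(loss):
                    raise SegmentationError(
                        f"non-finite loss at epoch {epoch}")
                self.model_.backward_full(grad)
                opt.step()
                losses.append(loss)
            rec = {"epoch": epoch, "lr": opt.lr,
                   "loss": float(np.mean(losses))}
            if n_val:
                rec["val_dice"] = self._dice_on(Xn[val_idx], y[val_idx])
            self.history_.append(rec)
            if log_sink is not None:
                log_sink(rec)
        return self

    def _dice_on(self, Xn, y):
        pred = self._predict_nchw(Xn)
        return rates(pixel_confusion(pred, y)).dice

    # -- inference ----------------------------------------------------------
    def _predict_proba_nchw(self, Xn):
        if not hasattr(self, "model_"):
            raise SegmentationError("segmenter is not fitted")
        out = []
        for start in range(0, len(Xn), self.batch_size):
            out.append(self.model_.predict_proba(Xn[start:start + self.batch_size]))
        return np.concatenate(out)[:, 0]

    def _predict_nchw(self, Xn):
        return self._predict_proba_nchw(Xn) >= self.threshold

    def predict_proba(self, X):
        """Per-pixel abnormality probabilities, (n, h, w) in (0, 1)."""
        return self._predict_proba_nchw(self._as_nchw(X))

    def predict(self, X):
        """Binary masks, (n, h, w) boolean."""
        return self.predict_proba(X) >= self.threshold

    def score(self, X, y):
        """Dice coefficient over the whole batch (the model-selection
        criterion)."""
        return rates(pixel_confusion(self.predict(X), np.asarray(y))).dice

    # -- persistence --------------------------------------------------------
    def save(self, model_dir):
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.model_.state_dict())
        (d / "config.json").write_text(json.dumps(self.get_params(), indent=2))
        with open(d / "history.csv", "w") as fh:
            cols = sorted({k for rec in self.history_ for k in rec})
            fh.write(",".join(cols) + "\n")
            for rec in self.history_:
                fh.write(",".join(str(rec.get(c, "")) for c in cols) + "\n")

    @classmethod
    def load(cls, model_dir):
        d = Path(model_dir)
        est = cls(**json.loads((d / "config.json").read_text()))
        est.model_ = est._build()
        with np.load(d / "weights.npz") as data:
            est.model_.load_state_dict(dict(data))
        est.history_ = []
        return est


# ---------------------------------------------------------------------------
# raw-image entry points
# ---------------------------------------------------------------------------

def predict_mask(segmenter: SkinSegmenter, original: np.ndarray,
                 pair: DecomposedPair | None = None,
                 rng_seed: int = 0) -> np.ndarray:
    """Segment one raw RGB image, returning a mask in its coordinate frame.

    Decomposes the image if no pair is supplied and the segmenter expects
    9 channels.
    """
    if pair is None and segmenter.in_channels == 9:
        pair = decompose(original, rng_seed=rng_seed)
    stack, geom = stack_inputs(original, pair if segmenter.in_channels == 9 else None,
                               segmenter.input_size)
    prob = segmenter.predict_proba(stack[None])[0]
    return geom.to_original(prob >= segmenter.threshold)
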