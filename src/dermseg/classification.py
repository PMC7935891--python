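"""Per-lesion disease classification.

Each localized crop is classified independently, so one photograph can carry
several diseases. The tested backbone is a compact CNN (three conv blocks,
global average pooling, softmax head); the ``efficientnet_b4`` profile name
is reserved for plugging in a full-scale backbone implementation and the
class count is configurable (the motivating application uses 18 diagnosis
categories).

Also here: the dataset-refinement filter (drop crops that are too small or
that miss every true lesion — the automatic surrogate for a manual quality
pass) and class balancing by augmentation-resampling or SMOTE-style pixel
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors

from ._nn import CLASSIFICATION_LOSSES, SmallCNN, make_optimizer, scheduled_lr


class ClassificationError(RuntimeError):
    pass


DEFAULT_CLASS_NAMES_18 = (
    "Acne and Rosacea", "Actinic keratosis", "Atopic dermatitis",
    "Bullous disease", "Cellulitis", "Contact dermatitis", "Eczema",
    "Exanthems", "Fungal infections", "Herpes", "Light chain disease",
    "Lupus erythematosus", "Psoriasis", "Scabies", "Systemic disease",
    "Urticaria", "Vasculitis", "Viral infections",
)


@dataclass
class Prediction:
    class_index: int
    class_name: str
    confidence: float
    full_distribution: np.ndarray


# ---------------------------------------------------------------------------
# dataset refinement and balancing
# ---------------------------------------------------------------------------

def refine_dataset(clusters, labels, truth_masks=None, min_area=50,
                   min_overlap=0.3):
    """Filter out crops that are too small or incorrectly segmented.

    ``truth_masks`` aligns with clusters (one truth mask per crop's source
    image). A crop is "incorrectly segmented" when the fraction of its bbox
    covered by true lesion pixels falls below ``min_overlap``. Returns
    (kept_indices, exclusion_log) where the log lists (index, reason).
    """
    kept, log = [], []
    for i, cluster in enumerate(clusters):
        if cluster.area < min_area:
            log.append((i, "too small"))
            continue
        if truth_masks is not None:
            truth = np.asarray(truth_masks[i]).astype(bool)
            rmin, cmin, rmax, cmax = cluster.bbox
            bbox_area = (rmax - rmin) * (cmax - cmin)
            overlap = truth[rmin:rmax, cmin:cmax].sum() / max(bbox_area, 1)
            if overlap < min_overlap:
                log.append((i, "incorrect segmentation"))
                continue
        kept.append(i)
    return kept, log


def _augment(rng, img):
    """Label-preserving flip/rotation augmentation."""
    k = int(rng.integers(0, 4))
    out = np.rot90(img, k)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def balance_classes(X, y, strategy="augment", seed=0):
    """Oversample minority classes to the majority count.

    ``augment``: seeded resampling with flips/rotations (the default — safe
    for images); ``smote``: interpolate between nearest neighbors in
    flattened pixel space.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing requires at least 2 classes present")
    target = counts.max()
    rng = np.random.default_rng(seed)
    out_X, out_y = [X], [y]
    for c, n_c in zip(classes, counts):
        deficit = target - n_c
        if deficit == 0:
            continue
        pool = np.where(y == c)[0]
        if strategy == "augment":
            picks = rng.choice(pool, size=deficit, replace=True)
            out_X.append(np.stack([_augment(rng, X[i]) for i in picks]))
        elif strategy == "smote":
            flat = X[pool].reshape(len(pool), -1).astype(float)
            k = min(5, len(pool) - 1)
            if k < 1:
                picks = rng.choice(pool, size=deficit, replace=True)
                out_X.append(X[picks].copy())
            else:
                nn = NearestNeighbors(n_neighbors=k + 1).fit(flat)
                _, nbrs = nn.kneighbors(flat)
                new = np.empty((deficit,) + X.shape[1:], dtype=X.dtype)
                for j in range(deficit):
                    i = rng.integers(0, len(pool))
                    nb = nbrs[i][1 + rng.integers(0, k)]
                    lam = rng.random()
                    interp = flat[i] + lam * (flat[nb] - flat[i])
                    new[j] = interp.reshape(X.shape[1:]).astype(X.dtype)
                out_X.append(new)
        else:
            raise ValueError(f"unknown strategy '{strategy}'")
        out_y.append(np.full(deficit, c, dtype=y.dtype))
    return np.concatenate(out_X), np.concatenate(out_y)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class LesionClassifier(BaseEstimator, ClassifierMixin):
    """Compact CNN classifier over lesion crops (sklearn protocol).

    Defaults follow the full-scale recipe: categorical cross-entropy, Adam
    at 1e-5 with weight decay 5e-4, 80 epochs, learning rate x0.1 every 20.
    The miniature profile shortens this for CPU-scale experiments.
    """

    def __init__(self, backbone="small_cnn", n_classes=18, input_size=64,
                 base_channels=8, loss="cce", optimizer="adam",
                 learning_rate=1e-5, weight_decay=5e-4, momentum=0.9,
                 epochs=80, lr_decay_factor=0.1, lr_decay_every=20,
                 oversample=False, batch_size=16, class_names=None, seed=0):
        self.backbone = backbone
        self.n_classes = n_classes
        self.input_size = input_size
        self.base_channels = base_channels
        self.loss = loss
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.epochs = epochs
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.oversample = oversample
        self.batch_size = batch_size
        self.class_names = class_names
        self.seed = seed

    @classmethod
    def miniature_profile(cls, **overrides):
        kw = dict(n_classes=3, input_size=32, epochs=20, learning_rate=2e-3,
                  batch_size=16)
        kw.update(overrides)
        return cls(**kw)

    def _build(self):
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.loss not in CLASSIFICATION_LOSSES:
            raise ValueError(f"unknown loss '{self.loss}'")
        if self.backbone == "small_cnn":
            return SmallCNN(in_channels=3, n_classes=self.n_classes,
                            base_channels=self.base_channels, seed=self.seed)
        if self.backbone == "efficientnet_b4":
            raise ClassificationError(
                "the 'efficientnet_b4' profile delegates to an external "
                "EfficientNet implementation; none is installed — use the "
                "'small_cnn' backbone")
        raise ValueError(f"unknown backbone '{self.backbone}'")

    @staticmethod
    def _as_nchw(X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"expected (n, s, s, 3) crops, got {X.shape}")
        if X.max() > 1.5:  # accept [0,255] or [0,1]
            X = X / 255.0
        return X.transpose(0, 3, 1, 2)

    def fit(self, X, y):
        """X: (n, s, s, 3) crops; y: (n,) integer labels."""
        y = np.asarray(y, dtype=int)
        if len(y) and (y.min() < 0 or y.max() >= self.n_classes):
            raise ValueError(
                f"labels must lie in [0, {self.n_classes}), got range "
                f"[{y.min()}, {y.max()}]")
        X = np.asarray(X)
        if self.oversample:
            X, y = balance_classes(X, y, strategy="augment", seed=self.seed)
        Xn = self._as_nchw(X)
        self.model_ = self._build()
        self.classes_ = np.arange(self.n_classes)
        rng = np.random.default_rng(self.seed)
        loss_fn = CLASSIFICATION_LOSSES[self.loss]
        opt = make_optimizer(self.optimizer, self.model_.params(),
                             self.learning_rate, self.weight_decay,
                             self.momentum)
        self.history_ = []
        for epoch in range(self.epochs):
            opt.lr = scheduled_lr(self.learning_rate, epoch,
                                  self.lr_decay_factor, self.lr_decay_every)
            order = rng.permutation(len(Xn))
            losses = []
            for start in range(0, len(order), self.batch_size):
                b = order[start:start + self.batch_size]
                logits = self.model_.forward(Xn[b], train=True)
                loss, grad = loss_fn(logits, y[b])
                if not np.isfinite(loss):
                    raise ClassificationError(f"non-finite loss at epoch {epoch}")
                self.model_.backward_full(grad)
                opt.step()
                losses.append(loss)
            acc = float(np.mean(self._predict_nchw(Xn) == y))
            self.history_.append({"epoch": epoch, "lr": opt.lr,
                                  "loss": float(np.mean(losses)),
                                  "train_accuracy": acc})
        return self

    def _predict_proba_nchw(self, Xn):
        if not hasattr(self, "model_"):
            raise ClassificationError("classifier is not fitted")
        out = []
        for start in range(0, len(Xn), self.batch_size):
            out.append(self.model_.predict_proba(Xn[start:start + self.batch_size]))
        return np.concatenate(out)

    def _predict_nchw(self, Xn):
        P = self._predict_proba_nchw(Xn)
        return np.argmin(-P, axis=1)  # argmax, lowest index on ties

    def predict_proba(self, X):
        return self._predict_proba_nchw(self._as_nchw(X))

    def predict(self, X):
        return self._predict_nchw(self._as_nchw(X))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def classify(model: LesionClassifier, crop: np.ndarray) -> Prediction:
    """Classify one crop, returning label, confidence, and the full
    distribution (ties broken toward the lowest class index)."""
    dist = model.predict_proba(np.asarray(crop)[None])[0]
    idx = int(np.argmin(-dist))
    names = model.class_names
    if names is None:
        names = (DEFAULT_CLASS_NAMES_18 if model.n_classes == 18
                 else tuple(f"class_{i}" for i in range(model.n_classes)))
    return Prediction(class_index=idx, class_name=names[idx],
                      confidence=float(dist[idx]), full_distribution=dist)
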