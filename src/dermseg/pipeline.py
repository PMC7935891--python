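"""End-to-end orchestration: analyze one image, or run the full experiment.

``analyze_skin`` is the deployment path: decompose -> segment -> localize ->
classify each cluster, returning a JSON-ready report (one entry per lesion,
so several diseases can be reported for a single photograph).

``run_experiment`` is the study protocol at a configurable scale: it
generates a synthetic dataset with distractor background, splits it by
source image (crops never cross the train/test boundary), trains the
segmentation arms (with / without chromophore decomposition) and the three
classification arms (whole images / contextual crops / refined crops), and
emits the two metric tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .classification import LesionClassifier, classify, refine_dataset
from .decomposition import decompose, estimate_density_matrix_pooled
from .evaluation import classification_report, hausdorff, pixel_confusion, rates
from .localization import LocalizationParams, localize
from .model_selection import split_by_source
from .segmentation import SkinSegmenter, predict_mask, resize_mask_to, stack_inputs
from .synthetic import SyntheticParams, generate_dataset

logger = logging.getLogger(__name__)


def analyze_skin(image, seg_model: SkinSegmenter, clf_model: LesionClassifier,
                 localization: LocalizationParams | None = None,
                 rng_seed: int = 0, image_path: str | None = None) -> dict:
    """Full two-phase analysis of one RGB image; returns the report dict."""
    image = np.asarray(image)
    report = {"image_path": image_path, "clusters": [],
              "config": {"segmenter": seg_model.get_params(),
                         "classifier": clf_model.get_params()},
              "timings": {}}
    t0 = time.perf_counter()
    pair = decompose(image, rng_seed=rng_seed) if seg_model.in_channels == 9 else None
    report["timings"]["decompose_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mask = predict_mask(seg_model, image, pair, rng_seed=rng_seed)
    report["timings"]["segment_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    localization = localization or LocalizationParams(
        target_size=clf_model.input_size)
    clusters = localize(image, mask, localization)
    for cluster in clusters:
        pred = classify(clf_model, cluster.crop)
        report["clusters"].append({
            "bbox": [int(v) for v in cluster.bbox],
            "area": int(cluster.area),
            "prediction": {
                "class_index": pred.class_index,
                "class_name": pred.class_name,
                "confidence": pred.confidence,
                "distribution": [float(p) for p in pred.full_distribution],
            },
        })
    report["timings"]["classify_s"] = time.perf_counter() - t0
    if not clusters:
        logger.info("analyze_skin: no abnormal-skin clusters found")
    return report


# ---------------------------------------------------------------------------
# experiment protocol
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Study-protocol settings at a configurable (default miniature) scale."""

    params: SyntheticParams = field(default_factory=lambda: SyntheticParams(
        height=64, width=64, lesion_radius=(5.0, 9.0),
        background_fraction=0.35, shading_sd=0.25, color_cast_sd=0.2,
        melanin_blobs=(1, 3), noise_sd=0.02))
    n_per_class: int = 40
    test_fraction: float = 0.2
    seg_epochs: int = 15
    seg_learning_rate: float = 1e-3
    clf_epochs: int = 12
    clf_learning_rate: float = 2e-3
    crop_size: int = 32
    min_overlap: float = 0.3
    pooled_density: bool = True
    seg_arms: tuple[str, ...] = ("with_decomposition", "without_decomposition")
    clf_arms: tuple[str, ...] = ("without_segmentation",
                                 "contextual_segmentation",
                                 "refined_contextual_segmentation")
    seed: int = 0


def _stacks_for(samples, with_pair, input_size, seed, density=None):
    X, Y = [], []
    for i, s in enumerate(samples):
        pair = (decompose(s.image, rng_seed=seed + i, density=density)
                if with_pair else None)
        stack, _ = stack_inputs(s.image, pair, input_size)
        X.append(stack)
        Y.append(resize_mask_to(s.mask, input_size))
    return np.stack(X).astype(np.float32), np.stack(Y)


def _segmentation_arm(samples, tr, te, with_pair, cfg: ExperimentConfig,
                      density=None):
    X, Y = _stacks_for(samples, with_pair, cfg.params.height, cfg.seed,
                       density=density)
    seg = SkinSegmenter.miniature_profile(
        input_size=cfg.params.height,
        in_channels=9 if with_pair else 3,
        epochs=cfg.seg_epochs, learning_rate=cfg.seg_learning_rate,
        seed=cfg.seed)
    seg.fit(X[tr], Y[tr])
    pred = seg.predict(X[te])
    counts = pixel_confusion(pred, Y[te])
    r = rates(counts)
    hd = []
    for p, t in zip(pred, Y[te]):
        if p.any() and t.any():
            hd.append(hausdorff(p, t))
    return seg, {"sensitivity": r.sensitivity, "specificity": r.specificity,
                 "dice": r.dice,
                 "hausdorff": float(np.mean(hd)) if hd else float("nan")}


def _crop_sets(samples, indices, seg, cfg: ExperimentConfig, with_pair=True,
               density=None):
    """Run the crop pipeline over source images; crops keep their source id."""
    loc = LocalizationParams(target_size=cfg.crop_size)
    crops, labels, clusters, truths, sources = [], [], [], [], []
    for i in indices:
        s = samples[i]
        pair = (decompose(s.image, rng_seed=cfg.seed + i, density=density)
                if with_pair else None)
        mask = predict_mask(seg, s.image, pair, rng_seed=cfg.seed + i)
        for cluster in localize(s.image, mask, loc):
            cluster.source_id = int(i)
            crops.append(cluster.crop)
            labels.append(s.label)
            clusters.append(cluster)
            truths.append(s.mask)
            sources.append(int(i))
    return crops, np.array(labels, dtype=int), clusters, truths, np.array(sources)


def _whole_images(samples, indices, size):
    out = []
    for i in indices:
        img = sktransform.resize(samples[i].image.astype(float), (size, size),
                                 order=1, preserve_range=True,
                                 anti_aliasing=False)
        out.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return np.stack(out), np.array([samples[i].label for i in indices], dtype=int)


def run_experiment(cfg: ExperimentConfig | None = None) -> dict:
    """Train and evaluate every configured arm; returns the metric tables."""
    cfg = cfg or ExperimentConfig()
    for arm in cfg.seg_arms:
        if arm not in ("with_decomposition", "without_decomposition"):
            raise ValueError(f"unknown segmentation arm '{arm}'")
    for arm in cfg.clf_arms:
        if arm not in ("without_segmentation", "contextual_segmentation",
                       "refined_contextual_segmentation"):
            raise ValueError(f"unknown classification arm '{arm}'")

    samples, _ = generate_dataset(cfg.params, cfg.n_per_class, seed=cfg.seed)
    source_ids = np.arange(len(samples))
    tr, te = split_by_source(source_ids, cfg.test_fraction, cfg.seed)
    report = {"segmentation": {}, "classification": {},
              "n_train_images": int(len(tr)), "n_test_images": int(len(te)),
              "exclusions": {}}

    # fit-once density estimation on training images only
    density = (estimate_density_matrix_pooled(
        [samples[i].image for i in tr], rng_seed=cfg.seed)
        if cfg.pooled_density else None)

    seg_with = None
    for arm in cfg.seg_arms:
        with_pair = arm == "with_decomposition"
        seg, metrics = _segmentation_arm(samples, tr, te, with_pair, cfg,
                                         density=density)
        report["segmentation"][arm] = metrics
        if with_pair:
            seg_with = seg
    if seg_with is None:  # classification arms need a segmenter
        seg_with, _ = _segmentation_arm(samples, tr, te, True, cfg,
                                        density=density)

    n_classes = cfg.params.n_classes
    clf_kw = dict(n_classes=n_classes, input_size=cfg.crop_size,
                  epochs=cfg.clf_epochs, learning_rate=cfg.clf_learning_rate,
                  seed=cfg.seed)

    need_crops = any(a != "without_segmentation" for a in cfg.clf_arms)
    if need_crops:
        tr_crops, tr_labels, tr_clusters, tr_truths, _ = _crop_sets(
            samples, tr, seg_with, cfg, density=density)
        te_crops, te_labels, te_clusters, te_truths, _ = _crop_sets(
            samples, te, seg_with, cfg, density=density)
        te_keep, te_log = refine_dataset(te_clusters, te_labels, te_truths,
                                         min_overlap=cfg.min_overlap)
        report["exclusions"]["test"] = [
            {"index": i, "reason": r} for i, r in te_log]
        Xte = np.stack([te_crops[i] for i in te_keep]) if te_keep else None
        yte = te_labels[te_keep]

    for arm in cfg.clf_arms:
        clf = LesionClassifier.miniature_profile(**clf_kw)
        if arm == "without_segmentation":
            Xtr, ytr = _whole_images(samples, tr, cfg.crop_size)
            Xev, yev = _whole_images(samples, te, cfg.crop_size)
        elif arm == "contextual_segmentation":
            if not len(tr_crops):
                report["classification"][arm] = {"error": "no training crops"}
                continue
            Xtr, ytr = np.stack(tr_crops), tr_labels
            Xev, yev = Xte, yte
        else:  # refined_contextual_segmentation
            keep, log = refine_dataset(tr_clusters, tr_labels, tr_truths,
                                       min_overlap=cfg.min_overlap)
            report["exclusions"]["train"] = [
                {"index": i, "reason": r} for i, r in log]
            if not keep:
                report["classification"][arm] = {
                    "error": "refinement excluded every training crop"}
                continue
            Xtr = np.stack([tr_crops[i] for i in keep])
            ytr = tr_labels[keep]
            Xev, yev = Xte, yte
        if Xev is None or not len(yev):
            report["classification"][arm] = {"error": "no evaluable test crops"}
            continue
        if len(np.unique(ytr)) < 2:
            report["classification"][arm] = {
                "error": "fewer than 2 classes among training crops"}
            continue
        clf.fit(Xtr, ytr)
        rep = classification_report(clf.predict_proba(Xev), yev, n_classes)
        report["classification"][arm] = {
            "accuracy": rep.accuracy,
            "auc": rep.weighted["auc"],
            "specificity": rep.weighted["specificity"],
            "sensitivity": rep.weighted["sensitivity"],
            "f1": rep.weighted["f1"],
            "topn": rep.topn,
            "n_train": int(len(ytr)), "n_test": int(len(yev)),
        }
    return report
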