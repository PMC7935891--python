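"""Replicated grid search and leakage-safe splitting.

Hyperparameters are selected by a three-replica protocol: each replica draws
its own 90/10 train/validation split of the training data, every grid point
is trained and scored on each replica, and scores are averaged across
replicas; the best configuration is the argmax, with ties broken by the
grid's declared ordering. The same machinery serves the segmenter
(validation Dice) and the classifier (validation accuracy).

Splits that feed the crop-then-classify pipeline must operate on *source
image* identifiers: crops inherit their source id, and a source never
appears on both sides of a split (subsections of one photograph in both
train and test would leak).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import clone


def replica_splits(n, n_replicas=3, val_fraction=0.1, seed=0):
    """Seeded (train_idx, val_idx) pairs, one per replica."""
    if n < 2:
        raise ValueError(f"need at least 2 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_fraction * n)))
    out = []
    for _ in range(n_replicas):
        perm = rng.permutation(n)
        out.append((perm[n_val:], perm[:n_val]))
    return out


def replica_grid_search(estimator, X, y, grid, n_replicas=3,
                        val_fraction=0.1, seed=0):
    """Score every grid point across seeded replicas; return the winner.

    ``grid`` is an ordered list of parameter dicts. Returns
    (best_params, table) where table rows carry the per-replica and mean
    validation scores (``estimator.score``).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X)
    y = np.asarray(y)
    splits = replica_splits(len(X), n_replicas, val_fraction, seed)
    table = []
    for point in grid:
        scores = []
        for tr, va in splits:
            est = clone(estimator).set_params(**point)
            est.fit(X[tr], y[tr])
            scores.append(float(est.score(X[va], y[va])))
        table.append({"params": dict(point), "scores": scores,
                      "mean_score": float(np.mean(scores))})
    best_i = int(np.argmax([row["mean_score"] for row in table]))
    return dict(grid[best_i]), table


def split_by_source(source_ids, test_fraction=0.2, seed=0):
    """Split sample indices so no source id crosses the boundary."""
    source_ids = np.asarray(source_ids)
    uniq = np.unique(source_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    n_test = max(1, int(round(test_fraction * len(uniq))))
    test_sources = set(perm[:n_test].tolist())
    test_mask = np.array([s in test_sources for s in source_ids])
    return np.where(~test_mask)[0], np.where(test_mask)[0]


# The hyperparameter grids of the full-scale protocol, in declared order.
SEGMENTATION_GRID = [
    {"loss": loss, "optimizer": opt, "learning_rate": lr, "epochs": ep,
     **({"momentum": 0.9} if opt == "sgd" else {})}
    for loss in ("bce", "dice")
    for opt, lrs in (("adam", (1e-4, 5e-5, 1e-5)),
                     ("rmsprop", (1e-4, 5e-5, 1e-5)),
                     ("sgd", (1e-1, 5e-2)))
    for lr in lrs
    for ep in (40, 60, 80)
]

CLASSIFICATION_GRID = [
    {"loss": loss, "optimizer": opt, "learning_rate": lr, "epochs": ep,
     **({"momentum": 0.9} if opt == "sgd" else {})}
    for loss in ("cce", "focal")
    for opt, lrs in (("adam", (1e-4, 5e-5, 1e-5)),
                     ("rmsprop", (1e-4, 5e-5, 1e-5)),
                     ("sgd", (1e-1, 5e-2)))
    for lr in lrs
    for ep in (40, 60, 80)
]
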