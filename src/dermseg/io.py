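"""Image, mask, and manifest I/O (PNG via Pillow, CSV manifests)."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image


def load_image(path) -> np.ndarray:
    """Load an RGB image as (h, w, 3) uint8."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) image, got shape {image.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.astype(np.uint8), mode="RGB").save(path)


def load_mask(path) -> np.ndarray:
    """Load a single-channel 0/255 mask PNG as (h, w) bool."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) >= 128


def save_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected (h, w) mask, got shape {mask.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def read_manifest(path):
    """Read a ``image,mask,label`` CSV; returns list of (image, mask, label)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            rows.append((rec["image"], rec.get("mask", ""), int(rec["label"])))
    return rows


def write_manifest(path, rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image", "mask", "label"])
        w.writerows(rows)
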