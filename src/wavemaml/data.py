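"""Labeled image-set container and PNG/CSV manifest I/O.

An :class:`ImageSet` is the in-memory currency between the scalogram stage
and the episodic trainer: a stack of grayscale images in ``[0, 1]``, integer
class labels, and a per-image metadata table (subject, channel, band, epoch)
that supports subject-grouped cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["ImageSet", "save_image_set", "load_image_set", "train_val_split"]


@dataclass
class ImageSet:
    """Stack of grayscale images with labels and optional metadata."""

    images: np.ndarray  # (N, H, W), float32 in [0, 1]
    labels: np.ndarray  # (N,), int
    meta: pd.DataFrame | None = None  # optional per-image rows

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3:
            raise ValueError(f"images must be (N, H, W), got shape {self.images.shape}")
        if len(self.labels) != len(self.images):
            raise ValueError("labels and images disagree in length")
        if self.images.size and (self.images.min() < -1e-6 or self.images.max() > 1 + 1e-6):
            raise ValueError("image values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx: np.ndarray) -> "ImageSet":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return ImageSet(self.images[idx], self.labels[idx], meta)


def save_image_set(dataset: ImageSet, out_dir: str | Path) -> pd.DataFrame:
    """Write one 8-bit grayscale PNG per image plus a ``manifest.csv``.

    Manifest columns: ``path, label`` plus any metadata columns present
    (``subject, band, channel, epoch``). Returns the manifest frame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(dataset.images, dataset.labels)):
        name = f"img_{i:06d}.png"
        arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / name)
        row = {"path": name, "label": int(label)}
        if dataset.meta is not None:
            row.update(dataset.meta.iloc[i].to_dict())
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=None)
    if not rows:
        manifest = pd.DataFrame(columns=["path", "label"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_image_set(in_dir: str | Path) -> ImageSet:
    """Load an image set written by :func:`save_image_set`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    images = []
    for path in manifest["path"]:
        with Image.open(in_dir / path) as im:
            images.append(np.asarray(im.convert("L"), dtype=np.float32) / 255.0)
    labels = manifest["label"].to_numpy()
    meta_cols = [c for c in manifest.columns if c not in ("path", "label")]
    meta = manifest[meta_cols].reset_index(drop=True) if meta_cols else None
    stack = np.stack(images) if images else np.zeros((0, 0, 0), dtype=np.float32)
    return ImageSet(stack, labels, meta)


def train_val_split(
    dataset: ImageSet, val_fraction: float = 0.2, seed: int = 0
) -> tuple[ImageSet, ImageSet]:
    """Stratified train/validation split (default 80/20), seeded."""
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in dataset.classes:
        idx = np.flatnonzero(dataset.labels == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(val_idx))
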