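"""Multi-crop test-time evaluation.

At test time the unscaled image is cropped into an ``n x n`` grid of
equally sized regions of interest spread equidistantly from the upper-left
corner to the lower-right corner (default 16 crops of 224x224), and the
classifier's per-crop probability vectors are averaged into the final
prediction.  Averaging probabilities keeps the output a valid distribution
(a convex combination of distributions).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["CropGrid", "grid_crops", "make_crop_grid", "multicrop_predict"]


@dataclasses.dataclass(frozen=True)
class CropGrid:
    crop_size: tuple[int, int]  # (height, width)
    offsets: tuple[tuple[int, int], ...]  # (x, y) top-left corners
    n_per_axis: int


def make_crop_grid(
    image_shape: tuple[int, int],
    crop_size: tuple[int, int] = (224, 224),
    n_per_axis: int = 4,
) -> CropGrid:
    """Equidistant top-left offsets: rounded linspace from 0 to the maximal
    in-bounds offset along each axis, both extremes included."""
    h, w = image_shape[:2]
    ch, cw = crop_size
    if h < ch or w < cw:
        raise ValueError(f"image {h}x{w} smaller than crop {ch}x{cw}")
    xs = np.round(np.linspace(0, w - cw, n_per_axis)).astype(int)
    ys = np.round(np.linspace(0, h - ch, n_per_axis)).astype(int)
    offsets = tuple((int(x), int(y)) for y in ys for x in xs)
    return CropGrid(crop_size=(ch, cw), offsets=offsets, n_per_axis=n_per_axis)


def grid_crops(
    image: np.ndarray,
    crop_size: tuple[int, int] = (224, 224),
    n_per_axis: int = 4,
) -> list[np.ndarray]:
    """Cut the ``n_per_axis**2`` grid crops out of one image (row-major)."""
    grid = make_crop_grid(image.shape[:2], crop_size, n_per_axis)
    ch, cw = grid.crop_size
    return [image[y : y + ch, x : x + cw] for x, y in grid.offsets]


def multicrop_predict(model, image: np.ndarray, crop_grid: CropGrid) -> np.ndarray:
    """Average the model's class probabilities over all grid crops.

    ``model`` is either a callable mapping one crop to a probability vector or
    an estimator with ``predict_proba`` over a batch of crops.
    """
    ch, cw = crop_grid.crop_size
    crops = [image[y : y + ch, x : x + cw] for x, y in crop_grid.offsets]
    if hasattr(model, "predict_proba"):
        probs = np.asarray(model.predict_proba(np.stack(crops)))
    else:
        probs = np.stack([np.asarray(model(c), dtype=np.float64) for c in crops])
    if probs.ndim != 2 or probs.shape[0] != len(crops):
        raise ValueError("model must return one probability vector per crop")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("model output rows must sum to 1 (probabilities, not logits)")
    return probs.mean(axis=0)
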