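"""Grad-CAM++ class activation heatmaps.

Given the feature maps ``A^k`` of the last convolutional layer and the first
three derivatives of a target class score ``Z_i`` with respect to them, the
pixel-wise gradient weights are

    alpha^{ki}_{mn} = d2Z / (2 d2Z + sum_{m,n} A^k d3Z),

the per-map channel weights are

    w^i_k = sum_{m,n} alpha^{ki}_{mn} relu(dZ/dA^k_{mn}),

and the heatmap is

    L^i_{mn} = relu(sum_k w^i_k A^k_{mn}),

nonnegative by construction.  Where the alpha denominator vanishes it is
replaced by 1, so alpha degrades gracefully to 0 when the numerator is also 0
(e.g. a score exactly linear in the feature maps).

How the three derivative tensors are produced is the backbone's concern; for
a global-average-pooling + linear head the exponential-score closed form is
used (see :meth:`lca.backbone.SmallCNNClassifier.feature_stack`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import transform as sktransform

__all__ = ["FeatureMapStack", "Heatmap", "alpha_weights", "channel_weights", "heatmap",
           "compute_heatmap", "overlay_heatmap"]

DENOM_EPS = 1e-8


@dataclasses.dataclass(frozen=True)
class FeatureMapStack:
    """Last-conv feature maps A (K,M,N) and dZ/dA, d2Z/dA2, d3Z/dA3."""

    A: np.ndarray
    grads1: np.ndarray
    grads2: np.ndarray
    grads3: np.ndarray
    target_class: int = 0

    def __post_init__(self):
        shapes = {t.shape for t in (self.A, self.grads1, self.grads2, self.grads3)}
        if len(shapes) != 1 or self.A.ndim != 3:
            raise ValueError("A and grads1..3 must share one (K, M, N) shape")


@dataclasses.dataclass(frozen=True)
class Heatmap:
    """Spatial relevance map for one image and one target class."""

    L: np.ndarray  # (M, N), nonnegative
    target_class: int

    @property
    def normalized(self) -> np.ndarray:
        """Min-max rescale to [0,1]; an all-constant map normalizes to zeros."""
        lo, hi = float(self.L.min()), float(self.L.max())
        if hi - lo < 1e-12:
            return np.zeros_like(self.L)
        return (self.L - lo) / (hi - lo)

    def upsampled(self, shape: tuple[int, int]) -> np.ndarray:
        """Bilinear upsample of the normalized map to image resolution."""
        return sktransform.resize(self.normalized, shape, order=1, mode="edge",
                                  anti_aliasing=False)


def alpha_weights(stack: FeatureMapStack) -> np.ndarray:
    """Pixel-wise gradient weights alpha^{ki}_{mn} (shape K,M,N)."""
    num = stack.grads2
    spatial = (stack.A * stack.grads3).sum(axis=(1, 2), keepdims=True)
    den = 2.0 * stack.grads2 + spatial
    den = np.where(np.abs(den) < DENOM_EPS, 1.0, den)
    return num / den


def channel_weights(stack: FeatureMapStack, alphas: np.ndarray) -> np.ndarray:
    """Channel weights w^i_k = sum_{m,n} alpha * relu(dZ/dA) (length K)."""
    if alphas.shape != stack.A.shape:
        raise ValueError("alphas must match the feature-map shape")
    return (alphas * np.maximum(stack.grads1, 0.0)).sum(axis=(1, 2))


def heatmap(stack: FeatureMapStack, weights: np.ndarray) -> Heatmap:
    """L = relu(sum_k w_k A^k)."""
    if weights.shape != (stack.A.shape[0],):
        raise ValueError("weights must have length K")
    L = np.maximum(np.tensordot(weights, stack.A, axes=1), 0.0)
    return Heatmap(L=L, target_class=stack.target_class)


def compute_heatmap(stack: FeatureMapStack) -> Heatmap:
    """The full three-step composition alpha -> w -> L."""
    alphas = alpha_weights(stack)
    w = channel_weights(stack, alphas)
    return heatmap(stack, w)


def overlay_heatmap(image: np.ndarray, hm: Heatmap, alpha: float = 0.4) -> np.ndarray:
    """Blend the jet-colored upsampled heatmap over an RGB image (uint8 out)."""
    from matplotlib import colormaps

    img = image.astype(np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    up = hm.upsampled(img.shape[:2])
    colored = colormaps["jet"](up)[..., :3]
    blend = (1 - alpha) * img + alpha * colored
    return np.round(np.clip(blend, 0, 1) * 255).astype(np.uint8)
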