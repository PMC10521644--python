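"""Small reference CNN backbone, pure NumPy, sklearn-style.

Two stride-2 3x3 convolutions with ReLU, a 2x2 average pooling, and a linear
head over the flattened pooled maps.  Deliberately tiny: it trains on a CPU
in seconds, needs no pretrained weights, and exposes exactly the contract
the search pipeline and Grad-CAM++ require from any pluggable backbone:

* ``predict_proba(X)`` over a batch of H x W x 3 images,
* ``train_step(X, y, class_weights, lr)`` for one Adam step,
* ``feature_stack(image, class)`` returning the last-conv feature maps and
  the first three derivatives of the class score for Grad-CAM++.

Because the head is linear in the (post-ReLU) feature maps, the raw class
score has vanishing second and third derivatives; the standard remedy is to
differentiate the exponential of the score instead, which has nonzero
derivatives of all orders and leaves the normalized heatmap unchanged.

The head's input dimension depends on the image size, so its weights are
created lazily at the first forward pass; a model therefore expects a fixed
input size once trained (the pipeline always feeds fixed-size crops).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .gradcam import FeatureMapStack
from .losses import softmax_probs

__all__ = ["SmallCNNClassifier"]

_K = 3  # kernel size
_STRIDE = 2
_PAD = 1


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B,C,H,W) -> (B,C,Ho,Wo,k,k) windows with stride 2, pad 1."""
    xp = np.pad(x, ((0, 0), (0, 0), (_PAD, _PAD), (_PAD, _PAD)))
    win = sliding_window_view(xp, (_K, _K), axis=(2, 3))
    return win[:, :, ::_STRIDE, ::_STRIDE]


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    win = _im2col(x)
    out = np.einsum("bchwij,fcij->bfhw", win, W, optimize=True) + b[None, :, None, None]
    return out, win


def _conv_backward(dout: np.ndarray, win: np.ndarray, W: np.ndarray, x_shape):
    dW = np.einsum("bchwij,bfhw->fcij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    gwin = np.einsum("bfhw,fcij->bchwij", dout, W, optimize=True)
    B, C, H, Wd = x_shape
    dxp = np.zeros((B, C, H + 2 * _PAD, Wd + 2 * _PAD))
    Ho, Wo = dout.shape[2], dout.shape[3]
    for i in range(_K):
        for j in range(_K):
            dxp[:, :, i : i + _STRIDE * Ho : _STRIDE, j : j + _STRIDE * Wo : _STRIDE] += gwin[
                :, :, :, :, i, j
            ]
    return dxp[:, :, _PAD : _PAD + H, _PAD : _PAD + Wd], dW, db


class _Adam:
    """Adam with lazily registered parameters (the head appears after the
    first forward pass fixes the input size)."""

    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


class SmallCNNClassifier(BaseEstimator, ClassifierMixin):
    """Tiny CNN classifier over RGB images.

    Parameters
    ----------
    n_filters : (int, int)
        Channels of the two convolutional layers.
    learning_rate : float
        Constant learning rate used by plain :meth:`fit`; the search pipeline
        drives :meth:`train_step` with its own schedule instead.
    n_epochs, batch_size : int
        Training loop settings for plain :meth:`fit`.
    random_state : int or None
        Seed for weight initialization and batch shuffling.
    """

    def __init__(self, n_filters=(8, 16), learning_rate=1e-3, n_epochs=10,
                 batch_size=32, random_state=None):
        self.n_filters = n_filters
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # -- parameter management -------------------------------------------------

    def init_params(self, n_classes: int, rng: np.random.Generator | None = None):
        """(Re-)initialize conv weights (He init); the linear head is created
        at the first forward pass, when the input size is known.  Called by
        fit and by the search pipeline, which needs a fresh model per fold."""
        if rng is None:
            rng = np.random.default_rng(self.random_state)
        f1, f2 = self.n_filters
        self.params_ = {
            "W1": rng.normal(0, np.sqrt(2.0 / (3 * _K * _K)), (f1, 3, _K, _K)),
            "b1": np.zeros(f1),
            "W2": rng.normal(0, np.sqrt(2.0 / (f1 * _K * _K)), (f2, f1, _K, _K)),
            "b2": np.zeros(f2),
        }
        self.optimizer_ = _Adam()
        self.n_classes_ = n_classes
        self._head_rng = rng
        return self

    def _ensure_head(self, pooled_shape: tuple[int, int, int]):
        if "Wd" in self.params_:
            return
        f2, m2, n2 = pooled_shape
        d = f2 * m2 * n2
        self.params_["Wd"] = self._head_rng.normal(0, np.sqrt(2.0 / d), (self.n_classes_, d))
        self.params_["bd"] = np.zeros(self.n_classes_)
        self._pooled_shape = (f2, m2, n2)

    def _as_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[None]
        if np.issubdtype(X.dtype, np.integer):
            X = X.astype(np.float64) / 255.0
        # center to roughly zero mean: all-positive inputs condition the
        # first layer badly and cost several epochs of plateau
        return np.ascontiguousarray(X.transpose(0, 3, 1, 2)) - 0.5  # BHWC -> BCHW

    # -- forward / backward ---------------------------------------------------

    def _forward(self, xb: np.ndarray):
        p = self.params_
        z1, win1 = _conv_forward(xb, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        z2, win2 = _conv_forward(a1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)  # last-conv feature maps
        B, f2, M, N = a2.shape
        m2, n2 = M // 2, N // 2
        pooled = a2[:, :, : 2 * m2, : 2 * n2].reshape(B, f2, m2, 2, n2, 2).mean(axis=(3, 5))
        self._ensure_head((f2, m2, n2))
        flat = pooled.reshape(B, -1)
        logits = flat @ p["Wd"].T + p["bd"]
        cache = (xb, z1, a1, win1, z2, a2, win2, flat)
        return logits, cache

    def train_step(self, X, y, class_weights=None, lr: float | None = None) -> float:
        """One Adam step on a batch; returns the weighted cross-entropy."""
        xb = self._as_batch(X)
        y = np.asarray(y)
        p = self.params_
        logits, (x, z1, a1, win1, z2, a2, win2, flat) = self._forward(xb)
        probs = softmax_probs(logits)
        B, C = probs.shape
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        w = np.ones(C) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
        wv = w[y]
        loss = float(np.mean(wv * -np.log(np.clip(probs[np.arange(B), y], 1e-12, None))))

        dlogits = wv[:, None] * (probs - onehot) / B
        grads = {"Wd": dlogits.T @ flat, "bd": dlogits.sum(axis=0)}
        f2, m2, n2 = self._pooled_shape
        dpooled = (dlogits @ p["Wd"]).reshape(B, f2, m2, n2)
        da2 = np.zeros_like(a2)
        da2[:, :, : 2 * m2, : 2 * n2] = np.repeat(np.repeat(dpooled, 2, axis=2), 2, axis=3) / 4.0
        dz2 = da2 * (z2 > 0)
        da1, grads["W2"], grads["b2"] = _conv_backward(dz2, win2, p["W2"], a1.shape)
        dz1 = da1 * (z1 > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(dz1, win1, p["W1"], x.shape)
        self.optimizer_.step(p, grads, self.learning_rate if lr is None else lr)
        return loss

    # -- sklearn surface ------------------------------------------------------

    def fit(self, X, y, class_weights=None):
        """Plain training loop at a constant learning rate (no augmentation);
        the search pipeline implements the full augmented protocol."""
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n_samples, H, W, 3)")
        rng = np.random.default_rng(self.random_state)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.init_params(len(self.classes_), rng)
        n = len(X)
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                self.train_step(X[idx], y_enc[idx], class_weights)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        logits, _ = self._forward(self._as_batch(X))
        return logits

    def predict_proba(self, X):
        return softmax_probs(self.decision_function(X))

    def predict(self, X):
        idx = self.predict_proba(X).argmax(axis=1)
        classes = getattr(self, "classes_", np.arange(self.n_classes_))
        return classes[idx]

    # -- Grad-CAM++ contract --------------------------------------------------

    def feature_maps(self, image) -> np.ndarray:
        """Last-conv (post-ReLU) feature maps A, shape (K, M, N)."""
        check_is_fitted(self, "params_")
        _, cache = self._forward(self._as_batch(image))
        return cache[5][0]

    def _score_gradient_map(self, target_class: int) -> np.ndarray:
        """dZ_i/dA as a (K,M,N) map: the head is average-pool + linear, so the
        gradient is the head weight spread uniformly over each 2x2 pool cell
        (zero on rows/columns cropped by the pooling)."""
        f2, m2, n2 = self._pooled_shape
        wrow = self.params_["Wd"][target_class].reshape(f2, m2, n2)
        g = np.repeat(np.repeat(wrow, 2, axis=1), 2, axis=2) / 4.0
        return g

    def feature_stack(self, image, target_class: int) -> FeatureMapStack:
        """A and dS/dA, d2S/dA2, d3S/dA3 for the exponential score S=exp(Z).

        Z is linear in A with pixelwise gradient map g, so dS/dA = S g,
        d2S/dA2 = S g^2, d3S/dA3 = S g^3 elementwise.  S is evaluated as
        exp(Z - max(Z)) — a positive rescale that leaves the Grad-CAM++
        alpha weights and the normalized heatmap unchanged but cannot
        overflow.
        """
        check_is_fitted(self, "params_")
        logits, cache = self._forward(self._as_batch(image))
        A = cache[5][0]
        K, M, N = A.shape
        g = np.zeros((K, M, N))
        gcore = self._score_gradient_map(target_class)
        g[:, : gcore.shape[1], : gcore.shape[2]] = gcore
        s = float(np.exp(logits[0, target_class] - logits[0].max()))
        return FeatureMapStack(
            A=A,
            grads1=s * g,
            grads2=s * g**2,
            grads3=s * g**3,
            target_class=target_class,
        )
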