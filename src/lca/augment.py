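"""Low-Cost-Augment (LCA) search space and stochastic augmentation executor.

The LCA space is an unordered set of 12 subpolicies, each pairing one color
transform with one geometric transform.  There are 12 distinct color ops and
only 6 geometric ops, so every geometric op appears in exactly two
subpolicies, giving color and geometric families the same marginal selection
probability.  During training one subpolicy is drawn uniformly per image and
each of its two ops executes independently with a single probability ``P`` —
the only searched hyperparameter.  ``P`` is restricted to a small ladder of
candidate values (default ``[0.1, 0.3, 0.5, 0.7, 0.9]``), so the whole search
space has ``12 * 5 = 60`` (subpolicy, probability) combinations.

Images are handled as float arrays in ``[0, 1]`` internally; 8-bit inputs are
converted on the way in and restored on the way out.  Every op clips its
output back into the valid range, and geometric ops preserve the image frame
(reflected padding for exposed pixels; scale is cropped/padded back).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import exposure as skexposure
from skimage import transform as sktransform

__all__ = [
    "TransformOp",
    "Subpolicy",
    "SearchSpace",
    "AugmentationStrategy",
    "build_default_space",
    "enumerate_candidates",
    "sample_subpolicy",
    "apply_strategy",
    "apply_op",
    "load_space_yaml",
    "COLOR_OPS",
    "GEOMETRIC_OPS",
]

DEFAULT_LADDER = (0.1, 0.3, 0.5, 0.7, 0.9)


# ---------------------------------------------------------------------------
# elementary transforms (float image in [0,1], channel-last RGB)
# ---------------------------------------------------------------------------

def _to_float(image: np.ndarray) -> tuple[np.ndarray, np.dtype]:
    dtype = image.dtype
    if np.issubdtype(dtype, np.integer):
        return image.astype(np.float64) / 255.0, dtype
    return image.astype(np.float64), dtype


def _from_float(image: np.ndarray, dtype: np.dtype) -> np.ndarray:
    image = np.clip(image, 0.0, 1.0)
    if np.issubdtype(dtype, np.integer):
        return np.round(image * 255.0).astype(dtype)
    return image.astype(dtype)


def _gray(image: np.ndarray) -> np.ndarray:
    g = image @ np.array([0.299, 0.587, 0.114])
    return g[..., None]


def _brightness(img, m, rng):
    return img * m


def _contrast(img, m, rng):
    mu = _gray(img).mean()
    return (img - mu) * m + mu


def _saturation(img, m, rng):
    g = _gray(img)
    return g + (img - g) * m


def _hue_shift(img, m, rng):
    hsv = skcolor.rgb2hsv(np.clip(img, 0, 1))
    hsv[..., 0] = (hsv[..., 0] + m) % 1.0
    return skcolor.hsv2rgb(hsv)


def _color_jitter(img, m, rng):
    # deterministic channel-gain tilt: warms/cools the image by magnitude
    gains = np.array([1.0 + m, 1.0, 1.0 - m])
    return img * gains


def _gaussian_noise(img, m, rng):
    if m == 0:
        return img.copy()
    return img + rng.normal(0.0, m, size=img.shape)


def _sharpness(img, m, rng):
    blurred = ndi.gaussian_filter(img, sigma=(1.0, 1.0, 0.0))
    return img + m * (img - blurred)


def _posterize(img, m, rng):
    bits = int(round(m))
    levels = 2**bits
    return np.floor(np.clip(img, 0, 1) * (levels - 1) + 0.5) / (levels - 1)


def _solarize(img, m, rng):
    out = img.copy()
    mask = out >= m
    out[mask] = 1.0 - out[mask]
    return out


def _equalize(img, m, rng):
    eq = np.stack(
        [skexposure.equalize_hist(np.clip(img[..., c], 0, 1)) for c in range(img.shape[-1])],
        axis=-1,
    )
    return (1.0 - m) * img + m * eq


def _autocontrast(img, m, rng):
    out = np.empty_like(img)
    for c in range(img.shape[-1]):
        ch = img[..., c]
        lo, hi = np.quantile(ch, [m, 1.0 - m])
        if hi - lo < 1e-9:
            out[..., c] = ch
        else:
            out[..., c] = (ch - lo) / (hi - lo)
    return out


def _gamma(img, m, rng):
    return np.power(np.clip(img, 0, 1), m)


def _hflip(img, m, rng):
    return img[:, ::-1]


def _vflip(img, m, rng):
    return img[::-1]


def _rotate(img, m, rng):
    if m == 0:
        return img.copy()
    return sktransform.rotate(img, angle=m, mode="reflect", order=1, preserve_range=True)


def _scale(img, m, rng):
    # rescale, then center-crop (zoom in) or reflect-pad (zoom out) back
    if m == 1.0:
        return img.copy()
    h, w = img.shape[:2]
    scaled = sktransform.rescale(
        img, m, channel_axis=-1, mode="reflect", order=1, preserve_range=True, anti_aliasing=m < 1.0
    )
    sh, sw = scaled.shape[:2]
    if sh >= h and sw >= w:
        top, left = (sh - h) // 2, (sw - w) // 2
        return scaled[top : top + h, left : left + w]
    ph, pw = h - sh, w - sw
    pads = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0))
    return np.pad(scaled, pads, mode="reflect")


def _translate(img, m, rng):
    if m == 0:
        return img.copy()
    h, w = img.shape[:2]
    dy, dx = int(round(m * h)), int(round(m * w))
    return np.pad(img, ((abs(dy),) * 2, (abs(dx),) * 2, (0, 0)), mode="reflect")[
        abs(dy) - dy : abs(dy) - dy + h, abs(dx) - dx : abs(dx) - dx + w
    ]


def _shear(img, m, rng):
    if m == 0:
        return img.copy()
    h, w = img.shape[:2]
    # shear about the image center so the content stays framed
    center = np.array([w / 2.0, h / 2.0])
    tf = (
        sktransform.AffineTransform(translation=-center)
        + sktransform.AffineTransform(shear=m)
        + sktransform.AffineTransform(translation=center)
    )
    return sktransform.warp(img, tf.inverse, mode="reflect", order=1, preserve_range=True)


# ---------------------------------------------------------------------------
# op registry and domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TransformOp:
    """One augmentation primitive with its magnitude range.

    ``apply`` is a pure function ``(image, magnitude, rng) -> image`` on float
    images in [0,1]; only ``gaussian_noise`` consumes the rng.  Units are
    op-specific: degrees (rotate), fraction of side (translate), multiplicative
    factor (scale/brightness/contrast/saturation/sharpness/gamma), hue offset
    (hue), intensity std-dev (gaussian_noise), bits (posterize), threshold
    (solarize), blend/cutoff fraction (equalize/autocontrast/color_jitter).
    """

    name: str
    category: str  # "color" | "geometric"
    magnitude_range: tuple[float, float]
    apply: Callable[[np.ndarray, float, np.random.Generator], np.ndarray] = dataclasses.field(
        compare=False
    )

    def __post_init__(self):
        if self.category not in ("color", "geometric"):
            raise ValueError(f"unknown category {self.category!r}")
        lo, hi = self.magnitude_range
        if lo > hi:
            raise ValueError(f"invalid magnitude range for {self.name}: [{lo}, {hi}]")


COLOR_OPS: dict[str, TransformOp] = {
    op.name: op
    for op in [
        TransformOp("brightness", "color", (0.6, 1.4), _brightness),
        TransformOp("contrast", "color", (0.6, 1.4), _contrast),
        TransformOp("saturation", "color", (0.6, 1.4), _saturation),
        TransformOp("hue", "color", (-0.1, 0.1), _hue_shift),
        TransformOp("color_jitter", "color", (0.0, 0.2), _color_jitter),
        TransformOp("gaussian_noise", "color", (0.0, 20.0 / 255.0), _gaussian_noise),
        TransformOp("sharpness", "color", (0.0, 2.0), _sharpness),
        TransformOp("posterize", "color", (4.0, 8.0), _posterize),
        TransformOp("solarize", "color", (0.5, 1.0), _solarize),
        TransformOp("equalize", "color", (0.0, 1.0), _equalize),
        TransformOp("autocontrast", "color", (0.0, 0.2), _autocontrast),
        TransformOp("gamma", "color", (0.7, 1.4), _gamma),
    ]
}

GEOMETRIC_OPS: dict[str, TransformOp] = {
    op.name: op
    for op in [
        TransformOp("horizontal_flip", "geometric", (0.0, 1.0), _hflip),
        TransformOp("vertical_flip", "geometric", (0.0, 1.0), _vflip),
        TransformOp("rotate", "geometric", (-30.0, 30.0), _rotate),
        TransformOp("scale", "geometric", (0.8, 1.2), _scale),
        TransformOp("translate", "geometric", (-0.2, 0.2), _translate),
        TransformOp("shear", "geometric", (-0.3, 0.3), _shear),
    ]
}

ALL_OPS = {**COLOR_OPS, **GEOMETRIC_OPS}

# color op -> geometric partner; every geometric op appears exactly twice
_DEFAULT_PAIRING = [
    ("brightness", "horizontal_flip"),
    ("contrast", "vertical_flip"),
    ("saturation", "rotate"),
    ("hue", "scale"),
    ("color_jitter", "translate"),
    ("gaussian_noise", "shear"),
    ("sharpness", "horizontal_flip"),
    ("posterize", "vertical_flip"),
    ("solarize", "rotate"),
    ("equalize", "scale"),
    ("autocontrast", "translate"),
    ("gamma", "shear"),
]


@dataclasses.dataclass(frozen=True)
class Subpolicy:
    """A (color op, geometric op) pair applied color-first."""

    color_op: TransformOp
    geometric_op: TransformOp
    id: int

    def __post_init__(self):
        if self.color_op.category != "color":
            raise ValueError("color_op must have category 'color'")
        if self.geometric_op.category != "geometric":
            raise ValueError("geometric_op must have category 'geometric'")


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    subpolicies: tuple[Subpolicy, ...]
    ladder_probabilities: tuple[float, ...] = DEFAULT_LADDER

    def __post_init__(self):
        if any(not (0.0 < p <= 1.0) for p in self.ladder_probabilities):
            raise ValueError("ladder probabilities must lie in (0, 1]")

    @property
    def combinatorial_size(self) -> int:
        """Number of (subpolicy, probability) combinations; 60 by default."""
        return len(self.subpolicies) * len(self.ladder_probabilities)

    def validate_default_structure(self) -> None:
        """Check the LCA construction rules: 12 distinct color ops, each of
        the 6 geometric ops used exactly twice."""
        color_names = [sp.color_op.name for sp in self.subpolicies]
        if len(set(color_names)) != len(color_names):
            raise ValueError("color ops must be pairwise distinct")
        geo_counts = Counter(sp.geometric_op.name for sp in self.subpolicies)
        if any(c != 2 for c in geo_counts.values()):
            raise ValueError("each geometric op must appear in exactly 2 subpolicies")


@dataclasses.dataclass(frozen=True)
class AugmentationStrategy:
    """A search space plus one execution probability P — the searched unit."""

    space: SearchSpace
    probability: float

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability must be in [0, 1], got {self.probability}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_default_space(ladder: Sequence[float] = DEFAULT_LADDER) -> SearchSpace:
    """Return the default LCA space: 12 subpolicies over 12 color x 6
    geometric ops (each geometric op used twice), ladder [0.1..0.9]."""
    subs = tuple(
        Subpolicy(COLOR_OPS[c], GEOMETRIC_OPS[g], i + 1)
        for i, (c, g) in enumerate(_DEFAULT_PAIRING)
    )
    space = SearchSpace(subs, tuple(ladder))
    space.validate_default_structure()
    return space


def enumerate_candidates(space: SearchSpace) -> list[AugmentationStrategy]:
    """One candidate strategy per ladder probability (the searched unit is the
    probability applied to the whole space; the 12x|ladder| combinatorial size
    is available as ``space.combinatorial_size`` for logging)."""
    if not space.ladder_probabilities:
        raise ValueError("empty probability ladder")
    return [AugmentationStrategy(space, p) for p in space.ladder_probabilities]


def sample_subpolicy(space: SearchSpace, rng: np.random.Generator) -> Subpolicy:
    """Uniform draw over the subpolicies of the space."""
    if not space.subpolicies:
        raise ValueError("empty search space")
    return space.subpolicies[rng.integers(len(space.subpolicies))]


def apply_op(
    image: np.ndarray,
    op: TransformOp,
    magnitude: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one transform at a fixed magnitude.

    Deterministic for every op except ``gaussian_noise`` (which consumes the
    rng).  Output has the same shape, dtype and valid pixel range as input.
    """
    lo, hi = op.magnitude_range
    if not (lo <= magnitude <= hi):
        raise ValueError(f"magnitude {magnitude} outside [{lo}, {hi}] for op {op.name}")
    if rng is None:
        rng = np.random.default_rng(0)
    img, dtype = _to_float(image)
    out = op.apply(img, magnitude, rng)
    return _from_float(out, dtype)


def apply_strategy(
    image: np.ndarray,
    strategy: AugmentationStrategy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastically augment one image.

    Draws one subpolicy uniformly; each of its two ops executes independently
    with probability ``P``; executed ops draw their magnitude uniformly from
    their range.  Color op first, then geometric.
    """
    if image.ndim != 3:
        raise ValueError("expected an H x W x C image")
    sub = sample_subpolicy(strategy.space, rng)
    p = strategy.probability
    exec_color = rng.random() < p
    exec_geo = rng.random() < p
    if not (exec_color or exec_geo):
        return image.copy()
    img, dtype = _to_float(image)
    for do_it, op in ((exec_color, sub.color_op), (exec_geo, sub.geometric_op)):
        if do_it:
            lo, hi = op.magnitude_range
            mag = rng.uniform(lo, hi)
            img = op.apply(img, mag, rng)
    return _from_float(img, dtype)


def load_space_yaml(path) -> SearchSpace:
    """Load a custom search space from YAML.

    Schema::

        ladder: [0.1, 0.3, 0.5, 0.7, 0.9]   # optional
        subpolicies:
          - {color_op: brightness, geometric_op: rotate,
             color_range: [0.6, 1.4], geometric_range: [-30, 30]}  # ranges optional
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "subpolicies" not in doc:
        raise ValueError("space YAML must contain a 'subpolicies' list")
    subs = []
    for i, entry in enumerate(doc["subpolicies"]):
        try:
            cop = COLOR_OPS[entry["color_op"]]
            gop = GEOMETRIC_OPS[entry["geometric_op"]]
        except KeyError as exc:
            raise ValueError(f"unknown op in subpolicy {i + 1}: {exc}") from None
        if "color_range" in entry:
            cop = dataclasses.replace(cop, magnitude_range=tuple(entry["color_range"]))
        if "geometric_range" in entry:
            gop = dataclasses.replace(gop, magnitude_range=tuple(entry["geometric_range"]))
        subs.append(Subpolicy(cop, gop, i + 1))
    ladder = tuple(doc.get("ladder", DEFAULT_LADDER))
    return SearchSpace(tuple(subs), ladder)
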