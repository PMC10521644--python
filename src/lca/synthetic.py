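"""Seeded generator of dermoscopy-like, class-imbalanced image datasets.

Emulates the structure of public skin-lesion archives at desk scale: a
skin-tone background, one centered elliptical "lesion" whose hue, texture,
border irregularity and eccentricity carry the class signal, additive
Gaussian pixel noise, and class counts spanning about two orders of
magnitude (the default mirrors the 7-class imbalance ratios of HAM10000,
6705 nevi down to 115 dermatofibromas, rescaled to 700 images).  Multiple
images of "the same lesion" share geometry and illumination up to a small
jitter and carry a common group id, so grouped cross-validation splits can
be exercised.

Two planted-invariance variants support augmentation-search recovery
experiments: one where the class is carried purely by lesion shape with
color randomized, and one where the class is the lesion pigment hue while
shape, pose and — crucially — a per-lesion illumination color cast are
nuisance variation that color augmentation can neutralize.

This emulates the statistics the pipeline cares about (imbalance, grouped
samples, color/shape class signals, nuisance variation), not photorealistic
dermoscopy: no hair, rulers, gel bubbles or vignetting, and real lesion
texture is far richer.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor

__all__ = [
    "SyntheticSpec",
    "HAM10000_COUNTS",
    "default_spec",
    "generate_dataset",
    "planted_invariance_dataset",
]

HAM10000_COUNTS = {
    "NV": 6705, "MEL": 1113, "BKL": 1099, "BCC": 514,
    "AKIEC": 327, "VASC": 142, "DF": 115,
}

_SKIN_RGB = np.array([0.80, 0.62, 0.52])


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset; identical spec+seed => identical bytes.

    color_signal maps class -> (hue, saturation) of the lesion fill;
    shape_signal maps class -> (eccentricity in [0,1), border irregularity
    amplitude).  ``groups_per_class`` gives the number of distinct lesions
    per class (images beyond that re-render an existing lesion with jitter);
    ``None`` means every image is its own lesion.
    """

    class_counts: dict
    image_size: tuple[int, int] = (96, 96)
    color_signal: dict | None = None
    shape_signal: dict | None = None
    noise_sigma: float = 0.03
    seed: int = 0
    groups_per_class: int | None = None

    def resolved_signals(self):
        classes = list(self.class_counts)
        c = len(classes)
        color = self.color_signal or {
            cls: (0.9 * j / c, 0.55) for j, cls in enumerate(classes)
        }
        shape = self.shape_signal or {
            cls: (0.15 + 0.6 * j / max(c - 1, 1), 0.1 + 0.3 * (j % 2))
            for j, cls in enumerate(classes)
        }
        return color, shape


def default_spec(total: int = 700, image_size=(96, 96), seed: int = 0) -> SyntheticSpec:
    """HAM10000-shaped imbalance rescaled to ``total`` images (largest-remainder
    rounding, so the counts sum exactly to ``total``)."""
    raw = np.array(list(HAM10000_COUNTS.values()), dtype=np.float64)
    scaled = raw / raw.sum() * total
    base = np.floor(scaled).astype(int)
    rem = scaled - base
    for idx in np.argsort(-rem)[: total - base.sum()]:
        base[idx] += 1
    counts = dict(zip(HAM10000_COUNTS, base.tolist()))
    return SyntheticSpec(class_counts=counts, image_size=image_size, seed=seed)


def _render_lesion(h, w, geom, hue, sat, noise_sigma, rng, value=0.45,
                   cast=None, edge=0.05):
    """One skin-background image with an irregular elliptical lesion.

    ``geom`` is (cy, cx, radius, eccentricity, irregularity, angle, phases)
    with center/radius as fractions of the image side.  ``cast`` is an
    optional per-channel illumination gain applied to the whole frame.
    """
    cy, cx, radius, ecc, irr, angle, phases = geom
    yy, xx = np.mgrid[0:h, 0:w]
    # slight deterministic illumination gradient + per-image tint jitter
    grad = 0.06 * (yy / h - 0.5)
    tint = 1.0 + rng.normal(0, 0.02, size=3)
    img = np.clip(_SKIN_RGB * tint + grad[..., None], 0, 1)

    ca, sa = np.cos(angle), np.sin(angle)
    dx, dy = (xx - cx) / w, (yy - cy) / h
    u = (ca * dx + sa * dy) / radius
    v = (-sa * dx + ca * dy) / (radius * np.sqrt(max(1.0 - ecc**2, 1e-3)))
    rho = np.sqrt(u**2 + v**2)
    theta = np.arctan2(v, u)
    boundary = 1.0 + irr * (
        0.5 * np.sin(3 * theta + phases[0])
        + 0.3 * np.sin(5 * theta + phases[1])
        + 0.2 * np.sin(7 * theta + phases[2])
    )
    alpha = np.clip((boundary - rho) / edge, 0.0, 1.0)[..., None]

    lesion_rgb = skcolor.hsv2rgb(np.array([[[hue % 1.0, sat, value]]]))[0, 0]
    texture = 1.0 + 0.12 * rng.standard_normal((h, w, 1))
    lesion = np.clip(lesion_rgb * texture, 0, 1)
    img = (1 - alpha) * img + alpha * lesion
    if cast is not None:
        img = np.clip(img * cast, 0, 1)
    img = img + rng.normal(0, noise_sigma, size=img.shape)
    return np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)


def _draw_geometry(rng, ecc, irr, center_jitter=0.08, radius=0.28, radius_jitter=0.15,
                   max_angle=0.35):
    cy = 0.5 + rng.uniform(-center_jitter, center_jitter)
    cx = 0.5 + rng.uniform(-center_jitter, center_jitter)
    r = radius * (1.0 + rng.uniform(-radius_jitter, radius_jitter))
    angle = rng.uniform(-max_angle, max_angle)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    return (cy, cx, r, ecc, irr, angle, phases)


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path | None = None):
    """Render the dataset described by ``spec``.

    Returns ``(images, manifest)`` where images is a (n, H, W, 3) uint8 array
    and manifest a DataFrame with columns image, label, group_id.  When
    ``out_dir`` is given, PNGs and manifest.csv are also written there.
    """
    if sum(spec.class_counts.values()) == 0:
        raise ValueError("dataset must contain at least one image")
    if any(c < 0 for c in spec.class_counts.values()):
        raise ValueError("class counts must be nonnegative")
    h, w = spec.image_size
    if h < 64 or w < 64:
        raise ValueError("image size must be at least 64x64")
    color_sig, shape_sig = spec.resolved_signals()
    rng = np.random.default_rng(spec.seed)
    images, rows = [], []
    group_counter = 0
    for cls in spec.class_counts:
        count = spec.class_counts[cls]
        hue, sat = color_sig[cls]
        ecc, irr = shape_sig[cls]
        n_groups = count if spec.groups_per_class is None else min(spec.groups_per_class, count)
        lesions = [_draw_geometry(rng, ecc, irr) for _ in range(n_groups)]
        for j in range(count):
            g = j % n_groups
            cy, cx, r, e, ir, ang, ph = lesions[g]
            # same lesion re-imaged: small pose jitter only
            geom = (
                cy + rng.uniform(-0.02, 0.02),
                cx + rng.uniform(-0.02, 0.02),
                r * (1 + rng.uniform(-0.05, 0.05)),
                e, ir,
                ang + rng.uniform(-0.1, 0.1),
                ph,
            )
            images.append(_render_lesion(h, w, geom, hue, sat, spec.noise_sigma, rng))
            rows.append(
                {
                    "image": f"{cls}_{j:05d}.png",
                    "label": cls,
                    "group_id": f"g{group_counter + g:06d}",
                }
            )
        group_counter += n_groups
    images = np.stack(images)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, manifest.itertuples()):
            Image.fromarray(img).save(out_dir / row.image)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, manifest


# four (eccentricity, irregularity) combinations used as shape classes
_SHAPE_CLASSES = [(0.0, 0.0), (0.92, 0.0), (0.0, 0.9), (0.92, 0.9)]
# four lesion pigment hues used as color classes
_COLOR_CLASSES = [0.0, 0.25, 0.5, 0.75]


def planted_invariance_dataset(kind: str, n: int = 400, seed: int = 0,
                               image_size=(64, 64), groups_per_class: int = 8):
    """Dataset with a planted invariance for augmentation-search recovery.

    kind="color-nuisance": the class is carried purely by lesion shape
    (eccentricity x border irregularity); hue is uniform random per image, so
    color carries no signal.

    kind="shape-nuisance": the class is the lesion pigment hue; shape and
    pose are random per lesion, and every lesion carries a random per-channel
    illumination color cast shared by all its images.  A classifier trained
    without augmentation tends to memorize each training lesion's cast and
    misreads the pigment of unseen lesions; photometric augmentation
    (brightness / saturation / channel jitter) simulates new casts and is
    what a correct augmentation search should discover.

    Images of one lesion (group) share geometry, color and cast up to a
    small re-imaging jitter; use the group ids for grouped CV splits.

    Returns ``(images, y, manifest)`` with integer labels 0..3.
    """
    if kind not in ("color-nuisance", "shape-nuisance"):
        raise ValueError(f"unknown kind {kind!r}")
    n_classes = 4
    if n < 40 * n_classes:
        raise ValueError("need n >= 40 per class")
    per_class = n // n_classes
    h, w = image_size
    rng = np.random.default_rng(seed)
    images, labels, groups = [], [], []
    gid = 0
    for cls in range(n_classes):
        base = per_class // groups_per_class
        for g in range(groups_per_class):
            # per-lesion latent state
            if kind == "color-nuisance":
                ecc, irr = _SHAPE_CLASSES[cls]
                hue = rng.uniform(0, 1)
                cast = None
            else:
                hue = _COLOR_CLASSES[cls]
                ecc = rng.uniform(0.0, 0.8)
                irr = rng.uniform(0.0, 0.6)
                cast = rng.uniform(0.65, 1.35, size=3)
            cy, cx, r, _, _, ang, ph = _draw_geometry(
                rng, ecc, irr, center_jitter=0.15, radius=0.26, radius_jitter=0.25
            )
            count = base + (1 if g < per_class % groups_per_class else 0)
            for _ in range(count):
                geom = (
                    cy + rng.uniform(-0.01, 0.01),
                    cx + rng.uniform(-0.01, 0.01),
                    r * (1 + rng.uniform(-0.02, 0.02)),
                    ecc, irr,
                    ang + rng.uniform(-0.05, 0.05),
                    ph,
                )
                images.append(
                    _render_lesion(h, w, geom, hue, 0.6, 0.05, rng, value=0.5, cast=cast)
                )
                labels.append(cls)
                groups.append(gid)
            gid += 1
    images = np.stack(images)
    y = np.array(labels)
    manifest = pd.DataFrame(
        {
            "image": [f"{kind}_{i:05d}.png" for i in range(len(y))],
            "label": y,
            "group_id": [f"g{g:06d}" for g in groups],
        }
    )
    return images, y, manifest
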