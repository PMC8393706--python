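"""Seeded generator of histology-like test images.

Real H&E tiles are red-blue dominant (hematoxylin/eosin staining leaves the
green channel depressed) and differ between tissue classes mainly in the
density and size of dark nuclear blobs.  The generator emulates exactly
those two properties — a controllable color cast plus class-dependent
Gaussian blob textures on a tinted background — so the enhancement
pipeline has a genuine cast to correct and a small classifier has genuine
class structure to learn.  It makes no attempt at realistic gland or
nucleus morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enhancement import EnhancementConfig, enhance_image, save_image

__all__ = [
    "CLASS_NAMES",
    "ClassTexture",
    "SyntheticSpec",
    "generate_dataset",
    "make_paired_dataset",
    "write_dataset",
]

#: class folder names mirroring the five-category lung/colon layout
CLASS_NAMES = ("lungaca", "lungscc", "lungn", "colonca", "colonn")


@dataclass(frozen=True)
class ClassTexture:
    """Blob statistics of one class.

    blob_density: expected blob count per tile (Poisson).
    blob_sigma:   (min, max) Gaussian radius of a blob in pixels.
    tint:         per-channel additive shift of the background color.
    """

    blob_density: float
    blob_sigma: tuple[float, float]
    tint: tuple[float, float, float]


def _default_textures() -> tuple[ClassTexture, ...]:
    # densities increase class by class; radii shrink so blobs stay resolvable
    return (
        ClassTexture(4.0, (2.0, 3.0), (0.03, 0.01, -0.02)),
        ClassTexture(10.0, (1.8, 2.6), (-0.02, 0.00, 0.03)),
        ClassTexture(18.0, (1.6, 2.2), (0.02, -0.01, 0.02)),
        ClassTexture(30.0, (1.4, 2.0), (-0.03, 0.02, -0.01)),
        ClassTexture(45.0, (1.2, 1.8), (0.00, -0.02, 0.00)),
    )


@dataclass
class SyntheticSpec:
    """Layout of a generated dataset.

    ``cast_strength`` is the gap by which the mean green channel sits below
    red and blue on the background, emulating the H&E color cast.
    """

    n_per_class: int = 40
    image_size: tuple[int, int] = (50, 50)
    n_classes: int = 5
    cast_strength: float = 0.15
    texture_params: tuple[ClassTexture, ...] = field(default_factory=_default_textures)
    noise_sigma: float = 0.02
    seed: int = 1485

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.image_size) < 8:
            raise ValueError("image_size must be at least 8x8")
        if self.n_classes < 2 or self.n_classes > len(self.texture_params):
            raise ValueError(
                "n_classes must be between 2 and the number of texture_params"
            )


#: dark purple blob color increment (keeps red/blue above green inside blobs)
_BLOB_COLOR = np.array([-0.22, -0.34, -0.16])


def _render_tile(rng: np.random.Generator, spec: SyntheticSpec, texture: ClassTexture) -> np.ndarray:
    h, w = spec.image_size
    g0 = 0.45
    background = np.array(
        [g0 + spec.cast_strength, g0, g0 + spec.cast_strength]
    ) + np.asarray(texture.tint)
    img = np.broadcast_to(background, (h, w, 3)).copy()
    n_blobs = rng.poisson(texture.blob_density)
    if n_blobs > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        fieldmap = np.zeros((h, w))
        cy = rng.uniform(0, h, n_blobs)
        cx = rng.uniform(0, w, n_blobs)
        sig = rng.uniform(*texture.blob_sigma, n_blobs)
        for y0, x0, s in zip(cy, cx, sig):
            fieldmap += np.exp(-(((yy - y0) ** 2 + (xx - x0) ** 2) / (2.0 * s * s)))
        img = img + np.clip(fieldmap, 0.0, 1.2)[..., None] * _BLOB_COLOR
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticSpec | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Generate ``n_per_class * n_classes`` labeled tiles.

    Returns ``(images, labels, class_names)`` with images (N, H, W, 3) in
    [0, 1]; bit-identical for a fixed spec (seed included).
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for c in range(spec.n_classes):
        texture = spec.texture_params[c]
        for _ in range(spec.n_per_class):
            images.append(_render_tile(rng, spec, texture))
            labels.append(c)
    order = rng.permutation(len(labels))
    images_arr = np.stack(images)[order]
    labels_arr = np.asarray(labels, dtype=int)[order]
    names = list(CLASS_NAMES[: spec.n_classes])
    return images_arr, labels_arr, names


def make_paired_dataset(
    spec: SyntheticSpec | None = None,
    enhancement_config: EnhancementConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Original + enhanced version of the same dataset, index-aligned.

    Returns ``(original, enhanced, labels, class_names)``; the enhanced set
    is the enhancement pipeline applied image by image.
    """
    enhancement_config = enhancement_config or EnhancementConfig()
    original, labels, names = generate_dataset(spec)
    enhanced = np.stack([enhance_image(im, enhancement_config) for im in original])
    return original, enhanced, labels, names


def write_dataset(out_dir, images: np.ndarray, labels: np.ndarray, class_names) -> list[Path]:
    """Write tiles as PNGs under class-named subdirectories.

    Mirrors the common histopathology folder layout (one directory per
    class).  Returns the written paths.
    """
    out_dir = Path(out_dir)
    written = []
    counters = {c: 0 for c in range(len(class_names))}
    for img, lab in zip(images, labels):
        sub = out_dir / class_names[int(lab)]
        sub.mkdir(parents=True, exist_ok=True)
        path = sub / f"{class_names[int(lab)]}_{counters[int(lab)]:04d}.png"
        save_image(path, img)
        counters[int(lab)] += 1
        written.append(path)
    return written
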