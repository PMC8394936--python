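"""Image normalisation, tiling and training-time augmentation.

The detector consumes images that have been intensity-inverted (so that the
dark TEM structures become bright), median-denoised and split into
non-overlapping 814x814 px patches.  The image is padded on the right and
bottom with its background level (estimated as the median grey value) to the
next multiple of the patch size, so the patches tile it exactly.

Augmentation operators (mirrorings, quarter-turn rotations) and the
class-balancing "cover" operator used during training are provided with the
matching coordinate/angle transforms, so that ground truth stays consistent
with the transformed pixels.  All angles are axial (mod 180).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

PATCH_SIZE = 814

AUGMENT_OPS = ("mirror_h", "mirror_v", "rot90", "rot180", "rot270")

__all__ = [
    "PATCH_SIZE",
    "AUGMENT_OPS",
    "Patch",
    "invert_image",
    "preprocess_image",
    "tile_image",
    "stitch_patches",
    "augment_patch",
    "augment_angle",
    "augment_point",
    "cover_annotations",
]


@dataclass
class Patch:
    """One tile of a source image.

    ``offset`` is the (x, y) of the patch origin in the source frame,
    0-based, top-left origin, half-open extents.
    """

    pixels: np.ndarray
    offset: tuple[int, int]


def _check_grayscale(image: np.ndarray) -> None:
    if not isinstance(image, np.ndarray) or image.ndim != 2:
        raise ValueError("expected a 2D grayscale array")


def invert_image(image: np.ndarray) -> np.ndarray:
    """8-bit intensity inversion, p -> 255 - p (an involution)."""
    _check_grayscale(image)
    return (255 - image.astype(np.int16)).astype(image.dtype)


def preprocess_image(image: np.ndarray, median_size: int = 3) -> np.ndarray:
    """Invert and denoise an 8-bit grayscale image.

    Denoising is a square median filter (default 3x3), which removes
    impulse noise without shifting edges; shape and dtype are preserved.
    """
    _check_grayscale(image)
    inv = invert_image(image)
    return ndimage.median_filter(inv, size=median_size)


def tile_image(image: np.ndarray, patch_size: int = PATCH_SIZE,
               pad_value: int | None = None) -> list[Patch]:
    """Cut an image into non-overlapping ``patch_size`` squares, row-major.

    The image is padded on the right/bottom to the next multiple of
    ``patch_size`` with ``pad_value`` (default: the image median, a robust
    background estimate).
    """
    _check_grayscale(image)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape
    if pad_value is None:
        pad_value = int(round(float(np.median(image))))
    hp = int(math.ceil(h / patch_size)) * patch_size
    wp = int(math.ceil(w / patch_size)) * patch_size
    padded = np.full((hp, wp), pad_value, dtype=image.dtype)
    padded[:h, :w] = image
    patches = []
    for y0 in range(0, hp, patch_size):
        for x0 in range(0, wp, patch_size):
            patches.append(Patch(
                pixels=padded[y0:y0 + patch_size, x0:x0 + patch_size].copy(),
                offset=(x0, y0),
            ))
    return patches


def stitch_patches(patches: list[Patch], shape: tuple[int, int]) -> np.ndarray:
    """Reassemble tiles and crop the padding; inverse of :func:`tile_image`."""
    if not patches:
        raise ValueError("no patches")
    ps = patches[0].pixels.shape[0]
    hp = max(p.offset[1] for p in patches) + ps
    wp = max(p.offset[0] for p in patches) + ps
    canvas = np.zeros((hp, wp), dtype=patches[0].pixels.dtype)
    for p in patches:
        x0, y0 = p.offset
        canvas[y0:y0 + ps, x0:x0 + ps] = p.pixels
    h, w = shape
    return canvas[:h, :w]


# ---------------------------------------------------------------------------
# augmentation

def augment_patch(pixels: np.ndarray, op: str) -> np.ndarray:
    """Apply a mirroring/rotation op to a square patch."""
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError("augmentation requires a square patch")
    if op == "mirror_h":
        return np.fliplr(pixels).copy()
    if op == "mirror_v":
        return np.flipud(pixels).copy()
    if op == "rot90":
        return np.rot90(pixels, 1).copy()
    if op == "rot180":
        return np.rot90(pixels, 2).copy()
    if op == "rot270":
        return np.rot90(pixels, 3).copy()
    raise ValueError(f"unknown augmentation op {op!r}")


def augment_angle(angle_deg: float, op: str) -> float:
    """Transform an axial angle consistently with :func:`augment_patch`."""
    if op in ("mirror_h", "mirror_v"):
        return (180.0 - angle_deg) % 180.0
    if op == "rot90":
        return (angle_deg + 90.0) % 180.0
    if op == "rot180":
        return angle_deg % 180.0
    if op == "rot270":
        return (angle_deg + 90.0) % 180.0
    raise ValueError(f"unknown augmentation op {op!r}")


def augment_point(xy: tuple[float, float], op: str, size: int) -> tuple[float, float]:
    """Transform a point (x, y) consistently with :func:`augment_patch`.

    ``size`` is the side length of the square patch; continuous coordinates
    map pixel centre i to size-1-i under a flip.
    """
    x, y = xy
    n = size - 1
    if op == "mirror_h":
        return (n - x, y)
    if op == "mirror_v":
        return (x, n - y)
    if op == "rot90":       # np.rot90 k=1: (r, c) -> (n - c, r)
        return (y, n - x)
    if op == "rot180":
        return (n - x, n - y)
    if op == "rot270":
        return (n - y, x)
    raise ValueError(f"unknown augmentation op {op!r}")


# ---------------------------------------------------------------------------
# class-balancing occlusion

def cover_annotations(pixels: np.ndarray, annotations: list,
                      classes_to_cover: set[str] | list[str],
                      cover_radius: float = 65.0,
                      rng: np.random.Generator | None = None):
    """Cover selected cilia with background-matched noise discs.

    Each annotation whose class is in ``classes_to_cover`` is occluded by a
    disc of the patch's background statistics (median, robust SD) and
    removed from the returned annotation list.  Annotations must expose
    ``.x``, ``.y`` and ``.cls`` (see :class:`ciliaquant.io.AnnotationRecord`)
    or be (x, y, class) triples.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    classes_to_cover = set(classes_to_cover)
    out = pixels.astype(float).copy()
    bg_mean = float(np.median(pixels))
    bg_sd = 1.4826 * float(np.median(np.abs(pixels.astype(float) - bg_mean)))
    h, w = pixels.shape
    kept = []
    for ann in annotations:
        if hasattr(ann, "cls"):
            x, y, cls = ann.x, ann.y, ann.cls
        else:
            x, y, cls = ann
        if cls not in classes_to_cover:
            kept.append(ann)
            continue
        yy, xx = np.ogrid[:h, :w]
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= cover_radius ** 2
        out[mask] = bg_mean + rng.normal(0.0, bg_sd, int(mask.sum()))
    out = np.clip(np.rint(out), 0, 255).astype(pixels.dtype)
    return out, kept
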