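"""Anchor-based cilium detection with NMS and centroid filtering.

A dense grid of square anchor boxes (several scales) is scored per class by
a pluggable *scorer*: any callable mapping ``(patch, box)`` to per-class
scores in [0, 1].  Candidates are pruned by greedy non-maximum suppression
on box overlap, reduced to centroid points, filtered by a score threshold
(0.15) and by centroid proximity, and flagged as confident when the score
reaches 0.75.

The bundled :class:`TemplateScorer` is a classical reference scorer: it
normalises each anchor crop, compares it against per-class cross-section
templates (rendered by the synthetic generator and inverted to the
detector's polarity) by Pearson correlation, and squashes the correlation
through a logistic to (0, 1).  It exists to exercise the pipeline contract
end to end at desk scale; the scorer interface equally admits a trained
network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize

from . import synth
from .preprocess import PATCH_SIZE, Patch, preprocess_image, tile_image
from .synth import CLASS_NAMES, CiliumSpec, DefectClass, DefectSubtype

__all__ = [
    "DetectionConfig",
    "TrainingConfig",
    "Detection",
    "ScorerContractError",
    "TemplateScorer",
    "score_patch",
    "nms_filter",
    "points_from_detections",
    "detect_image",
]


@dataclass
class DetectionConfig:
    """Thresholds and anchor layout of the detection stage.

    ``filter_threshold`` (0.15) removes low-score points entirely;
    ``confident_threshold`` (0.75) separates confident predictions from
    ones that a human should verify.
    """

    anchor_scales: tuple[int, ...] = (96, 128, 160)
    anchor_stride: int = 16
    filter_threshold: float = 0.15
    confident_threshold: float = 0.75
    nms_iou: float = 0.5
    proximity_radius: float = 85.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.filter_threshold < self.confident_threshold <= 1.0):
            raise ValueError("need 0 <= filter_threshold < confident_threshold <= 1")
        if not (0.0 < self.nms_iou < 1.0):
            raise ValueError("nms_iou must lie in (0, 1)")
        if self.anchor_stride <= 0 or any(s <= 0 for s in self.anchor_scales):
            raise ValueError("anchor stride and scales must be positive")


@dataclass
class TrainingConfig:
    """Hyperparameters of the trainable scorer backend (housed; large-scale
    training is not part of this package)."""

    optimizer: str = "Adam"
    learning_rate: float = 0.001
    batch_size: int = 16          # image segments per mini-batch
    max_epochs: int = 28
    early_stop_patience: int = 5  # epochs without validation improvement

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.early_stop_patience) <= 0:
            raise ValueError("all training hyperparameters must be positive")


@dataclass
class Detection:
    """One scored box/point; ``centroid`` is the box centre."""

    box: tuple[float, float, float, float]   # (x, y, w, h)
    class_label: str
    score: float
    confident: bool = False

    @property
    def centroid(self) -> tuple[float, float]:
        x, y, w, h = self.box
        return (x + w / 2.0, y + h / 2.0)


class ScorerContractError(ValueError):
    """A scorer returned scores outside [0, 1] or of the wrong shape."""


# ---------------------------------------------------------------------------
# reference scorer

class TemplateScorer:
    """Correlation-against-template scorer over the three cilium classes.

    Templates (rendered clean by the synthetic generator, inverted to the
    detector's polarity): an intact 9+2 cross-section for *normal*, a
    central-complex defect (empty centre) for *primary*, and a bank of
    compound cilia (two axonemes in one membrane, several axis rotations)
    for *secondary* — the compound axis is arbitrary in real sections, so
    the secondary score is the best match over the bank.

    Each anchor crop is decimated to the template size and compared by a
    centre-weighted Pearson correlation (Gaussian weight, ``weight_sigma``
    of the box side): the weighting makes the response fall off quickly for
    off-centre boxes, which sharpens localisation.  The correlation is
    squashed through a logistic to (0, 1).  Deterministic for fixed inputs.
    """

    def __init__(self, template_size: int = 48, ncc_center: float = 0.28,
                 ncc_gain: float = 15.0, weight_sigma: float = 0.5,
                 n_pair_angles: int = 12, n_compound_axes: int = 8):
        self.template_size = n = template_size
        self.ncc_center = ncc_center
        self.ncc_gain = ncc_gain
        yy, xx = np.mgrid[:n, :n].astype(float)
        c = (n - 1) / 2.0
        w = np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * (weight_sigma * n) ** 2))
        self.weight = w / w.sum()

        # the central-pair axis, the doublet-ring phase and the compound
        # axis are all arbitrary in real sections, so each class carries a
        # bank of rotated templates and scores with its best match
        def bank(kind, diam, n_angles, n_phases, ring_period):
            return [self._normalize(synth.render_prototype(
                kind, diam, angle_deg=a * 180.0 / n_angles,
                phase_deg=p * ring_period / n_phases))
                for a in range(n_angles) for p in range(n_phases)]

        normal = bank("normal", 110, n_pair_angles, 8, 40.0)
        primary = (bank("central_defect", 110, 1, 8, 40.0)
                   + bank("missing_peripheral", 110, 6, 4, 360.0 / 7))
        secondary = [self._normalize(synth.render_prototype(
            "compound", 140, axis_deg=k * 180.0 / n_compound_axes))
            for k in range(n_compound_axes)]
        secondary += bank("extra", 110, 6, 4, 30.0)
        secondary.append(self._normalize(synth.render_prototype("swollen", 130)))
        # one stacked array, sliced per class, so scoring is one tensordot
        self._bank = np.stack(normal + primary + secondary)
        i1 = len(normal)
        i2 = i1 + len(primary)
        self._class_slices = (slice(0, i1), slice(i1, i2),
                              slice(i2, self._bank.shape[0]))

    def _normalize(self, canvas: np.ndarray) -> np.ndarray:
        inv = 255.0 - canvas  # match the preprocessed (inverted) polarity
        t = resize(inv, (self.template_size, self.template_size),
                   order=1, anti_aliasing=True, preserve_range=True)
        t = t - (self.weight * t).sum()
        sd = math.sqrt((self.weight * t * t).sum())
        return t / sd if sd > 0 else t

    def __call__(self, patch: np.ndarray,
                 box: tuple[float, float, float, float]) -> np.ndarray:
        x, y, w, h = box
        bx0, by0 = int(round(x)), int(round(y))
        bx1, by1 = int(round(x + w)), int(round(y + h))
        x0, y0 = max(bx0, 0), max(by0, 0)
        x1 = min(bx1, patch.shape[1])
        y1 = min(by1, patch.shape[0])
        if x1 - x0 < 8 or y1 - y0 < 8:
            return np.zeros(3)
        visible = patch[y0:y1, x0:x1].astype(float)
        if (x1 - x0) * (y1 - y0) < 0.25 * (bx1 - bx0) * (by1 - by0):
            return np.zeros(3)
        if (x0, y0, x1, y1) == (bx0, by0, bx1, by1):
            crop = visible
        else:
            # box extends past the patch: pad with the local background so
            # the geometry of a half-visible cilium is preserved
            crop = np.full((by1 - by0, bx1 - bx0), np.median(visible))
            crop[y0 - by0:y1 - by0, x0 - bx0:x1 - bx0] = visible
        n = self.template_size
        # nearest-neighbour decimation (the generator's blur has already
        # band-limited the image, so plain decimation is adequate)
        ri = np.linspace(0, crop.shape[0] - 1, n).round().astype(int)
        ci = np.linspace(0, crop.shape[1] - 1, n).round().astype(int)
        small = crop[np.ix_(ri, ci)]
        small = small - (self.weight * small).sum()
        sd = math.sqrt((self.weight * small * small).sum())
        if sd < 1e-9:
            return np.zeros(3)
        small /= sd
        wp = (self.weight * small).ravel()
        all_ncc = self._bank.reshape(self._bank.shape[0], -1) @ wp
        ncc = np.array([all_ncc[s].max() for s in self._class_slices])
        return 1.0 / (1.0 + np.exp(-self.ncc_gain * (ncc - self.ncc_center)))


# ---------------------------------------------------------------------------
# pipeline stages

def _anchor_grid(shape: tuple[int, int], config: DetectionConfig):
    # anchors may extend past the patch border so that box *centres* cover
    # the whole patch: a cilium cut by the patch boundary still gets a
    # centred candidate (the scorer pads the hidden part with background)
    h, w = shape
    boxes = []
    for s in config.anchor_scales:
        half = s // 2
        xs = range(-half, w - half + 1, config.anchor_stride)
        ys = range(-half, h - half + 1, config.anchor_stride)
        for y0 in ys:
            for x0 in xs:
                boxes.append((float(x0), float(y0), float(s), float(s)))
    return boxes


def score_patch(patch: np.ndarray | Patch,
                scorer: Callable[[np.ndarray, tuple], np.ndarray],
                config: DetectionConfig) -> list[Detection]:
    """Score every (anchor, class) pair; keep candidates with score > 0."""
    pixels = patch.pixels if isinstance(patch, Patch) else patch
    candidates: list[Detection] = []
    for box in _anchor_grid(pixels.shape, config):
        scores = np.asarray(scorer(pixels, box), dtype=float)
        if scores.shape != (len(CLASS_NAMES),):
            raise ScorerContractError(
                f"scorer returned shape {scores.shape}, expected ({len(CLASS_NAMES)},)"
            )
        if np.any(scores < 0.0) or np.any(scores > 1.0):
            raise ScorerContractError("scorer returned scores outside [0, 1]")
        for cls, sc in zip(CLASS_NAMES, scores):
            if sc > 0.0:
                candidates.append(Detection(box=box, class_label=cls,
                                            score=float(sc)))
    return candidates


def _iou(box: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    x1 = np.maximum(box[0], boxes[:, 0])
    y1 = np.maximum(box[1], boxes[:, 1])
    x2 = np.minimum(box[0] + box[2], boxes[:, 0] + boxes[:, 2])
    y2 = np.minimum(box[1] + box[3], boxes[:, 1] + boxes[:, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    union = box[2] * box[3] + boxes[:, 2] * boxes[:, 3] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms_filter(candidates: Sequence[Detection],
               config: DetectionConfig) -> list[Detection]:
    """Greedy descending-score suppression of boxes with IoU > ``nms_iou``.

    Suppression is class-agnostic, so one cilium yields one surviving box
    carrying its best-scoring class.  Survivors are returned sorted by
    score (ties broken on position for determinism).  Idempotent.
    """
    if not candidates:
        return []
    order = sorted(range(len(candidates)),
                   key=lambda i: (-candidates[i].score,
                                  candidates[i].box[0], candidates[i].box[1],
                                  candidates[i].class_label))
    boxes = np.array([candidates[i].box for i in order], dtype=float)
    alive = np.ones(len(order), dtype=bool)
    keep = []
    for i in range(len(order)):
        if not alive[i]:
            continue
        keep.append(order[i])
        rest = np.nonzero(alive)[0]
        rest = rest[rest > i]
        if rest.size:
            ious = _iou(boxes[i], boxes[rest])
            alive[rest[ious > config.nms_iou]] = False
    return [candidates[i] for i in keep]


def points_from_detections(detections: Sequence[Detection],
                           config: DetectionConfig) -> list[Detection]:
    """Reduce NMS survivors to point annotations.

    Scores below ``filter_threshold`` are dropped; among centroids closer
    than ``proximity_radius`` only the higher score survives (boxes of
    different scales over one cilium overlap too little for NMS to merge
    them, so this proximity rule de-duplicates the points).  The
    ``confident`` flag is set by the 0.75 rule.
    """
    ordered = sorted(
        (d for d in detections if d.score >= config.filter_threshold),
        key=lambda d: (-d.score, d.box[0], d.box[1], d.class_label))
    kept: list[Detection] = []
    for d in ordered:
        cx, cy = d.centroid
        if any(math.hypot(cx - k.centroid[0], cy - k.centroid[1])
               < config.proximity_radius for k in kept):
            continue
        kept.append(Detection(box=d.box, class_label=d.class_label,
                              score=d.score,
                              confident=d.score >= config.confident_threshold))
    return kept


def detect_image(image: np.ndarray,
                 scorer: Callable[[np.ndarray, tuple], np.ndarray],
                 config: DetectionConfig | None = None,
                 patch_size: int = PATCH_SIZE) -> list[Detection]:
    """Full detection pipeline on one raw image.

    Preprocess (invert + denoise), tile into patches, score each patch, map
    boxes back through the patch offsets, suppress duplicates over the whole
    image and reduce to filtered centroid points.  Deterministic for a
    deterministic scorer.
    """
    if config is None:
        config = DetectionConfig()
    pre = preprocess_image(image)
    candidates: list[Detection] = []
    for patch in tile_image(pre, patch_size=patch_size):
        ox, oy = patch.offset
        for d in score_patch(patch.pixels, scorer, config):
            # sub-threshold candidates can never outlive the final score
            # filter nor suppress a kept box (greedy NMS is descending)
            if d.score < config.filter_threshold:
                continue
            x, y, w, h = d.box
            candidates.append(Detection(box=(x + ox, y + oy, w, h),
                                        class_label=d.class_label,
                                        score=d.score))
    survivors = nms_filter(candidates, config)
    return points_from_detections(survivors, config)
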