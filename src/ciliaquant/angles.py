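"""Central-pair orientation measurement and minimal-range re-referencing.

Respiratory cilia beat perpendicular to the plane through their two central
microtubules, so the mutual orientation of central pairs across a ciliary
border is diagnostically meaningful.  Orientations are *axial* angles — a
central pair has no direction — and all arithmetic here is modulo 180.

Measurement is classical: a 150x150 px patch around a detected centroid is
correlated with a bank of small elliptical microtubule-like kernels, the
correlation map is thresholded and cleaned morphologically, and the one or
two surviving components nearest the mass centre of all components are taken
as the central pair; the angle is the long-side orientation of the
minimum-area rotated rectangle around them.  When no admissible component
exists the measurement fails with the sentinel value -1, exported for
display as "-0".

Because every image is photographed at an arbitrary rotation, angle sets are
re-referenced before averaging: the zero direction is rotated so that the
minimum angle is 0 and the spread (max - min) is the smallest achievable for
that data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import match_template

SENTINEL = -1.0
SENTINEL_DISPLAY = "-0"
MEASURE_PATCH = 150  # px, side of the square measurement patch

__all__ = [
    "SENTINEL",
    "SENTINEL_DISPLAY",
    "MEASURE_PATCH",
    "AngleMeasurement",
    "AngleSet",
    "measure_angle",
    "renormalize_angles",
    "summarize_angles",
    "axial_difference",
]


@dataclass
class AngleMeasurement:
    """Measured central-pair angle of one cilium; -1 marks failure."""

    cilium_id: int
    angle_deg: float

    def __post_init__(self) -> None:
        if self.angle_deg != SENTINEL and not 0.0 <= self.angle_deg < 180.0:
            raise ValueError("angle_deg must lie in [0, 180) or be the -1 sentinel")

    @property
    def failed(self) -> bool:
        return self.angle_deg == SENTINEL

    @property
    def display_value(self) -> str:
        return SENTINEL_DISPLAY if self.failed else format(self.angle_deg, "g")


@dataclass
class AngleSet:
    """Re-referenced angles of one image with their summary statistics.

    ``normalized_deg`` is aligned with ``measurements``; failed entries hold
    NaN and are excluded from ``mean_deg``/``offsets_from_mean``.
    """

    measurements: list[AngleMeasurement]
    reference_offset_deg: float
    normalized_deg: np.ndarray
    mean_deg: float

    @property
    def offsets_from_mean(self) -> np.ndarray:
        return self.normalized_deg - self.mean_deg

    @property
    def n_failed(self) -> int:
        return sum(m.failed for m in self.measurements)


def axial_difference(a: float | np.ndarray, b: float | np.ndarray):
    """Distance between two axial angles on the 180-degree circle."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


# ---------------------------------------------------------------------------
# measurement

def _kernel_bank(n_orientations: int = 12, size: int = 15,
                 sigma_major: float = 3.5, sigma_minor: float = 2.5):
    """Zero-mean elliptical Gaussian spots at evenly spaced orientations."""
    half = size // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    bank = []
    for k in range(n_orientations):
        th = math.radians(k * 180.0 / n_orientations)
        u = xx * math.cos(th) + yy * math.sin(th)
        v = -xx * math.sin(th) + yy * math.cos(th)
        g = np.exp(-0.5 * ((u / sigma_major) ** 2 + (v / sigma_minor) ** 2))
        bank.append(g - g.mean())
    return bank


_BANK = _kernel_bank()


def _min_area_rect_angle(points_xy: np.ndarray) -> float:
    """Orientation (deg, [0,180)) of the long side of the minimum-area
    rotated rectangle enclosing the points."""
    pts = np.asarray(points_xy, dtype=float)
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:
        # degenerate (collinear) point set: principal axis
        c = pts - pts.mean(axis=0)
        _, vecs = np.linalg.eigh(c.T @ c)
        v = vecs[:, -1]
        return math.degrees(math.atan2(v[1], v[0])) % 180.0
    best = None
    m = len(hp)
    for i in range(m):
        edge = hp[(i + 1) % m] - hp[i]
        th = math.atan2(edge[1], edge[0])
        c, s = math.cos(-th), math.sin(-th)
        rx = hp[:, 0] * c - hp[:, 1] * s
        ry = hp[:, 0] * s + hp[:, 1] * c
        w = rx.max() - rx.min()
        h = ry.max() - ry.min()
        area = w * h
        if best is None or area < best[0]:
            long_th = th if w >= h else th + math.pi / 2.0
            best = (area, long_th)
    return math.degrees(best[1]) % 180.0


def measure_angle(image: np.ndarray, centroid: tuple[float, float],
                  cilium_id: int = 0,
                  corr_threshold_sd: float = 2.0,
                  min_component_px: int = 25,
                  pair_radius_frac: float = 0.35) -> AngleMeasurement:
    """Measure the central-pair axial angle at one detected centroid.

    Steps: extract a 150x150 patch (clamped at image borders); correlate
    with the microtubule kernel bank and keep the per-pixel maximum over
    orientations; threshold at mean + ``corr_threshold_sd``*SD; open
    morphologically and drop small components; find the mass centre of all
    surviving components; take the 1-2 components nearest it (within
    ``pair_radius_frac`` of the patch size) as the central pair; return the
    minimum-area-rectangle orientation of their pixels.

    Failure (no admissible component) returns ``angle_deg = -1``; it never
    raises.
    """
    h, w = image.shape
    half = MEASURE_PATCH // 2
    cx, cy = centroid
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("centroid outside the image")
    x0 = int(round(min(max(cx - half, 0), max(w - MEASURE_PATCH, 0))))
    y0 = int(round(min(max(cy - half, 0), max(h - MEASURE_PATCH, 0))))
    patch = image[y0:y0 + MEASURE_PATCH, x0:x0 + MEASURE_PATCH].astype(float)
    # bright-structure polarity for correlation
    work = 255.0 - patch

    corr = None
    for kern in _BANK:
        c = match_template(work, kern, pad_input=True, mode="reflect")
        corr = c if corr is None else np.maximum(corr, c)
    thr = corr.mean() + corr_threshold_sd * corr.std()
    mask = corr > thr
    mask = ndimage.binary_opening(mask, structure=np.ones((3, 3)))
    labels, n = ndimage.label(mask)
    if n == 0:
        return AngleMeasurement(cilium_id, SENTINEL)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    good = np.nonzero(sizes >= min_component_px)[0] + 1
    if good.size == 0:
        return AngleMeasurement(cilium_id, SENTINEL)

    keep_mask = np.isin(labels, good)
    mass_cy, mass_cx = ndimage.center_of_mass(keep_mask)
    cents = ndimage.center_of_mass(keep_mask, labels, index=good)
    dists = np.array([math.hypot(cc[1] - mass_cx, cc[0] - mass_cy)
                      for cc in cents])
    order = np.argsort(dists)
    limit = pair_radius_frac * MEASURE_PATCH
    if dists[order[0]] > limit:
        return AngleMeasurement(cilium_id, SENTINEL)
    chosen = [good[order[0]]]
    if order.size > 1 and dists[order[1]] <= limit:
        chosen.append(good[order[1]])
    ys, xs = np.nonzero(np.isin(labels, chosen))
    if xs.size < 3:
        return AngleMeasurement(cilium_id, SENTINEL)
    angle = _min_area_rect_angle(np.column_stack([xs, ys]))
    return AngleMeasurement(cilium_id, float(angle) % 180.0)


# ---------------------------------------------------------------------------
# re-referencing and summaries

def renormalize_angles(angles) -> tuple[float, np.ndarray]:
    """Rotate the zero reference so min = 0 and the range is minimal.

    Every observed angle is tried as the candidate new zero; the offset
    achieving the smallest (max - min) of the recalculated angles
    ``(theta - offset) mod 180`` wins, ties going to the smallest offset.
    On the axial circle the optimal cut always lies at an observed angle
    (the range is constant between observations), so this exhaustive search
    is exact.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size == 0:
        raise ValueError("no measurable angles to re-reference")
    if np.any((arr < 0) | (arr >= 180)):
        raise ValueError("angles must lie in [0, 180)")
    best_offset = None
    best_range = None
    for delta in sorted(set(arr.tolist())):
        vals = (arr - delta) % 180.0
        rng = vals.max()  # min is 0 (delta itself maps to 0)
        if best_range is None or rng < best_range - 1e-12:
            best_range = rng
            best_offset = delta
    return float(best_offset), (arr - best_offset) % 180.0


def summarize_angles(measurements: list[AngleMeasurement]) -> AngleSet:
    """Re-reference the valid angles of one image and summarise them.

    Sentinel measurements are carried through (display "-0") but excluded
    from the re-referencing, the mean rotation and the per-cilium offsets.
    """
    valid_idx = [i for i, m in enumerate(measurements) if not m.failed]
    if not valid_idx:
        raise ValueError("no valid angle measurements in this image")
    valid = [measurements[i].angle_deg for i in valid_idx]
    offset, renorm = renormalize_angles(valid)
    normalized = np.full(len(measurements), np.nan)
    normalized[valid_idx] = renorm
    mean = float(renorm.mean())
    return AngleSet(measurements=list(measurements),
                    reference_offset_deg=offset,
                    normalized_deg=normalized,
                    mean_deg=mean)
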