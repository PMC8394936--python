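"""Synthetic TEM-like scenes of ciliary cross-sections with full ground truth.

Motile cilia show a "9+2" axoneme in cross-section: nine peripheral
microtubule doublets on a ring inside the ciliary membrane, plus two central
microtubules whose connecting axis defines the cilium's orientation.  This
module renders stylised versions of such cross-sections — dark structures on
a bright, noisy background, as in transmission-electron-microscopy prints —
together with the exact centroid, defect class and central-pair angle of
every cilium, so that detection, angle measurement and evaluation can all be
tested against known truth.

Defect taxonomy (three classes):

* ``normal`` (0) — intact 9+2 arrangement;
* ``primary`` (1) — central-complex defects (one or both central microtubules
  absent, or a peripheral doublet translocated to the centre), microtubular
  disorganization, missing peripheral doublets;
* ``secondary`` (2) — compound cilia (several axonemes in one membrane),
  swollen membranes, vesicle formation, extra microtubules, free axonemes
  (no membrane).

The generator fixes the pixel scale of the whole toolchain: a normal cilium
has an outer membrane diameter of ~110 px, so a whole cilium fits the
150x150 px patch used for angle measurement.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DefectClass",
    "DefectSubtype",
    "CiliumSpec",
    "SyntheticScene",
    "CLASS_NAMES",
    "PRIMARY_SUBTYPES",
    "SECONDARY_SUBTYPES",
    "DEFAULT_NOISE_PARAMS",
    "render_cilium",
    "render_scene",
    "central_pair_coords",
    "write_ground_truth",
    "read_ground_truth",
]


class DefectClass(enum.IntEnum):
    NORMAL = 0
    PRIMARY = 1
    SECONDARY = 2


CLASS_NAMES = ("normal", "primary", "secondary")


class DefectSubtype(str, enum.Enum):
    NONE = "none"
    CENTRAL_COMPLEX_DEFECT = "central_complex_defect"
    MICROTUBULAR_DISORGANIZATION = "microtubular_disorganization"
    MISSING_PERIPHERAL_MT = "missing_peripheral_MT"
    COMPOUND = "compound"
    SWOLLEN_MEMBRANE = "swollen_membrane"
    VESICLE = "vesicle"
    EXTRA_MT = "extra_MT"
    FREE_AXONEME = "free_axoneme"


PRIMARY_SUBTYPES = (
    DefectSubtype.CENTRAL_COMPLEX_DEFECT,
    DefectSubtype.MICROTUBULAR_DISORGANIZATION,
    DefectSubtype.MISSING_PERIPHERAL_MT,
)
SECONDARY_SUBTYPES = (
    DefectSubtype.COMPOUND,
    DefectSubtype.SWOLLEN_MEMBRANE,
    DefectSubtype.VESICLE,
    DefectSubtype.EXTRA_MT,
    DefectSubtype.FREE_AXONEME,
)

SUBTYPE_CLASS = {DefectSubtype.NONE: DefectClass.NORMAL}
SUBTYPE_CLASS.update({s: DefectClass.PRIMARY for s in PRIMARY_SUBTYPES})
SUBTYPE_CLASS.update({s: DefectClass.SECONDARY for s in SECONDARY_SUBTYPES})

# Grey levels (8-bit) of the rendered structures.  Microtubules are rendered
# much darker than the membrane so that a single threshold separates the 11
# tubule blobs of a normal cilium from the membrane ring.
BACKGROUND = 200.0
INTERIOR = 178.0
MEMBRANE = 110.0
TUBULE = 40.0
LUCENT = 235.0

# Geometry as fractions of the outer radius R (R = outer_diameter_px / 2).
DOUBLET_RING_FRAC = 0.68     # radius of the peripheral-doublet ring
CENTRAL_OFFSET_FRAC = 0.20   # half-distance between the two central tubules
DOUBLET_RADIUS = 4.5         # px
CENTRAL_RADIUS = 4.0         # px
MEMBRANE_HALF_THICKNESS = 3.0  # px

DEFAULT_OUTER_DIAMETER = 110
MAX_OUTER_DIAMETER = 150  # must fit the 150x150 angle-measurement patch

DEFAULT_NOISE_PARAMS = {
    "background_mean": 200.0,
    "background_sd": 8.0,
    "blur_sigma": 1.5,
}

# Larger membranes for the subtypes that need them (still < 150 px).
SUBTYPE_DIAMETER = {
    DefectSubtype.COMPOUND: 140,
    DefectSubtype.SWOLLEN_MEMBRANE: 130,
}


@dataclass
class CiliumSpec:
    """Ground-truth description of one rendered cilium.

    ``angle_deg`` is the axial orientation of the central-pair axis in image
    coordinates (x to the right, y downwards), in [0, 180).  It is defined
    for every cilium, including defective ones, even when the rendering has
    no measurable central pair.
    """

    center: tuple[float, float]
    defect_class: DefectClass = DefectClass.NORMAL
    defect_subtype: DefectSubtype = DefectSubtype.NONE
    angle_deg: float = 0.0
    outer_diameter_px: int = DEFAULT_OUTER_DIAMETER
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        self.defect_class = DefectClass(self.defect_class)
        self.defect_subtype = DefectSubtype(self.defect_subtype)
        if (self.defect_subtype is DefectSubtype.NONE) != (
            self.defect_class is DefectClass.NORMAL
        ):
            raise ValueError(
                "defect_subtype must be 'none' exactly when defect_class is normal"
            )
        if self.defect_subtype is not DefectSubtype.NONE:
            if SUBTYPE_CLASS[self.defect_subtype] is not self.defect_class:
                raise ValueError(
                    f"subtype {self.defect_subtype.value} does not belong to "
                    f"class {self.defect_class.name}"
                )
        if not 0.0 <= self.angle_deg < 180.0:
            raise ValueError("angle_deg must lie in [0, 180)")
        if self.outer_diameter_px > MAX_OUTER_DIAMETER:
            raise ValueError(
                f"outer_diameter_px must be <= {MAX_OUTER_DIAMETER} px"
            )

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[int(self.defect_class)]


@dataclass
class SyntheticScene:
    """A rendered image plus the specs it was rendered from."""

    image: np.ndarray           # 2D uint8
    specs: list[CiliumSpec]
    noise_params: dict
    seed: int
    image_id: str = "scene"

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in CLASS_NAMES}
        for s in self.specs:
            counts[s.class_name] += 1
        return counts


class PackingError(RuntimeError):
    """Raised when the requested cilia cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# low-level painting helpers (dark structures: paint with minimum; lucent
# structures: paint with maximum)

def _paint_disc(img: np.ndarray, cx: float, cy: float, r: float,
                value: float, dark: bool = True) -> None:
    h, w = img.shape
    x0 = max(int(math.floor(cx - r - 1)), 0)
    x1 = min(int(math.ceil(cx + r + 2)), w)
    y0 = max(int(math.floor(cy - r - 1)), 0)
    y1 = min(int(math.ceil(cy + r + 2)), h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    region = img[y0:y1, x0:x1]
    if dark:
        region[mask] = np.minimum(region[mask], value)
    else:
        region[mask] = np.maximum(region[mask], value)


def _paint_annulus(img: np.ndarray, cx: float, cy: float, r_in: float,
                   r_out: float, value: float, dark: bool = True) -> None:
    h, w = img.shape
    x0 = max(int(math.floor(cx - r_out - 1)), 0)
    x1 = min(int(math.ceil(cx + r_out + 2)), w)
    y0 = max(int(math.floor(cy - r_out - 1)), 0)
    y1 = min(int(math.ceil(cy + r_out + 2)), h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    mask = (d2 >= r_in * r_in) & (d2 <= r_out * r_out)
    region = img[y0:y1, x0:x1]
    if dark:
        region[mask] = np.minimum(region[mask], value)
    else:
        region[mask] = np.maximum(region[mask], value)


def central_pair_coords(spec: CiliumSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    """Exact centres of the two central microtubules of ``spec``.

    The two blobs sit symmetrically about the cilium centre at
    ``CENTRAL_OFFSET_FRAC * R`` along the axis at ``angle_deg``; the line
    through them therefore recovers ``angle_deg`` exactly.
    """
    cx, cy = spec.center
    r = CENTRAL_OFFSET_FRAC * spec.outer_diameter_px / 2.0
    th = math.radians(spec.angle_deg)
    dx, dy = r * math.cos(th), r * math.sin(th)
    return (cx + dx, cy + dy), (cx - dx, cy - dy)


def _paint_doublets(img, cx, cy, radii, angles_deg, blob_r=DOUBLET_RADIUS):
    for r, a in zip(radii, angles_deg):
        th = math.radians(a)
        _paint_disc(img, cx + r * math.cos(th), cy + r * math.sin(th),
                    blob_r, TUBULE)


def _paint_axoneme(img, cx, cy, R, angle_deg, rng, *, n_doublets=9,
                   central=2, disorganized=False, scale=1.0):
    """9+2 tubule arrangement (no membrane) of outer radius R*scale."""
    ring = DOUBLET_RING_FRAC * R * scale
    phase = rng.uniform(0.0, 360.0)
    angs = phase + np.arange(n_doublets) * (360.0 / max(n_doublets, 1))
    angs = angs + rng.normal(0.0, 3.0, size=n_doublets)
    if disorganized:
        radii = rng.uniform(0.25 * R * scale, 0.80 * R * scale, size=n_doublets)
        angs = rng.uniform(0.0, 360.0, size=n_doublets)
    else:
        radii = ring + rng.normal(0.0, 1.0, size=n_doublets)
    _paint_doublets(img, cx, cy, radii, angs)
    if central:
        off = CENTRAL_OFFSET_FRAC * R * scale
        th = math.radians(angle_deg)
        dx, dy = off * math.cos(th), off * math.sin(th)
        _paint_disc(img, cx + dx, cy + dy, CENTRAL_RADIUS, TUBULE)
        if central == 2:
            _paint_disc(img, cx - dx, cy - dy, CENTRAL_RADIUS, TUBULE)


def render_cilium(spec: CiliumSpec, canvas: np.ndarray) -> np.ndarray:
    """Paint one cilium onto ``canvas`` (float image, modified in place).

    ``spec.center`` is interpreted in the canvas frame.  The canvas must be
    large enough to hold the cilium's outer diameter.
    """
    if min(canvas.shape) < spec.outer_diameter_px:
        raise ValueError(
            f"canvas {canvas.shape} too small for outer diameter "
            f"{spec.outer_diameter_px} px"
        )
    rng = np.random.default_rng(spec.jitter_seed)
    cx, cy = spec.center
    R = spec.outer_diameter_px / 2.0
    sub = spec.defect_subtype

    def membrane_and_interior(radius):
        _paint_disc(canvas, cx, cy, radius - MEMBRANE_HALF_THICKNESS, INTERIOR)
        _paint_annulus(canvas, cx, cy, radius - MEMBRANE_HALF_THICKNESS,
                       radius, MEMBRANE)

    if sub is DefectSubtype.NONE:
        membrane_and_interior(R)
        _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng)
    elif sub is DefectSubtype.CENTRAL_COMPLEX_DEFECT:
        membrane_and_interior(R)
        # variants: both central tubules absent, one absent, or a peripheral
        # doublet translocated to the centre
        variant = rng.integers(0, 3)
        if variant == 0:
            _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng, central=0)
        elif variant == 1:
            _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng, central=1)
        else:
            _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng,
                           n_doublets=8, central=0)
            _paint_disc(canvas, cx, cy, DOUBLET_RADIUS, TUBULE)
    elif sub is DefectSubtype.MICROTUBULAR_DISORGANIZATION:
        membrane_and_interior(R)
        _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng,
                       disorganized=True)
    elif sub is DefectSubtype.MISSING_PERIPHERAL_MT:
        membrane_and_interior(R)
        _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng,
                       n_doublets=int(rng.integers(5, 8)))
    elif sub is DefectSubtype.COMPOUND:
        membrane_and_interior(R)
        # two axonemes sharing one membrane
        axis = rng.uniform(0.0, math.pi)
        off = 0.46 * R
        for sgn in (+1.0, -1.0):
            ax = cx + sgn * off * math.cos(axis)
            ay = cy + sgn * off * math.sin(axis)
            _paint_axoneme(canvas, ax, ay, R, rng.uniform(0, 180), rng,
                           scale=0.55)
    elif sub is DefectSubtype.SWOLLEN_MEMBRANE:
        # enlarged membrane with an electron-lucent gap around a compressed
        # axoneme
        _paint_disc(canvas, cx, cy, R - MEMBRANE_HALF_THICKNESS, LUCENT,
                    dark=False)
        _paint_annulus(canvas, cx, cy, R - MEMBRANE_HALF_THICKNESS, R,
                       MEMBRANE)
        _paint_disc(canvas, cx, cy, 0.62 * R, INTERIOR)
        _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng, scale=0.60)
    elif sub is DefectSubtype.VESICLE:
        membrane_and_interior(R)
        _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng, scale=0.78)
        # lucent vesicle between membrane and axoneme
        vth = rng.uniform(0.0, 2 * math.pi)
        vr = 0.70 * R
        _paint_disc(canvas, cx + vr * math.cos(vth), cy + vr * math.sin(vth),
                    0.18 * R, LUCENT, dark=False)
    elif sub is DefectSubtype.EXTRA_MT:
        membrane_and_interior(R)
        _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng,
                       n_doublets=int(rng.integers(11, 14)))
    elif sub is DefectSubtype.FREE_AXONEME:
        # axoneme without a surrounding membrane
        _paint_disc(canvas, cx, cy, 0.80 * R, INTERIOR)
        _paint_axoneme(canvas, cx, cy, R, spec.angle_deg, rng, scale=0.9)
    else:  # pragma: no cover
        raise ValueError(f"unknown subtype {sub}")
    return canvas


def render_prototype(kind: str, outer_diameter_px: int = DEFAULT_OUTER_DIAMETER,
                     angle_deg: float = 0.0, axis_deg: float = 0.0,
                     phase_deg: float = 0.0) -> np.ndarray:
    """Canonical clean render of one cross-section kind, for template use.

    ``kind`` is ``"normal"`` (9+2), ``"central_defect"`` (9+0),
    ``"missing_peripheral"`` (7+2), ``"extra"`` (12+2), ``"compound"``
    (two axonemes in one membrane, sub-axoneme axis at ``axis_deg``) or
    ``"swollen"`` (lucent gap around a compressed axoneme).  Doublets are
    evenly spaced with no jitter; the canvas is ``outer_diameter_px + 14``
    square with the cilium centred.
    """
    side = outer_diameter_px + 14
    c = side / 2.0
    R = outer_diameter_px / 2.0
    canvas = np.full((side, side), BACKGROUND, dtype=float)
    if kind == "swollen":
        _paint_disc(canvas, c, c, R - MEMBRANE_HALF_THICKNESS, LUCENT,
                    dark=False)
        _paint_annulus(canvas, c, c, R - MEMBRANE_HALF_THICKNESS, R, MEMBRANE)
        _paint_disc(canvas, c, c, 0.62 * R, INTERIOR)
    else:
        _paint_disc(canvas, c, c, R - MEMBRANE_HALF_THICKNESS, INTERIOR)
        _paint_annulus(canvas, c, c, R - MEMBRANE_HALF_THICKNESS, R, MEMBRANE)

    def axoneme(cx, cy, scale, ang, central=2, n_doublets=9):
        # doublet-ring phase and central-pair axis are independent, as in
        # the jittered scene renders
        ring = DOUBLET_RING_FRAC * R * scale
        for k in range(n_doublets):
            th = math.radians(k * 360.0 / n_doublets + phase_deg)
            _paint_disc(canvas, cx + ring * math.cos(th),
                        cy + ring * math.sin(th), DOUBLET_RADIUS, TUBULE)
        off = CENTRAL_OFFSET_FRAC * R * scale
        th = math.radians(ang)
        for sgn in ((+1.0, -1.0) if central == 2 else ()):
            _paint_disc(canvas, cx + sgn * off * math.cos(th),
                        cy + sgn * off * math.sin(th), CENTRAL_RADIUS, TUBULE)

    if kind == "normal":
        axoneme(c, c, 1.0, angle_deg)
    elif kind == "swollen":
        axoneme(c, c, 0.60, angle_deg)
    elif kind == "central_defect":
        axoneme(c, c, 1.0, angle_deg, central=0)
    elif kind == "missing_peripheral":
        axoneme(c, c, 1.0, angle_deg, n_doublets=7)
    elif kind == "extra":
        axoneme(c, c, 1.0, angle_deg, n_doublets=12)
    elif kind == "compound":
        off = 0.46 * R
        th = math.radians(axis_deg)
        for sgn in (+1.0, -1.0):
            axoneme(c + sgn * off * math.cos(th), c + sgn * off * math.sin(th),
                    0.55, angle_deg)
    else:
        raise ValueError(f"unknown prototype kind {kind!r}")
    return canvas


# ---------------------------------------------------------------------------
# scene generation

def render_scene(
    n_cilia: int,
    class_mix: Sequence[float] = (0.7, 0.15, 0.15),
    image_size: tuple[int, int] = (814, 814),
    noise_params: dict | None = None,
    seed: int = 0,
    outer_diameter_px: int = DEFAULT_OUTER_DIAMETER,
    image_id: str = "scene",
) -> SyntheticScene:
    """Render a scene of ``n_cilia`` non-overlapping cilia with ground truth.

    Class counts are drawn from one multinomial draw of ``class_mix``;
    centres are placed by rejection sampling with a minimum separation of
    one outer diameter (+10 px), so non-compound cilia never overlap.  The
    scene is fully determined by its arguments: the same call produces a
    bit-identical image.
    """
    mix = np.asarray(class_mix, dtype=float)
    if mix.size != 3 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must be 3 non-negative numbers summing to 1")
    if n_cilia < 0:
        raise ValueError("n_cilia must be >= 0")
    np_ = dict(DEFAULT_NOISE_PARAMS)
    if noise_params:
        np_.update(noise_params)
    h, w = int(image_size[0]), int(image_size[1])

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cilia, mix)

    # placement margin must accommodate the largest possible membrane
    max_d = max([outer_diameter_px]
                + ([d for d in SUBTYPE_DIAMETER.values()] if mix[2] > 0 else []))
    margin = max_d / 2.0 + 10.0
    min_sep = outer_diameter_px + 10.0
    if n_cilia > 0 and (w - 2 * margin <= 0 or h - 2 * margin <= 0):
        raise PackingError("image too small for any cilium")

    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 + 500 * n_cilia
    while len(centers) < n_cilia:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"could only place {len(centers)} of {n_cilia} cilia in "
                f"{w}x{h} px after {max_attempts} attempts"
            )
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep ** 2
               for px, py in centers):
            centers.append((x, y))

    labels = np.repeat(np.arange(3), counts)
    rng.shuffle(labels)

    specs: list[CiliumSpec] = []
    for (x, y), lab in zip(centers, labels):
        cls = DefectClass(int(lab))
        if cls is DefectClass.NORMAL:
            sub = DefectSubtype.NONE
        elif cls is DefectClass.PRIMARY:
            sub = PRIMARY_SUBTYPES[rng.integers(0, len(PRIMARY_SUBTYPES))]
        else:
            sub = SECONDARY_SUBTYPES[rng.integers(0, len(SECONDARY_SUBTYPES))]
        angle = float(rng.uniform(0.0, 180.0))
        jseed = int(rng.integers(0, 2**31 - 1))
        diam = SUBTYPE_DIAMETER.get(sub, outer_diameter_px)
        specs.append(CiliumSpec(center=(x, y), defect_class=cls,
                                defect_subtype=sub, angle_deg=angle,
                                outer_diameter_px=diam, jitter_seed=jseed))

    canvas = np.full((h, w), np_["background_mean"], dtype=float)
    for spec in specs:
        render_cilium(spec, canvas)
    if np_["blur_sigma"] > 0:
        canvas = ndimage.gaussian_filter(canvas, np_["blur_sigma"])
    if np_["background_sd"] > 0:
        canvas = canvas + rng.normal(0.0, np_["background_sd"], canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, specs=specs, noise_params=np_,
                          seed=seed, image_id=image_id)


# ---------------------------------------------------------------------------
# ground-truth I/O

GT_COLUMNS = ["image_id", "x", "y", "class", "subtype", "angle_deg"]


def write_ground_truth(scene: SyntheticScene, path: str | Path) -> None:
    """Write the scene's annotations as a CSV (one row per cilium)."""
    rows = [
        {
            "image_id": scene.image_id,
            # repr gives the shortest lossless decimal form
            "x": repr(float(s.center[0])),
            "y": repr(float(s.center[1])),
            "class": s.class_name,
            "subtype": s.defect_subtype.value,
            "angle_deg": repr(float(s.angle_deg)),
        }
        for s in scene.specs
    ]
    pd.DataFrame(rows, columns=GT_COLUMNS).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth CSV back into a DataFrame (validated columns)."""
    df = pd.read_csv(path, dtype={"image_id": str},
                     float_precision="round_trip")
    missing = set(GT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth file {path} missing columns {sorted(missing)}")
    bad = ~df["class"].isin(CLASS_NAMES)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"unknown class {df['class'].iloc[row]!r} in row {row} of {path}"
        )
    return df
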