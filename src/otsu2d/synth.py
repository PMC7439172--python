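"""Seeded synthetic scenes with ground truth.

Two failure regimes of global thresholding are emulated: salt-and-pepper
impulse corruption at density delta (each pixel independently replaced by
0 or 255 with equal odds), and a vertically varying illumination field
strong enough that foreground in the dark region is darker than background
in the bright region — the contrast inversion that defeats any single
global threshold.  Objects are blob-like (disks, ellipses, rectangles) on
a smooth background, in the spirit of rice grains, coins and cells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import LEVELS, validate_gray, _round_half_up
from .metrics import evaluate


@dataclass(frozen=True)
class Disk:
    cx: float  # row of the centre
    cy: float  # column of the centre
    r: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (rows - self.cx) ** 2 + (cols - self.cy) ** 2 <= self.r**2


@dataclass(frozen=True)
class Ellipse:
    cx: float
    cy: float
    a: float  # semi-axis along rows before rotation
    b: float  # semi-axis along columns before rotation
    theta: float = 0.0  # radians

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr, dc = rows - self.cx, cols - self.cy
        u = dr * np.cos(self.theta) + dc * np.sin(self.theta)
        v = -dr * np.sin(self.theta) + dc * np.cos(self.theta)
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class Rect:
    r0: float
    c0: float
    r1: float
    c1: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (rows >= self.r0) & (rows <= self.r1) & \
               (cols >= self.c0) & (cols <= self.c1)


class Illumination(str, enum.Enum):
    NONE = "none"
    LINEAR = "linear"
    SIGMOID = "sigmoid"


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one deterministic scene.

    Illumination is a multiplicative per-row field running from
    ``illum_top`` at row 0 to ``illum_bottom`` at the last row; the
    SIGMOID profile switches around ``illum_center`` over a band of width
    ``illum_width`` rows.  Gaussian noise (``gauss_sigma`` levels) is added
    before the impulses so the salt-and-pepper extremes stay exact.
    """

    shape: tuple[int, int] = (128, 128)
    objects: tuple = ()
    fg_level: int = 190
    bg_level: int = 70
    illum: Illumination = Illumination.NONE
    illum_top: float = 1.0
    illum_bottom: float = 1.0
    illum_center: float | None = None  # default: middle row
    illum_width: float = 2.0
    blur_sigma: float = 0.0  # optical blur of the scene, before shading
    gauss_sigma: float = 0.0
    sp_delta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.sp_delta <= 1.0):
            raise ValueError("sp_delta must lie in [0, 1]")
        if self.fg_level == self.bg_level:
            raise ValueError("fg_level must differ from bg_level")
        object.__setattr__(self, "illum", Illumination(self.illum))


def illumination_field(spec: SceneSpec) -> np.ndarray:
    """Per-row multiplicative field of a scene."""
    m = spec.shape[0]
    x = np.arange(m, dtype=np.float64)
    if spec.illum is Illumination.NONE:
        return np.ones(m)
    top, bottom = spec.illum_top, spec.illum_bottom
    if spec.illum is Illumination.LINEAR:
        frac = x / max(m - 1, 1)
    else:
        center = m / 2.0 if spec.illum_center is None else spec.illum_center
        frac = 1.0 / (1.0 + np.exp(-(x - center) / spec.illum_width))
    return top + (bottom - top) * frac


def render(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene to a gray image and its ground-truth mask."""
    m, n = spec.shape
    rows, cols = np.mgrid[0:m, 0:n].astype(np.float64)
    mask = np.zeros((m, n), dtype=np.uint8)
    for obj in spec.objects:
        inside = obj.contains(rows, cols)
        if not inside.any():
            raise ValueError(f"object {obj} lies fully outside the frame")
        mask[inside] = 1
    img = np.where(mask == 1, float(spec.fg_level), float(spec.bg_level))
    if spec.blur_sigma > 0:
        # soft object edges (optical defocus); shading stays sharp
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    img = img * illumination_field(spec)[:, None]
    rng = np.random.default_rng(spec.seed)
    if spec.gauss_sigma > 0:
        img = img + rng.normal(0.0, spec.gauss_sigma, size=img.shape)
    img = np.clip(_round_half_up(img), 0, LEVELS - 1)
    if spec.sp_delta > 0:
        img = add_salt_pepper(img, spec.sp_delta, rng)
    return validate_gray(img), mask


def add_salt_pepper(img: np.ndarray, delta: float, seed) -> np.ndarray:
    """Corrupt each pixel with probability delta to 0 or L-1 (50/50)."""
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    arr = validate_gray(img).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hit = rng.random(arr.shape) < delta
    salt = rng.random(arr.shape) < 0.5
    arr[hit & salt] = LEVELS - 1
    arr[hit & ~salt] = 0
    return arr


def coins_scene(seed: int = 0, shape: tuple[int, int] = (128, 128)) -> SceneSpec:
    """Bright coin-like disks on a darker uniform background."""
    m, n = shape
    rng = np.random.default_rng(seed)
    objects = []
    for i in range(3):
        for j in range(3):
            cx = m * (2 * i + 1) / 6.0 + rng.uniform(-2, 2)
            cy = n * (2 * j + 1) / 6.0 + rng.uniform(-2, 2)
            objects.append(Disk(cx=cx, cy=cy, r=min(m, n) / 10.0))
    return SceneSpec(shape=shape, objects=tuple(objects), fg_level=190,
                     bg_level=70, gauss_sigma=3.0, seed=seed)


def uneven_scene(seed: int = 0, shape: tuple[int, int] = (128, 128)) -> SceneSpec:
    """Contrast-inversion fixture: vertically dimmed scene.

    The sigmoid field drops sharply from 1.0 to 0.3 across the middle
    rows, so dark-region foreground (about 0.3 * fg) ends up darker than
    bright-region background — no single global threshold can be right in
    both halves.  Objects are softly defocused and keep clear of the
    transition band, so the shading boundary carries the dominant
    splitting-line energy; the dark half is densely populated with grains
    while the bright half is sparse, the asymmetry that misleads the
    whole-image criterion.
    """
    m, n = shape
    cols = [n * (2 * j + 1) / 6.0 for j in range(3)]
    objects = [Disk(cx=m * 0.23, cy=c, r=m * 0.125) for c in cols]
    objects += [Disk(cx=m * 0.75, cy=c, r=m * 0.146) for c in cols]
    return SceneSpec(shape=shape, objects=tuple(objects), fg_level=220,
                     bg_level=150, illum=Illumination.SIGMOID, illum_top=1.0,
                     illum_bottom=0.3, illum_width=0.3, blur_sigma=0.8,
                     gauss_sigma=2.0, seed=seed)


def noise_sweep(
    spec: SceneSpec,
    deltas,
    methods,
    seed: int | None = None,
) -> pd.DataFrame:
    """Corrupt, segment and evaluate over a grid of noise densities.

    For each delta the clean scene is corrupted with salt-and-pepper noise
    and each named method is run against the ground truth.  Returns a
    tidy frame with columns (method, delta, me, dsc).
    """
    from .estimators import make_segmenter

    deltas = list(deltas)
    if not deltas:
        raise ValueError("empty delta list")
    base = replace(spec, sp_delta=0.0)
    clean, gt = render(base)
    root = spec.seed if seed is None else seed
    rows = []
    for di, delta in enumerate(deltas):
        noisy = add_salt_pepper(clean, delta, np.random.default_rng(root + 1000 * di)) \
            if delta > 0 else clean
        for method in methods:
            est = make_segmenter(method)
            rep = evaluate(est.fit_predict(noisy), gt)
            rows.append({"method": method, "delta": delta,
                         "me": rep.me, "dsc": rep.dsc})
    return pd.DataFrame(rows)
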