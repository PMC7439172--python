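"""Energy-based splitting line for vertically uneven illumination.

A splitting line is an 8-connected path, one row per column, that cuts the
image into a top and a bottom part of roughly uniform illumination.  It is
the mirror image of a stitching seam: instead of minimising the intensity
change across the line we maximise it, while a Sobel-gradient penalty keeps
the line away from texture (object boundaries) and a Gaussian position
weight centred on the middle row keeps the two parts balanced:

    E(x, y) = W(x) * (w1 * E_color(x, y) - w2 * E_geom(x, y))

with E_color the squared difference between vertically adjacent pixels,
E_geom the Sobel gradient magnitude, and W(x) = exp(-(x - m/2)^2 / (2 s^2)).
The maximum-energy path is found by dynamic programming over columns.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import validate_gray

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)


class SigmaMode(str, enum.Enum):
    """Width convention of the Gaussian position weight.

    ``SIGMA_HALF_M`` uses sigma = m/2 (denominator m^2/2 in the exponent);
    ``LITERAL_2M`` uses denominator 2m.  The two agree only at m = 4.
    """

    SIGMA_HALF_M = "sigma_half_m"
    LITERAL_2M = "literal_2m"


class EnergySource(str, enum.Enum):
    """Image the energy is computed on: the raw input or its median."""

    RAW = "raw"
    MEDIAN = "median"


@dataclass(frozen=True)
class EnergyConfig:
    """Weights and conventions of the splitting-line energy.

    w1 rewards intensity change across the line (default 2), w2 penalises
    crossing texture (default 1); both are dimensionless multipliers of
    squared-intensity terms.
    """

    w1: float = 2.0
    w2: float = 1.0
    sigma_mode: SigmaMode = SigmaMode.SIGMA_HALF_M
    source: EnergySource = EnergySource.RAW

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("energy weights must be nonnegative")
        object.__setattr__(self, "sigma_mode", SigmaMode(self.sigma_mode))
        object.__setattr__(self, "source", EnergySource(self.source))


@dataclass
class EnergyMap:
    """Combined energy grid with its three components kept for inspection."""

    E: np.ndarray
    color: np.ndarray
    geometrical: np.ndarray
    position: np.ndarray  # per-row weights broadcast over columns


@dataclass
class SplitPath:
    """One row index per column; adjacent entries differ by at most 1."""

    rows: np.ndarray
    total_energy: float

    @property
    def mean_energy(self) -> float:
        return self.total_energy / len(self.rows)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.ndim != 1 or self.rows.size == 0:
            raise ValueError("path must be a nonempty 1-D row sequence")
        if np.abs(np.diff(self.rows)).max(initial=0) > 1:
            raise ValueError("path must be 8-connected (row steps of at most 1)")


def color_energy(img: np.ndarray) -> np.ndarray:
    """Squared difference between each pixel and its upper neighbour.

    The first row is padded with itself, so its energy is zero.
    """
    arr = validate_gray(img).astype(np.float64)
    out = np.zeros_like(arr)
    out[1:] = (arr[1:] - arr[:-1]) ** 2
    return out


def geometric_energy(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude with replicate-padded borders."""
    arr = validate_gray(img).astype(np.float64)
    gx = ndimage.correlate(arr, SOBEL_X, mode="nearest")
    gy = ndimage.correlate(arr, SOBEL_Y, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


def position_weight(m: int, sigma_mode: SigmaMode = SigmaMode.SIGMA_HALF_M) -> np.ndarray:
    """Per-row Gaussian weight centred on the middle row m/2."""
    if m < 1:
        raise ValueError("m must be >= 1")
    x = np.arange(m, dtype=np.float64)
    mu = m / 2.0
    if SigmaMode(sigma_mode) is SigmaMode.SIGMA_HALF_M:
        denom = 2.0 * (m / 2.0) ** 2
    else:
        denom = 2.0 * m
    return np.exp(-((x - mu) ** 2) / denom)


def energy_map(img: np.ndarray, cfg: EnergyConfig = EnergyConfig()) -> EnergyMap:
    """Combine colour, geometric and position terms into the energy grid."""
    arr = validate_gray(img)
    if cfg.source is EnergySource.MEDIAN:
        from .histogram import median_filter

        arr = median_filter(arr, 3)
    ec = color_energy(arr)
    eg = geometric_energy(arr)
    w = position_weight(arr.shape[0], cfg.sigma_mode)
    E = w[:, None] * (cfg.w1 * ec - cfg.w2 * eg)
    return EnergyMap(E=E, color=ec, geometrical=eg, position=w)


def find_splitline(E: EnergyMap | np.ndarray) -> SplitPath:
    """Maximum-energy 8-connected path, one row per column, by DP.

    The cumulative energy of a cell is its own energy plus the best of the
    three predecessors in the previous column (rows x-1, x, x+1, clipped to
    the image).  Ties prefer the same row, then the row above, then the row
    below; ties among last-column maxima prefer the smallest row.  All
    paths span every column, so maximising total energy and mean energy
    coincide.
    """
    grid = E.E if isinstance(E, EnergyMap) else np.asarray(E, dtype=np.float64)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("energy grid must be a nonempty 2-D array")
    m, n = grid.shape
    cum = np.empty((m, n))
    # predecessor row offset chosen at each cell, in preference order
    choice = np.zeros((m, n), dtype=np.int64)
    cum[:, 0] = grid[:, 0]
    neg = -np.inf
    for y in range(1, n):
        prev = cum[:, y - 1]
        same = prev
        up = np.concatenate(([neg], prev[:-1]))  # predecessor at row x-1
        down = np.concatenate((prev[1:], [neg]))  # predecessor at row x+1
        cand = np.stack([same, up, down])  # preference order
        best_idx = np.argmax(cand, axis=0)  # first max wins -> preference
        cum[:, y] = cand[best_idx, np.arange(m)] + grid[:, y]
        choice[:, y] = best_idx
    rows = np.empty(n, dtype=np.int64)
    rows[-1] = int(np.argmax(cum[:, -1]))  # smallest row on ties
    offsets = np.array([0, -1, 1])
    for y in range(n - 1, 0, -1):
        rows[y - 1] = rows[y] + offsets[choice[rows[y], y]]
    return SplitPath(rows=rows, total_energy=float(cum[rows[-1], -1]))


def partition(shape: tuple[int, int], path: SplitPath) -> tuple[np.ndarray, np.ndarray]:
    """Split a pixel grid into the part on/above the path and the rest.

    Part 1 holds pixels with row <= path(column); part 2 is the complement.
    If the path hugs the bottom row everywhere, part 2 is empty: a warning
    is raised and both parts fall back to the whole image.
    """
    m, n = shape
    if len(path.rows) != n:
        raise ValueError("path length must equal the number of columns")
    if path.rows.min() < 0 or path.rows.max() > m - 1:
        raise ValueError("path rows out of range")
    rows = np.arange(m)[:, None]
    part1 = (rows <= path.rows[None, :]).astype(np.uint8)
    part2 = 1 - part1
    if not part2.any():
        warnings.warn(
            "splitting line leaves one part empty; falling back to the whole image",
            stacklevel=2,
        )
        whole = np.ones((m, n), dtype=np.uint8)
        return whole, whole
    return part1, part2
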