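"""2-D histogram construction from filtered image pairs.

A 2-D histogram counts gray-level pairs ``(i, j)`` where ``i`` comes from a
"first coordinate" image and ``j`` from a smoothed "second coordinate"
image.  Three pairings are supported:

``AVG_ONLY``
    ``(I, avg(I))`` — the classic 2-D Otsu histogram.
``ORIG_MEDAVG``
    ``(I, avg(med(I)))`` — raw image against the median-average image.
``MED_MEDAVG``
    ``(med(I), avg(med(I)))`` — the salt-and-pepper-robust pairing: the
    median image removes impulses from the first coordinate too, which
    pulls the histogram mass back onto the diagonal.

Both filters use a k x k window (k odd, default 3) with replicate padding;
the average is rounded half-up so the result stays an integer gray level.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import LEVELS, validate_gray, _round_half_up


class Strategy(str, enum.Enum):
    """Which image pair feeds the 2-D histogram."""

    AVG_ONLY = "avg_only"
    ORIG_MEDAVG = "orig_medavg"
    MED_MEDAVG = "med_medavg"


@dataclass(frozen=True)
class FilterConfig:
    """Smoothing-window size and histogram strategy.

    Parameters
    ----------
    k : int
        Odd window size in pixels for both the median and average filters.
    strategy : Strategy
        Image pairing used for the histogram coordinates.
    """

    k: int = 3
    strategy: Strategy = Strategy.MED_MEDAVG

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"window size k must be odd and >= 1, got {self.k}")
        object.__setattr__(self, "strategy", Strategy(self.strategy))


@dataclass
class Histogram2D:
    """Joint probability table over (first, second) gray-level pairs.

    Attributes
    ----------
    counts : (L, L) int64 array
        Pair counts f_ij.
    p : (L, L) float64 array
        Probabilities p_ij = f_ij / total.
    total : int
        Number of pixels in the region.
    mean_vector : (u_i, u_j)
        Gray-level mean of each coordinate over the region.
    levels : int
        Number of gray levels L.
    """

    counts: np.ndarray
    total: int
    levels: int = LEVELS
    p: np.ndarray = field(init=False)
    mean_vector: tuple[float, float] = field(init=False)

    def __post_init__(self):
        L = self.levels
        if self.counts.shape != (L, L):
            raise ValueError(f"counts must be {L}x{L}")
        if self.total <= 0 or self.counts.sum() != self.total:
            raise ValueError("counts must sum to a positive total")
        self.p = self.counts.astype(np.float64) / self.total
        idx = np.arange(L, dtype=np.float64)
        self.mean_vector = (
            float((self.p.sum(axis=1) * idx).sum()),
            float((self.p.sum(axis=0) * idx).sum()),
        )


def average_filter(img: np.ndarray, k: int = 3) -> np.ndarray:
    """k x k arithmetic-mean filter, replicate padded, rounded half-up."""
    arr = validate_gray(img)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"window size k must be odd and >= 1, got {k}")
    kernel = np.full((k, k), 1.0 / (k * k))
    out = ndimage.correlate(arr.astype(np.float64), kernel, mode="nearest")
    return np.clip(_round_half_up(out), 0, LEVELS - 1)


def median_filter(img: np.ndarray, k: int = 3) -> np.ndarray:
    """k x k median filter with replicate padding."""
    arr = validate_gray(img)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"window size k must be odd and >= 1, got {k}")
    return ndimage.median_filter(arr, size=k, mode="nearest")


def pair_images(img: np.ndarray, cfg: FilterConfig) -> tuple[np.ndarray, np.ndarray]:
    """The (first, second) coordinate images for a histogram strategy.

    Filters are always computed on the whole image; restricting to a pixel
    region happens afterwards, so a splitting line never fabricates an
    artificial gradient in the filtered images.
    """
    arr = validate_gray(img)
    if cfg.strategy is Strategy.AVG_ONLY:
        return arr, average_filter(arr, cfg.k)
    med = median_filter(arr, cfg.k)
    medavg = average_filter(med, cfg.k)
    if cfg.strategy is Strategy.ORIG_MEDAVG:
        return arr, medavg
    return med, medavg


def histogram_from_pair(
    first: np.ndarray,
    second: np.ndarray,
    levels: int = LEVELS,
    region: np.ndarray | None = None,
) -> Histogram2D:
    """Count (i, j) pairs from two coordinate images into a 2-D histogram."""
    first = np.asarray(first, dtype=np.int64)
    second = np.asarray(second, dtype=np.int64)
    if first.shape != second.shape:
        raise ValueError("coordinate images must share a shape")
    if region is not None:
        sel = np.asarray(region, dtype=bool)
        if sel.shape != first.shape:
            raise ValueError("region shape must match the image")
        if not sel.any():
            raise ValueError("region selects no pixels")
        i, j = first[sel], second[sel]
    else:
        i, j = first.ravel(), second.ravel()
    counts = np.bincount(i * levels + j, minlength=levels * levels)
    return Histogram2D(counts=counts.reshape(levels, levels), total=int(i.size), levels=levels)


def build_histogram2d(
    img: np.ndarray,
    cfg: FilterConfig = FilterConfig(),
    region: np.ndarray | None = None,
) -> Histogram2D:
    """Build the 2-D histogram of an image, optionally over a pixel region.

    Parameters
    ----------
    img : 2-D int array
        Gray image.
    cfg : FilterConfig
        Window size and pairing strategy.
    region : 2-D {0,1} array, optional
        Pixels included in the histogram; default: the whole image.
    """
    first, second = pair_images(img, cfg)
    return histogram_from_pair(first, second, levels=LEVELS, region=region)


def histogram_to_tsv(h: Histogram2D, path) -> None:
    """Dump the nonzero histogram cells as TSV (i, j, count, p)."""
    ii, jj = np.nonzero(h.counts)
    with open(path, "w") as fh:
        fh.write("i\tj\tcount\tp\n")
        for i, j in zip(ii.tolist(), jj.tolist()):
            fh.write(f"{i}\t{j}\t{h.counts[i, j]}\t{h.p[i, j]:.12g}\n")


def histogram_compactness(h: Histogram2D) -> float:
    """Mean squared off-diagonal distance  sum_ij p_ij (i - j)^2.

    Smaller values mean the histogram mass hugs the diagonal, i.e. the
    smoothed coordinate agrees with the first coordinate — the signature of
    an impulse-noise-free pairing.
    """
    idx = np.arange(h.levels, dtype=np.float64)
    d2 = (idx[:, None] - idx[None, :]) ** 2
    return float((h.p * d2).sum())
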