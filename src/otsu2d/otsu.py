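"""The 2-D Otsu criterion: class statistics, trace criterion, threshold search.

A threshold pair (s, t) splits the (i, j) plane into four quadrants.  The
diagonal quadrants hold background (i <= s, j <= t) and foreground
(i > s, j > t); the off-diagonal quadrants correspond to edges and noise
and carry negligible mass.  The optimal pair maximises the trace of the
between-class scatter matrix

    tr(sigma_B) = w0 ||u0 - uT||^2 + w1 ||u1 - uT||^2,

where w_k and u_k are the quadrant masses and mean vectors and uT is the
global histogram mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .histogram import Histogram2D

#: How pixels in the off-diagonal quadrants II/III are labelled.
AMBIGUOUS_RULES = ("smoothed", "raw", "nearest")


@dataclass(frozen=True)
class ThresholdPair:
    """An (s, t) threshold pair with its achieved criterion value."""

    s: int
    t: int
    criterion: float

    def __post_init__(self):
        if self.criterion < 0:
            raise ValueError("criterion must be nonnegative")


@dataclass(frozen=True)
class ClassStatistics:
    """Quadrant masses and mean vectors for one (s, t) pair."""

    w0: float
    w1: float
    u0: tuple[float, float]
    u1: tuple[float, float]
    degenerate: bool  # true when either class carries no mass


def class_stats(h: Histogram2D, s: int, t: int) -> ClassStatistics:
    """Masses and mean vectors of the background/foreground quadrants."""
    L = h.levels
    if not (0 <= s <= L - 2 and 0 <= t <= L - 2):
        raise ValueError(f"thresholds must lie in [0, {L - 2}]")
    idx = np.arange(L, dtype=np.float64)
    p0 = h.p[: s + 1, : t + 1]
    p1 = h.p[s + 1 :, t + 1 :]
    w0 = float(p0.sum())
    w1 = float(p1.sum())
    if w0 > 0:
        u0 = (
            float((p0.sum(axis=1) * idx[: s + 1]).sum() / w0),
            float((p0.sum(axis=0) * idx[: t + 1]).sum() / w0),
        )
    else:
        u0 = (0.0, 0.0)
    if w1 > 0:
        u1 = (
            float((p1.sum(axis=1) * idx[s + 1 :]).sum() / w1),
            float((p1.sum(axis=0) * idx[t + 1 :]).sum() / w1),
        )
    else:
        u1 = (0.0, 0.0)
    return ClassStatistics(w0=w0, w1=w1, u0=u0, u1=u1, degenerate=(w0 == 0 or w1 == 0))


def trace_criterion(h: Histogram2D, s: int, t: int) -> float:
    """Between-class scatter trace at (s, t); zero when a class is empty."""
    st = class_stats(h, s, t)
    if st.degenerate:
        return 0.0
    uTi, uTj = h.mean_vector
    d0 = (st.u0[0] - uTi) ** 2 + (st.u0[1] - uTj) ** 2
    d1 = (st.u1[0] - uTi) ** 2 + (st.u1[1] - uTj) ** 2
    return st.w0 * d0 + st.w1 * d1


def criterion_table(h: Histogram2D) -> np.ndarray:
    """Trace criterion for every (s, t) in [0, L-2]^2, via cumulative sums.

    Inclusion-exclusion on 2-D prefix sums of p, i*p and j*p evaluates each
    pair in O(1); the result matches direct summation to within 1e-9.
    Entries where either class is empty are exactly 0.
    """
    L = h.levels
    idx = np.arange(L, dtype=np.float64)
    P = h.p.cumsum(axis=0).cumsum(axis=1)
    Si = (h.p * idx[:, None]).cumsum(axis=0).cumsum(axis=1)
    Sj = (h.p * idx[None, :]).cumsum(axis=0).cumsum(axis=1)
    uTi, uTj = h.mean_vector

    w0 = P[: L - 1, : L - 1]
    m0i = Si[: L - 1, : L - 1]
    m0j = Sj[: L - 1, : L - 1]
    # mass/moments of the strict upper-right quadrant (i > s and j > t)
    w1 = P[-1, -1] - P[: L - 1, -1][:, None] - P[-1, : L - 1][None, :] + w0
    m1i = Si[-1, -1] - Si[: L - 1, -1][:, None] - Si[-1, : L - 1][None, :] + m0i
    m1j = Sj[-1, -1] - Sj[: L - 1, -1][:, None] - Sj[-1, : L - 1][None, :] + m0j

    crit = np.zeros((L - 1, L - 1))
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d0 = (m0i / w0 - uTi) ** 2 + (m0j / w0 - uTj) ** 2
        d1 = (m1i / w1 - uTi) ** 2 + (m1j / w1 - uTj) ** 2
        vals = w0 * d0 + w1 * d1
    crit[valid] = vals[valid]
    return crit


def find_threshold(h: Histogram2D) -> ThresholdPair:
    """The (s, t) maximising the trace criterion over [0, L-2]^2.

    Ties break to the lexicographically smallest (s, t).  A histogram with
    all mass in one cell has criterion 0 everywhere; the pair (i0, j0) at
    that cell (clipped into range) is returned with a degeneracy warning.
    """
    crit = criterion_table(h)
    flat = int(np.argmax(crit))
    s, t = divmod(flat, h.levels - 1)
    best = float(crit[s, t])
    if best == 0.0:
        i0, j0 = np.unravel_index(int(np.argmax(h.counts)), h.counts.shape)
        warnings.warn("degenerate histogram: criterion is 0 everywhere", stacklevel=2)
        s = min(int(i0), h.levels - 2)
        t = min(int(j0), h.levels - 2)
    return ThresholdPair(s=int(s), t=int(t), criterion=best)


def binarize(
    first: np.ndarray,
    second: np.ndarray,
    tp: ThresholdPair,
    ambiguous: str = "smoothed",
    h: Histogram2D | None = None,
) -> np.ndarray:
    """Label pixels from their (i, j) pair against a threshold pair.

    Quadrant IV (i > s, j > t) is foreground and quadrant I (i <= s,
    j <= t) background.  Pixels in the off-diagonal quadrants II/III are
    labelled per ``ambiguous``:

    - ``"smoothed"`` (default): the smoothed coordinate decides (j > t),
      since the neighbourhood average is the noise-robust coordinate;
    - ``"raw"``: the raw coordinate decides (i > s);
    - ``"nearest"``: the class whose mean vector is closer in the (i, j)
      plane wins (requires ``h`` for the class statistics).
    """
    first = np.asarray(first)
    second = np.asarray(second)
    if first.shape != second.shape:
        raise ValueError("coordinate images must share a shape")
    if ambiguous not in AMBIGUOUS_RULES:
        raise ValueError(f"ambiguous must be one of {AMBIGUOUS_RULES}")
    fg = (first > tp.s) & (second > tp.t)
    bg = (first <= tp.s) & (second <= tp.t)
    mask = fg.astype(np.uint8)
    amb = ~(fg | bg)
    if amb.any():
        if ambiguous == "smoothed":
            mask[amb] = (second[amb] > tp.t).astype(np.uint8)
        elif ambiguous == "raw":
            mask[amb] = (first[amb] > tp.s).astype(np.uint8)
        else:
            if h is None:
                raise ValueError("ambiguous='nearest' needs the histogram")
            st = class_stats(h, tp.s, tp.t)
            i, j = first[amb].astype(np.float64), second[amb].astype(np.float64)
            d0 = (i - st.u0[0]) ** 2 + (j - st.u0[1]) ** 2
            d1 = (i - st.u1[0]) ** 2 + (j - st.u1[1]) ** 2
            mask[amb] = (d1 < d0).astype(np.uint8)
    return mask
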