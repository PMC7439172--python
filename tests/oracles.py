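"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fast paths: direct nested-loop
summation for the threshold criterion, full path enumeration for the
splitting line, and windowed sorting for the filters.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_class_moments(p: np.ndarray, s: int, t: int):
    """Direct-summation quadrant masses and raw moments."""
    L = p.shape[0]
    w0 = m0i = m0j = 0.0
    w1 = m1i = m1j = 0.0
    for i in range(L):
        for j in range(L):
            if i <= s and j <= t:
                w0 += p[i, j]
                m0i += i * p[i, j]
                m0j += j * p[i, j]
            elif i > s and j > t:
                w1 += p[i, j]
                m1i += i * p[i, j]
                m1j += j * p[i, j]
    return w0, m0i, m0j, w1, m1i, m1j


def naive_trace(p: np.ndarray, s: int, t: int) -> float:
    """Between-class scatter trace by direct summation."""
    L = p.shape[0]
    ii = np.arange(L, dtype=float)
    uTi = float((p.sum(axis=1) * ii).sum())
    uTj = float((p.sum(axis=0) * ii).sum())
    w0, m0i, m0j, w1, m1i, m1j = naive_class_moments(p, s, t)
    if w0 <= 0 or w1 <= 0:
        return 0.0
    d0 = (m0i / w0 - uTi) ** 2 + (m0j / w0 - uTj) ** 2
    d1 = (m1i / w1 - uTi) ** 2 + (m1j / w1 - uTj) ** 2
    return w0 * d0 + w1 * d1


def naive_find_threshold(p: np.ndarray):
    """Exhaustive (s, t) search with strict-improvement lexicographic scan."""
    L = p.shape[0]
    best = (-1.0, 0, 0)
    for s in range(L - 1):
        for t in range(L - 1):
            v = naive_trace(p, s, t)
            if v > best[0]:
                best = (v, s, t)
    return best[1], best[2], best[0]


def enumerate_paths(E: np.ndarray):
    """All 8-connected one-row-per-column paths and their total energies."""
    m, n = E.shape
    for start in range(m):
        for steps in itertools.product((-1, 0, 1), repeat=n - 1):
            rows = [start]
            ok = True
            for d in steps:
                nxt = rows[-1] + d
                if not (0 <= nxt < m):
                    ok = False
                    break
                rows.append(nxt)
            if ok:
                total = 0.0
                for c, r in enumerate(rows):
                    total += E[r, c]
                yield rows, total


def best_path_total(E: np.ndarray) -> float:
    return max(t for _, t in enumerate_paths(E))


def windowed_median(img: np.ndarray, k: int) -> np.ndarray:
    """Median filter by explicit edge padding and window sorting."""
    r = k // 2
    pad = np.pad(img, r, mode="edge")
    out = np.empty_like(img)
    m, n = img.shape
    for x in range(m):
        for y in range(n):
            out[x, y] = np.median(pad[x : x + k, y : y + k])
    return out


def count_confusion(pred: np.ndarray, gt: np.ndarray):
    """Pixel-by-pixel confusion counts with plain Python loops."""
    tp = fp = fn = tn = 0
    for a, b in zip(pred.ravel().tolist(), gt.ravel().tolist()):
        if a == 1 and b == 1:
            tp += 1
        elif a == 1:
            fp += 1
        elif b == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
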