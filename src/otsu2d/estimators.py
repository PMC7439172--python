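"""Scikit-learn-style segmenter estimators.

``Otsu2DSegmenter`` is whole-image 2-D Otsu thresholding: ``fit`` learns
the threshold pair from an image, ``predict`` labels pixels.  With the
default ``strategy='med_medavg'`` it is the salt-and-pepper-robust variant;
``strategy='avg_only'`` recovers the classic 2-D Otsu method.

``PartitionedOtsu2DSegmenter`` first cuts the image along the maximum-
energy splitting line and then thresholds the two parts, either
independently (``scheme='s1'``) or with a single pair maximising the
product of the two parts' between-class criteria (``scheme='s2'``).

Both follow the estimator contract (get_params/set_params, fitted
attributes with trailing underscores) and compose with sklearn tooling;
``X`` is a single 2-D gray image rather than a sample matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .histogram import FilterConfig, histogram_from_pair, pair_images
from .imgio import LEVELS, validate_gray
from .otsu import ThresholdPair, binarize, criterion_table, find_threshold
from .splitline import EnergyConfig, energy_map, find_splitline, partition


class Otsu2DSegmenter(BaseEstimator):
    """Global 2-D Otsu thresholding of a gray image.

    Parameters
    ----------
    strategy : {'med_medavg', 'orig_medavg', 'avg_only'}
        Histogram pairing; the default uses the median image against the
        median-average image.
    k : int
        Odd smoothing-window size in pixels.
    ambiguous : {'smoothed', 'raw', 'nearest'}
        How pixels in the off-diagonal histogram quadrants are labelled.

    Attributes
    ----------
    threshold_ : ThresholdPair
        Optimal (s, t) with its criterion value.
    histogram_ : Histogram2D
        The 2-D histogram the threshold was found on.
    """

    def __init__(self, strategy: str = "med_medavg", k: int = 3,
                 ambiguous: str = "smoothed"):
        self.strategy = strategy
        self.k = k
        self.ambiguous = ambiguous

    def _config(self) -> FilterConfig:
        return FilterConfig(k=self.k, strategy=self.strategy)

    def fit(self, X: np.ndarray, y=None) -> "Otsu2DSegmenter":
        """Learn the threshold pair from the image ``X``."""
        img = validate_gray(X)
        first, second = pair_images(img, self._config())
        self.histogram_ = histogram_from_pair(first, second, LEVELS)
        self.threshold_ = find_threshold(self.histogram_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binarise the image ``X`` with the fitted threshold pair."""
        img = validate_gray(X)
        first, second = pair_images(img, self._config())
        return binarize(first, second, self.threshold_,
                        ambiguous=self.ambiguous, h=self.histogram_)

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def make_segmenter(method: str):
    """Build the segmenter an experiment name refers to.

    ``otsu2d`` is the classic whole-image method, ``maotsu2d`` pairs the
    raw image with the median-average image, ``mmaotsu2d`` is the robust
    median/median-average pairing, and ``scheme1``/``scheme2`` add the
    splitting-line partition.
    """
    if method == "otsu2d":
        return Otsu2DSegmenter(strategy="avg_only")
    if method == "maotsu2d":
        return Otsu2DSegmenter(strategy="orig_medavg")
    if method == "mmaotsu2d":
        return Otsu2DSegmenter(strategy="med_medavg")
    if method == "scheme1":
        return PartitionedOtsu2DSegmenter(scheme="s1")
    if method == "scheme2":
        return PartitionedOtsu2DSegmenter(scheme="s2")
    raise ValueError(f"unknown method {method!r}")


class PartitionedOtsu2DSegmenter(BaseEstimator):
    """Splitting-line partition followed by per-part 2-D Otsu thresholding.

    Parameters
    ----------
    scheme : {'s1', 's2'}
        's1' thresholds the two parts independently (two pairs); 's2'
        finds one pair maximising the product of the parts' criteria.
    strategy, k, ambiguous
        As in :class:`Otsu2DSegmenter`.
    w1, w2 : float
        Colour-reward and texture-penalty weights of the splitting energy.
    sigma_mode : {'sigma_half_m', 'literal_2m'}
        Width convention of the Gaussian position weight.
    source : {'raw', 'median'}
        Image the splitting energy is computed on.

    Attributes
    ----------
    split_path_ : SplitPath
        The maximum-energy splitting line.
    parts_ : (part1, part2) uint8 region masks.
    thresholds_ : list of ThresholdPair (two for 's1', one for 's2').
    """

    def __init__(self, scheme: str = "s1", strategy: str = "med_medavg",
                 k: int = 3, ambiguous: str = "smoothed", w1: float = 2.0,
                 w2: float = 1.0, sigma_mode: str = "sigma_half_m",
                 source: str = "raw"):
        self.scheme = scheme
        self.strategy = strategy
        self.k = k
        self.ambiguous = ambiguous
        self.w1 = w1
        self.w2 = w2
        self.sigma_mode = sigma_mode
        self.source = source

    def _configs(self) -> tuple[FilterConfig, EnergyConfig]:
        return (FilterConfig(k=self.k, strategy=self.strategy),
                EnergyConfig(w1=self.w1, w2=self.w2,
                             sigma_mode=self.sigma_mode, source=self.source))

    def fit(self, X: np.ndarray, y=None) -> "PartitionedOtsu2DSegmenter":
        """Find the splitting line and the per-part threshold pair(s)."""
        if self.scheme not in ("s1", "s2"):
            raise ValueError("scheme must be 's1' or 's2'")
        img = validate_gray(X)
        fcfg, ecfg = self._configs()
        self.split_path_ = find_splitline(energy_map(img, ecfg))
        self.parts_ = partition(img.shape, self.split_path_)
        first, second = pair_images(img, fcfg)
        hists = [histogram_from_pair(first, second, LEVELS, region=part)
                 for part in self.parts_]
        self.histograms_ = hists
        if self.scheme == "s1":
            self.thresholds_ = [find_threshold(h) for h in hists]
        else:
            self.thresholds_ = [self._joint_threshold(hists)]
        return self

    @staticmethod
    def _joint_threshold(hists) -> ThresholdPair:
        """One (s, t) maximising the product of the two parts' criteria.

        A part whose criterion is identically zero (a constant part)
        would collapse the product everywhere; such a part is dropped
        from the objective with a warning.
        """
        tables = [criterion_table(h) for h in hists]
        live = [tb for tb in tables if tb.max() > 0]
        if not live:
            warnings.warn("both parts degenerate: criterion is 0 everywhere",
                          stacklevel=2)
            return ThresholdPair(s=0, t=0, criterion=0.0)
        if len(live) < len(tables):
            warnings.warn("one part degenerate; maximising the other part's "
                          "criterion alone", stacklevel=2)
        objective = live[0].copy()
        for tb in live[1:]:
            objective *= tb
        if objective.max() == 0.0:
            # the parts' criteria have disjoint (s, t) supports, so the
            # product vanishes everywhere; break the tie by the sum
            warnings.warn("joint criterion product is 0 everywhere; "
                          "tie-breaking by the sum of part criteria",
                          stacklevel=2)
            objective = sum(live)
        flat = int(np.argmax(objective))
        s, t = divmod(flat, objective.shape[1])
        return ThresholdPair(s=s, t=t, criterion=float(objective[s, t]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binarise ``X`` with the fitted split and threshold pair(s)."""
        img = validate_gray(X)
        fcfg, _ = self._configs()
        first, second = pair_images(img, fcfg)
        if self.scheme == "s2":
            return binarize(first, second, self.thresholds_[0],
                            ambiguous=self.ambiguous)
        mask = np.zeros(img.shape, dtype=np.uint8)
        for part, tp, h in zip(self.parts_, self.thresholds_, self.histograms_):
            sel = part.astype(bool)
            if tp.criterion == 0.0:
                # constant part: no contrast to threshold, label background
                continue
            sub = binarize(first, second, tp, ambiguous=self.ambiguous, h=h)
            mask[sel] = sub[sel]
        return mask

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).predict(X)
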