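"""Partition-based thresholding workflows.

Thin functional wrappers over :class:`PartitionedOtsu2DSegmenter`: split
the image along the maximum-energy line, threshold the two parts per-part
(scheme 1) or jointly (scheme 2), and optionally pick the better scheme by
misclassification error when a ground-truth mask is available.  No
unsupervised selection rule exists, so without ground truth both results
are returned and none is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import PartitionedOtsu2DSegmenter
from .metrics import EvalReport, evaluate
from .otsu import ThresholdPair
from .splitline import SplitPath


@dataclass
class SchemeResult:
    """Mask, thresholds and split of one scheme run."""

    mask: np.ndarray
    thresholds: list[ThresholdPair]
    scheme: str  # 's1' or 's2'
    split: SplitPath
    report: EvalReport | None = field(default=None)

    def as_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "thresholds": [
                {"s": tp.s, "t": tp.t, "criterion": tp.criterion}
                for tp in self.thresholds
            ],
            "split_rows": self.split.rows.tolist(),
        }
        if self.report is not None:
            d["metrics"] = self.report.as_dict()
        return d


def _run(img: np.ndarray, scheme: str, **params) -> SchemeResult:
    est = PartitionedOtsu2DSegmenter(scheme=scheme, **params)
    mask = est.fit_predict(img)
    return SchemeResult(mask=mask, thresholds=list(est.thresholds_),
                        scheme=scheme, split=est.split_path_)


def scheme1(img: np.ndarray, **params) -> SchemeResult:
    """Split, then threshold each part independently (two pairs)."""
    return _run(img, "s1", **params)


def scheme2(img: np.ndarray, **params) -> SchemeResult:
    """Split, then find one pair maximising the product of part criteria."""
    return _run(img, "s2", **params)


def run_pipeline(
    img: np.ndarray,
    gt: np.ndarray | None = None,
    **params,
) -> tuple[SchemeResult, SchemeResult, str | None]:
    """Run both schemes; select the lower-ME one when ground truth is given.

    Returns ``(scheme1_result, scheme2_result, selected)`` with ``selected``
    in ``{'s1', 's2', None}``; ties go to scheme 1.
    """
    r1 = scheme1(img, **params)
    r2 = scheme2(img, **params)
    selected = None
    if gt is not None:
        r1.report = evaluate(r1.mask, gt)
        r2.report = evaluate(r2.mask, gt)
        selected = "s1" if r1.report.me <= r2.report.me else "s2"
    return r1, r2, selected
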