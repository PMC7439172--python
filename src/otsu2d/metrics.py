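"""Segmentation quality metrics: misclassification error and Dice.

ME = 1 - (|F_o ∩ F_T| + |B_o ∩ B_T|) / (|B_T| + |F_T|)  — the fraction of
pixels whose label disagrees with the ground truth — and
DSC = 2 TP / (2 TP + FP + FN), a foreground-overlap measure.  DSC of two
masks with empty foreground is defined as 1 (perfect agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import validate_mask


@dataclass(frozen=True)
class EvalReport:
    me: float
    dsc: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict:
        return {"me": self.me, "dsc": self.dsc, "tp": self.tp,
                "fp": self.fp, "fn": self.fn, "tn": self.tn}


def evaluate(pred: np.ndarray, gt: np.ndarray) -> EvalReport:
    """Compare a predicted binary mask against ground truth."""
    p = validate_mask(pred).astype(bool)
    g = validate_mask(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    total = tp + fp + fn + tn
    me = 1.0 - (tp + tn) / total
    denom = 2 * tp + fp + fn
    dsc = 1.0 if denom == 0 else 2 * tp / denom
    return EvalReport(me=me, dsc=dsc, tp=tp, fp=fp, fn=fn, tn=tn)
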