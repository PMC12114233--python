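"""Classification and virtual-screening metrics.

MCC and balanced accuracy follow the standard confusion-matrix formulas;
ROC AUC is the rank-based (Mann-Whitney) estimator with ties counted as
one half; the enrichment factor is the active fraction in the top-ranked
``fraction`` of the library relative to the overall active fraction.

Score ``orientation`` matters throughout: raw docking scores rank
lower-is-better (more negative = stronger predicted binding) while
calibrated scores approximate pChEMBL and rank higher-is-better.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

LOWER_IS_ACTIVE = "lower_is_active"
HIGHER_IS_ACTIVE = "higher_is_active"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must be index-aligned")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    factor in the denominator returns 0 with a warning (the conventional
    degenerate value).
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if 0 in denom_factors:
        warnings.warn("MCC denominator has a zero factor; returning 0", stacklevel=2)
        return 0.0
    # float products to avoid int overflow on huge counts
    num = float(tp) * tn - float(fp) * fn
    denom = math.sqrt(math.prod(float(f) for f in denom_factors))
    return num / denom


def balanced_accuracy(c: ConfusionCounts) -> float:
    """BA = (sensitivity + specificity) / 2."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("balanced accuracy undefined: a class is absent")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return 0.5 * (sens + spec)


def _ranking_scores(scores, orientation: str) -> np.ndarray:
    """Map scores so larger = more active-looking under the given orientation."""
    scores = np.asarray(scores, dtype=float)
    if orientation == LOWER_IS_ACTIVE:
        return -scores
    if orientation == HIGHER_IS_ACTIVE:
        return scores
    raise ValueError(f"unknown orientation {orientation!r}")


def roc_auc(scores, labels, orientation: str = LOWER_IS_ACTIVE) -> float:
    """Rank-based ROC AUC: P(random active outranks random inactive), ties = 1/2."""
    s = _ranking_scores(scores, orientation)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC requires both classes present")
    ranks = stats.rankdata(s)  # average ranks handle ties as 1/2
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def enrichment_factor(
    scores,
    labels,
    fraction: float = 0.10,
    orientation: str = LOWER_IS_ACTIVE,
) -> float:
    """Enrichment factor at a top fraction of the ranked library.

    EF = (actives in top ceil(fraction*N) / ceil(fraction*N))
         / (total actives / N).
    Ties at the cutoff rank are resolved by stable sort order.
    """
    s = _ranking_scores(scores, orientation)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n == 0:
        raise ValueError("empty input")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_actives = int(np.sum(y == 1))
    if n_actives == 0 or n_actives == n:
        raise ValueError("enrichment factor requires both classes present")
    n_top = math.ceil(fraction * n)
    order = np.argsort(-s, kind="stable")
    top_actives = int(np.sum(y[order[:n_top]] == 1))
    return (top_actives / n_top) / (n_actives / n)
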