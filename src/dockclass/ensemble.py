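"""Ensemble docking classification via rank-by-number score averaging.

Every subset of the available target structures (sizes 2..K) defines one
ensemble model: each compound's ensemble score is the arithmetic mean of
its docking scores across the member structures, and a KDE-intersection
threshold is fitted on those means. A compound missing a score in any
member structure is excluded from that ensemble (no mean-of-partial bias).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import ScoreTable
from .kde_threshold import classify, find_threshold
from .metrics import ConfusionCounts, balanced_accuracy, mcc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleSpec:
    """A subset of structure identifiers defining one ensemble model."""

    structure_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.structure_ids)) != len(self.structure_ids):
            raise ValueError("ensemble members must be distinct")
        if len(self.structure_ids) < 2:
            raise ValueError("an ensemble needs at least two structures")

    @property
    def size(self) -> int:
        return len(self.structure_ids)


def enumerate_ensembles(
    structure_ids: list[str],
    min_size: int = 2,
    max_size: int | None = None,
) -> list[EnsembleSpec]:
    """All structure subsets of sizes min_size..max_size, by size then lexicographic."""
    if max_size is None:
        max_size = len(structure_ids)
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if min_size > max_size:
        raise ValueError("min_size exceeds max_size")
    if max_size > len(structure_ids):
        raise ValueError("max_size exceeds the number of structures")
    specs = []
    for size in range(min_size, max_size + 1):
        for combo in combinations(sorted(structure_ids), size):
            specs.append(EnsembleSpec(structure_ids=combo))
    return specs


def ensemble_scores(
    table: ScoreTable, spec: EnsembleSpec
) -> tuple[np.ndarray, list[str]]:
    """Mean score per compound over the spec's structures (rank-by-number).

    Only compounds with a score in *every* member structure are retained.
    Returns the mean-score vector and the aligned retained compound ids.
    """
    missing = set(spec.structure_ids) - set(table.structures)
    if missing:
        raise ValueError(f"structures not in table: {sorted(missing)}")
    sub = table.frame[list(spec.structure_ids)]
    complete = sub.dropna()
    if complete.empty:
        raise ValueError("no compound has scores in every ensemble structure")
    return complete.mean(axis=1).to_numpy(), list(complete.index)


class EnsembleThresholdClassifier(BaseEstimator, ClassifierMixin):
    """KDE-threshold classifier on the mean score over a fixed structure subset.

    ``fit`` consumes the per-structure score matrix (columns ordered as
    ``structures``); rows with any missing member score must be dropped by
    the caller — :func:`ensemble_scores` does that bookkeeping.
    """

    def __init__(self, structures: tuple[str, ...] = ()):
        self.structures = structures

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a compounds x structures matrix")
        if np.isnan(X).any():
            raise ValueError("missing member scores; drop incomplete compounds first")
        means = X.mean(axis=1)
        y = np.asarray(y, dtype=int)
        self.model_ = find_threshold(means[y == 1], means[y == 0])
        self.threshold_ = self.model_.threshold
        self.orientation_ = self.model_.orientation
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return classify(X.mean(axis=1), self.model_)


def scan_ensembles(
    table: ScoreTable,
    labels: dict[str, int] | pd.Series,
    min_size: int = 2,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Fit one threshold model per structure subset and rank subsets by MCC.

    Each spec is evaluated on its own retained compound set (compounds
    docked in every member structure). Specs where threshold fitting
    fails are reported, not fatal. Returns a DataFrame sorted by MCC
    descending (ties: smaller ensemble, then lexicographic members) with
    columns: members, size, threshold, orientation, mcc, ba, n_retained.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    rows = []
    for spec in enumerate_ensembles(table.structures, min_size, max_size):
        try:
            means, ids = ensemble_scores(table, spec)
            y = np.array([labels[cid] for cid in ids], dtype=int)
            model = find_threshold(means[y == 1], means[y == 0])
            pred = classify(means, model)
            c = ConfusionCounts.from_predictions(y, pred)
            rows.append(
                {
                    "members": ",".join(spec.structure_ids),
                    "size": spec.size,
                    "threshold": model.threshold,
                    "orientation": model.orientation,
                    "mcc": mcc(c),
                    "ba": balanced_accuracy(c),
                    "n_retained": len(ids),
                }
            )
        except (ValueError, KeyError) as exc:
            logger.warning("ensemble %s failed: %s", spec.structure_ids, exc)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        by=["mcc", "size", "members"], ascending=[False, True, True]
    ).reset_index(drop=True)
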