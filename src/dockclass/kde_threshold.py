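"""KDE-intersection threshold classification (the "Threshold Method").

Gaussian kernel density estimates are fitted to the active and inactive
score distributions; the crossing point of the two density curves becomes
the classification cutoff. At the crossing, the density mass misclassified
on either side is balanced, so false positives and false negatives are
penalised equally.

Orientation is inferred from the class means: on raw docking scores the
actives sit lower (more negative), on calibrated pChEMBL-like scores they
sit higher. A score exactly at the threshold is classified inactive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import HIGHER_IS_ACTIVE, LOWER_IS_ACTIVE

N_GRID = 2048
GRID_PAD_BANDWIDTHS = 3.0


@dataclass(frozen=True)
class ThresholdModel:
    """A fitted classification threshold with its KDE provenance."""

    threshold: float
    orientation: str
    bandwidth_active: float
    bandwidth_inactive: float
    grid_range: tuple[float, float]
    n_grid: int = N_GRID

    def __post_init__(self) -> None:
        lo, hi = self.grid_range
        if not lo <= self.threshold <= hi:
            raise ValueError("threshold outside the evaluation grid")
        if self.bandwidth_active <= 0 or self.bandwidth_inactive <= 0:
            raise ValueError("bandwidths must be positive")


def fit_kde(scores, bandwidth_rule: str = "scott"):
    """Fit a Gaussian-kernel density with Scott's bandwidth rule.

    Returns a ``scipy.stats.gaussian_kde`` instance; its bandwidth in
    score units is ``kde.factor * std(scores)``.
    """
    if bandwidth_rule != "scott":
        raise ValueError(f"unsupported bandwidth rule {bandwidth_rule!r}")
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.ptp(scores) == 0:
        raise ValueError("KDE requires at least two distinct values")
    return stats.gaussian_kde(scores, bw_method="scott")


def kde_bandwidth(kde) -> float:
    """Bandwidth of a fitted 1-D gaussian_kde in data units."""
    return float(np.sqrt(kde.covariance[0, 0]))


def _density_crossings(grid: np.ndarray, diff: np.ndarray) -> list[float]:
    """Locate sign changes of ``diff`` on ``grid`` by linear interpolation."""
    crossings: list[float] = []
    sign = np.sign(diff)
    for i in range(len(grid) - 1):
        s0, s1 = sign[i], sign[i + 1]
        if s0 == 0:
            crossings.append(float(grid[i]))
        elif s0 * s1 < 0:
            x0, x1 = grid[i], grid[i + 1]
            d0, d1 = diff[i], diff[i + 1]
            crossings.append(float(x0 + (x1 - x0) * d0 / (d0 - d1)))
    if sign[-1] == 0:
        crossings.append(float(grid[-1]))
    return crossings


def find_threshold(active_scores, inactive_scores) -> ThresholdModel:
    """Fit per-class KDEs and take their intersection as the threshold.

    The evaluation grid spans the pooled score range padded by three
    bandwidths on each side. Among multiple density crossings, the one
    lying between the two class means and nearest their midpoint is
    chosen (KDE tails can cross spuriously far from the bulk). The
    orientation puts the active class's mean on the active side.
    """
    a = np.asarray(active_scores, dtype=float)
    i = np.asarray(inactive_scores, dtype=float)
    kde_a = fit_kde(a)
    kde_i = fit_kde(i)
    bw_a = kde_bandwidth(kde_a)
    bw_i = kde_bandwidth(kde_i)
    pooled = np.concatenate([a, i])
    pad = GRID_PAD_BANDWIDTHS * max(bw_a, bw_i)
    lo, hi = pooled.min() - pad, pooled.max() + pad
    grid = np.linspace(lo, hi, N_GRID)
    diff = kde_a(grid) - kde_i(grid)
    crossings = _density_crossings(grid, diff)
    if not crossings:
        raise ValueError(
            f"class densities do not cross on the grid [{lo:.4g}, {hi:.4g}]"
        )
    mu_a, mu_i = float(a.mean()), float(i.mean())
    lo_mu, hi_mu = min(mu_a, mu_i), max(mu_a, mu_i)
    between = [c for c in crossings if lo_mu <= c <= hi_mu]
    candidates = between if between else crossings
    midpoint = 0.5 * (mu_a + mu_i)
    threshold = min(candidates, key=lambda c: abs(c - midpoint))
    orientation = LOWER_IS_ACTIVE if mu_a < mu_i else HIGHER_IS_ACTIVE
    return ThresholdModel(
        threshold=threshold,
        orientation=orientation,
        bandwidth_active=bw_a,
        bandwidth_inactive=bw_i,
        grid_range=(float(lo), float(hi)),
    )


def classify(scores, model: ThresholdModel) -> np.ndarray:
    """Binary predictions from a threshold model.

    ``lower_is_active``: predict 1 iff score < threshold;
    ``higher_is_active``: predict 1 iff score > threshold.
    A score exactly at the threshold is predicted inactive.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if model.orientation == LOWER_IS_ACTIVE:
        return (scores < model.threshold).astype(int)
    return (scores > model.threshold).astype(int)


class KDEThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier thresholding 1-D scores at the KDE intersection.

    Fits one Gaussian KDE (Scott's rule) per class and places the decision
    cutoff at the crossing of the two density curves, orienting the
    decision so the active-class mean falls on the active side.

    Attributes
    ----------
    threshold_ : float
        The crossing point used as cutoff.
    orientation_ : str
        "lower_is_active" or "higher_is_active".
    model_ : ThresholdModel
        Full provenance (bandwidths, grid).
    """

    def __init__(self, bandwidth_rule: str = "scott"):
        self.bandwidth_rule = bandwidth_rule

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single score feature")
            X = X[:, 0]
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if self.bandwidth_rule != "scott":
            raise ValueError(f"unsupported bandwidth rule {self.bandwidth_rule!r}")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("need both classes 0 and 1 to fit a threshold")
        self.classes_ = classes
        self.model_ = find_threshold(X[y == 1], X[y == 0])
        self.threshold_ = self.model_.threshold
        self.orientation_ = self.model_.orientation
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return classify(X, self.model_)
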