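"""Weighted k-nearest-neighbour classification and evaluation.

Neighbours vote with weight 1/d², d the Euclidean distance to the query,
so near neighbours dominate and — with the default k = "all" — no
neighbour count needs choosing: remote points contribute negligibly.  An
exact match (d = 0) is the limit of 1/d² and takes all the weight.

Evaluation reports confusion counts and accuracy / sensitivity /
specificity in percent, with *high* situational interest as the positive
class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_signals import ConfigurationError, DomainError, FeatureTable

logger = logging.getLogger(__name__)

LABELS = ("high", "low")


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def inverse_square_weights(distances: np.ndarray) -> np.ndarray:
    """Vote weights 1/d².

    If any distance is exactly zero those points share a total weight of
    1 and all others get 0 (the d -> 0 limit of 1/d²: exact matches
    decide by majority among themselves).
    """
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise DomainError("distances must be non-negative")
    zero = d == 0
    if zero.any():
        w = np.zeros_like(d)
        w[zero] = 1.0 / zero.sum()
        return w
    return 1.0 / d**2


@dataclass
class WkNNModel:
    """Stored training set for weighted kNN (fit = memorize)."""

    X: np.ndarray
    y: np.ndarray
    k: int | str = "all"  # neighbour count, or "all" for pure weighting
    standardize: bool = False
    _mean: np.ndarray = field(init=False, repr=False, default=None)
    _std: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ConfigurationError("X must be n x d with one label per row")
        if len(self.X) == 0:
            raise ConfigurationError("cannot fit wkNN on an empty training set")
        if self.k != "all":
            if not 1 <= int(self.k) <= len(self.X):
                raise ConfigurationError(
                    f"k={self.k} outside [1, {len(self.X)}]"
                )
            self.k = int(self.k)
        if self.standardize:
            self._mean = self.X.mean(axis=0)
            self._std = self.X.std(axis=0)
            self._std[self._std == 0] = 1.0
            self.X = (self.X - self._mean) / self._std

    def _transform(self, q: np.ndarray) -> np.ndarray:
        if self.standardize:
            return (q - self._mean) / self._std
        return q


def wknn_predict(model: WkNNModel, query: np.ndarray) -> tuple[str, dict[str, float]]:
    """Predict the class of ``query``; also return per-class weight sums.

    Ties in total weight fall back to the label of the single nearest
    neighbour; a residual tie goes to the lexicographically smaller label
    with a warning.
    """
    q = np.asarray(query, dtype=float)
    if q.shape != (model.X.shape[1],):
        raise DomainError(
            f"query of dimension {q.shape} does not match model "
            f"dimension {model.X.shape[1]}"
        )
    q = model._transform(q)
    dists = np.sqrt(np.sum((model.X - q) ** 2, axis=1))
    order = np.argsort(dists, kind="stable")
    k = len(dists) if model.k == "all" else model.k
    nearest = order[:k]
    weights = inverse_square_weights(dists[nearest])
    sums: dict[str, float] = {}
    for idx, w in zip(nearest, weights):
        sums[model.y[idx]] = sums.get(model.y[idx], 0.0) + float(w)
    best = max(sums.values())
    winners = sorted(lbl for lbl, s in sums.items() if s == best)
    if len(winners) == 1:
        return winners[0], sums
    nearest_label = model.y[order[0]]
    if nearest_label in winners:
        return str(nearest_label), sums
    logger.warning("unresolvable class-weight tie; choosing %r", winners[0])
    return winners[0], sums


@dataclass
class EvalReport:
    """Confusion counts and percent metrics (positive class = high)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return round(100.0 * (self.tp + self.tn) / self.n, 1)

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            warnings.warn("no positive-class samples: sensitivity undefined",
                          stacklevel=2)
            return float("nan")
        return round(100.0 * self.tp / (self.tp + self.fn), 1)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            warnings.warn("no negative-class samples: specificity undefined",
                          stacklevel=2)
            return float("nan")
        return round(100.0 * self.tn / (self.tn + self.fp), 1)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def evaluate(predicted, truth, positive: str = "high") -> EvalReport:
    """Confusion counts and metrics for predicted vs true labels."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise DomainError("predicted and truth must have equal length")
    bad = (set(predicted) | set(truth)) - set(LABELS)
    if bad:
        raise DomainError(f"labels outside {{high, low}}: {sorted(bad)}")
    tp = sum(p == positive and t == positive for p, t in zip(predicted, truth))
    fn = sum(p != positive and t == positive for p, t in zip(predicted, truth))
    fp = sum(p == positive and t != positive for p, t in zip(predicted, truth))
    tn = sum(p != positive and t != positive for p, t in zip(predicted, truth))
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn)


def cross_validate(
    table: FeatureTable,
    k: int | str = "all",
    scheme: str = "loo",
    n_folds: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> EvalReport:
    """Pooled held-out evaluation: leave-one-out or stratified k-fold.

    Leave-one-out is deterministic; k-fold shuffles with ``seed``.  A fold
    whose training split loses a class entirely is skipped with a warning.
    """
    X, y = table.X, table.y
    for lbl in LABELS:
        if (y == lbl).sum() < 2:
            raise ConfigurationError(
                f"need >= 2 rows per class, class {lbl!r} has "
                f"{(y == lbl).sum()}"
            )
    if scheme == "loo":
        folds = [(np.delete(np.arange(len(y)), i), np.array([i]))
                 for i in range(len(y))]
    elif scheme == "kfold":
        from sklearn.model_selection import StratifiedKFold

        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
        folds = list(splitter.split(X, y))
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    predicted: list[str] = []
    truth: list[str] = []
    for train_idx, test_idx in folds:
        if len(set(y[train_idx])) < 2:
            logger.warning("fold lost a class from training; skipped")
            continue
        model = WkNNModel(X=X[train_idx], y=y[train_idx], k=k,
                          standardize=standardize)
        for i in test_idx:
            label, _ = wknn_predict(model, X[i])
            predicted.append(label)
            truth.append(str(y[i]))
    return evaluate(predicted, truth)
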