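"""Classifier performance measures: AUC (Hand & Till for multiclass),
balanced accuracy, and signal-detection measures (hr, far, d')."""

from __future__ import annotations

import numpy as np
from scipy.stats import norm
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

__all__ = [
    "score_auc",
    "score_balanced_accuracy",
    "score_sdt",
    "chance_level",
]


def _pairwise_auc(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Rank-based two-class AUC: P(score_pos > score_neg), ties count 0.5."""
    return float(roc_auc_score(is_positive.astype(int), scores))


def score_auc(
    scores: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> float:
    """Area under the ROC curve from graded decision values.

    Two classes: `scores` is 1-D, higher meaning more evidence for the
    first (sorted) class; the AUC is the rank probability that a random
    trial of that class outscores a random trial of the other, ties 0.5.

    More than two classes (Hand & Till 2001): `scores` is
    ``(n_trials, n_pairs)`` of pairwise decision values and the result is
    the unweighted mean of all pairwise two-class AUCs, each computed on
    the trials of its two classes only.  Chance is 0.5 regardless of the
    number of classes.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = np.unique(y)
    k = len(classes)
    if k < 2:
        raise ValueError("AUC undefined for a single class")
    if k == 2:
        s = scores[:, 0] if scores.ndim == 2 else scores
        pos = y == classes[0]
        if pos.all() or not pos.any():
            raise ValueError("AUC needs trials from both classes")
        return _pairwise_auc(s, pos)
    if scores.ndim != 2:
        raise ValueError("multiclass AUC needs (n_trials, n_pairs) scores")
    if pairs is None:
        from itertools import combinations

        pairs = list(combinations(range(k), 2))
    if scores.shape[1] != len(pairs):
        raise ValueError("scores second dimension must match class pairs")
    aucs = []
    for d, (a, b) in enumerate(pairs):
        mask = (y == classes[a]) | (y == classes[b])
        if not ((y[mask] == classes[a]).any() and (y[mask] == classes[b]).any()):
            raise ValueError("AUC needs trials from both classes of every pair")
        aucs.append(_pairwise_auc(scores[mask, d], y[mask] == classes[a]))
    return float(np.mean(aucs))


def score_balanced_accuracy(predicted: np.ndarray, y: np.ndarray) -> float:
    """Per-class correct fractions averaged across classes (insensitive to
    class frequency)."""
    predicted = np.asarray(predicted)
    y = np.asarray(y)
    if len(predicted) != len(y):
        raise ValueError("predictions and labels must have the same length")
    if len(y) == 0:
        raise ValueError("empty input")
    return float(balanced_accuracy_score(y, predicted))


def score_sdt(
    predicted: np.ndarray,
    y: np.ndarray,
    positive_class,
) -> tuple[float, float, float]:
    """Hit rate, false-alarm rate and d' for a two-class problem.

    ``dprime = z(hr) - z(far)``; extreme rates are clipped to
    ``1/(2N)`` and ``1 - 1/(2N)`` of their trial count before the inverse
    normal, so perfect performance yields a finite d'.
    """
    predicted = np.asarray(predicted)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("signal-detection measures are defined for 2 classes")
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not among labels")
    pos = y == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    hr = float(np.mean(predicted[pos] == positive_class))
    far = float(np.mean(predicted[~pos] == positive_class))
    hr_c = np.clip(hr, 1.0 / (2 * n_pos), 1.0 - 1.0 / (2 * n_pos))
    far_c = np.clip(far, 1.0 / (2 * n_neg), 1.0 - 1.0 / (2 * n_neg))
    dprime = float(norm.ppf(hr_c) - norm.ppf(far_c))
    return hr, far, dprime


def chance_level(metric: str, n_classes: int = 2) -> float:
    """Reference (chance) level used in group tests for each metric."""
    if metric == "auc":
        return 0.5
    if metric == "balanced_accuracy":
        return 1.0 / n_classes
    if metric in ("hr", "far"):
        return 0.5
    if metric == "dprime":
        return 0.0
    raise ValueError(f"unknown metric {metric!r}")
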