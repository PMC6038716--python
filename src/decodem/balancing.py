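"""Design balancing: within-class undersampling, between-class oversampling.

Unbalanced factorial designs bias linear decoders in two ways.  When event
types within a class are unequally frequent, the over-represented event can
dominate the class representation; this is corrected *before* analysis by
undersampling every event type down to a common multiple of its ratio
weight.  When whole classes are unequally sized, the classifier can exploit
base rates; this is corrected *inside each training fold* by synthesizing
minority-class trials with a boundary-weighted (ADASYN-style) interpolation
scheme, so that synthetic trials never reach a test fold or an ERP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .epochs import ClassSpec, EpochSet

__all__ = [
    "BalancePlan",
    "plan_within_class_balance",
    "undersample_trials",
    "BoundaryOversampler",
    "oversample_minority",
]


@dataclass
class BalancePlan:
    """Retained trial counts per class and event code after undersampling."""

    retained: list[dict[int, int]]
    units: list[int] = field(default_factory=list)  # m per class

    def total(self, class_idx: int) -> int:
        return sum(self.retained[class_idx].values())


def plan_within_class_balance(
    event_counts: list[dict[int, int]],
    ratios: list[dict[int, int]] | None = None,
) -> BalancePlan:
    """Compute per-event retained counts so events match their ratio weights.

    For each class the retained count of code ``c`` is ``m * ratio(c)`` with
    ``m`` the largest integer such that ``m * ratio(c) <= count(c)`` for
    every code in the class (so with unit ratios every event is cut to the
    minimum count).
    """
    plan: list[dict[int, int]] = []
    units: list[int] = []
    for ci, counts in enumerate(event_counts):
        r = ratios[ci] if ratios is not None else {c: 1 for c in counts}
        if any(n < 1 for n in counts.values()):
            raise ValueError("every event type needs at least one trial")
        m = min(counts[c] // r[c] for c in counts)
        if m < 1:
            short = [c for c in counts if counts[c] < r[c]]
            raise ValueError(
                f"event code(s) {short} have fewer trials than their ratio "
                "weight; cannot satisfy one balancing unit"
            )
        plan.append({c: m * r[c] for c in counts})
        units.append(m)
    return BalancePlan(retained=plan, units=units)


def undersample_trials(
    epochs: EpochSet,
    spec: ClassSpec,
    class_indices: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], BalancePlan]:
    """Apply within-class event balancing to already-selected trial indices.

    Returns per-class retained indices (uniformly subsampled without
    replacement per event code, order preserved) and the plan used.
    """
    event_counts = []
    ratios = []
    for cls, idx in zip(spec.classes, class_indices):
        codes = dict(cls)
        present = epochs.event_code[idx]
        event_counts.append({c: int(np.sum(present == c)) for c in codes})
        ratios.append({c: w for c, w in cls})
    plan = plan_within_class_balance(event_counts, ratios)
    kept: list[np.ndarray] = []
    for cls, idx, retained in zip(spec.classes, class_indices, plan.retained):
        keep_parts = []
        for code, _w in cls:
            code_idx = idx[epochs.event_code[idx] == code]
            n_keep = retained[code]
            if n_keep < len(code_idx):
                code_idx = rng.choice(code_idx, size=n_keep, replace=False)
            keep_parts.append(code_idx)
        kept.append(np.sort(np.concatenate(keep_parts)))
    return kept, plan


class BoundaryOversampler(BaseEstimator):
    """Boundary-weighted synthetic oversampling of minority classes.

    Variant of ADASYN (He et al., 2008): every class smaller than the
    largest class receives exactly ``majority_count - class_count``
    synthetic trials.  The per-trial synthesis budget is allocated
    proportionally to the fraction of *other-class* members among each
    minority trial's ``k_neighbors`` nearest neighbours in the full
    training set, so trials near the decision boundary spawn more
    synthetic instances.  Each synthetic trial is a convex combination
    ``x_i + u (x_nn - x_i)``, ``u ~ U(0, 1)``, of a minority trial and one
    of its ``k_neighbors`` nearest same-class neighbours.

    Parameters
    ----------
    k_neighbors : int
        Neighbourhood size for both the boundary weighting and the
        interpolation partner; silently reduced when a class has fewer
        members.
    random_state : int, Generator or None
        Source of randomness for budget remainders, partner choice and
        interpolation coefficients.
    """

    def __init__(self, k_neighbors: int = 5, random_state=None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X_aug, y_aug)`` with equal class counts.

        Original rows are passed through unmodified and come first; the
        synthetic rows follow, grouped by class.  Also sets
        ``sample_indicator_`` (bool, True for synthetic rows) and
        ``n_synthetic_`` (dict class -> count).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (trials x features)")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes to oversample")
        rng = np.random.default_rng(self.random_state)
        n_major = counts.max()
        new_X = [X]
        new_y = [y]
        self.n_synthetic_ = {}
        for cls, count in zip(classes, counts):
            deficit = int(n_major - count)
            self.n_synthetic_[cls] = deficit
            if deficit == 0:
                continue
            if count < 2:
                raise ValueError(
                    f"class {cls!r} has a single trial; cannot interpolate "
                    "synthetic neighbours"
                )
            idx = np.flatnonzero(y == cls)
            Xc = X[idx]
            k_boundary = min(self.k_neighbors, len(X) - 1)
            nn_all = NearestNeighbors(n_neighbors=k_boundary + 1).fit(X)
            _, neigh = nn_all.kneighbors(Xc)
            neigh = neigh[:, 1:]  # drop self
            other_frac = (y[neigh] != cls).mean(axis=1)
            budgets = _allocate_budget(other_frac, deficit)
            k_intra = min(self.k_neighbors, len(Xc) - 1)
            nn_cls = NearestNeighbors(n_neighbors=k_intra + 1).fit(Xc)
            _, neigh_c = nn_cls.kneighbors(Xc)
            neigh_c = neigh_c[:, 1:]
            synth = np.empty((deficit, X.shape[1]))
            row = 0
            for i, g in enumerate(budgets):
                for _ in range(g):
                    partner = neigh_c[i, rng.integers(k_intra)]
                    u = rng.uniform(0.0, 1.0)
                    synth[row] = Xc[i] + u * (Xc[partner] - Xc[i])
                    row += 1
            new_X.append(synth)
            new_y.append(np.full(deficit, cls, dtype=y.dtype))
        X_aug = np.concatenate(new_X, axis=0)
        y_aug = np.concatenate(new_y, axis=0)
        self.sample_indicator_ = np.zeros(len(X_aug), dtype=bool)
        self.sample_indicator_[len(X):] = True
        return X_aug, y_aug


def _allocate_budget(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights` (largest
    remainder; uniform when all weights vanish)."""
    weights = np.asarray(weights, dtype=float)
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    if weights.sum() <= 0:
        weights = np.ones(len(weights))
    share = weights / weights.sum() * total
    base = np.floor(share).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(share - base), kind="stable")
        base[order[:rem]] += 1
    return base


def oversample_minority(
    train_X: np.ndarray,
    train_y: np.ndarray,
    k_neighbors: int = 5,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper around :class:`BoundaryOversampler`."""
    return BoundaryOversampler(
        k_neighbors=k_neighbors, random_state=seed
    ).fit_resample(train_X, train_y)
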