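"""First-level backward decoding: per-time-point LDA under stratified
k-fold cross-validation, with diagonal or temporal-generalization scoring.

At every training time point the feature vector is the channel vector at
that single sample.  A classifier trained at time ``t`` is evaluated on the
held-out fold either at ``t`` only (diagonal decoding) or at every test
time ``t'`` (temporal generalization), yielding a train x test performance
matrix whose diagonal equals the diagonal-only run under the same seed.
Per-fold metrics are averaged with equal weight across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .balancing import BoundaryOversampler, undersample_trials
from .epochs import AnalysisConfig, ClassSpec, EpochSet
from .lda import ShrinkageLDA
from .metrics import score_auc, score_balanced_accuracy, score_sdt
from .preprocessing import apply_channelpool, baseline_correct, resample_epochs

__all__ = [
    "kfold_splits",
    "TemporalDecoder",
    "FirstLevelResult",
    "decode_first_level",
    "save_first_level",
    "load_first_level",
]


def kfold_splits(
    labels: np.ndarray, nfolds: int, seed=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of trials into train/test index pairs.

    Folds are disjoint, every trial is tested exactly once, and per-fold
    class proportions match the global proportions within one trial.  When
    ``nfolds`` exceeds the smallest class count the split degrades to
    leave-one-out (one fold per trial).  ``nfolds < 2`` is refused: train
    and test data would coincide.
    """
    labels = np.asarray(labels)
    if nfolds < 2:
        raise ValueError(
            "nfolds must be >= 2: training and testing on the same trials "
            "would overfit"
        )
    _, counts = np.unique(labels, return_counts=True)
    if nfolds > counts.min():
        # leave-one-out: each trial is its own test fold
        n = len(labels)
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    skf = StratifiedKFold(n_splits=nfolds, shuffle=True, random_state=_as_int_seed(seed))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _as_int_seed(seed) -> int | None:
    if seed is None or isinstance(seed, (int, np.integer)):
        return None if seed is None else int(seed)
    # a SeedSequence or Generator: derive a 31-bit int
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31))
    return int(np.random.default_rng(seed).integers(2**31))


def _predict_from_dv(dv: np.ndarray, classes: np.ndarray, pairs) -> np.ndarray:
    """Pairwise-vote class predictions from (n_trials, n_pairs) decision
    values (mirrors ShrinkageLDA.predict)."""
    k = len(classes)
    votes = np.zeros((len(dv), k))
    margins = np.zeros((len(dv), k))
    for d, (a, b) in enumerate(pairs):
        winner = np.where(dv[:, d] > 0, a, b)
        votes[np.arange(len(dv)), winner] += 1
        margins[:, a] += dv[:, d]
        margins[:, b] -= dv[:, d]
    best = votes + 1e-9 * np.tanh(margins)
    return classes[np.argmax(best, axis=1)]


def _score(metric: str, dv: np.ndarray, y, classes, pairs) -> float:
    if metric == "auc":
        return score_auc(dv, y, classes=classes, pairs=pairs)
    pred = _predict_from_dv(dv, classes, pairs)
    if metric == "balanced_accuracy":
        return score_balanced_accuracy(pred, y)
    hr, far, dprime = score_sdt(pred, y, positive_class=classes[0])
    return {"hr": hr, "far": far, "dprime": dprime}[metric]


class TemporalDecoder(BaseEstimator):
    """Time-resolved LDA decoder with cross-validation, sklearn-style.

    ``fit(X, y)`` runs the full cross-validated analysis on
    ``X`` of shape ``(n_trials, n_channels, n_times)`` and stores results in
    fitted attributes; pass ``X_test, y_test`` for the independent
    train/test mode (cross-validation is then skipped and ``nfolds``
    disregarded).

    Parameters
    ----------
    metric : {"auc", "balanced_accuracy", "dprime", "hr", "far"}
    nfolds : int
        Cross-validation folds; silently degrades to leave-one-out when it
        exceeds the smallest class count.
    crossclass : bool
        When True, every training time point is also tested at every other
        time point (temporal generalization).
    balance_classes : bool
        Boundary-weighted oversampling of minority classes inside each
        training fold.
    k_neighbors : int
        Neighbourhood size of the oversampler.
    shrinkage : "auto" or float
        Covariance shrinkage of the LDA (see :class:`ShrinkageLDA`).
    compute_patterns : bool
        Also store Haufe-transformed activation patterns (first
        discriminant), computed from the training-fold data covariance.
    random_state : int or None

    Attributes
    ----------
    scores_ : ndarray, (n_times,) or (n_times, n_times)
        Metric averaged over folds; rows are training times.
    weights_ : ndarray (n_channels, n_times)
        First-discriminant classifier weights, fold-averaged.
    patterns_ : ndarray (n_channels, n_times) or None
    classes_ : ndarray
    fold_scores_ : ndarray, (n_folds,) + scores_.shape
    """

    def __init__(
        self,
        metric: str = "auc",
        nfolds: int = 5,
        crossclass: bool = False,
        balance_classes: bool = True,
        k_neighbors: int = 5,
        shrinkage: str | float = "auto",
        compute_patterns: bool = True,
        random_state=None,
    ):
        self.metric = metric
        self.nfolds = nfolds
        self.crossclass = crossclass
        self.balance_classes = balance_classes
        self.k_neighbors = k_neighbors
        self.shrinkage = shrinkage
        self.compute_patterns = compute_patterns
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, X_test=None, y_test=None) -> "TemporalDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (trials, channels, times)")
        if (X_test is None) != (y_test is None):
            raise ValueError("provide both X_test and y_test or neither")
        ss = np.random.SeedSequence(self.random_state)
        ss_folds, ss_over = ss.spawn(2)
        if X_test is not None:
            X_test = np.asarray(X_test, dtype=float)
            y_test = np.asarray(y_test)
            if X_test.shape[1:] != X.shape[1:]:
                raise ValueError("train and test data shapes disagree")
            splits = [("independent", (X, y, X_test, y_test))]
        else:
            folds = kfold_splits(y, self.nfolds, seed=ss_folds)
            splits = [
                (fi, (X[tr], y[tr], X[te], y[te]))
                for fi, (tr, te) in enumerate(folds)
            ]
        over_children = ss_over.spawn(len(splits))
        classes = np.unique(y)
        n_ch, n_times = X.shape[1], X.shape[2]
        fold_scores = []
        weights_acc = np.zeros((n_ch, n_times))
        patterns_acc = np.zeros((n_ch, n_times)) if self.compute_patterns else None
        for (tag, (Xtr, ytr, Xte, yte)), child in zip(splits, over_children):
            counts = np.bincount(np.searchsorted(classes, ytr))
            if self.balance_classes and counts.min() != counts.max():
                flat = Xtr.reshape(len(Xtr), -1)
                os = BoundaryOversampler(
                    k_neighbors=self.k_neighbors,
                    random_state=np.random.default_rng(child),
                )
                flat_aug, ytr = os.fit_resample(flat, ytr)
                Xtr = flat_aug.reshape(len(flat_aug), n_ch, n_times)
            sc, w, pat = self._run_fold(Xtr, ytr, Xte, yte, classes)
            fold_scores.append(sc)
            weights_acc += w
            if patterns_acc is not None:
                patterns_acc += pat
        self.classes_ = classes
        self.fold_scores_ = np.stack(fold_scores)
        self.scores_ = self.fold_scores_.mean(axis=0)
        self.weights_ = weights_acc / len(splits)
        self.patterns_ = (
            None if patterns_acc is None else patterns_acc / len(splits)
        )
        self.n_folds_ = len(splits)
        return self

    # ------------------------------------------------------------------
    def _run_fold(self, Xtr, ytr, Xte, yte, classes):
        n_ch, n_times = Xtr.shape[1], Xtr.shape[2]
        model0 = ShrinkageLDA(shrinkage=self.shrinkage)
        if self.crossclass:
            scores = np.empty((n_times, n_times))
        else:
            scores = np.empty(n_times)
        weights = np.empty((n_ch, n_times))
        patterns = np.empty((n_ch, n_times)) if self.compute_patterns else None
        for t in range(n_times):
            model = ShrinkageLDA(shrinkage=self.shrinkage).fit(Xtr[:, :, t], ytr)
            W, b, pairs = model.weights_, model.biases_, model.pairs_
            weights[:, t] = W[0]
            if self.compute_patterns:
                Xt = Xtr[:, :, t]
                Xc = Xt - Xt.mean(axis=0)
                cov = Xc.T @ Xc / max(len(Xt) - 1, 1)
                patterns[:, t] = cov @ W[0]
            if self.crossclass:
                # dv[n, d, t'] for the model trained at t
                dv_all = np.einsum("npt,dp->ndt", Xte, W) + b[None, :, None]
                for t2 in range(n_times):
                    scores[t, t2] = _score(
                        self.metric, dv_all[:, :, t2], yte, classes, pairs
                    )
            else:
                dv = Xte[:, :, t] @ W.T + b
                scores[t] = _score(self.metric, dv, yte, classes, pairs)
        return scores, weights, patterns


# ---------------------------------------------------------------------------
# First-level result container
# ---------------------------------------------------------------------------

@dataclass
class FirstLevelResult:
    """Per-subject decoding output with full settings provenance."""

    metric_name: str
    performance: np.ndarray  # (n_times,) or (n_train_times, n_test_times)
    times_ms: np.ndarray
    class_erps: np.ndarray  # (n_classes, n_channels, n_times)
    weights: np.ndarray  # (n_channels, n_times)
    patterns: np.ndarray | None
    channels: list[str]
    positions: np.ndarray | None
    subject_id: str
    n_classes: int
    settings: dict = field(default_factory=dict)

    @property
    def crossclass(self) -> bool:
        return self.performance.ndim == 2


def save_first_level(result: FirstLevelResult, path: str | Path) -> Path:
    """Serialize a FirstLevelResult to a ``.flr`` file (NumPy archive with a
    JSON settings record)."""
    path = Path(path)
    if path.suffix != ".flr":
        path = path.with_suffix(".flr")
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(
        schema=np.array(["decodem-flr-1"]),
        metric_name=np.array([result.metric_name]),
        performance=result.performance,
        times_ms=result.times_ms,
        class_erps=result.class_erps,
        weights=result.weights,
        channels=np.array(result.channels),
        subject_id=np.array([result.subject_id]),
        n_classes=np.array([result.n_classes]),
        settings_json=np.array([json.dumps(result.settings)]),
    )
    if result.patterns is not None:
        payload["patterns"] = result.patterns
    if result.positions is not None:
        payload["positions"] = result.positions
    with open(path, "wb") as fh:
        np.savez(fh, **payload)
    return path


def load_first_level(path: str | Path) -> FirstLevelResult:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        return FirstLevelResult(
            metric_name=str(z["metric_name"][0]),
            performance=z["performance"],
            times_ms=z["times_ms"],
            class_erps=z["class_erps"],
            weights=z["weights"],
            patterns=z["patterns"] if "patterns" in z else None,
            channels=[str(c) for c in z["channels"]],
            positions=z["positions"] if "positions" in z else None,
            subject_id=str(z["subject_id"][0]),
            n_classes=int(z["n_classes"][0]),
            settings=json.loads(str(z["settings_json"][0])),
        )


# ---------------------------------------------------------------------------
# First-level driver
# ---------------------------------------------------------------------------

def decode_first_level(
    epochs: EpochSet,
    spec: ClassSpec,
    cfg: AnalysisConfig,
    test_epochs: EpochSet | None = None,
) -> FirstLevelResult:
    """Run the complete single-subject analysis.

    Pipeline: trial selection -> within-class event balancing ->
    preprocessing (channel pool, resampling, baseline) -> stratified folds
    -> per-fold between-class oversampling of the training set -> per
    train time point LDA -> metric averaged over folds.  Class ERPs are
    the per-class trial means over the balanced (undersampled, never
    oversampled) trials after preprocessing.

    When ``test_epochs`` is given, or the spec defines distinct train/test
    classes, training and testing use independent trials and ``nfolds`` is
    disregarded.
    """
    if spec.n_classes < 2:
        raise ValueError("decoding needs at least two classes")
    cfg.validate_against(epochs)
    ss = np.random.SeedSequence(cfg.seed)
    ss_under, ss_decoder = ss.spawn(2)
    rng_under = np.random.default_rng(ss_under)

    separate = test_epochs is not None or (
        spec.train_classes is not None or spec.test_classes is not None
    )

    def prepare(ep: EpochSet, which: str):
        from .epochs import select_trials

        idx = select_trials(ep, spec, which=which)
        if cfg.balance_events:
            idx, _plan = undersample_trials(ep, spec, idx, rng_under)
        ep = apply_channelpool(ep, cfg.channelpool)
        if cfg.resample_to is not None:
            ep = resample_epochs(ep, cfg.resample_to)
        if cfg.erp_baseline is not None:
            ep = baseline_correct(ep, cfg.erp_baseline)
        X = np.concatenate([ep.data[i] for i in idx], axis=0)
        y = np.concatenate(
            [np.full(len(i), ci) for ci, i in enumerate(idx)]
        )
        return ep, X, y, idx

    decoder = TemporalDecoder(
        metric=cfg.metric,
        nfolds=cfg.nfolds,
        crossclass=cfg.crossclass,
        balance_classes=cfg.balance_classes,
        k_neighbors=cfg.k_neighbors,
        shrinkage=cfg.shrinkage,
        random_state=_as_int_seed(ss_decoder),
    )

    if separate:
        ep_train, X, y, _ = prepare(epochs, "train")
        test_source = test_epochs if test_epochs is not None else epochs
        ep_used, X_te, y_te, idx_te = prepare(test_source, "test")
        if test_epochs is None:
            # same recordings for train and test demands disjoint trials
            tr_idx = set(np.concatenate(_sel_for(epochs, spec, "train")))
            te_idx = set(np.concatenate(_sel_for(epochs, spec, "test")))
            if tr_idx & te_idx:
                raise ValueError(
                    "train and test class definitions share trials; use "
                    "cross-validation instead"
                )
        decoder.fit(X, y, X_test=X_te, y_test=y_te)
        erp_ep, erp_idx = ep_used, idx_te
    else:
        ep_used, X, y, idx = prepare(epochs, "classes")
        decoder.fit(X, y)
        erp_ep, erp_idx = ep_used, idx

    class_erps = np.stack(
        [erp_ep.data[i].mean(axis=0) for i in erp_idx]
    )
    settings = dict(
        nfolds=cfg.nfolds,
        crossclass=cfg.crossclass,
        metric=cfg.metric,
        channelpool=cfg.channelpool
        if isinstance(cfg.channelpool, str)
        else list(cfg.channelpool),
        resample_to=cfg.resample_to,
        erp_baseline=list(cfg.erp_baseline) if cfg.erp_baseline else None,
        balance_events=cfg.balance_events,
        balance_classes=cfg.balance_classes,
        k_neighbors=cfg.k_neighbors,
        seed=cfg.seed,
        class_names=spec.class_names(),
        n_folds_used=decoder.n_folds_,
    )
    return FirstLevelResult(
        metric_name=cfg.metric,
        performance=decoder.scores_,
        times_ms=erp_ep.times.copy(),
        class_erps=class_erps,
        weights=decoder.weights_,
        patterns=decoder.patterns_,
        channels=list(erp_ep.channels),
        positions=None if erp_ep.positions is None else erp_ep.positions.copy(),
        subject_id=epochs.subject_id,
        n_classes=spec.n_classes,
        settings=settings,
    )


def _sel_for(epochs, spec, which):
    from .epochs import select_trials

    return select_trials(epochs, spec, which=which)
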