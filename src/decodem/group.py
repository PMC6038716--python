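"""Group-level inference on first-level decoding and ERP results.

Per-sample one-sample t-tests compare the subject ensemble against a
reference level (0.5 chance for AUC, 0 for d' or an ERP difference).
Multiple comparisons are controlled either by cluster-based permutation
(Maris & Oostenveld 2007: clusters of contiguously supra-threshold t-values
scored by their summed t "mass" against a max-mass null built from
per-subject random sign flips of metric - reference) or by
Benjamini-Yekutieli FDR, valid under dependency.  Each significant cluster
is recorded with its permutation p (reported as the bound ``1/n_iter`` when
no null mass reached it), size, data size and start/stop/peak times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .decoding import FirstLevelResult, load_first_level
from .metrics import chance_level

__all__ = [
    "GroupConfig",
    "ClusterRecord",
    "GroupStats",
    "save_group_stats",
    "load_group_stats",
    "reduce_dims",
    "ttest_vs_reference",
    "cluster_permutation",
    "fdr_correct",
    "electrode_adjacency",
    "compute_group_mvpa",
    "compute_group_erp",
    "compare_stats",
]


# ---------------------------------------------------------------------------
# Configuration and result records
# ---------------------------------------------------------------------------

@dataclass
class GroupConfig:
    """Settings for group statistics (keys mirror the cookbook cfg)."""

    mpcompcor_method: str = "cluster_based"  # cluster_based|fdr|uncorrected|none
    iterations: int = 1000
    cluster_alpha: float = 0.05  # cluster-forming sample threshold (two-tailed)
    alpha: float = 0.05  # cluster / FDR significance level
    tails: int = 2
    reduce_dims: str | None = None  # diag | avtrain | avtest | None
    trainlim: tuple[float, float] | None = None
    testlim: tuple[float, float] | None = None
    reference: float | None = None  # None -> metric-specific chance level
    electrode_def: list[str] | None = None
    condition_method: str = "none"  # none | subtract
    seed: int | None = None

    def __post_init__(self) -> None:
        valid = ("cluster_based", "fdr", "uncorrected", "none")
        if self.mpcompcor_method not in valid:
            raise ValueError(f"mpcompcor_method must be one of {valid}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


@dataclass
class ClusterRecord:
    """One significant cluster from the permutation test."""

    clusterpval: float
    p_is_bound: bool
    clustersize: int
    datasize: int
    start_time: float | None = None
    stop_time: float | None = None
    peak_time: float | None = None
    channels: list[str] | None = None
    indices: np.ndarray | None = None
    mass: float = 0.0

    @property
    def pvalue_label(self) -> str:
        if self.p_is_bound:
            return f"p < {self.clusterpval:g}"
        return f"p = {self.clusterpval:g}"


@dataclass
class GroupStats:
    """Outcome of one group analysis."""

    condname: str
    mean: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    sig_mask: np.ndarray
    clusters: dict = field(
        default_factory=lambda: {"posclusters": [], "negclusters": []}
    )
    reduction: str | None = None
    n_subjects: int = 0
    correction: str = "none"
    times: np.ndarray | None = None  # axis of the reduced dimension (test)
    train_times: np.ndarray | None = None  # rows for unreduced matrices
    subject_values: np.ndarray | None = None  # (n_subjects, ...) reduced
    reference: float = 0.0
    metric_name: str = ""
    channels: list[str] | None = None
    positions: np.ndarray | None = None

    @property
    def pStruct(self) -> dict:
        return self.clusters


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_group_stats(stats: GroupStats, path: str | Path) -> Path:
    """Write a GroupStats to ``<path>.gst`` (NumPy archive; cluster records
    and scalars carried as a JSON sidecar key)."""
    path = Path(path)
    if path.suffix != ".gst":
        path = path.with_suffix(".gst")
    path.parent.mkdir(parents=True, exist_ok=True)

    def rec_dict(r: ClusterRecord) -> dict:
        return dict(
            clusterpval=r.clusterpval,
            p_is_bound=r.p_is_bound,
            clustersize=r.clustersize,
            datasize=r.datasize,
            start_time=r.start_time,
            stop_time=r.stop_time,
            peak_time=r.peak_time,
            channels=r.channels,
            indices=None if r.indices is None else r.indices.tolist(),
            mass=r.mass,
        )

    meta = dict(
        condname=stats.condname,
        reduction=stats.reduction,
        n_subjects=stats.n_subjects,
        correction=stats.correction,
        reference=stats.reference,
        metric_name=stats.metric_name,
        channels=stats.channels,
        posclusters=[rec_dict(r) for r in stats.clusters["posclusters"]],
        negclusters=[rec_dict(r) for r in stats.clusters["negclusters"]],
    )
    payload = dict(
        mean=stats.mean,
        tvals=stats.tvals,
        pvals=stats.pvals,
        sig_mask=stats.sig_mask,
        meta_json=np.array([json.dumps(meta)]),
    )
    if stats.times is not None:
        payload["times"] = stats.times
    if stats.train_times is not None:
        payload["train_times"] = stats.train_times
    if stats.subject_values is not None:
        payload["subject_values"] = stats.subject_values
    if stats.positions is not None:
        payload["positions"] = stats.positions
    with open(path, "wb") as fh:
        np.savez(fh, **payload)
    return path


def load_group_stats(path: str | Path) -> GroupStats:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"][0]))

        def rec(d: dict) -> ClusterRecord:
            return ClusterRecord(
                clusterpval=d["clusterpval"],
                p_is_bound=d["p_is_bound"],
                clustersize=d["clustersize"],
                datasize=d["datasize"],
                start_time=d["start_time"],
                stop_time=d["stop_time"],
                peak_time=d["peak_time"],
                channels=d["channels"],
                indices=None if d["indices"] is None else np.asarray(d["indices"]),
                mass=d["mass"],
            )

        return GroupStats(
            condname=meta["condname"],
            mean=z["mean"],
            tvals=z["tvals"],
            pvals=z["pvals"],
            sig_mask=z["sig_mask"].astype(bool),
            clusters={
                "posclusters": [rec(d) for d in meta["posclusters"]],
                "negclusters": [rec(d) for d in meta["negclusters"]],
            },
            reduction=meta["reduction"],
            n_subjects=meta["n_subjects"],
            correction=meta["correction"],
            times=z["times"] if "times" in z else None,
            train_times=z["train_times"] if "train_times" in z else None,
            subject_values=z["subject_values"] if "subject_values" in z else None,
            reference=meta["reference"],
            metric_name=meta["metric_name"],
            channels=meta["channels"],
            positions=z["positions"] if "positions" in z else None,
        )


# ---------------------------------------------------------------------------
# Dimension reduction
# ---------------------------------------------------------------------------

def _window_mask(times: np.ndarray, lim) -> np.ndarray:
    if lim is None:
        return np.ones(len(times), dtype=bool)
    lo, hi = lim
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] ms contains no samples")
    return mask


def reduce_dims(
    performance: np.ndarray,
    mode: str | None,
    train_times: np.ndarray,
    test_times: np.ndarray,
    trainlim=None,
    testlim=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce per-subject train x test matrices to vectors.

    ``performance`` is ``(n_subjects, n_train, n_test)``; limits are
    applied before averaging.  Returns ``(values, axis_times)`` where
    values is ``(n_subjects, n)``.

    Modes: ``diag`` extracts the train==test diagonal; ``avtrain``
    averages over training rows inside ``trainlim`` yielding a test-time
    series; ``avtest`` is symmetric; ``None`` leaves the (windowed) matrix.
    """
    perf = np.asarray(performance, dtype=float)
    if perf.ndim == 2:  # already diagonal-only first levels
        mask = _window_mask(test_times, testlim)
        return perf[:, mask], test_times[mask]
    tr_mask = _window_mask(train_times, trainlim)
    te_mask = _window_mask(test_times, testlim)
    perf = perf[:, tr_mask][:, :, te_mask]
    if mode is None or mode == "none":
        return perf, test_times[te_mask]
    if mode == "diag":
        if perf.shape[1] != perf.shape[2]:
            raise ValueError("diag reduction needs a square train x test matrix")
        return np.diagonal(perf, axis1=1, axis2=2).copy(), test_times[te_mask]
    if mode == "avtrain":
        return perf.mean(axis=1), test_times[te_mask]
    if mode == "avtest":
        return perf.mean(axis=2), train_times[tr_mask]
    raise ValueError(f"unknown reduce_dims mode {mode!r}")


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def ttest_vs_reference(
    values: np.ndarray, reference: float, tails: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample one-sample t-test of ``values - reference`` against zero.

    Degenerate zero-variance samples yield ``t = 0, p = 1`` when the mean
    equals the reference and ``t = +/-inf, p = 0`` otherwise.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("group tests need at least 2 subjects")
    d = values - reference
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    sem = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            sem > 0,
            mean / np.where(sem > 0, sem, 1.0),
            np.where(mean == 0, 0.0, np.sign(mean) * np.inf),
        )
    df = n - 1
    p = t_dist.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    if tails == 2:
        p = np.minimum(2 * p, 1.0)
    return t, p


# ---------------------------------------------------------------------------
# Cluster machinery
# ---------------------------------------------------------------------------

def _find_clusters(mask: np.ndarray, adjacency) -> list[np.ndarray]:
    """Connected components of a boolean mask; returns flat index arrays."""
    if isinstance(adjacency, str) and adjacency == "chain":
        m = mask.ravel()
        edges = np.diff(np.concatenate(([0], m.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        return [np.arange(a, b) for a, b in zip(starts, stops)]
    if isinstance(adjacency, str) and adjacency == "lattice":
        labels, n = ndimage.label(mask)
        return [
            np.flatnonzero(labels.ravel() == i) for i in range(1, n + 1)
        ]
    # sparse adjacency graph over flattened samples (electrode clusters)
    adj = sparse.csr_matrix(adjacency)
    idx = np.flatnonzero(mask.ravel())
    if len(idx) == 0:
        return []
    sub = adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == i] for i in range(n_comp)]


def _max_run_masses(mask: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Per-row maximal contiguous-run mass, fully vectorized.

    mask, vals: (n_rows, n_samples); returns (n_rows,) of the largest sum
    of vals over contiguous True runs in each row (0 when none).
    """
    n_rows, n = mask.shape
    padded = np.zeros((n_rows, n + 1), dtype=np.int8)
    padded[:, :n] = mask
    flat_mask = padded.ravel()
    padded_vals = np.zeros((n_rows, n + 1))
    padded_vals[:, :n] = np.where(mask, vals, 0.0)
    flat_vals = padded_vals.ravel()
    edges = np.diff(np.concatenate(([0], flat_mask, [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    out = np.zeros(n_rows)
    if len(starts) == 0:
        return out
    cs = np.concatenate(([0.0], np.cumsum(flat_vals)))
    masses = cs[stops] - cs[starts]
    rows = starts // (n + 1)
    np.maximum.at(out, rows, masses)
    return out


def _perm_t(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-values for every sign-flip permutation, vectorized.

    d: (n_subjects, n_samples); signs: (n_iter, n_subjects).
    Uses E[x^2] invariance under sign flips.
    """
    n = d.shape[0]
    mean = signs @ d / n
    msq = (d**2).mean(axis=0)
    var = (msq[None, :] - mean**2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def cluster_permutation(
    values: np.ndarray,
    reference: float,
    n_iter: int = 1000,
    cluster_alpha: float = 0.05,
    tails: int = 2,
    adjacency="chain",
    alpha: float = 0.05,
    seed=None,
    times: np.ndarray | None = None,
    channels: list[str] | None = None,
) -> tuple[list[ClusterRecord], list[ClusterRecord], np.ndarray]:
    """Cluster-based permutation test of subject values against a reference.

    Observed clusters are contiguous samples whose one-sample t-test falls
    below ``cluster_alpha`` (two-tailed, positive and negative tails
    separately); each cluster is scored by its summed t.  The null
    distribution collects, per random per-subject sign flip of
    ``values - reference``, the maximal cluster mass of that tail.  A
    cluster's p is the fraction of null masses at least as large; when that
    count is zero the p is reported as the bound ``1/n_iter``
    (``p_is_bound``).  ``sig_mask`` marks members of clusters with p below
    ``alpha``.

    ``adjacency``: "chain" for a time axis, "lattice" for a train x test
    matrix (4-connectivity), or a sparse channel adjacency for electrode
    clusters.
    """
    values = np.asarray(values, dtype=float)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n_sub = values.shape[0]
    if n_sub < 2:
        raise ValueError("cluster test needs at least 2 subjects")
    shape = values.shape[1:]
    d = (values - reference).reshape(n_sub, -1)
    t_obs, _ = ttest_vs_reference(values.reshape(n_sub, -1), reference)
    df = n_sub - 1
    if tails == 2:
        t_crit = t_dist.ppf(1 - cluster_alpha / 2, df)
    else:
        t_crit = t_dist.ppf(1 - cluster_alpha, df)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iter, n_sub))
    t_perm = _perm_t(d, signs)

    chain = isinstance(adjacency, str) and adjacency == "chain"
    if chain:
        null_pos = _max_run_masses(t_perm > t_crit, t_perm)
        null_neg = _max_run_masses(t_perm < -t_crit, -t_perm)
    else:
        null_pos = np.zeros(n_iter)
        null_neg = np.zeros(n_iter)
        for i in range(n_iter):
            tp = t_perm[i].reshape(shape)
            for clu in _find_clusters(tp > t_crit, adjacency):
                null_pos[i] = max(null_pos[i], tp.ravel()[clu].sum())
            for clu in _find_clusters(tp < -t_crit, adjacency):
                null_neg[i] = max(null_neg[i], -tp.ravel()[clu].sum())
    if tails == 2:
        # two-sided control: both tails are referred to the null of the
        # maximal cluster mass over either sign, keeping the family-wise
        # error of the whole two-sided test at alpha
        null_pos = null_neg = np.maximum(null_pos, null_neg)

    group_mean = d.mean(axis=0)
    sig_mask = np.zeros(d.shape[1], dtype=bool)

    def make_records(mask_flat, sign, null):
        t2 = t_obs.reshape(shape)
        clusters = _find_clusters((mask_flat).reshape(shape), adjacency)
        records = []
        for clu in clusters:
            mass = sign * t_obs[clu].sum()
            count = int(np.sum(null >= mass))
            if count == 0:
                pval, bound = 1.0 / n_iter, True
            else:
                pval, bound = count / n_iter, False
            rec = ClusterRecord(
                clusterpval=pval,
                p_is_bound=bound,
                clustersize=len(clu),
                datasize=d.shape[1],
                indices=clu,
                mass=mass,
            )
            peak = clu[np.argmax(np.abs(group_mean[clu]))]
            if times is not None and len(shape) == 1:
                rec.start_time = float(times[clu.min()])
                rec.stop_time = float(times[clu.max()])
                rec.peak_time = float(times[peak])
            elif times is not None and len(shape) == 2:
                # report bounds/peak on the test (second) axis
                cols = np.unique(clu % shape[1])
                rec.start_time = float(times[cols.min()])
                rec.stop_time = float(times[cols.max()])
                rec.peak_time = float(times[peak % shape[1]])
            if channels is not None:
                rec.channels = [channels[i] for i in clu]
            if pval < alpha:
                sig_mask[clu] = True
            records.append(rec)
        records.sort(key=lambda r: (r.clusterpval, -abs(r.mass)))
        return records

    pos_records = make_records(t_obs > t_crit, +1.0, null_pos)
    neg_records = (
        make_records(t_obs < -t_crit, -1.0, null_neg) if tails == 2 else []
    )
    return pos_records, neg_records, sig_mask.reshape(shape)


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR control (valid under dependency)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    mask, *_ = multipletests(p.ravel(), alpha=q, method="fdr_by")
    return mask.reshape(p.shape)


def electrode_adjacency(
    positions: np.ndarray, scale: float = 1.5
) -> sparse.csr_matrix:
    """Neighbour graph over sensors from 2-D layout positions.

    Two sensors are adjacent when their distance is below ``scale`` times
    the median nearest-neighbour distance.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    thresh = scale * np.median(dist.min(axis=1))
    adj = dist < thresh
    return sparse.csr_matrix(adj)


# ---------------------------------------------------------------------------
# High-level drivers
# ---------------------------------------------------------------------------

def _apply_correction(
    subject_values: np.ndarray,
    reference: float,
    cfg: GroupConfig,
    adjacency="chain",
    times=None,
    channels=None,
):
    tvals, pvals = ttest_vs_reference(subject_values, reference, tails=cfg.tails)
    clusters = {"posclusters": [], "negclusters": []}
    if cfg.mpcompcor_method == "cluster_based":
        pos, neg, sig = cluster_permutation(
            subject_values,
            reference,
            n_iter=cfg.iterations,
            cluster_alpha=cfg.cluster_alpha,
            tails=cfg.tails,
            adjacency=adjacency,
            alpha=cfg.alpha,
            seed=cfg.seed,
            times=times,
            channels=channels,
        )
        clusters = {"posclusters": pos, "negclusters": neg}
    elif cfg.mpcompcor_method == "fdr":
        sig = fdr_correct(pvals, q=cfg.alpha)
    elif cfg.mpcompcor_method == "uncorrected":
        sig = pvals < cfg.alpha
    else:  # "none"
        sig = np.zeros_like(pvals, dtype=bool)
    return tvals, pvals, sig, clusters


def _load_results(source) -> list[FirstLevelResult]:
    if isinstance(source, (list, tuple)):
        return list(source)
    raise TypeError("expected a list of FirstLevelResult or a directory path")


def _find_analyses(root: Path) -> list[tuple[str, list[Path]]]:
    """Locate analysis folders below `root`.

    A "leaf" is any directory directly containing ``.flr`` files (by the
    results-tree convention this is a channel-pool folder); the analysis
    name is the leaf's parent folder, or the root itself when flat.
    """
    root = Path(root)
    leaves = sorted(
        {p.parent for p in root.rglob("*.flr")}, key=lambda p: str(p)
    )
    if not leaves:
        raise FileNotFoundError(f"no first-level (.flr) files under {root}")
    out = []
    for leaf in leaves:
        if leaf == root:
            name = root.name
        elif leaf.parent == root:
            name = root.name
        else:
            name = leaf.parent.name
        out.append((name, sorted(leaf.glob("*.flr"))))
    return out


def _stack_results(results: list[FirstLevelResult], condname: str):
    times = results[0].times_ms
    for r in results[1:]:
        if r.performance.shape != results[0].performance.shape or not np.allclose(
            r.times_ms, times
        ):
            raise ValueError(
                f"subject {r.subject_id!r} has mismatching shape or time axis"
            )
    return np.stack([r.performance for r in results]), times


def compute_group_mvpa(
    source, cfg: GroupConfig | None = None
) -> GroupStats | list[GroupStats]:
    """Group statistics on first-level decoding results.

    ``source`` may be a list of :class:`FirstLevelResult`, a directory of
    one analysis, or a directory containing several analyses (a list of
    GroupStats, one per analysis folder, is then returned).
    """
    cfg = cfg or GroupConfig()
    if isinstance(source, (str, Path)):
        analyses = _find_analyses(Path(source))
        stats = [
            _group_mvpa_one([load_first_level(f) for f in files], name, cfg)
            for name, files in analyses
        ]
        return stats[0] if len(stats) == 1 else stats
    return _group_mvpa_one(_load_results(source), "", cfg)


def _group_mvpa_one(
    results: list[FirstLevelResult], condname: str, cfg: GroupConfig
) -> GroupStats:
    if len(results) < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    perf, times = _stack_results(results, condname)
    metric = results[0].metric_name
    reference = (
        cfg.reference
        if cfg.reference is not None
        else chance_level(metric, results[0].n_classes)
    )
    if perf.ndim == 3:
        values, axis_times = reduce_dims(
            perf, cfg.reduce_dims, times, times, cfg.trainlim, cfg.testlim
        )
    else:
        mask = _window_mask(times, cfg.testlim)
        values, axis_times = perf[:, mask], times[mask]
    adjacency = "lattice" if values.ndim == 3 else "chain"
    tvals, pvals, sig, clusters = _apply_correction(
        values,
        reference,
        cfg,
        adjacency=adjacency,
        times=axis_times,
    )
    return GroupStats(
        condname=condname,
        mean=values.mean(axis=0),
        tvals=tvals.reshape(values.shape[1:]),
        pvals=pvals.reshape(values.shape[1:]),
        sig_mask=np.asarray(sig).reshape(values.shape[1:]),
        clusters=clusters,
        reduction=cfg.reduce_dims,
        n_subjects=len(results),
        correction=cfg.mpcompcor_method,
        times=axis_times,
        train_times=times if values.ndim == 3 else None,
        subject_values=values,
        reference=reference,
        metric_name=metric,
        channels=list(results[0].channels),
        positions=results[0].positions,
    )


def compute_group_erp(
    source, cfg: GroupConfig
) -> GroupStats | list[GroupStats]:
    """Group statistics on class ERPs averaged over ``cfg.electrode_def``.

    ``condition_method='subtract'`` tests class1 - class2 against zero and
    returns a single GroupStats; otherwise each class ERP is tested against
    zero and a list (one per class) is returned.
    """
    if isinstance(source, (str, Path)):
        analyses = _find_analyses(Path(source))
        if len(analyses) != 1:
            out = []
            for name, files in analyses:
                res = [load_first_level(f) for f in files]
                got = _group_erp_one(res, name, cfg)
                out.extend(got if isinstance(got, list) else [got])
            return out
        name, files = analyses[0]
        results = [load_first_level(f) for f in files]
    else:
        results = _load_results(source)
        name = ""
    return _group_erp_one(results, name, cfg)


def _group_erp_one(results, condname, cfg):
    if len(results) < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    if cfg.electrode_def is None:
        raise ValueError("cfg.electrode_def must name the ERP electrode(s)")
    channels = results[0].channels
    missing = [ch for ch in cfg.electrode_def if ch not in channels]
    if missing:
        raise ValueError(f"electrode(s) {missing} not present in the data")
    sel = [channels.index(ch) for ch in cfg.electrode_def]
    times = results[0].times_ms
    # (n_subjects, n_classes, n_times)
    erps = np.stack([r.class_erps[:, sel, :].mean(axis=1) for r in results])
    mask = _window_mask(times, cfg.testlim)
    erps, axis_times = erps[:, :, mask], times[mask]
    names = results[0].settings.get("class_names")

    def build(values, label):
        tvals, pvals, sig, clusters = _apply_correction(
            values, 0.0, cfg, adjacency="chain", times=axis_times
        )
        return GroupStats(
            condname=label,
            mean=values.mean(axis=0),
            tvals=tvals,
            pvals=pvals,
            sig_mask=sig,
            clusters=clusters,
            n_subjects=len(results),
            correction=cfg.mpcompcor_method,
            times=axis_times,
            subject_values=values,
            reference=0.0,
            metric_name="uV",
            channels=channels,
            positions=results[0].positions,
        )

    if cfg.condition_method == "subtract":
        if erps.shape[1] < 2:
            raise ValueError("subtract needs at least two classes")
        diff = erps[:, 0] - erps[:, 1]
        return build(diff, f"{condname} (subtraction)")
    labels = names or [f"class{i + 1}" for i in range(erps.shape[1])]
    return [
        build(erps[:, ci], f"{condname} {labels[ci]}")
        for ci in range(erps.shape[1])
    ]


def compare_stats(
    stats_a: GroupStats | np.ndarray,
    stats_b: GroupStats | np.ndarray,
    cfg: GroupConfig | None = None,
) -> GroupStats:
    """Paired per-sample comparison of two analyses (positive = A > B).

    Both inputs must carry per-subject values for the same subjects on the
    same reduced axis; per-subject differences A - B are tested against 0
    with the same correction machinery (permutation = random A/B swap per
    subject, i.e. a sign flip of the difference).
    """
    cfg = cfg or GroupConfig()
    va = stats_a.subject_values if isinstance(stats_a, GroupStats) else np.asarray(stats_a)
    vb = stats_b.subject_values if isinstance(stats_b, GroupStats) else np.asarray(stats_b)
    if va is None or vb is None:
        raise ValueError("inputs must carry per-subject values")
    if va.shape != vb.shape:
        raise ValueError(
            f"subject sets or shapes differ: {va.shape} vs {vb.shape}"
        )
    diff = va - vb
    times = stats_a.times if isinstance(stats_a, GroupStats) else None
    adjacency = "lattice" if diff.ndim == 3 else "chain"
    tvals, pvals, sig, clusters = _apply_correction(
        diff, 0.0, cfg, adjacency=adjacency, times=times
    )
    name_a = stats_a.condname if isinstance(stats_a, GroupStats) else "A"
    name_b = stats_b.condname if isinstance(stats_b, GroupStats) else "B"
    return GroupStats(
        condname=f"{name_a} - {name_b}",
        mean=diff.mean(axis=0),
        tvals=tvals.reshape(diff.shape[1:]),
        pvals=pvals.reshape(diff.shape[1:]),
        sig_mask=np.asarray(sig).reshape(diff.shape[1:]),
        clusters=clusters,
        n_subjects=diff.shape[0],
        correction=cfg.mpcompcor_method,
        times=times,
        subject_values=diff,
        reference=0.0,
        metric_name=(
            stats_a.metric_name if isinstance(stats_a, GroupStats) else ""
        ),
    )
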