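"""Publication-style plotting of group results.

Line graphs show the group mean over time with a between-subject
standard-error band; significant spans are drawn with a thicker line and
marked near the time axis.  Temporal generalization matrices are drawn as
train x test heatmaps with non-significant cells desaturated.  Topographies
are drawn from channel layouts with significant channels emphasized.  The
``splinefreq`` smoothing is visualization-only: statistics always operate
on the unaltered data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import CubicSpline

from .group import GroupStats
from .patterns import TopoMap

__all__ = ["PlotConfig", "spline_smooth", "plot_group", "plot_topomap", "plot_subject_grid"]


@dataclass
class PlotConfig:
    """Plot settings (mirrors the cookbook cfg plotting keys)."""

    singleplot: bool = False
    line_colors: list[tuple[float, float, float]] | None = None
    acclim: tuple[float, float] | None = None
    splinefreq: float | None = None
    plot_order: list[str] | None = None
    plotsubjects: bool = False

    def __post_init__(self) -> None:
        if self.line_colors is not None:
            for c in self.line_colors:
                if any(not 0.0 <= v <= 1.0 for v in c):
                    raise ValueError("RGB components must lie in [0, 1]")
        if self.splinefreq is not None and self.splinefreq <= 0:
            raise ValueError("splinefreq must be positive")


def spline_smooth(
    series: np.ndarray, times_ms: np.ndarray, splinefreq_hz: float
) -> np.ndarray:
    """Low-pass a series for display by downsampling to ``splinefreq`` and
    refitting a cubic spline on the original grid.

    The anchor grid is phased so it contains the sample with the largest
    absolute value, so the global peak (or trough) survives smoothing
    exactly.  With ``splinefreq`` at or above the original rate this is the
    identity.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    if splinefreq_hz <= 0:
        raise ValueError("splinefreq must be positive")
    if len(series) != len(times):
        raise ValueError("series and time axis length mismatch")
    if len(series) < 3:
        return series.copy()
    srate = 1000.0 / np.median(np.diff(times))
    step = int(round(srate / splinefreq_hz))
    if step <= 1:
        return series.copy()
    extremum = int(np.argmax(np.abs(series)))
    anchors = np.arange(extremum % step, len(series), step)
    anchors = np.unique(np.concatenate(([0, len(series) - 1], anchors)))
    spline = CubicSpline(times[anchors], series[anchors])
    out = spline(times)
    out[extremum] = series[extremum]  # exact by construction; enforce bit-exact
    return out


_DEFAULT_COLORS = [
    (0.85, 0.33, 0.10),
    (0.00, 0.45, 0.74),
    (0.47, 0.67, 0.19),
    (0.49, 0.18, 0.56),
    (0.93, 0.69, 0.13),
    (0.30, 0.75, 0.93),
]


def _ordered(stats_list: list[GroupStats], plot_order) -> list[GroupStats]:
    if not plot_order:
        return stats_list
    by_name = {s.condname: s for s in stats_list}
    ordered = [by_name[n] for n in plot_order if n in by_name]
    ordered += [s for s in stats_list if s.condname not in plot_order]
    return ordered


def plot_group(
    stats: GroupStats | list[GroupStats],
    plot_cfg: PlotConfig | None = None,
    outdir: str | Path = ".",
    basename: str = "group",
    formats: tuple[str, ...] = ("png", "pdf"),
) -> list[Path]:
    """Render group stats to files; returns the paths written."""
    plot_cfg = plot_cfg or PlotConfig()
    stats_list = stats if isinstance(stats, list) else [stats]
    if not stats_list:
        raise ValueError("no stats to plot")
    stats_list = _ordered(stats_list, plot_cfg.plot_order)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    lines = [s for s in stats_list if s.mean.ndim == 1]
    mats = [s for s in stats_list if s.mean.ndim == 2]

    if lines:
        if plot_cfg.singleplot:
            fig, ax = plt.subplots(figsize=(6, 4))
            axes = [ax] * len(lines)
        else:
            fig, axs = plt.subplots(
                1, len(lines), figsize=(5 * len(lines), 4), squeeze=False
            )
            axes = list(axs.ravel())
        colors = plot_cfg.line_colors or _DEFAULT_COLORS
        for i, (s, ax) in enumerate(zip(lines, axes)):
            color = colors[i % len(colors)]
            _plot_line(s, ax, color, plot_cfg)
        for ax in set(axes):
            if ax.get_legend_handles_labels()[1]:
                ax.legend(fontsize=8)
            if plot_cfg.acclim:
                ax.set_ylim(*plot_cfg.acclim)
        fig.tight_layout()
        for ext in formats:
            path = outdir / f"{basename}_lines.{ext}"
            fig.savefig(path)
            written.append(path)
        plt.close(fig)

    for mi, s in enumerate(mats):
        fig, ax = plt.subplots(figsize=(5, 4.5))
        _plot_matrix(s, ax)
        fig.tight_layout()
        for ext in formats:
            path = outdir / f"{basename}_tgm{mi}.{ext}"
            fig.savefig(path)
            written.append(path)
        plt.close(fig)
    return written


def _smooth(y, times, plot_cfg):
    if plot_cfg.splinefreq is not None:
        return spline_smooth(y, times, plot_cfg.splinefreq)
    return y


def _plot_line(s: GroupStats, ax, color, plot_cfg: PlotConfig) -> None:
    times = s.times if s.times is not None else np.arange(len(s.mean))
    mean = _smooth(s.mean, times, plot_cfg)
    ax.plot(times, mean, color=color, lw=1.0, label=s.condname)
    if s.subject_values is not None and s.n_subjects > 1:
        sem = s.subject_values.std(axis=0, ddof=1) / np.sqrt(s.n_subjects)
        ax.fill_between(times, mean - sem, mean + sem, color=color, alpha=0.25, lw=0)
    if s.sig_mask is not None and s.sig_mask.any():
        sig_y = np.where(s.sig_mask, mean, np.nan)
        ax.plot(times, sig_y, color=color, lw=3.0)
        ymin = ax.get_ylim()[0]
        ax.plot(
            times[s.sig_mask],
            np.full(s.sig_mask.sum(), ymin),
            ".",
            color=color,
            ms=3,
        )
    ax.axhline(s.reference, color="k", lw=0.5, ls=":")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(s.metric_name or "metric")


def _plot_matrix(s: GroupStats, ax) -> None:
    te = s.times if s.times is not None else np.arange(s.mean.shape[1])
    tr = s.train_times if s.train_times is not None else te
    extent = [te[0], te[-1], tr[0], tr[-1]]
    vmax = np.abs(s.mean - s.reference).max() or 1.0
    # saturated colors for significant cells, washed-out elsewhere
    ax.imshow(
        s.mean,
        origin="lower",
        aspect="auto",
        extent=extent,
        cmap="RdBu_r",
        vmin=s.reference - vmax,
        vmax=s.reference + vmax,
        alpha=0.35,
    )
    if s.sig_mask is not None and s.sig_mask.any():
        masked = np.where(s.sig_mask, s.mean, np.nan)
        ax.imshow(
            masked,
            origin="lower",
            aspect="auto",
            extent=extent,
            cmap="RdBu_r",
            vmin=s.reference - vmax,
            vmax=s.reference + vmax,
        )
    ax.set_xlabel("test time (ms)")
    ax.set_ylabel("train time (ms)")
    ax.set_title(s.condname, fontsize=9)


def plot_topomap(
    topo: TopoMap,
    sig_channels: list[str] | None = None,
    ax=None,
    outfile: str | Path | None = None,
):
    """Scatter-style topography from 2-D channel positions; significant
    channels drawn emphasized (larger, outlined)."""
    if topo.positions is None:
        raise ValueError("topography plotting needs channel positions")
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    v = topo.values
    vmax = np.abs(v).max() or 1.0
    sc = ax.scatter(
        topo.positions[:, 0],
        topo.positions[:, 1],
        c=v,
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        s=120,
    )
    if sig_channels and topo.channels:
        idx = [i for i, ch in enumerate(topo.channels) if ch in sig_channels]
        ax.scatter(
            topo.positions[idx, 0],
            topo.positions[idx, 1],
            facecolors="none",
            edgecolors="k",
            linewidths=2.0,
            s=220,
        )
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.colorbar(sc, ax=ax, shrink=0.7)
    if outfile is not None:
        fig.savefig(outfile)
        plt.close(fig)
        return Path(outfile)
    return ax


def plot_subject_grid(
    subject_values: np.ndarray,
    times: np.ndarray,
    subject_ids: list[str] | None = None,
    plot_cfg: PlotConfig | None = None,
    outfile: str | Path | None = None,
    reference: float = 0.5,
):
    """Grid of single-subject time courses with equalized vertical axes;
    tick marks sit at half each subject's maximum."""
    plot_cfg = plot_cfg or PlotConfig()
    S = len(subject_values)
    n_cols = int(np.ceil(np.sqrt(S)))
    n_rows = int(np.ceil(S / n_cols))
    fig, axs = plt.subplots(
        n_rows, n_cols, figsize=(3 * n_cols, 2.2 * n_rows), squeeze=False
    )
    ylim = (
        float(np.min(subject_values)),
        float(np.max(subject_values)),
    )
    for si in range(n_rows * n_cols):
        ax = axs[si // n_cols, si % n_cols]
        if si >= S:
            ax.set_axis_off()
            continue
        y = _smooth(subject_values[si], times, plot_cfg)
        ax.plot(times, y, lw=0.8)
        ax.axhline(reference, color="k", lw=0.5, ls=":")
        ax.set_ylim(*ylim)
        ax.set_yticks([reference, (np.max(subject_values[si]) + reference) / 2.0])
        title = subject_ids[si] if subject_ids else f"S{si + 1}"
        ax.set_title(title, fontsize=8)
    fig.tight_layout()
    if outfile is not None:
        fig.savefig(outfile)
        plt.close(fig)
        return Path(outfile)
    return fig
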