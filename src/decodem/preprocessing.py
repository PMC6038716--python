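"""In-pipeline preprocessing: channel-pool selection, resampling, baseline.

These are the only preprocessing steps the pipeline performs itself; input
epochs are assumed to be cleaned/filtered upstream.  The first-level driver
applies them in the order channel pool -> resample -> baseline so that the
baseline is taken on the final time grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .epochs import ALL_NOSELECTION, EpochSet

__all__ = [
    "ChannelPool",
    "BUILTIN_POOLS",
    "apply_channelpool",
    "resample_epochs",
    "baseline_correct",
]


@dataclass
class ChannelPool:
    """A named subset of channels used as decoding features."""

    name: str
    members: list[str]


# Named pools are matched against labels present in the data; occipital pools
# follow the 10-10 convention (O*, PO*, Oz, Iz).
def _occipital_members(channels: list[str]) -> list[str]:
    keep = []
    for ch in channels:
        up = ch.upper()
        if up.startswith(("O", "PO", "I")) and any(c.isdigit() or c == "Z" for c in up):
            keep.append(ch)
    return keep


BUILTIN_POOLS = {"OCCIP": _occipital_members}


def resolve_channelpool(
    epochs: EpochSet, pool: str | list[str] | ChannelPool
) -> ChannelPool:
    """Turn a pool name / label list / ChannelPool into a concrete pool."""
    if isinstance(pool, ChannelPool):
        return pool
    if isinstance(pool, str):
        if pool == ALL_NOSELECTION:
            return ChannelPool(ALL_NOSELECTION, list(epochs.channels))
        if pool in BUILTIN_POOLS:
            members = BUILTIN_POOLS[pool](epochs.channels)
            if not members:
                raise ValueError(
                    f"named pool {pool!r} matches no channel in the data"
                )
            return ChannelPool(pool, members)
        raise ValueError(f"unknown channel pool name {pool!r}")
    return ChannelPool("CUSTOM", list(pool))


def apply_channelpool(
    epochs: EpochSet, pool: str | list[str] | ChannelPool
) -> EpochSet:
    """Restrict an EpochSet to the channels of a pool, in pool order."""
    pool = resolve_channelpool(epochs, pool)
    index = {ch: i for i, ch in enumerate(epochs.channels)}
    missing = [ch for ch in pool.members if ch not in index]
    if missing:
        raise ValueError(f"channel(s) {missing} not present in the data")
    sel = [index[ch] for ch in pool.members]
    return epochs.copy(
        data=epochs.data[:, sel, :],
        channels=[epochs.channels[i] for i in sel],
        positions=None if epochs.positions is None else epochs.positions[sel],
    )


def resample_epochs(epochs: EpochSet, new_rate_hz: float) -> EpochSet:
    """Anti-aliased polyphase downsampling of every trial.

    The rational resampling factor is the reduced fraction of
    ``new_rate / srate``; the epoch onset time is preserved and the new time
    axis is ``times[0] + k * 1000/new_rate``.  Upsampling is refused.
    """
    if new_rate_hz <= 0:
        raise ValueError("new sampling rate must be positive")
    if new_rate_hz > epochs.srate:
        raise ValueError(
            f"cannot upsample: requested {new_rate_hz} Hz > srate {epochs.srate} Hz"
        )
    if np.isclose(new_rate_hz, epochs.srate):
        return epochs.copy()
    frac = Fraction(new_rate_hz / epochs.srate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    # linear-extension padding keeps DC and slow trends exact at the edges
    data = resample_poly(epochs.data, up, down, axis=2, padtype="line")
    n_new = data.shape[2]
    new_times = epochs.times[0] + np.arange(n_new) * 1000.0 / new_rate_hz
    return epochs.copy(data=data, times=new_times, srate=float(new_rate_hz))


def baseline_correct(
    epochs: EpochSet, window_ms: tuple[float, float]
) -> EpochSet:
    """Subtract, per trial and channel, the mean over ``start <= t <= end``.

    The window is closed on both ends and must overlap the epoch.
    """
    start, end = window_ms
    if not start < end:
        raise ValueError("baseline window start must be < end")
    mask = (epochs.times >= start) & (epochs.times <= end)
    if not mask.any():
        raise ValueError(
            f"baseline window [{start}, {end}] ms contains no samples of the "
            f"epoch [{epochs.times[0]:.1f}, {epochs.times[-1]:.1f}] ms"
        )
    mean = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy(data=epochs.data - mean)
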