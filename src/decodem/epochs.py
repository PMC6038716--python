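"""Epoched data model, class specifications and the neutral on-disk container.

The universal input to every analysis is an :class:`EpochSet`: a
``(trial, channel, time)`` array of stimulus-locked signal (µV or fT/cm)
together with a millisecond time axis, one integer event code per trial,
ordered channel labels and optional 2-D sensor positions.  Experimental
conditions are addressed through those event codes: a :class:`ClassSpec`
groups codes (with optional ratio weights) into the classes a decoder
should discriminate, mirroring the cells of a factorial design table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EpochSet",
    "ClassSpec",
    "AnalysisConfig",
    "ALL_NOSELECTION",
    "cond_string",
    "parse_cond",
    "read_epochs",
    "write_epochs",
    "select_trials",
]

#: Sentinel channel-pool name meaning "keep every channel".
ALL_NOSELECTION = "ALL_NOSELECTION"

_META_KEYS = ("srate", "times_ms", "channels", "event_code", "dtype", "shape")


@dataclass
class EpochSet:
    """Epoched multichannel time series for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Signal in µV (EEG) or fT/cm (gradiometer MEG).
    times : ndarray, shape (n_times,)
        Epoch time axis in milliseconds, strictly increasing with uniform
        spacing ``1000 / srate``.  The sample at ``t == 0`` is the
        stimulus-locked sample.
    srate : float
        Sampling rate in Hz.
    event_code : ndarray of int, shape (n_trials,)
        Numeric condition code per trial.
    channels : list of str
        Unique, ordered channel labels.
    positions : ndarray, shape (n_channels, 2), optional
        2-D layout coordinates used for topographies and electrode
        clustering.
    subject_id : str
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    event_code: np.ndarray
    channels: list[str]
    positions: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.event_code = np.asarray(self.event_code, dtype=int)
        self.channels = list(self.channels)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trial, channel, time), got ndim={self.data.ndim}"
            )
        n_trials, n_channels, n_times = self.data.shape
        if n_trials == 0:
            raise ValueError("empty epoch set (0 trials)")
        if len(self.times) != n_times:
            raise ValueError(
                f"times length {len(self.times)} != data time dimension {n_times}"
            )
        if len(self.event_code) != n_trials:
            raise ValueError(
                f"event_code length {len(self.event_code)} != n_trials {n_trials}"
            )
        if len(self.channels) != n_channels:
            raise ValueError(
                f"{len(self.channels)} channel labels for {n_channels} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if n_times > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            expected = 1000.0 / self.srate
            if not np.allclose(dt, expected, rtol=1e-3, atol=1e-6):
                raise ValueError(
                    f"time spacing {dt.mean():.4f} ms inconsistent with "
                    f"srate {self.srate} Hz (expected {expected:.4f} ms)"
                )
        if self.positions is not None and self.positions.shape != (n_channels, 2):
            raise ValueError(
                f"positions must be ({n_channels}, 2), got {self.positions.shape}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self, **changes) -> "EpochSet":
        """Return a copy, optionally replacing fields (arrays are copied)."""
        base = dict(
            data=self.data.copy(),
            times=self.times.copy(),
            srate=self.srate,
            event_code=self.event_code.copy(),
            channels=list(self.channels),
            positions=None if self.positions is None else self.positions.copy(),
            subject_id=self.subject_id,
        )
        base.update(changes)
        return EpochSet(**base)


# ---------------------------------------------------------------------------
# Class specifications
# ---------------------------------------------------------------------------

@dataclass
class ClassSpec:
    """Classes to discriminate, each a list of ``(event_code, ratio_weight)``.

    ``ratio_weight`` expresses the desired within-class proportion of each
    event type after event balancing (e.g. two first presentations for every
    immediate and delayed repeat would be weights ``2, 1, 1``).  Distinct
    train/test class definitions (the semicolon convention of cookbook
    scripts) are expressed through ``train_classes`` / ``test_classes``.
    """

    classes: list[list[tuple[int, int]]]
    train_classes: list[list[tuple[int, int]]] | None = None
    test_classes: list[list[tuple[int, int]]] | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        for cls in self.classes:
            codes = [c for c, _ in cls]
            if len(set(codes)) != len(codes):
                dup = sorted({c for c in codes if codes.count(c) > 1})
                raise ValueError(f"duplicate event code(s) {dup} within one class")
            for code, w in cls:
                if w < 1:
                    raise ValueError(f"ratio weight for code {code} must be >= 1")
        # a code shared between two classes would leak trials across classes
        all_codes = [c for cls in self.classes for c, _ in cls]
        if len(set(all_codes)) != len(all_codes):
            shared = sorted({c for c in all_codes if all_codes.count(c) > 1})
            raise ValueError(
                f"event code(s) {shared} appear in more than one class"
            )
        if self.train_classes is not None and self.test_classes is not None:
            if len(self.train_classes) != len(self.test_classes):
                raise ValueError(
                    "train and test specifications must have equal class counts"
                )
        if self.names is not None and len(self.names) != len(self.classes):
            raise ValueError("names must match number of classes")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_names(self) -> list[str]:
        if self.names is not None:
            return list(self.names)
        return [cond_string_one(cls) for cls in self.classes]

    @classmethod
    def from_strings(cls, class_strings: Sequence[str], **kw) -> "ClassSpec":
        """Build a spec from canonical class strings like ``"2*5,6,7"``."""
        return cls(classes=[parse_cond(s) for s in class_strings], **kw)


def cond_string_one(cls: list[tuple[int, int]]) -> str:
    """Canonical text for one class: codes joined by commas, weight prefixed
    as ``w*code`` and omitted when 1 (``"2*5,6,7"``)."""
    parts = []
    for code, w in cls:
        parts.append(f"{w}*{code}" if w != 1 else f"{code}")
    return ",".join(parts)


def cond_string(
    event_code_groups: Sequence[Sequence[int]],
    ratios: Sequence[Sequence[int]] | None = None,
) -> list[str]:
    """Create canonical class-definition strings from event-code groups.

    Each group of codes becomes one class; optional per-code ratio weights
    give the within-class balancing proportions.

    Examples
    --------
    >>> cond_string([[13, 14, 15], [17, 18, 19]])
    ['13,14,15', '17,18,19']
    >>> cond_string([[5, 6, 7]], ratios=[[2, 1, 1]])
    ['2*5,6,7']
    """
    out = []
    for gi, group in enumerate(event_code_groups):
        codes = list(group)
        if any(int(c) <= 0 for c in codes):
            raise ValueError("event codes must be positive integers")
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate event code(s) {dup} within one class")
        if ratios is not None:
            weights = [int(w) for w in ratios[gi]]
            if len(weights) != len(codes):
                raise ValueError("ratios must match codes per class")
        else:
            weights = [1] * len(codes)
        out.append(cond_string_one(list(zip(map(int, codes), weights))))
    return out


_COND_TOKEN = re.compile(r"^(?:(\d+)\*)?(\d+)$")


def parse_cond(class_string: str) -> list[tuple[int, int]]:
    """Parse one canonical class string back into ``(code, weight)`` pairs."""
    items: list[tuple[int, int]] = []
    for token in class_string.split(","):
        m = _COND_TOKEN.match(token.strip())
        if m is None:
            raise ValueError(f"cannot parse class token {token!r}")
        w = int(m.group(1)) if m.group(1) else 1
        items.append((int(m.group(2)), w))
    codes = [c for c, _ in items]
    if len(set(codes)) != len(codes):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate event code(s) {dup} within one class")
    return items


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """First-level analysis settings (mirrors the cookbook ``cfg`` fields)."""

    nfolds: int = 5
    crossclass: bool = False
    metric: str = "auc"
    channelpool: str | list[str] = ALL_NOSELECTION
    resample_to: float | None = None
    erp_baseline: tuple[float, float] | None = None
    balance_events: bool = True
    balance_classes: bool = True
    k_neighbors: int = 5
    shrinkage: str | float = "auto"
    outputdir: str | None = None
    seed: int | None = None

    _METRICS = ("auc", "balanced_accuracy", "dprime", "hr", "far")

    def __post_init__(self) -> None:
        if self.nfolds < 1:
            raise ValueError("nfolds must be >= 1")
        if self.metric not in self._METRICS:
            raise ValueError(
                f"metric must be one of {self._METRICS}, got {self.metric!r}"
            )
        if self.erp_baseline is not None:
            start, end = self.erp_baseline
            if not start < end:
                raise ValueError("erp_baseline start must be < end")

    def validate_against(self, epochs: EpochSet) -> None:
        if self.resample_to is not None and self.resample_to > epochs.srate:
            raise ValueError(
                f"resample_to {self.resample_to} Hz exceeds srate {epochs.srate} Hz"
            )


# ---------------------------------------------------------------------------
# Neutral on-disk container
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet to a ``<name>.epochs/`` directory.

    Layout: ``data.bin`` (little-endian float32, trial-major C order) plus a
    ``meta.json`` sidecar carrying srate, time axis, labels, positions,
    event codes, subject id, dtype and shape.
    """
    path = Path(path)
    if path.suffix != ".epochs":
        path = path.with_suffix(".epochs")
    path.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(epochs.data, dtype="<f4")
    arr.tofile(path / "data.bin")
    meta = {
        "srate": float(epochs.srate),
        "times_ms": epochs.times.tolist(),
        "channels": list(epochs.channels),
        "positions": None
        if epochs.positions is None
        else epochs.positions.tolist(),
        "event_code": epochs.event_code.tolist(),
        "subject_id": epochs.subject_id,
        "dtype": "<f4",
        "shape": list(epochs.data.shape),
    }
    (path / "meta.json").write_text(json.dumps(meta))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValueError(f"meta.json missing required key(s): {missing}")
    shape = tuple(meta["shape"])
    if shape[0] == 0:
        raise ValueError("empty epoch set (0 trials)")
    data = np.fromfile(path / "data.bin", dtype=meta["dtype"])
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"data.bin holds {data.size} values, expected {int(np.prod(shape))} "
            f"for shape {shape}"
        )
    positions = meta.get("positions")
    return EpochSet(
        data=data.reshape(shape).astype(float),
        times=np.asarray(meta["times_ms"], dtype=float),
        srate=float(meta["srate"]),
        event_code=np.asarray(meta["event_code"], dtype=int),
        channels=list(meta["channels"]),
        positions=None if positions is None else np.asarray(positions, float),
        subject_id=meta.get("subject_id", ""),
    )


# ---------------------------------------------------------------------------
# Trial selection
# ---------------------------------------------------------------------------

def select_trials(
    epochs: EpochSet,
    spec: ClassSpec,
    which: str = "classes",
) -> list[np.ndarray]:
    """Return per-class trial indices for a class specification.

    Trials whose event codes belong to no class are excluded.  Every code
    named in the spec must occur at least once in the data.

    Parameters
    ----------
    which : {"classes", "train", "test"}
        Which class definition to use; "train"/"test" fall back to the
        common definition when no distinct one was given.
    """
    if which == "train" and spec.train_classes is not None:
        classes = spec.train_classes
    elif which == "test" and spec.test_classes is not None:
        classes = spec.test_classes
    else:
        classes = spec.classes
    present = set(np.unique(epochs.event_code).tolist())
    wanted = [c for cls in classes for c, _ in cls]
    absent = sorted(set(wanted) - present)
    if absent:
        raise ValueError(f"event code(s) {absent} not present in the data")
    out = []
    for cls in classes:
        codes = [c for c, _ in cls]
        mask = np.isin(epochs.event_code, codes)
        out.append(np.flatnonzero(mask))
    return out
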