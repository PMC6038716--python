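"""Forward-transformed classifier weights (activation patterns).

Backward-model weight vectors are not interpretable as neural sources; the
forward transform of Haufe et al. (2014) recovers interpretable activation
patterns as the product of the data covariance and the weight vector,
``a = Sigma_x w``.  For LDA weights computed on the same data this is
proportional to the univariate class-mean difference.  Multiplying by the
data *correlation* matrix instead yields correlation / class-separability
maps that de-emphasize high-variance artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TopoMap",
    "haufe_pattern",
    "correlation_pattern",
    "znorm_map",
]


@dataclass
class TopoMap:
    """One value per channel, plus layout metadata for plotting."""

    values: np.ndarray
    channels: list[str] | None = None
    positions: np.ndarray | None = None
    normalization: str = "raw"  # "raw" | "zscored"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.channels is not None and len(self.channels) != len(self.values):
            raise ValueError("channel labels must match number of values")


def _check_square(mat: np.ndarray, n: int, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (n, n):
        raise ValueError(f"{name} must be ({n}, {n}), got {mat.shape}")
    if not np.allclose(mat, mat.T, rtol=1e-8, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    return mat


def haufe_pattern(
    weights: np.ndarray,
    data_cov: np.ndarray,
    channels: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> TopoMap:
    """Activation pattern ``a = data_cov @ weights`` (Haufe transform)."""
    w = np.asarray(weights, dtype=float).ravel()
    cov = _check_square(data_cov, len(w), "data_cov")
    return TopoMap(cov @ w, channels=channels, positions=positions)


def correlation_pattern(
    weights: np.ndarray,
    data_corr: np.ndarray,
    channels: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> TopoMap:
    """Correlation / class-separability map ``data_corr @ weights``.

    ``data_corr`` must be a correlation matrix (unit diagonal).
    """
    w = np.asarray(weights, dtype=float).ravel()
    corr = _check_square(data_corr, len(w), "data_corr")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("data_corr must have a unit diagonal")
    return TopoMap(corr @ w, channels=channels, positions=positions)


def znorm_map(topo: TopoMap) -> TopoMap:
    """Spatially z-score a map across channels (mean 0, sd 1)."""
    v = topo.values
    if len(v) < 2:
        raise ValueError("z-scoring needs at least 2 channels")
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant map")
    return TopoMap(
        (v - v.mean()) / sd,
        channels=topo.channels,
        positions=topo.positions,
        normalization="zscored",
    )
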