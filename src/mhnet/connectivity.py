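"""Connectivity statistics: RV coefficient, Pearson FC, adjacency
thresholding and knee-based cutoff selection.

The RV coefficient generalizes squared correlation to two multivariate
signal matrices A (n x p) and B (n x q) sharing time points:

    RV(A, B) = Tr(AA'BB') / sqrt(Tr[(AA')^2] Tr[(BB')^2])

computed here on column-centered matrices (the classical definition;
``center=False`` gives the raw cross-product form).  Graph edges keep the
RV value where it strictly exceeds a sparsity cutoff gamma, the diagonal is
1, everything else 0.  The cutoff is chosen at the knee of the
retained-edge curve (fraction of surviving off-diagonal entries as a
function of gamma), located as the maximum discrete curvature of the
min-max-normalized curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import RegionMeanSeries
from .errors import ConfigError, DataValidationError, DegenerateInputError, NoKneeError

__all__ = [
    "ThresholdConfig",
    "RetainedEdgeCurve",
    "rv_coefficient",
    "pearson_fc",
    "threshold_adjacency",
    "retained_edge_curve",
    "select_cutoff",
]


DEFAULT_GRID = np.round(np.arange(0.0, 1.0, 0.01), 10)


@dataclass
class ThresholdConfig:
    """Sparsity cutoff gamma in [0, 1) and the candidate grid scanned when
    selecting it from data."""

    gamma: float = 0.0
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ConfigError(f"gamma must be in [0, 1), got {self.gamma}")
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ConfigError("grid must be strictly increasing")


@dataclass
class RetainedEdgeCurve:
    gammas: np.ndarray
    retained_fraction: np.ndarray

    def __post_init__(self):
        self.gammas = np.asarray(self.gammas, dtype=float)
        self.retained_fraction = np.asarray(self.retained_fraction, dtype=float)
        if np.any(np.diff(self.retained_fraction) > 1e-12):
            raise DataValidationError("retained fraction must be non-increasing")


def rv_coefficient(A: np.ndarray, B: np.ndarray, center: bool = True) -> float:
    """RV coefficient between two time x voxel matrices sharing rows.

    Uses the identity Tr(AA'BB') = ||A'B||_F^2 to avoid forming the n x n
    cross-product matrices.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2:
        raise DataValidationError("rv_coefficient expects 2-D matrices")
    if A.shape[0] != B.shape[0]:
        raise DataValidationError(
            f"row counts differ: {A.shape[0]} vs {B.shape[0]}"
        )
    if A.shape[0] < 3:
        raise DataValidationError("need at least 3 time points")
    if center:
        A = A - A.mean(axis=0, keepdims=True)
        B = B - B.mean(axis=0, keepdims=True)
    num = float(np.sum((A.T @ B) ** 2))
    den_a = float(np.sum((A.T @ A) ** 2))
    den_b = float(np.sum((B.T @ B) ** 2))
    if den_a == 0.0 or den_b == 0.0:
        raise DegenerateInputError(
            "all-constant matrix: RV coefficient undefined (zero denominator)"
        )
    return num / np.sqrt(den_a * den_b)


def pearson_fc(series: RegionMeanSeries) -> np.ndarray:
    """Region x region Pearson correlation matrix with exact unit diagonal,
    clipped to [-1, 1]."""
    bad = series.zero_variance_regions()
    if bad:
        raise DegenerateInputError(
            f"zero-variance region(s): {', '.join(bad)}"
        )
    fc = np.corrcoef(series.series, rowvar=False)
    fc = np.clip(fc, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fc


def threshold_adjacency(R: np.ndarray, gamma: float) -> np.ndarray:
    """Keep R(i,j) where it strictly exceeds gamma; unit diagonal; 0
    elsewhere."""
    if not 0.0 <= gamma < 1.0:
        raise ConfigError(f"gamma must be in [0, 1), got {gamma}")
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise DataValidationError("R must be square")
    if not np.allclose(R, R.T):
        raise DataValidationError("R must be symmetric")
    A = np.where(R > gamma, R, 0.0)
    np.fill_diagonal(A, 1.0)
    return A


def retained_edge_curve(R: np.ndarray, grid=None) -> RetainedEdgeCurve:
    """Fraction of strictly-upper-triangle entries surviving each candidate
    gamma."""
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ConfigError("grid must be strictly increasing")
    R = np.asarray(R, dtype=float)
    iu = np.triu_indices(R.shape[0], k=1)
    vals = R[iu]
    if vals.size == 0:
        raise DataValidationError("matrix has no off-diagonal entries")
    fractions = np.array([np.mean(vals > g) for g in grid])
    return RetainedEdgeCurve(gammas=grid, retained_fraction=fractions)


def select_cutoff(curve: RetainedEdgeCurve) -> float:
    """Knee of the retained-edge curve: the grid gamma maximizing discrete
    curvature of the min-max-normalized curve (ties -> smallest gamma).

    Raises :class:`NoKneeError` on constant or strictly linear curves.
    """
    x = curve.gammas
    y = curve.retained_fraction
    if x.size < 5:
        raise ConfigError("need at least 5 grid points for knee selection")
    if np.ptp(y) == 0.0:
        raise NoKneeError("retained-edge curve is constant")
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    # central first/second differences on the (possibly non-uniform) grid;
    # interior points only — one-sided end estimates are unreliable
    h_l = xn[1:-1] - xn[:-2]
    h_r = xn[2:] - xn[1:-1]
    dy = (yn[2:] - yn[:-2]) / (h_l + h_r)
    d2y = 2.0 * (
        yn[:-2] / (h_l * (h_l + h_r))
        - yn[1:-1] / (h_l * h_r)
        + yn[2:] / (h_r * (h_l + h_r))
    )
    curvature = np.abs(d2y) / (1.0 + dy**2) ** 1.5
    if np.max(curvature) < 1e-9 * max(1.0, np.max(np.abs(dy))):
        raise NoKneeError("retained-edge curve has no knee (linear)")
    return float(x[1 + int(np.argmax(curvature))])
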