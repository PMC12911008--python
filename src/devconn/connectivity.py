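"""Functional connectivity construction, vectorization, and motion quality control.

A connectivity matrix here is the Pearson correlation matrix of region-level
time series: symmetric, unit diagonal, off-diagonal entries in [-1, 1]. The
pipeline consumes the upper triangle (diagonal excluded) as a flat feature
vector in a fixed row-major order, so that each position can be mapped back to
a region pair for block-level bookkeeping (e.g. grouped permutation
importance over named network blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "MotionSummary",
    "fc_matrix",
    "vectorize_upper",
    "unvectorize_upper",
    "upper_triangle_pairs",
    "qc_filter",
]

#: QC rule: exclude if mean FD strictly exceeds this many mm.
FD_MEAN_THRESHOLD = 0.5
#: QC rule: exclude if strictly more than this fraction of volumes exceed the
#: per-volume FD cutoff.
FD_PROP_THRESHOLD = 0.20


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region correlation matrix with a network partition.

    Parameters
    ----------
    values : (P, P) ndarray
        Correlation values. Unit diagonal unless Fisher-z transformed, in
        which case the diagonal is NaN-masked.
    region_labels : list of str
        One label per region.
    network_of_region : (P,) ndarray of int
        Network index of each region (the partition used for block summaries).
    fisher_z : bool
        Whether ``values`` holds atanh-transformed correlations.
    """

    values: np.ndarray
    region_labels: list = field(default_factory=list)
    network_of_region: np.ndarray | None = None
    fisher_z: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        self.values = v
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(v.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MotionSummary:
    """Per-scan head-motion summary used by the QC exclusion rule."""

    mean_fd: float
    prop_volumes_over_threshold: float

    def __post_init__(self):
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be nonnegative")
        if not 0 <= self.prop_volumes_over_threshold <= 1:
            raise ValueError("prop_volumes_over_threshold must be in [0, 1]")


def fc_matrix(
    timeseries: np.ndarray,
    fisher_z: bool = False,
    region_labels: list | None = None,
    network_of_region: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation matrix of region time series.

    Parameters
    ----------
    timeseries : (P, T) ndarray
        One row per region, one column per time point; T >= 3.
    fisher_z : bool
        If True, apply atanh elementwise and mask the diagonal with NaN.

    Raises
    ------
    ValueError
        If fewer than 3 time points, or any region has zero variance (a
        constant series would silently produce NaN correlations that poison
        every downstream graph metric, so it is a hard error naming the
        region).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (regions x time)")
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 time points for a correlation matrix")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        labels = region_labels or [f"R{i:03d}" for i in range(ts.shape[0])]
        names = ", ".join(labels[i] for i in dead[:5])
        raise ValueError(f"constant time series for region(s): {names}")
    r = np.corrcoef(ts)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    if fisher_z:
        with np.errstate(divide="ignore"):
            r = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        np.fill_diagonal(r, np.nan)
    return ConnectivityMatrix(
        r,
        region_labels=list(region_labels) if region_labels else [],
        network_of_region=network_of_region,
        fisher_z=fisher_z,
    )


def upper_triangle_pairs(p: int) -> np.ndarray:
    """Region-pair (i, j) index table for the fixed vectorization order.

    Row-major upper triangle: pairs (i, j) with i < j, sorted by i then j.
    Returns an (E, 2) int array with E = p(p-1)/2. This order is the contract
    between `vectorize_upper`, the model's connectivity channel, and the
    importance module's edge-group definitions.
    """
    iu, ju = np.triu_indices(p, k=1)
    return np.column_stack([iu, ju])


def vectorize_upper(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle of a symmetric matrix.

    Returns a vector of length P(P-1)/2 in row-major (i<j, i-then-j) order;
    P=360 gives the familiar 64,620-edge feature vector.
    """
    v = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {v.shape}")
    iu, ju = np.triu_indices(v.shape[0], k=1)
    return v[iu, ju].copy()


def unvectorize_upper(vec: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Inverse of `vectorize_upper`: rebuild the symmetric matrix.

    The edge count must be triangular, i.e. len(vec) = P(P-1)/2 for integer P.
    """
    vec = np.asarray(vec, dtype=float)
    e = vec.size
    p = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if p * (p - 1) // 2 != e:
        raise ValueError(f"vector length {e} is not a triangular number")
    out = np.full((p, p), diag, dtype=float)
    iu, ju = np.triu_indices(p, k=1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def qc_filter(records: list[MotionSummary]) -> tuple[list[int], list[tuple[int, str]]]:
    """Motion quality control.

    Excludes a scan iff mean FD > 0.5 mm OR more than 20% of volumes exceed
    the per-volume FD cutoff. Both inequalities are strict, so records exactly
    at (0.5, 0.20) pass.

    Returns
    -------
    retained : list of int
        Indices passing QC.
    excluded : list of (int, str)
        Indices failing QC with a human-readable reason.
    """
    retained, excluded = [], []
    for i, rec in enumerate(records):
        reasons = []
        if rec.mean_fd > FD_MEAN_THRESHOLD:
            reasons.append(f"mean FD {rec.mean_fd:.3f} mm > {FD_MEAN_THRESHOLD} mm")
        if rec.prop_volumes_over_threshold > FD_PROP_THRESHOLD:
            reasons.append(
                f"{100 * rec.prop_volumes_over_threshold:.1f}% of volumes over the "
                f"FD cutoff (> {100 * FD_PROP_THRESHOLD:.0f}%)"
            )
        if reasons:
            excluded.append((i, "; ".join(reasons)))
        else:
            retained.append(i)
    return retained, excluded
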