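"""Per-subject voxel-wise connectivity matrices.

Edges are Pearson correlations between cleaned voxel time series; negative
correlations are removed (set to zero — the edge is simply absent, which
keeps the metric sums well defined) and the diagonal is forced to zero so
self-connections never enter any sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prep import VoxelTimeSeries

WHOLE_BRAIN = "whole_brain"
ISOCORTICAL = "isocortical"


@dataclass
class ConnectivityMatrix:
    """Symmetric voxel x voxel edge-weight matrix with zero diagonal.

    Fresh from :func:`pearson_matrix` the weights lie in [-1, 1]; after
    :func:`remove_negatives` they lie in [0, 1].
    """

    weights: np.ndarray
    voxel_index: np.ndarray
    scope: str = WHOLE_BRAIN
    zero_variance_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if len(self.voxel_index) != n:
            raise ValueError("voxel_index must match matrix dimension")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]


def pearson_matrix(ts: VoxelTimeSeries, block_size: int | None = None) -> ConnectivityMatrix:
    """Pearson correlation between every pair of voxel series.

    Zero-variance voxels get all-zero rows/columns and are listed in
    ``zero_variance_voxels`` for QC. With ``block_size`` the matrix is
    assembled in row blocks from the standardized data — identical result,
    bounded peak memory for large masks.
    """
    x = ts.data
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points for a correlation")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    z = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    z[:, bad] = 0.0
    n_t, n_v = z.shape
    if block_size is None:
        w = (z.T @ z) / n_t
    else:
        w = np.empty((n_v, n_v))
        for start in range(0, n_v, block_size):
            stop = min(start + block_size, n_v)
            w[start:stop] = (z[:, start:stop].T @ z) / n_t
    w = np.clip(w, -1.0, 1.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, ts.voxel_index, scope=WHOLE_BRAIN,
                              zero_variance_voxels=bad)


def remove_negatives(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero out negative edges; nonnegative entries pass through unchanged."""
    return ConnectivityMatrix(np.maximum(cm.weights, 0.0), cm.voxel_index,
                              scope=cm.scope, zero_variance_voxels=cm.zero_variance_voxels)


def restrict_isocortex(cm: ConnectivityMatrix, parcellation: np.ndarray):
    """Submatrix over voxels with a network label >= 1, order preserved.

    ``parcellation`` is the labelled grid (0 = non-isocortical). Returns the
    isocortical ConnectivityMatrix and the per-voxel labels of the retained
    voxels; dropped voxels are simply absent (counted by the caller if
    needed).
    """
    labels = parcellation[cm.voxel_index[:, 0], cm.voxel_index[:, 1], cm.voxel_index[:, 2]]
    keep = np.flatnonzero(labels >= 1)
    sub = ConnectivityMatrix(cm.weights[np.ix_(keep, keep)], cm.voxel_index[keep],
                             scope=ISOCORTICAL)
    return sub, labels[keep].astype(int)
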