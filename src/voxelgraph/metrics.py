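"""Per-voxel graph metrics: weighted-degree, integration, segregation.

Weighted-degree of voxel i is the sum of its nonnegative edge weights to
every other voxel — a centrality measure over the whole brain. Restricted
to the isocortex and split by a seven-network parcellation, the same sum
decomposes into *integration* (edges ending in a different network:
between-network communication) and *segregation* (edges ending in the same
network: within-network communication). All three are raw sums, not
normalized by voxel count; cross-subject comparability comes later from
healthy-control normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix, ISOCORTICAL

YEO7_NAMES = {
    1: "visual",
    2: "somatomotor",
    3: "dorsal_attention",
    4: "ventral_attention",   # salience
    5: "limbic",
    6: "frontoparietal",
    7: "default_mode",
}

WEIGHTED_DEGREE = "weighted_degree"
INTEGRATION = "integration"
SEGREGATION = "segregation"
METRICS = (WEIGHTED_DEGREE, INTEGRATION, SEGREGATION)


@dataclass
class NetworkAssignment:
    """One network label per isocortical voxel (1..n_networks)."""

    labels: np.ndarray
    names: dict = field(default_factory=lambda: dict(YEO7_NAMES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any(self.labels < 1):
            raise ValueError("every isocortical voxel needs a label >= 1")


@dataclass
class MetricMap:
    metric: str
    values: np.ndarray
    voxel_index: np.ndarray
    scope: str
    normalized: bool = False
    subject_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index)
        if len(self.values) != len(self.voxel_index):
            raise ValueError("values and voxel_index must align")


def weighted_degree(cm: ConnectivityMatrix, subject_id: str | None = None) -> MetricMap:
    """Row sums of the (nonnegative, zero-diagonal) edge-weight matrix."""
    if np.any(cm.weights < 0):
        raise ValueError("weighted_degree expects a nonnegative matrix "
                         "(apply remove_negatives first)")
    return MetricMap(WEIGHTED_DEGREE, cm.weights.sum(axis=1), cm.voxel_index,
                     scope=cm.scope, subject_id=subject_id)


def _check_isocortical(cm: ConnectivityMatrix, assignment: NetworkAssignment):
    if cm.scope != ISOCORTICAL:
        raise ValueError("integration/segregation require an isocortical matrix")
    if len(assignment.labels) != cm.n_voxels:
        raise ValueError("assignment must cover every voxel of the matrix")


def integration(cm: ConnectivityMatrix, assignment: NetworkAssignment,
                subject_id: str | None = None) -> MetricMap:
    """Sum of edges to voxels in a *different* network."""
    _check_isocortical(cm, assignment)
    between = assignment.labels[:, None] != assignment.labels[None, :]
    return MetricMap(INTEGRATION, (cm.weights * between).sum(axis=1), cm.voxel_index,
                     scope=cm.scope, subject_id=subject_id)


def segregation(cm: ConnectivityMatrix, assignment: NetworkAssignment,
                subject_id: str | None = None) -> MetricMap:
    """Sum of edges to voxels in the *same* network (diagonal excluded)."""
    _check_isocortical(cm, assignment)
    within = assignment.labels[:, None] == assignment.labels[None, :]
    return MetricMap(SEGREGATION, (cm.weights * within).sum(axis=1), cm.voxel_index,
                     scope=cm.scope, subject_id=subject_id)


def all_metrics(cm_whole: ConnectivityMatrix, cm_iso: ConnectivityMatrix,
                assignment: NetworkAssignment, subject_id: str | None = None) -> dict:
    """The three maps for one subject, keyed by metric name."""
    return {
        WEIGHTED_DEGREE: weighted_degree(cm_whole, subject_id),
        INTEGRATION: integration(cm_iso, assignment, subject_id),
        SEGREGATION: segregation(cm_iso, assignment, subject_id),
    }
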