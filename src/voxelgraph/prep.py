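"""Functional time-series denoising.

Emulates the standard resting-state cleanup applied before voxel-wise
connectivity: nuisance (confound) regression, band-pass filtering
(0.01-0.08 Hz), framewise-displacement (FD) computation, scrubbing of
high-motion volumes (FD > 0.5 mm), run concatenation and retention of the
first 120 surviving volumes per subject.

Pipeline order is fixed: confound regression -> band-pass -> scrub/select.
Scrubbing deletes volumes after filtering (no interpolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

FD_THRESHOLD_MM = 0.5
N_VOLUMES = 120
ROTATION_RADIUS_MM = 50.0
MOTION_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz"]


@dataclass
class VoxelTimeSeries:
    """Masked voxel signals over time.

    data is time x voxel; ``voxel_index`` maps columns to grid coordinates;
    ``kept_volume_ids`` tracks which original volumes survive scrubbing
    (offset by run when several runs were concatenated).
    """

    data: np.ndarray
    voxel_index: np.ndarray
    tr_seconds: float
    kept_volume_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index)
        if self.kept_volume_ids is None:
            self.kept_volume_ids = np.arange(self.data.shape[0])
        else:
            self.kept_volume_ids = np.asarray(self.kept_volume_ids)
        if self.data.ndim != 2:
            raise ValueError("data must be time x voxel")
        if len(self.voxel_index) != self.data.shape[1]:
            raise ValueError("voxel_index length must match data columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class ConfoundMatrix:
    """Nuisance design: time x k columns with labels; includes a constant."""

    columns: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.shape[1] != len(self.names):
            raise ValueError("names must label every column")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.columns))


@dataclass
class MotionSummary:
    fd: np.ndarray                   # mm, one value per volume transition
    scrubbed_volume_ids: set
    usable_volumes: int


@dataclass
class Exclusion:
    """A subject dropped from analysis, with the reason recorded."""

    reason: str
    detail: str = ""


def framewise_displacement(motion_table, rotation_radius_mm: float = ROTATION_RADIUS_MM,
                           fd_threshold_mm: float = FD_THRESHOLD_MM) -> MotionSummary:
    """Power-convention FD and the scrub decision per volume.

    FD at transition t is sum|d translation| + radius * sum|d rotation|.
    The volume *terminating* a transition with FD strictly above the
    threshold is scrubbed; the first volume is never scrubbed.
    """
    if isinstance(motion_table, pd.DataFrame):
        motion = motion_table[MOTION_COLUMNS].to_numpy(float) \
            if set(MOTION_COLUMNS) <= set(motion_table.columns) \
            else motion_table.to_numpy(float)
    else:
        motion = np.asarray(motion_table, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("motion table needs at least 2 rows")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + rotation_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    scrubbed = set((np.flatnonzero(fd > fd_threshold_mm) + 1).tolist())
    return MotionSummary(fd=fd, scrubbed_volume_ids=scrubbed,
                         usable_volumes=motion.shape[0] - len(scrubbed))


def motion_confounds(motion_table, include_trends: bool = True) -> ConfoundMatrix:
    """Constant + 6 motion parameters + their backward derivatives
    (+ linear and quadratic trends). The derivative at the first volume is 0.
    """
    if isinstance(motion_table, pd.DataFrame):
        motion = motion_table.to_numpy(float)
    else:
        motion = np.asarray(motion_table, dtype=float)
    n = motion.shape[0]
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    cols = [np.ones((n, 1)), motion, deriv]
    names = ["const"] + MOTION_COLUMNS + [f"d_{c}" for c in MOTION_COLUMNS]
    if include_trends:
        t = np.linspace(-1.0, 1.0, n)
        cols.append(np.column_stack([t, t ** 2]))
        names += ["trend_lin", "trend_quad"]
    return ConfoundMatrix(np.hstack(cols), names)


def compcor_components(noise_signals: np.ndarray, n_components: int = 5) -> np.ndarray:
    """Top principal components of a nuisance-tissue signal block.

    ``noise_signals`` is time x voxel (e.g. ventricle or white-matter
    stand-in voxels); columns are demeaned and the leading left singular
    vectors returned, unit-normed, as time x n_components.
    """
    x = np.asarray(noise_signals, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, (s > 1e-12 * max(s.max(), 1e-300)).sum())
    return u[:, :k]


def build_confounds(motion_table, noise_blocks: dict[str, np.ndarray] | None = None,
                    n_components: int = 5, include_trends: bool = True) -> ConfoundMatrix:
    """Full nuisance design: motion set plus per-tissue aCompCor components."""
    base = motion_confounds(motion_table, include_trends=include_trends)
    cols, names = [base.columns], list(base.names)
    for tissue, block in (noise_blocks or {}).items():
        comp = compcor_components(block, n_components)
        cols.append(comp)
        names += [f"{tissue}_pc{i + 1}" for i in range(comp.shape[1])]
    return ConfoundMatrix(np.hstack(cols), names)


def _independent_columns(x: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    from scipy.linalg import qr
    r = np.linalg.matrix_rank(x)
    if r == x.shape[1]:
        return np.arange(x.shape[1])
    _, _, piv = qr(x, mode="economic", pivoting=True)
    return np.sort(piv[:r])


def regress_confounds(ts: VoxelTimeSeries, confounds: ConfoundMatrix) -> VoxelTimeSeries:
    """OLS residuals of every voxel series on the confound columns.

    Rank-deficient designs are repaired by dropping dependent columns (with
    a warning). Residuals are orthogonal to every retained column.
    """
    x = confounds.columns
    if x.shape[0] != ts.n_timepoints:
        raise ValueError("confound rows must match time-series rows")
    # constant regressors (e.g. motion parameters held at zero) are
    # degenerate with the intercept; drop them quietly before the rank check
    const = (np.ptp(x, axis=0) == 0) & (np.arange(x.shape[1]) != 0)
    if const.any():
        x = x[:, ~const]
        confounds = ConfoundMatrix(x, [n for n, c in
                                       zip(confounds.names, const) if not c])
    keep = _independent_columns(x)
    if len(keep) < x.shape[1]:
        dropped = [confounds.names[i] for i in range(x.shape[1]) if i not in set(keep.tolist())]
        warnings.warn(f"dropping {len(dropped)} dependent confound column(s): {dropped}")
        x = x[:, keep]
    beta, *_ = np.linalg.lstsq(x, ts.data, rcond=None)
    resid = ts.data - x @ beta
    return VoxelTimeSeries(resid, ts.voxel_index, ts.tr_seconds, ts.kept_volume_ids)


def bandpass(ts: VoxelTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08,
             order: int = 4) -> VoxelTimeSeries:
    """Zero-phase Butterworth band-pass along time (forward-backward IIR)."""
    nyquist = 0.5 / ts.tr_seconds
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyquist}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return VoxelTimeSeries(filtered, ts.voxel_index, ts.tr_seconds, ts.kept_volume_ids)


def select_volumes(runs: list[VoxelTimeSeries], motion_summaries: list[MotionSummary],
                   n_volumes: int = N_VOLUMES):
    """Drop scrubbed volumes, concatenate runs, keep the first ``n_volumes``.

    Returns a VoxelTimeSeries with exactly ``n_volumes`` rows, or an
    Exclusion("motion") when fewer usable volumes survive — no third outcome.
    """
    if len(runs) != len(motion_summaries):
        raise ValueError("one motion summary per run required")
    ref = runs[0]
    for r in runs[1:]:
        if not np.array_equal(r.voxel_index, ref.voxel_index):
            raise ValueError("runs must share voxel_index")
        if r.tr_seconds != ref.tr_seconds:
            raise ValueError("runs must share TR")
    pieces, ids, offset = [], [], 0
    for run, ms in zip(runs, motion_summaries):
        keep = np.array([t for t in range(run.n_timepoints)
                         if t not in ms.scrubbed_volume_ids], dtype=int)
        pieces.append(run.data[keep])
        ids.append(keep + offset)
        offset += run.n_timepoints
    data = np.vstack(pieces)
    kept = np.concatenate(ids)
    if data.shape[0] < n_volumes:
        return Exclusion(reason="motion",
                         detail=f"{data.shape[0]} usable volumes (< {n_volumes})")
    return VoxelTimeSeries(data[:n_volumes], ref.voxel_index, ref.tr_seconds,
                           kept[:n_volumes])


def preprocess_subject(image_4d: np.ndarray, mask: np.ndarray, motion_table,
                       tr_seconds: float, noise_rois: dict[str, np.ndarray] | None = None,
                       n_volumes: int = N_VOLUMES):
    """Full denoising for one subject (single run).

    ``noise_rois`` maps tissue name -> coordinates (M x 3) of out-of-mask
    voxels whose signals provide the aCompCor components. Returns a cleaned
    120-volume VoxelTimeSeries or an Exclusion.
    """
    voxel_index = np.argwhere(mask)
    data = image_4d[mask].T          # time x voxel
    blocks = None
    if noise_rois:
        blocks = {name: image_4d[tuple(np.asarray(c).T)].T for name, c in noise_rois.items()}
    ts = VoxelTimeSeries(data, voxel_index, tr_seconds)
    confounds = build_confounds(motion_table, blocks)
    ts = regress_confounds(ts, confounds)
    ts = bandpass(ts)
    ms = framewise_displacement(motion_table)
    return select_volumes([ts], [ms], n_volumes=n_volumes)
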