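"""Seed-to-voxel connectivity from integration peaks.

One seed per hemisphere is placed on the peak-z voxel of the corrected
integration contrast (restricted to voxels surviving every analysis — the
intersection mask). The seed ROI is the 3 x 3 x 3 voxel neighbourhood of
the peak (27 voxels when interior: a "3 mm sphere" at 3 mm resolution with
the printed member count taken as normative). Each subject's seed-mean
time course is correlated with every isocortical voxel, Fisher r-to-z
transformed, and the maps contrasted between groups with the same
clusterwise machinery; significant (positive) voxels are then decomposed
into percentages over the six networks other than the seed's own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import hemisphere_labels
from .inference import DesignSpec, GroupInferenceResult, run_group_inference
from .metrics import YEO7_NAMES
from .prep import VoxelTimeSeries


@dataclass
class SeedROI:
    centre: tuple                  # grid coordinate of the peak voxel
    member_voxels: np.ndarray      # M x 3 grid coordinates
    hemisphere: str
    source_metric: str = "integration"

    def __post_init__(self):
        self.member_voxels = np.asarray(self.member_voxels)
        if not any(np.array_equal(m, np.asarray(self.centre))
                   for m in self.member_voxels):
            raise ValueError("centre must belong to member_voxels")

    @property
    def n_members(self) -> int:
        return len(self.member_voxels)


@dataclass
class NetworkComposition:
    percents: dict                 # network name -> % of significant voxels
    excluded_network: str
    n_significant: int


def find_peaks(zvals: np.ndarray, voxel_index: np.ndarray, corrected_mask: np.ndarray,
               intersection_mask: np.ndarray, affine: np.ndarray) -> dict:
    """Per-hemisphere peak voxel within corrected AND intersection masks.

    Ties in z break lexicographically on the grid coordinate. A hemisphere
    with no eligible voxel is skipped with a warning.
    """
    hemis = hemisphere_labels(voxel_index, affine)
    eligible = np.asarray(corrected_mask, bool) & np.asarray(intersection_mask, bool)
    peaks = {}
    for side in ("left", "right"):
        idx = np.flatnonzero(eligible & (hemis == side))
        if idx.size == 0:
            warnings.warn(f"no eligible seed voxel in {side} hemisphere; skipped")
            continue
        zmax = zvals[idx].max()
        best = idx[np.isclose(zvals[idx], zmax)]
        coords = voxel_index[best]
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        peaks[side] = tuple(int(v) for v in coords[order[0]])
    return peaks


def build_seed(peak: tuple, mask: np.ndarray, hemisphere: str,
               source_metric: str = "integration") -> SeedROI:
    """Chebyshev-radius-1 neighbourhood of the peak, inside the mask.

    27 members for an interior peak; edge seeds are smaller and kept.
    """
    peak = tuple(int(v) for v in peak)
    if not mask[peak]:
        raise ValueError("peak must lie inside the mask")
    shape = mask.shape
    members = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                w = (peak[0] + di, peak[1] + dj, peak[2] + dk)
                if all(0 <= w[a] < shape[a] for a in range(3)) and mask[w]:
                    members.append(w)
    if len(members) < 27:
        warnings.warn(f"seed at {peak} truncated to {len(members)} voxels "
                      "(mask or grid edge)")
    return SeedROI(centre=peak, member_voxels=np.array(members),
                   hemisphere=hemisphere, source_metric=source_metric)


def fisher_z(r: np.ndarray, clip: float = 1 - 1e-7) -> np.ndarray:
    """atanh with |r| clipped just below 1 (variance ~ 1/(n-3))."""
    return np.arctanh(np.clip(r, -clip, clip))


def seed_to_voxel(ts: VoxelTimeSeries, seed: SeedROI,
                  target_selector: np.ndarray | None = None) -> tuple:
    """Fisher-z correlation of the seed-mean series with every target voxel.

    ``target_selector`` is a boolean per ts voxel (e.g. isocortical);
    seed-member voxels are always excluded from the map. Returns
    (z values, indices of mapped voxels into ts.voxel_index).
    """
    coords = np.asarray(ts.voxel_index)
    member_set = {tuple(m) for m in seed.member_voxels}
    is_member = np.array([tuple(c) in member_set for c in coords])
    if not is_member.any():
        raise ValueError("seed members not found in the time series")
    sel = np.ones(len(coords), bool) if target_selector is None \
        else np.asarray(target_selector, bool).copy()
    sel &= ~is_member
    seed_series = ts.data[:, is_member].mean(axis=1)
    x = ts.data[:, sel]
    sc = (seed_series - seed_series.mean())
    denom = np.sqrt((sc ** 2).sum()) * np.sqrt(((x - x.mean(0)) ** 2).sum(0))
    denom = np.where(denom == 0, np.inf, denom)
    r = (sc @ (x - x.mean(0))) / denom
    return fisher_z(r), np.flatnonzero(sel)


def seed_glm_and_compose(seed_maps: np.ndarray, subjects, design: DesignSpec,
                         labels: np.ndarray, seed_network: int,
                         voxel_index: np.ndarray, grid_shape,
                         n_iter: int = 10_000, seed: int = 0,
                         network_names: dict | None = None):
    """Group contrast on seed connectivity maps + seven-network composition.

    ``seed_maps`` is subjects x target-voxels (Fisher-z), ``labels`` the
    network label per target voxel. Composition counts significant voxels
    with a positive group effect and reports percentages over the six
    networks other than the seed's; the seed's network is excluded because
    within-network edges are not integration-relevant.
    """
    names = network_names or YEO7_NAMES
    result = run_group_inference(seed_maps, subjects, design, voxel_index,
                                 grid_shape, n_iter=n_iter, seed=seed)
    sig_pos = np.zeros(seed_maps.shape[1], dtype=bool)
    for c in result.clusters:
        if c.p_corrected is not None and c.p_corrected < result.params["alpha"] \
                and c.sign > 0:
            sig_pos[c.voxels] = True
    other = {lab: name for lab, name in names.items() if lab != seed_network}
    counts = {name: int(((labels == lab) & sig_pos).sum()) for lab, name in other.items()}
    total = sum(counts.values())
    if total == 0:
        percents = {name: 0.0 for name in counts}
    else:
        percents = {name: 100.0 * n / total for name, n in counts.items()}
    comp = NetworkComposition(percents=percents,
                              excluded_network=names[seed_network],
                              n_significant=total)
    return result, comp
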