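"""Voxel-wise GLM group contrasts with Monte Carlo clusterwise correction.

Per voxel, a normalized metric value is regressed on an intercept, a group
indicator and nuisance covariates (SSRI/SNRI use by default; age and sex
are already removed upstream); the group coefficient's t statistic is
mapped to a z statistic. Suprathreshold voxels (|z| > 1.96, signs kept
separate) are grouped into 26-connected clusters, and cluster extents are
referred to a permutation null: group labels are shuffled within the two
contrasted groups (covariates stay attached to their subjects), the z-map
recomputed, and the maximum suprathreshold cluster extent recorded per
iteration. Corrected p uses the +1 convention,
p = (1 + #{null max >= extent}) / (1 + n_iter).

Healthy controls never enter a contrast — they only define the
normalization scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .grid import scatter_to_grid

CLUSTER_FORMING_Z = 1.96
N_ITER = 10_000
ALPHA = 0.05
CONNECTIVITY = 26


@dataclass
class DesignSpec:
    contrast: tuple            # (group A, group B); indicator is 1 for A
    covariates: tuple = ("ssri",)
    two_sided: bool = True


@dataclass
class Cluster:
    voxels: np.ndarray         # indices into the map's voxel vector
    sign: int                  # +1 or -1
    extent: int
    peak_z: float
    peak_coord: tuple
    p_corrected: float | None = None


@dataclass
class ClusterNullDistribution:
    max_extents: np.ndarray
    seed: int
    threshold: float = CLUSTER_FORMING_Z
    connectivity: int = CONNECTIVITY

    def __post_init__(self):
        self.max_extents = np.asarray(self.max_extents, dtype=int)
        if np.any(self.max_extents < 0):
            raise ValueError("extents must be nonnegative")


@dataclass
class GroupInferenceResult:
    zmap: np.ndarray
    clusters: list
    corrected_mask: np.ndarray          # boolean, per map voxel
    params: dict = field(default_factory=dict)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18 or 26")


def build_design(subjects, design: DesignSpec):
    """(rows, X, group column index) for the contrasted subjects only."""
    a, b = design.contrast
    if "HC" in (a, b):
        warnings.warn("healthy controls entering a contrast; they normally "
                      "only define the normalization reference")
    rows = [i for i, s in enumerate(subjects) if s.group in (a, b)
            or (s.group == "FND" and s.subtype in (a, b))]
    if not rows:
        raise ValueError("empty contrast")
    sel = [subjects[i] for i in rows]

    def is_a(s):
        return s.group == a or s.subtype == a

    g = np.array([1.0 if is_a(s) else 0.0 for s in sel])
    if g.sum() < 3 or (len(g) - g.sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    cols, names = [np.ones(len(sel)), g], ["const", "group"]
    for c in design.covariates:
        if c == "sex":
            v = np.array([1.0 if s.sex == "M" else 0.0 for s in sel])
        elif c == "ssri":
            v = np.array([1.0 if s.ssri else 0.0 for s in sel])
        else:
            v = np.array([float(getattr(s, c) or 0.0) for s in sel])
        if np.ptp(v) == 0:
            warnings.warn(f"constant covariate {c!r} dropped from design")
            continue
        cols.append(v)
        names.append(c)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix: " + ", ".join(names))
    return np.array(rows), x, 1


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    p = stats.t.cdf(t, df)
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return stats.norm.ppf(p)


def glm_contrast(values: np.ndarray, subjects, design: DesignSpec) -> np.ndarray:
    """Per-voxel z statistic for the group coefficient."""
    rows, x, gcol = build_design(subjects, design)
    y = np.asarray(values, float)[rows]
    n, k = x.shape
    df = n - k
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[gcol, gcol], 1e-300))
    return _t_to_z(beta[gcol] / se, df)


def cluster_extract(zvals: np.ndarray, voxel_index: np.ndarray, grid_shape,
                    threshold: float = CLUSTER_FORMING_Z, two_sided: bool = True,
                    connectivity: int = CONNECTIVITY) -> list:
    """Sign-separated connected components of suprathreshold voxels."""
    struct = _structure(connectivity)
    vol = scatter_to_grid(zvals, voxel_index, tuple(grid_shape), fill=0.0)
    flat_of = {tuple(c): i for i, c in enumerate(np.asarray(voxel_index))}
    clusters = []
    signs = (1, -1) if two_sided else (1,)
    for sign in signs:
        mask3d = (sign * vol) > threshold
        labelled, n = ndimage.label(mask3d, structure=struct)
        for lab in range(1, n + 1):
            coords = np.argwhere(labelled == lab)
            idx = np.array([flat_of[tuple(c)] for c in coords])
            zs = zvals[idx]
            peak_local = np.argmax(sign * zs)
            clusters.append(Cluster(voxels=idx, sign=sign, extent=len(idx),
                                    peak_z=float(zs[peak_local]),
                                    peak_coord=tuple(coords[peak_local])))
    clusters.sort(key=lambda c: -c.extent)
    return clusters


def _max_extent(mask3d: np.ndarray, struct: np.ndarray) -> int:
    labelled, n = ndimage.label(mask3d, structure=struct)
    if n == 0:
        return 0
    return int(np.bincount(labelled.ravel())[1:].max())


def monte_carlo_null(values: np.ndarray, subjects, design: DesignSpec,
                     voxel_index: np.ndarray, grid_shape, n_iter: int = N_ITER,
                     seed: int = 0, threshold: float = CLUSTER_FORMING_Z,
                     connectivity: int = CONNECTIVITY,
                     batch: int = 250) -> ClusterNullDistribution:
    """Permutation null of the maximum suprathreshold cluster extent.

    Each iteration permutes the group indicator across the contrasted
    subjects (covariate columns stay put), recomputes every voxel's group
    t statistic in closed form (batched linear algebra) and records the
    largest cluster extent over both signs. Thresholding happens on the t
    scale at the value equivalent to the requested z threshold, which gives
    the identical suprathreshold set without per-iteration quantile
    transforms.
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100: corrected-p tail will be unstable")
    rng = np.random.default_rng(seed)
    rows, x, gcol = build_design(subjects, design)
    y = np.asarray(values, float)[rows]
    n, k = x.shape
    df = n - k
    struct = _structure(connectivity)
    t_crit = stats.t.ppf(stats.norm.cdf(threshold), df)
    g = x[:, gcol]
    others = np.delete(x, gcol, axis=1)            # n x (k-1), fixed columns
    oto = others.T @ others
    oty = others.T @ y
    y2 = (y ** 2).sum(axis=0)
    coords = np.asarray(voxel_index)
    vol = np.zeros(tuple(grid_shape), dtype=bool)

    max_extents = np.empty(n_iter, dtype=int)
    done = 0
    while done < n_iter:
        b = min(batch, n_iter - done)
        gp = np.array([rng.permutation(g) for _ in range(b)])     # b x n
        # assemble X'X (b,k,k) and X'Y (b,k,V) with the group row varying
        gtg = (gp ** 2).sum(axis=1)
        gto = gp @ others                                          # b x (k-1)
        xtx = np.empty((b, k, k))
        xtx[:, 0, 0] = gtg
        xtx[:, 0, 1:] = gto
        xtx[:, 1:, 0] = gto
        xtx[:, 1:, 1:] = oto
        xty = np.empty((b, k, y.shape[1]))
        xty[:, 0, :] = gp @ y
        xty[:, 1:, :] = oty
        # pinv, not solve: a permutation can make the group column collinear
        # with a binary covariate at small n; the degenerate draw then
        # contributes a zero t-map instead of aborting the null
        xtx_inv = np.linalg.pinv(xtx)
        beta = xtx_inv @ xty
        rss = y2 - np.einsum("bkv,bkv->bv", beta, xty)
        xtx_inv_gg = xtx_inv[:, 0, 0]
        se = np.sqrt(np.maximum(rss / df, 1e-300) * xtx_inv_gg[:, None])
        tstat = beta[:, 0, :] / se
        for i in range(b):
            best = 0
            for sign in (1, -1):
                sup = (sign * tstat[i]) > t_crit
                if sup.any():
                    vol[:] = False
                    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = sup
                    best = max(best, _max_extent(vol, struct))
            max_extents[done + i] = best
        done += b
    return ClusterNullDistribution(max_extents, seed=seed, threshold=threshold,
                                   connectivity=connectivity)


def correct_clusters(zvals: np.ndarray, clusters: list, null_dist: ClusterNullDistribution,
                     alpha: float = ALPHA, threshold: float = CLUSTER_FORMING_Z,
                     connectivity: int = CONNECTIVITY) -> GroupInferenceResult:
    """Attach corrected p to every cluster; keep those with p < alpha."""
    if null_dist.threshold != threshold or null_dist.connectivity != connectivity:
        raise ValueError("null distribution built with different cluster parameters")
    n_iter = len(null_dist.max_extents)
    n_vox = len(zvals)
    mask = np.zeros(n_vox, dtype=bool)
    out = []
    for c in clusters:
        p = (1 + int((null_dist.max_extents >= c.extent).sum())) / (1 + n_iter)
        c.p_corrected = p
        out.append(c)
        if p < alpha:
            mask[c.voxels] = True
    params = {"cluster_forming_z": threshold, "n_iterations": n_iter,
              "alpha": alpha, "connectivity_rule": connectivity}
    return GroupInferenceResult(zmap=zvals, clusters=out, corrected_mask=mask,
                                params=params)


def run_group_inference(values: np.ndarray, subjects, design: DesignSpec,
                        voxel_index: np.ndarray, grid_shape, n_iter: int = N_ITER,
                        seed: int = 0, threshold: float = CLUSTER_FORMING_Z,
                        alpha: float = ALPHA,
                        connectivity: int = CONNECTIVITY) -> GroupInferenceResult:
    """zmap -> clusters -> permutation null -> corrected result, one call."""
    zvals = glm_contrast(values, subjects, design)
    clusters = cluster_extract(zvals, voxel_index, grid_shape, threshold,
                               design.two_sided, connectivity)
    null = monte_carlo_null(values, subjects, design, voxel_index, grid_shape,
                            n_iter=n_iter, seed=seed, threshold=threshold,
                            connectivity=connectivity)
    return correct_clusters(zvals, clusters, null, alpha, threshold, connectivity)


def intersection_map(masks: list) -> np.ndarray:
    """Voxelwise AND across corrected masks (same grid required)."""
    if not masks:
        raise ValueError("need at least one mask")
    out = np.asarray(masks[0], bool).copy()
    for m in masks[1:]:
        m = np.asarray(m, bool)
        if m.shape != out.shape:
            raise ValueError("mask shape mismatch")
        out &= m
    return out
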