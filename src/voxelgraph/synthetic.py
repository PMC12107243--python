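"""Synthetic resting-state cohorts with the statistical structure the
analysis assumes.

Each subject's in-mask voxel signals are drawn from a multivariate normal
whose correlation matrix is block-structured by a seven-network
parcellation: ``base_within_corr`` on same-network voxel pairs,
``base_between_corr`` on different-network pairs, plus per-group effect
deltas on selected edges. Observation noise and a pair of weakly coupled
nuisance components ("ventricle" / "white matter" stand-ins outside the
brain mask) are added on top, and a motion table with occasional
supra-threshold spikes exercises scrubbing.

The generator makes no attempt at realistic haemodynamics, spatial noise
autocorrelation or multi-site effects; what it reproduces is the covariance
geometry that the graph metrics and the group inference consume.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import default_affine, ellipsoid_mask, coords_to_flat
from .normalization import SubjectRecord

BETWEEN_NETWORK_GAIN = "between_network_gain"
WITHIN_NETWORK_GAIN = "within_network_gain"
GLOBAL_GAIN = "global_gain"
EFFECT_MODES = (BETWEEN_NETWORK_GAIN, WITHIN_NETWORK_GAIN, GLOBAL_GAIN)


@dataclass
class EffectSpec:
    """A group-confined shift of edge correlations.

    ``region`` holds flat grid indices (C-order). ``delta_corr`` is added to
    every edge touching the region that matches ``mode``; an optional
    ``covariate_link`` (name, slope) makes the per-subject delta
    delta_corr + slope * standardized covariate, producing a monotone
    symptom-connectivity relationship.
    """

    target_group: str
    region: np.ndarray
    mode: str
    delta_corr: float
    covariate_link: tuple[str, float] | None = None

    def __post_init__(self):
        self.region = np.asarray(self.region, dtype=int)
        if self.mode not in EFFECT_MODES:
            raise ValueError(f"unknown effect mode {self.mode!r}")

    def to_dict(self) -> dict:
        return {"target_group": self.target_group, "region": self.region.tolist(),
                "mode": self.mode, "delta_corr": self.delta_corr,
                "covariate_link": list(self.covariate_link) if self.covariate_link else None}

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        link = tuple(d["covariate_link"]) if d.get("covariate_link") else None
        return cls(d["target_group"], np.asarray(d["region"]), d["mode"],
                   d["delta_corr"], link)


@dataclass
class SyntheticConfig:
    grid_shape: tuple = (12, 12, 12)
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    n_networks: int = 7
    # Cohort sizes mirror the study design (61 FND / 58 PC / 59 HC).
    group_sizes: dict = field(default_factory=lambda: {"FND": 61, "PC": 58, "HC": 59})
    effect_spec: list = field(default_factory=list)
    noise_sd: float = 0.1
    base_within_corr: float = 0.3
    base_between_corr: float = 0.1
    seed: int = 0
    zero_fraction: float = 0.1          # non-isocortical fraction of the mask
    n_motion_spikes: int = 4
    spike_magnitude_mm: float = 0.8
    nuisance_coupling: float = 0.07     # loading of tissue factors on brain voxels
    # per-subject global connectivity level g ~ U(range): R_subj = g R + (1-g) I.
    # Emulates between-subject variation in overall coupling strength.
    subject_scale_range: tuple = (0.92, 1.0)

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if not (0 < self.base_within_corr < 1):
            raise ValueError("base_within_corr must lie in (0, 1)")
        if not (0 <= self.base_between_corr < self.base_within_corr):
            raise ValueError("need 0 <= base_between_corr < base_within_corr")
        if self.n_timepoints < 120:
            raise ValueError("n_timepoints must be >= 120")
        if min(self.grid_shape) < 1 or any(g <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if int(np.prod(self.grid_shape)) < self.n_networks:
            raise ValueError("grid too small for the requested networks")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_spec"] = [e.to_dict() for e in self.effect_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["effect_spec"] = [EffectSpec.from_dict(e) for e in d.get("effect_spec", [])]
        d["group_sizes"] = {k: int(v) for k, v in d["group_sizes"].items()}
        return cls(**d)


@dataclass
class SyntheticCohort:
    images: dict                     # subject id -> 4-D array (x, y, z, t)
    motion_tables: dict              # subject id -> DataFrame (tx..rz)
    mask: np.ndarray
    parcellation: np.ndarray
    subjects: list
    truth: list                      # the EffectSpec list actually used
    noise_rois: dict                 # tissue -> voxel coordinates (out of mask)
    affine: np.ndarray
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# parcellation

def make_parcellation(grid_shape, n_networks: int = 7, seed: int = 0,
                      mask: np.ndarray | None = None,
                      zero_fraction: float = 0.1) -> np.ndarray:
    """Partition the mask into spatially contiguous network blocks.

    Balanced multi-source region growing (6-connectivity) from random seed
    voxels; when ``zero_fraction`` > 0 one extra region of that size is
    grown and labelled 0 to stand in for non-isocortical grey matter.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = ellipsoid_mask(grid_shape)
    coords = np.argwhere(mask)
    n_vox = len(coords)
    n_regions = n_networks + (1 if zero_fraction > 0 else 0)
    if n_vox < n_regions:
        raise ValueError(f"mask has {n_vox} voxels; cannot fit {n_regions} regions")

    zero_target = int(round(zero_fraction * n_vox)) if zero_fraction > 0 else 0
    if zero_fraction > 0 and zero_target == 0:
        zero_target = 1
    share = (n_vox - zero_target) / n_networks
    targets = [max(1, zero_target)] if zero_fraction > 0 else []
    targets += [max(1, share)] * n_networks
    labels_of_region = ([0] if zero_fraction > 0 else []) + list(range(1, n_networks + 1))

    seeds = coords[rng.choice(n_vox, size=n_regions, replace=False)]
    assigned = np.full(grid_shape, -1, dtype=int)   # region index, -1 unassigned
    in_mask = mask.astype(bool)
    frontiers = []
    sizes = [0] * n_regions
    from collections import deque
    for r, s in enumerate(seeds):
        frontiers.append(deque([tuple(s)]))
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    n_assigned = 0
    while n_assigned < n_vox:
        # grow the most under-filled region that still has a frontier
        order = sorted(range(n_regions), key=lambda r: sizes[r] / targets[r])
        grew = False
        for r in order:
            while frontiers[r]:
                v = frontiers[r].popleft()
                if assigned[v] != -1:
                    continue
                assigned[v] = r
                sizes[r] += 1
                n_assigned += 1
                for d in offsets:
                    w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                    if all(0 <= w[a] < grid_shape[a] for a in range(3)) \
                            and in_mask[w] and assigned[w] == -1:
                        frontiers[r].append(w)
                grew = True
                break
            if grew:
                break
        if not grew:
            # disconnected pocket: attach remaining voxels to the nearest seed
            rest = coords[assigned[coords[:, 0], coords[:, 1], coords[:, 2]] == -1]
            d2 = ((rest[:, None, :] - seeds[None, :, :]) ** 2).sum(-1)
            near = d2.argmin(axis=1)
            for v, r in zip(rest, near):
                assigned[tuple(v)] = r
                sizes[r] += 1
            n_assigned = n_vox

    parc = np.zeros(grid_shape, dtype=int)
    for r, lab in enumerate(labels_of_region):
        parc[assigned == r] = lab
    parc[~in_mask] = 0
    return parc


def pick_effect_region(parcellation: np.ndarray, network: int, size: int,
                       seed: int = 0) -> np.ndarray:
    """A contiguous chunk of ``size`` voxels inside one network, as flat indices."""
    rng = np.random.default_rng(seed)
    coords = np.argwhere(parcellation == network)
    if len(coords) < size:
        raise ValueError(f"network {network} has only {len(coords)} voxels (< {size})")
    from collections import deque
    start = tuple(coords[rng.integers(len(coords))])
    seen = {start}
    queue = deque([start])
    picked = []
    shape = parcellation.shape
    while queue and len(picked) < size:
        v = queue.popleft()
        picked.append(v)
        for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if all(0 <= w[a] < shape[a] for a in range(3)) and w not in seen \
                    and parcellation[w] == network:
                seen.add(w)
                queue.append(w)
    if len(picked) < size:   # component smaller than requested: top up randomly
        extra = [tuple(c) for c in coords if tuple(c) not in set(picked)]
        rng.shuffle(extra)
        picked += extra[:size - len(picked)]
    return coords_to_flat(np.array(picked), shape)


# ---------------------------------------------------------------------------
# covariance construction

def constrained_nearest_psd(target: np.ndarray, free: np.ndarray,
                            tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """PSD matrix matching ``target`` exactly on the non-free entries.

    Alternating projections between the PSD cone and the affine set that
    pins every fixed entry (diagonal included) to its target value; the
    free entries absorb the adjustment. The fixed set always contains a
    feasible point (the no-effect base matrix), so the iteration
    converges. Returns the PSD iterate once fixed-entry error < tol.
    """
    fixed = ~np.asarray(free, bool)
    np.fill_diagonal(fixed, True)
    x = np.asarray(target, float).copy()
    xp = x
    for _ in range(max_iter):
        w, v = np.linalg.eigh((x + x.T) / 2)
        xp = (v * np.maximum(w, 0.0)) @ v.T
        err = np.abs(xp[fixed] - target[fixed]).max()
        if err < tol:
            return xp
        x = xp.copy()
        x[fixed] = target[fixed]
    warnings.warn(f"constrained PSD repair stopped at error {err:.2e}")
    return xp


def nearest_correlation(a: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections."""
    y = np.asarray(a, float).copy()
    ds = np.zeros_like(y)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh((r + r.T) / 2)
        x = (v * np.maximum(w, 0)) @ v.T
        ds = x - r
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.abs(y - x).max() < tol and np.linalg.eigvalsh(y).min() > -tol:
            break
    w, v = np.linalg.eigh((y + y.T) / 2)
    y = (v * np.maximum(w, 1e-10)) @ v.T
    d = np.sqrt(np.diag(y))
    return y / np.outer(d, d)


def target_correlation(labels: np.ndarray, base_within: float, base_between: float,
                       region_mask_sets: list) -> np.ndarray:
    """Block correlation target plus effect deltas.

    ``labels`` is per-masked-voxel (0 = non-isocortical, treated as its own
    block); ``region_mask_sets`` holds (boolean in-region vector, mode,
    delta) triples already resolved for the subject at hand.
    """
    same = labels[:, None] == labels[None, :]
    r = np.where(same, base_within, base_between).astype(float)
    for in_region, mode, delta in region_mask_sets:
        touches = in_region[:, None] | in_region[None, :]
        if mode == BETWEEN_NETWORK_GAIN:
            sel = touches & ~same
        elif mode == WITHIN_NETWORK_GAIN:
            sel = touches & same
        else:
            sel = touches
        r = r + delta * sel
    r = np.clip(r, -0.99, 0.99)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2


def _free_edge_mask(labels: np.ndarray, resolved: list) -> np.ndarray | None:
    """Edge class allowed to absorb the PSD repair.

    A between-network effect must leave every within-network correlation
    untouched (and vice versa) or the uninvolved metric would show a
    spurious group difference; the repair therefore redistributes only
    within the touched edge class. Mixed/global effects free all edges.
    """
    modes = {m for _, m, _ in resolved}
    if not modes:
        return None
    same = labels[:, None] == labels[None, :]
    if modes == {BETWEEN_NETWORK_GAIN}:
        return ~same
    if modes == {WITHIN_NETWORK_GAIN}:
        free = same.copy()
        np.fill_diagonal(free, False)
        return free
    return ~np.eye(len(labels), dtype=bool)


def build_subject_target(labels: np.ndarray, base_within: float, base_between: float,
                         resolved: list) -> np.ndarray:
    """The correlation matrix a subject's signals are actually drawn from.

    The naive block-plus-delta target can lose positive semidefiniteness
    (a uniform correlation increase of one region to many voxels is not in
    general a valid correlation structure); when that happens the matrix is
    repaired by constrained projection and the *realized* effect can be
    smaller than ``delta_corr``. Tests should oracle against this matrix.
    """
    r = target_correlation(labels, base_within, base_between, resolved)
    if np.linalg.eigvalsh(r).min() > 1e-10:
        return r
    free = _free_edge_mask(labels, resolved)
    warnings.warn("target correlation not positive definite; repaired by "
                  "constrained PSD projection (realized deltas may shrink)")
    if free is None:
        return nearest_correlation(r)
    return constrained_nearest_psd(r, free)


def _cholesky_of(r: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(r + 1e-8 * np.eye(len(r)))


# ---------------------------------------------------------------------------
# subjects

def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(subject_id.encode())]))


def _standardized_covariate(record: SubjectRecord, name: str, pool_stats) -> float:
    val = getattr(record, name)
    if val is None:
        return 0.0
    mu, sd = pool_stats.get(name, (0.0, 1.0))
    return (float(val) - mu) / (sd if sd > 0 else 1.0)


def _resolve_effects(config, record, effect_specs, mask_flat, pool_stats) -> list:
    resolved = []
    for eff in effect_specs:
        if record.group != eff.target_group:
            continue
        delta = eff.delta_corr
        if eff.covariate_link is not None:
            name, slope = eff.covariate_link
            delta = delta + slope * _standardized_covariate(record, name, pool_stats)
        in_region = np.isin(mask_flat, eff.region)
        resolved.append((in_region, eff.mode, float(delta)))
    return resolved


def default_noise_rois(grid_shape, mask: np.ndarray) -> dict:
    """Two out-of-mask corner blocks standing in for lateral ventricles and
    white matter (the aCompCor nuisance sources)."""
    b = max(2, min(grid_shape) // 4)
    boxes = {"ventricle": tuple(slice(0, b) for _ in range(3)),
             "white_matter": tuple(slice(s - b, s) for s in grid_shape)}
    rois = {}
    for name, sl in boxes.items():
        block = np.zeros(grid_shape, dtype=bool)
        block[sl] = True
        block &= ~mask
        rois[name] = np.argwhere(block)
    return rois


def simulate_motion(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Mostly sub-threshold jitter plus ``n_motion_spikes`` translation steps
    exceeding the 0.5 mm FD threshold; rotations held at zero."""
    t = config.n_timepoints
    steps = rng.normal(0.0, 0.015, size=(t, 3))
    steps[0] = 0.0
    if config.n_motion_spikes > 0:
        spikes = rng.choice(np.arange(1, t), size=min(config.n_motion_spikes, t - 1),
                            replace=False)
        steps[spikes, 0] += config.spike_magnitude_mm * rng.choice([-1, 1], size=len(spikes))
    trans = np.cumsum(steps, axis=0)
    out = np.zeros((t, 6))
    out[:, :3] = trans
    return pd.DataFrame(out, columns=["tx", "ty", "tz", "rx", "ry", "rz"])


def simulate_subject(config: SyntheticConfig, parcellation: np.ndarray,
                     record: SubjectRecord, effect_specs, mask: np.ndarray | None = None,
                     noise_rois: dict | None = None, pool_stats: dict | None = None,
                     chol_cache: dict | None = None):
    """One subject's 4-D image and motion table.

    Deterministic under (config.seed, subject id). The in-mask correlation
    target is the network-block structure plus this subject's resolved
    effect deltas; the realized series get independent observation noise
    and a weak loading on the two nuisance-tissue factors (so confound
    regression has something real to remove).
    """
    if mask is None:
        mask = ellipsoid_mask(config.grid_shape)
    if noise_rois is None:
        noise_rois = default_noise_rois(config.grid_shape, mask)
    rng = _subject_rng(config.seed, record.id)
    coords = np.argwhere(mask)
    labels = parcellation[coords[:, 0], coords[:, 1], coords[:, 2]]
    mask_flat = coords_to_flat(coords, config.grid_shape)
    resolved = _resolve_effects(config, record, effect_specs, mask_flat, pool_stats or {})

    key = tuple((m, round(d, 9), in_r.tobytes()) for in_r, m, d in resolved)
    if chol_cache is not None and key in chol_cache:
        r = chol_cache[key]
    else:
        r = build_subject_target(labels, config.base_within_corr,
                                 config.base_between_corr, resolved)
        if chol_cache is not None:
            chol_cache[key] = r
    lo, hi = config.subject_scale_range
    g = float(rng.uniform(lo, hi))
    r_subj = g * r + (1 - g) * np.eye(len(r))
    chol = _cholesky_of(r_subj)
    t, v = config.n_timepoints, len(coords)
    signal = rng.standard_normal((t, v)) @ chol.T

    image = np.zeros(config.grid_shape + (t,), dtype=np.float32)
    # nuisance tissue factors; the first factor of each tissue leaks into the brain
    for tissue, roi in noise_rois.items():
        if len(roi) == 0:
            continue
        factors = rng.standard_normal((t, 5))
        load = rng.normal(0.0, 0.5, size=(5, len(roi)))
        series = factors @ load + rng.normal(0.0, 0.2, size=(t, len(roi)))
        image[roi[:, 0], roi[:, 1], roi[:, 2], :] = series.T.astype(np.float32)
        leak = rng.normal(0.0, config.nuisance_coupling, size=v)
        signal += np.outer(factors[:, 0], leak)

    signal += rng.normal(0.0, config.noise_sd, size=(t, v))
    image[coords[:, 0], coords[:, 1], coords[:, 2], :] = signal.T.astype(np.float32)
    motion = simulate_motion(config, rng)
    return image, motion


# ---------------------------------------------------------------------------
# cohorts

_COVARIATE_PARAMS = {
    # (age mean, age sd), P(female), P(ssri), sdq20 (mu, sd), phq15 (mu, sd)
    "FND": ((40, 13), 0.75, 0.38, (32, 8), (13, 5)),
    "PC": ((40, 13), 0.75, 0.40, (27, 6), (10, 4)),
    "HC": ((40, 13), 0.72, 0.03, (21, 2), (3, 2)),
}


def _draw_record(group: str, idx: int, rng: np.random.Generator) -> SubjectRecord:
    (age_mu, age_sd), p_f, p_ssri, sdq, phq = _COVARIATE_PARAMS[group]
    age = float(np.clip(rng.normal(age_mu, age_sd), 18, 80).round())
    sex = "F" if rng.random() < p_f else "M"
    ssri = bool(rng.random() < p_ssri)
    sdq20 = float(np.clip(rng.normal(*sdq), 20, 100).round())
    phq15 = float(np.clip(rng.normal(*phq), 0, 30).round())
    subtype = None
    if group == "FND":
        subtype = "motor" if rng.random() < 2 / 3 else "seiz"
    return SubjectRecord(id=f"{group}{idx:03d}", group=group, age=age, sex=sex,
                         ssri=ssri, sdq20=sdq20, phq15=phq15, subtype=subtype)


def make_subjects(config: SyntheticConfig) -> list:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    out = []
    for group, n in config.group_sizes.items():
        for i in range(n):
            out.append(_draw_record(group, i, rng))
    return out


def simulate_cohort(config: SyntheticConfig, subjects: list | None = None) -> SyntheticCohort:
    """Full cohort: parcellation, subjects with covariates, images, motion."""
    mask = ellipsoid_mask(config.grid_shape)
    parc = make_parcellation(config.grid_shape, config.n_networks, seed=config.seed,
                             mask=mask, zero_fraction=config.zero_fraction)
    noise_rois = default_noise_rois(config.grid_shape, mask)
    if subjects is None:
        subjects = make_subjects(config)
    pool_stats = {}
    for name in ("sdq20", "phq15", "age"):
        vals = np.array([getattr(s, name) for s in subjects
                         if getattr(s, name) is not None], dtype=float)
        if len(vals):
            pool_stats[name] = (float(vals.mean()), float(vals.std()))
    images, motions, cache = {}, {}, {}
    for rec in subjects:
        img, mot = simulate_subject(config, parc, rec, config.effect_spec, mask=mask,
                                    noise_rois=noise_rois, pool_stats=pool_stats,
                                    chol_cache=cache)
        images[rec.id] = img
        motions[rec.id] = mot
    return SyntheticCohort(images=images, motion_tables=motions, mask=mask,
                           parcellation=parc, subjects=subjects,
                           truth=list(config.effect_spec), noise_rois=noise_rois,
                           affine=default_affine(config.grid_shape), config=config)


def simulate_null_maps(group_sizes: dict, grid_shape, mask: np.ndarray | None = None,
                       smooth_sigma: float = 1.0, seed: int = 0):
    """Map-level null cohort: per-subject normalized maps with no group effect.

    Each map is spatially smoothed white noise (Gaussian kernel,
    ``smooth_sigma`` voxels — the mild smoothness real normalized maps carry)
    standardized to unit variance. Returns (values n_subjects x n_voxels,
    subjects, voxel_index).
    """
    from scipy.ndimage import gaussian_filter
    if mask is None:
        mask = ellipsoid_mask(grid_shape)
    coords = np.argwhere(mask)
    rng = np.random.default_rng(seed)
    subjects, rows = [], []
    for group, n in group_sizes.items():
        for i in range(n):
            rec = _draw_record(group, i, rng)
            field3d = gaussian_filter(rng.standard_normal(grid_shape), smooth_sigma)
            vals = field3d[coords[:, 0], coords[:, 1], coords[:, 2]]
            rows.append((vals - vals.mean()) / vals.std())
            subjects.append(rec)
    return np.vstack(rows), subjects, coords


def simulate_symptom_link(n_subjects: int, slope: float = 0.05, noise_sd: float = 1.2,
                          seed: int = 0):
    """Cluster-mean connectivity values with a monotone somatic-symptom link.

    PHQ-15 scores are drawn on their 0-30 scale; the cluster-mean
    (HC-normalized) connectivity value is ``slope * phq15`` plus Gaussian
    noise. The defaults give a moderate monotone association
    (population Spearman rho ~ 0.35, the size of reported cluster-symptom
    correlations); ``slope=0`` gives the null. Returns (phq15, values).
    """
    rng = np.random.default_rng(seed)
    phq = np.clip(np.round(rng.normal(11, 9, size=n_subjects)), 0, 30)
    values = slope * phq + rng.normal(0.0, noise_sd, size=n_subjects)
    return phq, values


# ---------------------------------------------------------------------------
# persistence

def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write the cohort as NIfTI + TSV + JSON; returns a path manifest."""
    import nibabel as nib
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = cohort.affine
    manifest = {"images": {}, "motion": {}}
    for sid, img in cohort.images.items():
        p = out / f"{sid}_bold.nii"
        nib.save(nib.Nifti1Image(np.asarray(img, np.float32), aff), p)
        manifest["images"][sid] = str(p)
        m = out / f"{sid}_motion.tsv"
        cohort.motion_tables[sid].to_csv(m, sep="\t", index=False)
        manifest["motion"][sid] = str(m)
    for name, vol, dt in (("mask", cohort.mask, np.uint8),
                          ("parcellation", cohort.parcellation, np.int16)):
        p = out / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(vol, dt), aff), p)
        manifest[name] = str(p)
    subj = pd.DataFrame([{"id": s.id, "group": s.group, "subtype": s.subtype or "",
                          "age": s.age, "sex": s.sex, "ssri": int(s.ssri),
                          "sdq20": s.sdq20, "phq15": s.phq15} for s in cohort.subjects])
    p = out / "subjects.tsv"
    subj.to_csv(p, sep="\t", index=False)
    manifest["subjects"] = str(p)
    p = out / "truth.json"
    p.write_text(json.dumps([e.to_dict() for e in cohort.truth], indent=1))
    manifest["truth"] = str(p)
    p = out / "config.json"
    p.write_text(json.dumps(cohort.config.to_dict(), indent=1))
    manifest["config"] = str(p)
    rois = {k: v.tolist() for k, v in cohort.noise_rois.items()}
    p = out / "noise_rois.json"
    p.write_text(json.dumps(rois))
    manifest["noise_rois"] = str(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_truth(path) -> list:
    return [EffectSpec.from_dict(d) for d in json.loads(Path(path).read_text())]
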