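"""Self-contained property benchmarks.

Because the clinical data behind the original analysis are not public, the
pipeline's correctness is demonstrated on properties that carry their own
ground truth: the exact integration + segregation = weighted-degree
decomposition, the healthy-control normalization audit, familywise error
control of the clusterwise permutation correction under the global null,
recovery/dissociation of injected between- vs within-network effects, and
the power/size of the cluster-mean symptom correlation. Each function here
recomputes its quantity from scratch by running the package; the test
suite asserts on these numbers and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import connectivity as conn
from . import inference, metrics, symptoms
from .grid import coords_to_flat
from .pipeline import Dataset, PipelineParams, inference_stage, metrics_stage, \
    prep_stage, qc_normalize_stage
from .synthetic import EffectSpec, SyntheticConfig, make_parcellation, \
    pick_effect_region, simulate_cohort, simulate_null_maps, simulate_symptom_link


def _random_isocortical_matrix(rng, n_min=50, n_max=500, n_networks=7):
    n = int(rng.integers(n_min, n_max + 1))
    a = rng.random((n, n))
    w = np.triu(a, 1)
    w = w + w.T
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    cm = conn.ConnectivityMatrix(w, coords, scope=conn.ISOCORTICAL)
    labels = rng.integers(1, n_networks + 1, size=n)
    return cm, metrics.NetworkAssignment(labels)


def decomposition_error(n_matrices: int = 200, seed: int = 0) -> float:
    """Max elementwise |integration + segregation - weighted_degree| over
    random isocortical matrices with random seven-network labels."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        cm, assign = _random_isocortical_matrix(rng)
        wd = metrics.weighted_degree(cm).values
        tot = metrics.integration(cm, assign).values + \
            metrics.segregation(cm, assign).values
        worst = max(worst, float(np.abs(tot - wd).max()))
    return worst


def toy_graph_values() -> dict:
    """The 3-voxel worked example: w(A,B)=0.5, w(A,C)=0.3, w(B,C)=0.2,
    A and B in one network, C in another."""
    w = np.array([[0.0, 0.5, 0.3], [0.5, 0.0, 0.2], [0.3, 0.2, 0.0]])
    coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    cm = conn.ConnectivityMatrix(w, coords, scope=conn.ISOCORTICAL)
    assign = metrics.NetworkAssignment([1, 1, 2])
    return {
        "weighted_degree": metrics.weighted_degree(cm).values,
        "integration": metrics.integration(cm, assign).values,
        "segregation": metrics.segregation(cm, assign).values,
    }


def _cohort_to_dataset(cohort) -> Dataset:
    return Dataset(images=cohort.images, motion=cohort.motion_tables,
                   mask=cohort.mask, parcellation=cohort.parcellation,
                   affine=cohort.affine, subjects=cohort.subjects,
                   tr_seconds=cohort.config.tr_seconds,
                   noise_rois=cohort.noise_rois)


def hc_normalization_audit(n_hc: int = 30, grid_shape=(10, 10, 10), seed: int = 0):
    """(max |HC per-voxel mean|, max |HC per-voxel SD - 1|) after the full
    simulate -> prep -> connectivity -> metrics -> normalize chain."""
    cfg = SyntheticConfig(grid_shape=grid_shape, group_sizes={"HC": n_hc}, seed=seed)
    ds = _cohort_to_dataset(simulate_cohort(cfg))
    params = PipelineParams(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cleaned, subjects = prep_stage(ds, params)
        values, iso_index, wb_index, _, ids = metrics_stage(cleaned, ds)
        norm, survivors, _ = qc_normalize_stage(values, subjects, ids, params)
    worst_mean = worst_sd = 0.0
    hc_rows = np.array([s.group == "HC" for s in survivors])
    for vals in norm.values():
        hc = vals[hc_rows]
        worst_mean = max(worst_mean, float(np.abs(hc.mean(axis=0)).max()))
        worst_sd = max(worst_sd, float(np.abs(hc.std(axis=0, ddof=1) - 1).max()))
    return worst_mean, worst_sd


def familywise_error(n_cohorts: int = 500, n_per_group: int = 30,
                     grid_shape=(12, 12, 12), n_iter: int = 1000,
                     seed: int = 0) -> float:
    """Fraction of simulated null cohorts in which any cluster survives the
    permutation clusterwise correction (nominal 0.05)."""
    rng = np.random.default_rng(seed)
    design = inference.DesignSpec(("FND", "PC"))
    hits = 0
    for _ in range(n_cohorts):
        s1, s2 = int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))
        vals, subjects, coords = simulate_null_maps(
            {"FND": n_per_group, "PC": n_per_group}, grid_shape, seed=s1)
        res = inference.run_group_inference(vals, subjects, design, coords,
                                            grid_shape, n_iter=n_iter, seed=s2)
        if res.corrected_mask.any():
            hits += 1
    return hits / n_cohorts


def effect_recovery(mode: str, delta: float = 0.2, region_size: int = 100,
                    n_per_group: int = 30, grid_shape=(12, 12, 12),
                    n_iter: int = 1000, seed: int = 0) -> dict:
    """End-to-end recovery of an injected connectivity effect.

    Returns the fraction of the true region covered by corrected clusters
    of the affected metric, and the corrected-voxel count and region
    overlap of the complementary metric (which the effect must not touch).
    """
    affected = metrics.INTEGRATION if mode == "between_network_gain" \
        else metrics.SEGREGATION
    other = metrics.SEGREGATION if affected == metrics.INTEGRATION \
        else metrics.INTEGRATION
    parc = make_parcellation(grid_shape, 7, seed=seed, zero_fraction=0.1)
    region = pick_effect_region(parc, network=2, size=region_size, seed=seed)
    eff = EffectSpec("FND", region, mode, delta)
    cfg = SyntheticConfig(grid_shape=grid_shape, seed=seed, effect_spec=[eff],
                          group_sizes={"FND": n_per_group, "PC": n_per_group,
                                       "HC": n_per_group})
    ds = _cohort_to_dataset(simulate_cohort(cfg))
    params = PipelineParams(n_iter=n_iter, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cleaned, subjects = prep_stage(ds, params)
        values, iso_index, wb_index, _, ids = metrics_stage(cleaned, ds)
        norm, survivors, _ = qc_normalize_stage(values, subjects, ids, params)
        results = inference_stage(norm, survivors, iso_index, wb_index,
                                  ds.mask.shape, params)
    iso_flat = coords_to_flat(iso_index, grid_shape)
    in_region = np.isin(iso_flat, region)
    aff_mask = results[affected].corrected_mask
    oth_mask = results[other].corrected_mask
    return {
        "coverage": float((aff_mask & in_region).sum() / in_region.sum()),
        "other_corrected_voxels": int(oth_mask.sum()),
        "other_region_overlap": float((oth_mask & in_region).sum() / in_region.sum()),
    }


def symptom_power(n_subjects: int = 100, n_reps: int = 500, slope: float = 0.05,
                  alpha: float = 0.05, seed: int = 0):
    """(power at the default monotone link, type-I rate under the null) of
    the IQR-filtered Spearman correlation."""
    rng = np.random.default_rng(seed)

    def rate(s):
        rej = 0
        for _ in range(n_reps):
            phq, vals = simulate_symptom_link(n_subjects, slope=s,
                                              seed=int(rng.integers(2 ** 31)))
            keep = symptoms.iqr_outlier_filter(vals)
            _, p = symptoms.spearman(vals[keep], phq[keep])
            if p < alpha:
                rej += 1
        return rej / n_reps

    return rate(slope), rate(0.0)
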