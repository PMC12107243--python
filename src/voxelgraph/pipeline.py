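"""End-to-end orchestration of the analysis stages.

The on-disk layout produced by ``synthetic.write_cohort`` (or arranged the
same way for real data) is consumed stage by stage:

    prep          cleaned 120-volume series per subject (+ exclusion log)
    connectivity  per-subject edge matrices (in memory; optionally on disk)
    metrics       weighted-degree / integration / segregation maps
    qc/normalize  weighted-degree outlier QC, age+sex removal, HC z-scoring
    glm/cluster   FND vs PC contrasts with Monte Carlo clusterwise correction
    seed          integration-peak seed connectivity + network composition
    correlate     cluster-mean symptom correlations with FDR

``run_pipeline`` chains everything and writes the reportable artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import inference, metrics, normalization, seeds, symptoms
from .io import cluster_table, load_volume, read_subjects_tsv, save_map, save_table, \
    write_provenance
from .prep import Exclusion, preprocess_subject

log = logging.getLogger("voxelgraph")


@dataclass
class PipelineParams:
    """Stage parameters; defaults follow the published analysis."""

    fd_threshold_mm: float = 0.5
    n_volumes: int = 120
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    cluster_forming_z: float = 1.96
    n_iter: int = 10_000
    alpha: float = 0.05
    connectivity: int = 26
    seed: int = 0
    contrast: tuple = ("FND", "PC")
    covariates: tuple = ("ssri",)
    residual_covariates: tuple = ("age", "sex")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


@dataclass
class Dataset:
    images: dict
    motion: dict
    mask: np.ndarray
    parcellation: np.ndarray
    affine: np.ndarray
    subjects: list
    tr_seconds: float
    noise_rois: dict = field(default_factory=dict)


def load_dataset(data_dir) -> Dataset:
    d = Path(data_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    mask, affine = load_volume(manifest["mask"])
    parc, _ = load_volume(manifest["parcellation"])
    subjects = read_subjects_tsv(manifest["subjects"])
    cfg = json.loads((d / "config.json").read_text()) if (d / "config.json").exists() else {}
    tr = float(cfg.get("tr_seconds", 2.0))
    rois = {}
    roi_path = d / "noise_rois.json"
    if roi_path.exists():
        rois = {k: np.asarray(v, int) for k, v in json.loads(roi_path.read_text()).items()}
    images = {sid: load_volume(p)[0] for sid, p in manifest["images"].items()}
    motion = {sid: pd.read_csv(p, sep="\t") for sid, p in manifest["motion"].items()}
    return Dataset(images=images, motion=motion, mask=mask.astype(bool),
                   parcellation=np.asarray(parc, int), affine=affine,
                   subjects=subjects, tr_seconds=tr, noise_rois=rois)


def prep_stage(ds: Dataset, params: PipelineParams):
    """Clean every subject; returns ({id: VoxelTimeSeries}, updated subjects)."""
    cleaned, updated = {}, []
    for s in ds.subjects:
        result = preprocess_subject(ds.images[s.id], ds.mask, ds.motion[s.id],
                                    ds.tr_seconds, noise_rois=ds.noise_rois,
                                    n_volumes=params.n_volumes)
        if isinstance(result, Exclusion):
            log.info("subject %s excluded: %s (%s)", s.id, result.reason, result.detail)
            updated.append(s.exclude(result.reason))
        else:
            cleaned[s.id] = result
            updated.append(s)
    return cleaned, updated


def metrics_stage(cleaned: dict, ds: Dataset):
    """Connectivity + graph metrics for every cleaned subject.

    Returns (metric name -> subjects x voxels array over included subjects,
    isocortical voxel_index, whole-brain voxel_index, NetworkAssignment,
    ordered included ids).
    """
    ids = list(cleaned)
    wb_rows, iso_rows = [], []
    assignment = None
    iso_index = wb_index = None
    for sid in ids:
        ts = cleaned[sid]
        cm = conn.remove_negatives(conn.pearson_matrix(ts))
        cm_iso, labels = conn.restrict_isocortex(cm, ds.parcellation)
        if assignment is None:
            assignment = metrics.NetworkAssignment(labels)
            iso_index = cm_iso.voxel_index
            wb_index = cm.voxel_index
        wb_rows.append(metrics.weighted_degree(cm, sid).values)
        iso_rows.append((metrics.integration(cm_iso, assignment, sid).values,
                         metrics.segregation(cm_iso, assignment, sid).values))
    values = {
        metrics.WEIGHTED_DEGREE: np.vstack(wb_rows),
        metrics.INTEGRATION: np.vstack([r[0] for r in iso_rows]),
        metrics.SEGREGATION: np.vstack([r[1] for r in iso_rows]),
    }
    return values, iso_index, wb_index, assignment, ids


def qc_normalize_stage(values: dict, subjects: list, ids: list,
                       params: PipelineParams):
    """WD outlier QC, then age/sex removal and HC normalization per metric.

    Returns (metric -> normalized subjects x voxels over surviving subjects,
    surviving subject records in row order, updated full subject list).
    """
    by_id = {s.id: s for s in subjects}
    wd = values[metrics.WEIGHTED_DEGREE]
    wd_maps = {sid: wd[i] for i, sid in enumerate(ids)}
    updated = normalization.wd_outlier_qc([by_id[sid] for sid in ids], wd_maps)
    survivors = [s for s in updated if s.included]
    surv_rows = [ids.index(s.id) for s in survivors]
    out = {}
    for name, vals in values.items():
        z, _ = normalization.normalize_maps(vals[surv_rows], survivors,
                                            covariates=params.residual_covariates)
        out[name] = z
    all_updated = [next((u for u in updated if u.id == s.id), s) for s in subjects]
    return out, survivors, all_updated


def inference_stage(norm_values: dict, survivors: list, iso_index, wb_index,
                    grid_shape, params: PipelineParams) -> dict:
    """FND-vs-PC corrected contrast per metric."""
    design = inference.DesignSpec(contrast=params.contrast,
                                  covariates=params.covariates)
    results = {}
    for i, (name, vals) in enumerate(norm_values.items()):
        vindex = wb_index if name == metrics.WEIGHTED_DEGREE else iso_index
        results[name] = inference.run_group_inference(
            vals, survivors, design, vindex, grid_shape,
            n_iter=params.n_iter, seed=params.seed + 1000 + i,
            threshold=params.cluster_forming_z, alpha=params.alpha,
            connectivity=params.connectivity)
    return results


def seed_stage(cleaned: dict, survivors: list, results: dict, assignment,
               iso_index, ds: Dataset, params: PipelineParams):
    """Integration-peak seeds, seed-to-voxel GLM, network composition."""
    integ = results[metrics.INTEGRATION]
    corrected = integ.corrected_mask
    peaks = seeds.find_peaks(integ.zmap, iso_index, corrected,
                             np.ones_like(corrected, bool), ds.affine)
    out = {}
    iso_set = {tuple(c) for c in iso_index}
    for j, (side, peak) in enumerate(sorted(peaks.items())):
        roi = seeds.build_seed(peak, ds.mask, hemisphere=side)
        maps, tgt_idx = None, None
        rows = []
        for s in survivors:
            ts = cleaned[s.id]
            selector = np.array([tuple(c) in iso_set for c in ts.voxel_index])
            z, tgt_idx = seeds.seed_to_voxel(ts, roi, selector)
            rows.append(z)
        maps = np.vstack(rows)
        tgt_coords = cleaned[survivors[0].id].voxel_index[tgt_idx]
        lbl = ds.parcellation[tgt_coords[:, 0], tgt_coords[:, 1], tgt_coords[:, 2]]
        seed_net = int(ds.parcellation[peak])
        design = inference.DesignSpec(contrast=params.contrast,
                                      covariates=params.covariates)
        res, comp = seeds.seed_glm_and_compose(
            maps, survivors, design, lbl, seed_net, tgt_coords, ds.mask.shape,
            n_iter=params.n_iter, seed=params.seed + 2000 + j,
            network_names=assignment.names)
        out[side] = {"roi": roi, "result": res, "composition": comp,
                     "target_coords": tgt_coords}
    return out


def run_pipeline(ds: Dataset, params: PipelineParams, out_dir) -> dict:
    """Everything, with artifacts written under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = params.to_dict()

    cleaned, subjects = prep_stage(ds, params)
    excl = pd.DataFrame([{"id": s.id, "reason": s.exclusion_reason}
                         for s in subjects if not s.included])
    save_table(excl if len(excl) else pd.DataFrame(columns=["id", "reason"]),
               out / "exclusions.tsv", "prep", p)

    values, iso_index, wb_index, assignment, ids = metrics_stage(cleaned, ds)
    norm_values, survivors, subjects = qc_normalize_stage(values, subjects, ids, params)
    excl2 = pd.DataFrame([{"id": s.id, "reason": s.exclusion_reason}
                          for s in subjects if not s.included])
    save_table(excl2 if len(excl2) else pd.DataFrame(columns=["id", "reason"]),
               out / "qc_exclusions.tsv", "qc", p)

    results = inference_stage(norm_values, survivors, iso_index, wb_index,
                              ds.mask.shape, params)
    clusters_by_metric = {}
    for name, res in results.items():
        vindex = wb_index if name == metrics.WEIGHTED_DEGREE else iso_index
        save_map(res.zmap, vindex, ds.mask.shape, ds.affine,
                 out / f"zmap_{name}.nii", "glm", p)
        save_table(cluster_table(res), out / f"clusters_{name}.tsv", "cluster", p)
        clusters_by_metric[name] = [c for c in res.clusters
                                    if c.p_corrected is not None
                                    and c.p_corrected < params.alpha]

    seed_out = seed_stage(cleaned, survivors, results, assignment, iso_index, ds, params)
    seed_report = {}
    for side, info in seed_out.items():
        comp = info["composition"]
        seed_report[side] = {
            "centre": [int(v) for v in info["roi"].centre],
            "n_members": info["roi"].n_members,
            "excluded_network": comp.excluded_network,
            "n_significant": comp.n_significant,
            "percents": {k: round(v, 2) for k, v in comp.percents.items()},
        }
    (out / "seeds.json").write_text(json.dumps(seed_report, indent=1))

    corr = symptoms.run_symptom_correlations(norm_values, survivors, clusters_by_metric)
    save_table(symptoms.results_table(corr), out / "correlations.tsv", "correlate", p)

    (out / "resolved_config.json").write_text(json.dumps(p, indent=1))
    write_provenance(out / "resolved_config.json", "run-all", p)
    return {"out_dir": str(out), "n_included": len(survivors),
            "n_excluded": sum(not s.included for s in subjects),
            "results": results, "seeds": seed_out, "correlations": corr,
            "norm_values": norm_values, "survivors": survivors,
            "iso_index": iso_index, "wb_index": wb_index}
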