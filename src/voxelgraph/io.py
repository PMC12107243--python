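"""File formats and provenance.

NIfTI-1 for volumes, TSV for tables, JSON for configuration and manifests.
Every artifact written by a pipeline stage gets a JSON sidecar carrying the
stage name, the resolved-parameter hash and the package version, so a run
can always be traced back to its configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .grid import scatter_to_grid
from .normalization import SubjectRecord


def config_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, stage: str, params: dict):
    side = Path(str(path) + ".json")
    side.write_text(json.dumps({"stage": stage, "config_hash": config_hash(params),
                                "software": f"voxelgraph {__version__}"}, indent=1))


def save_volume(data: np.ndarray, affine: np.ndarray, path, stage: str = "",
                params: dict | None = None):
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    if stage:
        write_provenance(path, stage, params or {})


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_map(values: np.ndarray, voxel_index: np.ndarray, grid_shape, affine, path,
             stage: str = "map", params: dict | None = None):
    vol = scatter_to_grid(np.asarray(values, float), np.asarray(voxel_index),
                          tuple(grid_shape), fill=0.0)
    save_volume(vol.astype(np.float32), affine, path, stage, params)


def save_table(df: pd.DataFrame, path, stage: str = "", params: dict | None = None):
    df.to_csv(str(path), sep="\t", index=False)
    if stage:
        write_provenance(path, stage, params or {})


def read_subjects_tsv(path) -> list:
    df = pd.read_csv(str(path), sep="\t")
    recs = []
    for _, row in df.iterrows():
        recs.append(SubjectRecord(
            id=str(row["id"]), group=str(row["group"]), age=float(row["age"]),
            sex=str(row["sex"]), ssri=bool(int(row["ssri"])),
            sdq20=None if pd.isna(row.get("sdq20")) else float(row["sdq20"]),
            phq15=None if pd.isna(row.get("phq15")) else float(row["phq15"]),
            subtype=(str(row["subtype"]) if "subtype" in row and
                     isinstance(row["subtype"], str) and row["subtype"] else None)))
    return recs


def cluster_table(result) -> pd.DataFrame:
    """TSV-ready summary: id, sign, extent, peak z, peak coordinate, p."""
    rows = []
    for i, c in enumerate(result.clusters):
        rows.append({"cluster": i, "sign": c.sign, "extent": c.extent,
                     "peak_z": round(c.peak_z, 6),
                     "peak_i": c.peak_coord[0], "peak_j": c.peak_coord[1],
                     "peak_k": c.peak_coord[2],
                     "p_corrected": c.p_corrected})
    return pd.DataFrame(rows, columns=["cluster", "sign", "extent", "peak_z",
                                       "peak_i", "peak_j", "peak_k", "p_corrected"])
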