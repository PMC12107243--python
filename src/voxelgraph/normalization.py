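"""Subject bookkeeping, covariate residualization and HC normalization.

Metric maps are compared between patient cohorts (FND vs. psychiatric
controls) but interpreted on the healthy-control scale: after removing age
and sex with a per-voxel general linear model, every subject's map is
z-scored against the healthy controls' per-voxel mean and standard
deviation. Subject-level QC runs in a fixed order — motion exclusion first
(done upstream by volume selection), then the weighted-degree outlier rule
(mean whole-brain weighted-degree outside the 1.5 x IQR Tukey fences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .metrics import MetricMap

GROUPS = ("FND", "PC", "HC")
INCLUDED = "included"
EXCLUDED = "excluded"


@dataclass
class SubjectRecord:
    """Group membership, covariates, symptom scores and QC status."""

    id: str
    group: str                      # FND | PC | HC
    age: float
    sex: str                        # F | M
    ssri: bool = False
    sdq20: float | None = None
    phq15: float | None = None
    subtype: str | None = None      # motor | seiz (FND only)
    qc_status: str = INCLUDED
    exclusion_reason: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")

    @property
    def included(self) -> bool:
        return self.qc_status == INCLUDED

    def exclude(self, reason: str) -> "SubjectRecord":
        return replace(self, qc_status=EXCLUDED, exclusion_reason=reason)


def included_subjects(subjects) -> list:
    return [s for s in subjects if s.included]


def tukey_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """(lower, upper) fences at Q1 - k*IQR and Q3 + k*IQR.

    Quartiles use linear interpolation (type-7), numpy's default.
    """
    q1, q3 = np.percentile(np.asarray(values, float), [25, 75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def wd_outlier_qc(subjects, wd_maps: dict) -> list:
    """Flag subjects whose mean whole-brain weighted-degree is an outlier.

    The statistic is the mean of the whole-brain weighted-degree map;
    fences are pooled over all currently included subjects. Comparison is
    strict, so a zero IQR excludes nobody. With fewer than 4 subjects
    quartiles are unstable and QC is skipped with a warning.
    """
    inc = included_subjects(subjects)
    stats = {s.id: float(np.mean(np.asarray(wd_maps[s.id].values
                                            if isinstance(wd_maps[s.id], MetricMap)
                                            else wd_maps[s.id])))
             for s in inc}
    if len(inc) < 4:
        warnings.warn("fewer than 4 subjects: weighted-degree outlier QC skipped")
        return list(subjects)
    lo, hi = tukey_fences(np.array(list(stats.values())))
    out = []
    for s in subjects:
        if s.included and not (lo <= stats[s.id] <= hi) and \
                (stats[s.id] < lo or stats[s.id] > hi):
            out.append(s.exclude("wd_outlier"))
        else:
            out.append(s)
    return out


def _design(subjects, covariates=("age", "sex")) -> np.ndarray:
    cols = [np.ones(len(subjects))]
    for c in covariates:
        if c == "sex":
            v = np.array([1.0 if s.sex == "M" else 0.0 for s in subjects])
        elif c == "ssri":
            v = np.array([1.0 if s.ssri else 0.0 for s in subjects])
        else:
            v = np.array([float(getattr(s, c)) for s in subjects])
        if np.ptp(v) == 0:
            warnings.warn(f"constant covariate {c!r} dropped")
            continue
        cols.append(v)
    return np.column_stack(cols)


def residualize_covariates(values: np.ndarray, subjects,
                           covariates=("age", "sex"), hc_only: bool = False) -> np.ndarray:
    """Per-voxel OLS residuals of map values on [1, covariates...].

    ``values`` is subjects x voxels (rows aligned with ``subjects``, all
    QC-included). The model is fitted on the pooled sample by default; with
    ``hc_only`` the coefficients are estimated on healthy controls and the
    fitted effect removed from everyone.
    """
    y = np.asarray(values, float)
    if y.shape[0] != len(subjects):
        raise ValueError("one row per subject required")
    x = _design(subjects, covariates)
    if hc_only:
        rows = np.array([s.group == "HC" for s in subjects])
        beta, *_ = np.linalg.lstsq(x[rows], y[rows], rcond=None)
    else:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def normalize_to_hc(values: np.ndarray, subjects, ddof: int = 1):
    """Z-score every subject's map against the HC per-voxel mean and SD.

    SD uses the sample (n-1) denominator. Voxels with zero HC SD are set to
    0 for all subjects and returned as flagged indices.
    Returns (normalized values, flagged voxel indices).
    """
    y = np.asarray(values, float)
    hc_rows = np.array([s.group == "HC" for s in subjects])
    if hc_rows.sum() < 2:
        raise ValueError("need at least 2 included HC subjects to normalize")
    mu = y[hc_rows].mean(axis=0)
    sd = y[hc_rows].std(axis=0, ddof=ddof)
    flagged = np.flatnonzero(sd == 0)
    if flagged.size:
        warnings.warn(f"{flagged.size} voxel(s) with zero HC SD set to 0")
    safe = np.where(sd == 0, 1.0, sd)
    z = (y - mu) / safe
    z[:, flagged] = 0.0
    return z, flagged


def normalize_maps(values: np.ndarray, subjects, covariates=("age", "sex"),
                   hc_only: bool = False):
    """Residualize age/sex then HC-normalize; the standard two-step."""
    resid = residualize_covariates(values, subjects, covariates, hc_only=hc_only)
    return normalize_to_hc(resid, subjects)
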