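"""Cluster-mean symptom correlations.

For every significant cluster, each subject's mean normalized metric value
is correlated (Spearman) with symptom scores: conversion/dissociation
severity (SDQ-20) and somatic symptom burden (PHQ-15) within the FND
cohorts, and PHQ-15 only across combined FND + psychiatric-control
samples. Metric-value outliers beyond the 1.5 x IQR fences are removed
before correlating (symptom scores are not filtered); missing scores drop
pairwise. False-discovery-rate control is Benjamini-Hochberg within each
(cohort pair, metric) family.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import tukey_fences

# the documented cohort combinations: symptom scores within FND cohorts,
# PHQ-15 only for combined FND + PC samples
DEFAULT_COMBINATIONS = (
    ("FND", ("sdq20", "phq15")),
    ("motor", ("sdq20", "phq15")),
    ("seiz", ("sdq20", "phq15")),
    ("FND+PC", ("phq15",)),
    ("motor+PC", ("phq15",)),
    ("seiz+PC", ("phq15",)),
)


@dataclass
class CorrelationResult:
    cohort: str
    metric: str
    cluster_id: int
    score: str
    n: int
    rho: float
    p_raw: float
    p_fdr: float | None = None


def cluster_means(values: np.ndarray, subjects, clusters) -> pd.DataFrame:
    """Mean normalized value over each cluster's voxels, per subject.

    ``values`` is subjects x voxels (QC-included subjects only). Empty
    clusters are skipped with a warning.
    """
    rows = []
    for cid, c in enumerate(clusters):
        idx = np.asarray(c.voxels if hasattr(c, "voxels") else c, dtype=int)
        if idx.size == 0:
            warnings.warn(f"cluster {cid} is empty; skipped")
            continue
        means = np.asarray(values, float)[:, idx].mean(axis=1)
        for s, m in zip(subjects, means):
            rows.append({"subject": s.id, "cluster": cid, "value": float(m)})
    return pd.DataFrame(rows)


def iqr_outlier_filter(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean keep-mask: True where the value lies inside the Tukey fences.

    Fewer than 4 values: nothing is filtered (quartiles too unstable)."""
    v = np.asarray(values, float)
    if v.size < 4:
        warnings.warn("fewer than 4 values: outlier filtering skipped")
        return np.ones(v.size, dtype=bool)
    lo, hi = tukey_fences(v, k)
    return (v >= lo) & (v <= hi)


def spearman(x, y, exact: bool = False):
    """Spearman rho with mid-ranks and a t-approximation p value.

    Pairs with a missing value are dropped; fewer than 4 complete pairs is
    an error. ``exact=True`` (n <= 10 only) enumerates all permutations of
    one variable for the p value instead of the t approximation — exact but
    combinatorial, so slow as n approaches 10. Zero rank variance yields
    (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
        obs = abs(rxc @ ryc)
        count = total = 0
        for perm in itertools.permutations(ryc):
            total += 1
            if abs(rxc @ np.asarray(perm)) >= obs - 1e-12:
                count += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1 - rho ** 2, 1e-300))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fdr_correct(results: list) -> list:
    """BH within each (cohort, metric) family; NaN p values pass through."""
    by_family: dict = {}
    for r in results:
        by_family.setdefault((r.cohort, r.metric), []).append(r)
    for fam in by_family.values():
        idx = [i for i, r in enumerate(fam) if not math.isnan(r.p_raw)]
        adj = bh_adjust(np.array([fam[i].p_raw for i in idx]))
        for i, a in zip(idx, adj):
            fam[i].p_fdr = float(a)
    return results


def _cohort_members(subjects, cohort: str):
    parts = cohort.split("+")
    out = []
    for s in subjects:
        for p in parts:
            if s.group == p or (s.group == "FND" and s.subtype == p):
                out.append(s)
                break
    return out


def run_symptom_correlations(metric_values: dict, subjects, clusters_by_metric: dict,
                             combinations=DEFAULT_COMBINATIONS,
                             exact: bool = False) -> list:
    """All documented cohort x score x cluster correlations, FDR-corrected.

    ``metric_values`` maps metric name -> subjects x voxels array (rows
    aligned with ``subjects``); ``clusters_by_metric`` maps metric name ->
    list of significant clusters. The IQR filter applies to the
    connectivity variable only, per cluster x metric x cohort pair.
    """
    id_row = {s.id: i for i, s in enumerate(subjects)}
    results = []
    for cohort, scores in combinations:
        members = _cohort_members(subjects, cohort)
        if len(members) < 4:
            continue
        rows = np.array([id_row[s.id] for s in members])
        for metric, clusters in clusters_by_metric.items():
            if metric not in metric_values:
                continue
            vals = np.asarray(metric_values[metric], float)
            for cid, c in enumerate(clusters):
                idx = np.asarray(c.voxels if hasattr(c, "voxels") else c, dtype=int)
                if idx.size == 0:
                    continue
                cm = vals[np.ix_(rows, idx)].mean(axis=1)
                keep = iqr_outlier_filter(cm)
                for score in scores:
                    sy = np.array([float(s.__dict__[score]) if s.__dict__[score]
                                   is not None else np.nan for s in members])
                    xk, yk = cm[keep], sy[keep]
                    if (~np.isnan(yk)).sum() < 4:
                        continue
                    rho, p = spearman(xk, yk, exact=exact)
                    results.append(CorrelationResult(
                        cohort=cohort, metric=metric, cluster_id=cid, score=score,
                        n=int((~np.isnan(yk)).sum()), rho=rho, p_raw=p))
    return fdr_correct(results)


def results_table(results: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "cohort": r.cohort, "metric": r.metric, "cluster": r.cluster_id,
        "score": r.score, "n": r.n, "rho": r.rho, "p_raw": r.p_raw,
        "p_fdr": r.p_fdr} for r in results])
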