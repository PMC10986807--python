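"""Normalization and imputation of the protein intensity matrix.

The screen downstream assumes a complete, log2-scale, sample-median-centred
matrix. This module provides:

* ``log2_transform`` — raw positive intensities to log2 (refuses to run twice);
* ``median_normalize`` — per-sample additive shift so every sample's median
  equals the grand median of sample medians (rank-preserving within sample);
* ``drop_sparse_proteins`` — guard removing proteins missing in more than a
  configurable fraction of samples before imputation;
* ``impute_missing`` — half-minimum (left-censoring-aware) or k-nearest-
  neighbour imputation, with per-cell provenance codes.

kNN imputation fills a missing cell with the mean of the k nearest samples
(Euclidean distance over co-observed proteins) that observed that protein;
cells with fewer than k such neighbours fall back to half-minimum and are
logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import ProteinMatrix

log = logging.getLogger(__name__)


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Replace observed raw intensities by their log2."""
    if matrix.log2:
        raise ValueError("matrix is already log2-transformed")
    vals = matrix.values.to_numpy()
    observed = ~np.isnan(vals)
    if np.any(vals[observed] <= 0):
        raise ValueError("non-positive observed intensity; cannot log-transform")
    out = matrix.copy()
    logged = np.full_like(vals, np.nan)
    np.log2(vals, out=logged, where=observed)
    out.values = pd.DataFrame(logged, index=matrix.values.index,
                              columns=matrix.values.columns)
    out.log2 = True
    return out


def median_normalize(matrix: ProteinMatrix) -> ProteinMatrix:
    """Shift each sample so its median matches the grand median of medians."""
    if not matrix.log2:
        raise ValueError("median normalization expects a log-scale matrix")
    medians = matrix.values.median(axis=1, skipna=True)
    if medians.isna().any():
        empty = list(medians.index[medians.isna()])
        raise ValueError(f"samples with zero observed values: {empty[:5]}")
    grand = float(np.median(medians.to_numpy()))
    shifts = grand - medians
    out = matrix.copy()
    out.values = matrix.values.add(shifts, axis=0)
    if out.shadow is not None:
        out.shadow = out.shadow.add(shifts, axis=0)
    out.sample_shifts = {s: float(v) for s, v in shifts.items()}
    return out


def drop_sparse_proteins(
    matrix: ProteinMatrix, max_missing: float = 0.5
) -> tuple[ProteinMatrix, list[str]]:
    """Drop proteins missing in more than `max_missing` of samples."""
    frac = matrix.values.isna().mean(axis=0)
    dropped = sorted(frac.index[frac > max_missing])
    if dropped:
        log.info("dropping %d proteins missing in > %.0f%% of samples: %s",
                 len(dropped), 100 * max_missing, dropped[:10])
    out = matrix.copy()
    out.values = out.values.drop(columns=dropped)
    if out.shadow is not None:
        out.shadow = out.shadow.drop(columns=dropped)
    if out.provenance is not None:
        out.provenance = out.provenance.drop(columns=dropped)
    return out, dropped


def _half_min_fill(vals: np.ndarray) -> np.ndarray:
    """Per-protein fill value: minimum observed minus 1 (log2 halving)."""
    with np.errstate(all="ignore"):
        col_min = np.nanmin(vals, axis=0)
    return col_min - 1.0


def impute_missing(
    matrix: ProteinMatrix, method: str = "knn", k: int = 5
) -> ProteinMatrix:
    """Fill every missing cell; observed cells are never altered.

    half_min: per-protein minimum observed value minus 1 log2 unit.
    knn: mean of the k nearest samples (Euclidean over co-observed
    proteins) among samples observing that protein; half_min fallback
    per cell when fewer than k qualify.
    """
    if method not in {"half_min", "knn"}:
        raise ValueError("method must be 'half_min' or 'knn'")
    if method == "knn" and k < 1:
        raise ValueError("k must be >= 1 for knn imputation")
    vals = matrix.values.to_numpy(copy=True)
    miss = np.isnan(vals)
    prov = np.where(miss, "missing", "observed").astype(object)
    out = matrix.copy()
    if not miss.any():
        out.provenance = pd.DataFrame(prov, index=matrix.values.index,
                                      columns=matrix.values.columns)
        return out

    never_observed = miss.all(axis=0)
    if never_observed.any():
        names = list(matrix.values.columns[never_observed])
        raise ValueError(
            f"proteins with zero observations cannot be imputed: {names[:10]}"
        )

    fill = _half_min_fill(vals)
    if method == "half_min":
        rows, cols = np.nonzero(miss)
        vals[rows, cols] = fill[cols]
        prov[rows, cols] = "imputed_halfmin"
    else:
        n = vals.shape[0]
        # pairwise nan-Euclidean distances over co-observed proteins,
        # rescaled by the number of shared proteins
        dist = np.full((n, n), np.inf)
        obs = ~miss
        for i in range(n):
            shared = obs[i] & obs
            diff = np.where(shared, vals[i] - vals, 0.0)
            cnt = shared.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.sqrt((diff ** 2).sum(axis=1) * vals.shape[1] / cnt)
            d[cnt == 0] = np.inf
            dist[i] = d
        np.fill_diagonal(dist, np.inf)
        order = np.argsort(dist, axis=1, kind="stable")
        n_fallback = 0
        for i, j in zip(*np.nonzero(miss)):
            donors = [r for r in order[i]
                      if np.isfinite(dist[i, r]) and obs[r, j]][:k]
            if len(donors) < k:
                vals[i, j] = fill[j]
                prov[i, j] = "imputed_halfmin"
                n_fallback += 1
            else:
                vals[i, j] = vals[donors, j].mean()
                prov[i, j] = "imputed_knn"
        if n_fallback:
            log.info("knn imputation fell back to half_min for %d cells",
                     n_fallback)

    out.values = pd.DataFrame(vals, index=matrix.values.index,
                              columns=matrix.values.columns)
    out.provenance = pd.DataFrame(prov, index=matrix.values.index,
                                  columns=matrix.values.columns)
    return out


def preprocess(
    matrix: ProteinMatrix,
    method: str = "knn",
    k: int = 5,
    max_missing: float = 0.5,
) -> tuple[ProteinMatrix, dict]:
    """Standard chain: sparse-protein guard, median centring, imputation."""
    guarded, dropped = drop_sparse_proteins(matrix, max_missing)
    normed = median_normalize(guarded)
    imputed = impute_missing(normed, method=method, k=k)
    summary = {
        "n_samples": imputed.n_samples,
        "n_proteins": imputed.n_proteins,
        "dropped_proteins": dropped,
        "n_imputed": int((imputed.provenance.to_numpy() != "observed").sum())
        if imputed.provenance is not None else 0,
        "method": method,
    }
    return imputed, summary


__all__ = [
    "log2_transform",
    "median_normalize",
    "drop_sparse_proteins",
    "impute_missing",
    "preprocess",
]
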