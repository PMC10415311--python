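"""Mitochondrial connectivity matrices, nodal degree, and the
within- vs between-area modularity permutation test."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import BRAIN_FEATURES, CohortTable, ConnectivityMatrix, MultilayerNetwork

log = logging.getLogger(__name__)

MIN_OVERLAP = 4  # animal pairs needed for a correlation entry


def _pairwise_corr(wide: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlations and per-entry overlap counts."""
    values = wide.corr(method="pearson", min_periods=MIN_OVERLAP).to_numpy()
    present = wide.notna().to_numpy().astype(int)
    n_used = present.T @ present
    np.fill_diagonal(values, 1.0)
    return values, n_used


def _ward_order(values: np.ndarray) -> np.ndarray:
    """Hierarchical-cluster leaf order (Euclidean distance, Ward) of rows."""
    filled = np.nan_to_num(values, nan=0.0)
    if filled.shape[0] < 3:
        return np.arange(filled.shape[0])
    d = squareform(
        np.sqrt(np.maximum(
            ((filled[:, None, :] - filled[None, :, :]) ** 2).sum(-1), 0.0)),
        checks=False,
    )
    link = hierarchy.linkage(d, method="ward")
    return np.asarray(hierarchy.leaves_list(link))


def feature_area_matrix(
    cohort: CohortTable,
    include_tissues: bool = False,
    features=BRAIN_FEATURES,
) -> ConnectivityMatrix:
    """Across-animal Pearson correlation over (site, feature) rows.

    With 17 brain areas and 6 features this is the 102 x 102 matrix; tissues
    can be appended for brain-vs-tissue summaries.  Entries with fewer than
    4 overlapping animals are NaN.
    """
    sites = list(cohort.areas) + (list(cohort.tissues) if include_tissues else [])
    wide = cohort.wide(sites=sites, features=features)
    cols = [(s, f) for s in sites for f in features if (s, f) in wide.columns]
    wide = wide[cols]
    values, n_used = _pairwise_corr(wide)
    order = _ward_order(values)
    return ConnectivityMatrix(labels=cols, values=values, n_used=n_used,
                              cluster_order=order)


def per_feature_slices(
    cohort: CohortTable, features=BRAIN_FEATURES
) -> MultilayerNetwork:
    """One area x area Pearson correlation slice per mitochondrial feature."""
    areas = list(cohort.areas)
    slices = []
    for feat in features:
        wide = cohort.wide(sites=areas, features=[feat])
        wide = wide.reindex(columns=[(a, feat) for a in areas])
        values, _ = _pairwise_corr(wide)
        slices.append(values)
    return MultilayerNetwork(labels=areas, slices=slices,
                             slice_names=tuple(features))


def nodal_degree(matrix: ConnectivityMatrix) -> pd.Series:
    """Per-area mean correlation with all other areas (self excluded).

    For (site, feature)-level matrices, the feature-block correlations are
    averaged within each area pair first, then averaged across partner areas.
    """
    labels = list(matrix.labels)
    if labels and isinstance(labels[0], tuple):
        sites = list(dict.fromkeys(l[0] for l in labels))
        site_of = np.array([sites.index(l[0]) for l in labels])
        n = len(sites)
        area_mat = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                block = matrix.values[np.ix_(site_of == i, site_of == j)]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    area_mat[i, j] = np.nanmean(block)
    else:
        sites = labels
        area_mat = matrix.values.copy()
    np.fill_diagonal(area_mat, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        deg = np.nanmean(area_mat, axis=1)
    return pd.Series(deg, index=sites, name="nodal_degree")


def _within_between_stat(values: np.ndarray, site_idx: np.ndarray) -> float:
    same = site_idx[:, None] == site_idx[None, :]
    off = ~np.eye(len(site_idx), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        within = np.nanmean(values[same & off])
        between = np.nanmean(values[~same])
    return float(within - between)


def within_between_permutation(
    matrix: ConnectivityMatrix,
    site_labels=None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation test that same-site feature correlations exceed cross-site.

    Statistic: mean(within-site entries) - mean(between-site entries); the
    null shuffles row/column site labels.  p = (1 + #null >= obs)/(n_perm+1).
    """
    if n_perm < 100:
        log.warning("n_perm=%d is low; p-value resolution is coarse", n_perm)
    if site_labels is None:
        site_labels = [l[0] if isinstance(l, tuple) else l for l in matrix.labels]
    sites = list(dict.fromkeys(site_labels))
    if len(sites) < 2:
        raise ValueError("need >=2 distinct sites for the permutation test")
    site_idx = np.array([sites.index(s) for s in site_labels])
    values = matrix.values
    observed = _within_between_stat(values, site_idx)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(site_idx)
        if _within_between_stat(values, perm) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return {"statistic": observed, "p": p, "n_perm": n_perm}
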