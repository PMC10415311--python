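"""Transcriptional mitochondrial phenotypes: network-level fold genes,
pathway-level expression scoring, mitotype ranking/ratios, and
clustering/PCA projection of area signatures."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .core import Partition

log = logging.getLogger(__name__)

SCORE_MEAN = 100.0
SCORE_SD = 10.0


def _validate_expr(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.columns.duplicated().any():
        raise ValueError("duplicate gene symbols in expression table")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression estimates must be nonnegative")
    return expr.astype(float)


def network_fold_genes(
    expr: pd.DataFrame,
    partition: Partition,
    network: int,
    threshold_log2: float = 1.0,
) -> dict:
    """Genes over/under-expressed in one network vs the remaining areas.

    log2(mean over network areas / mean over the rest); genes at or past the
    threshold in either direction are listed (boundary inclusive).  Genes
    with a zero mean on either side are excluded and counted.
    """
    expr = _validate_expr(expr)
    in_net = [a for a in partition.labels
              if partition.assignment[a] == network and a in expr.index]
    rest = [a for a in expr.index if a not in in_net]
    if not in_net:
        raise ValueError(f"network {network} has no areas in the table")
    m_in = expr.loc[in_net].mean(axis=0)
    m_out = expr.loc[rest].mean(axis=0)
    valid = (m_in > 0) & (m_out > 0)
    n_excluded = int((~valid).sum())
    lfc = np.log2(m_in[valid] / m_out[valid])
    over = lfc[lfc >= threshold_log2].sort_values(ascending=False)
    under = lfc[lfc <= -threshold_log2].sort_values()
    return {"network": network, "log2fc": lfc,
            "over": list(over.index), "under": list(under.index),
            "n_excluded": n_excluded}


@dataclass
class PathwayScoreMatrix:
    """Areas x pathways mean transformed-expression scores."""

    scores: pd.DataFrame
    target_mean: float = SCORE_MEAN
    target_sd: float = SCORE_SD
    gene_to_pathway: dict = field(default_factory=dict)
    dropped_pathways: list = field(default_factory=list)
    flat_genes: list = field(default_factory=list)


def pathway_scores(
    expr: pd.DataFrame, gene_to_pathway: pd.DataFrame | dict
) -> PathwayScoreMatrix:
    """Pathway-level scores: each gene z-scored across areas, rescaled to
    mean 100 / SD 10, then averaged over each pathway's member genes.

    Pathways with no mapped gene in the table are dropped (reported);
    constant genes transform to a flat 100 and are flagged.
    """
    expr = _validate_expr(expr)
    if isinstance(gene_to_pathway, pd.DataFrame):
        g2p = dict(zip(gene_to_pathway.iloc[:, 0], gene_to_pathway.iloc[:, 1]))
    else:
        g2p = dict(gene_to_pathway)
    genes = [g for g in expr.columns if g in g2p]
    if not genes:
        raise ValueError("gene->pathway map covers no gene in the table")
    x = expr[genes]
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    flat = sd.index[sd == 0].tolist()
    if flat:
        log.warning("%d constant genes transformed to flat %.0f",
                    len(flat), SCORE_MEAN)
    sd = sd.replace(0.0, np.nan)
    z = ((x - mu) / sd).fillna(0.0)
    transformed = z * SCORE_SD + SCORE_MEAN

    pathways = sorted(set(g2p.values()))
    cols = {}
    dropped = []
    for pw in pathways:
        members = [g for g in genes if g2p[g] == pw]
        if not members:
            dropped.append(pw)
            continue
        cols[pw] = transformed[members].mean(axis=1)
    requested = set(g2p.values())
    dropped += sorted(requested - set(cols))
    scores = pd.DataFrame(cols, index=expr.index)
    return PathwayScoreMatrix(scores=scores, gene_to_pathway=g2p,
                              dropped_pathways=sorted(set(dropped)),
                              flat_genes=flat)


def rank_pathways(
    scores: PathwayScoreMatrix, partition: Partition, network: int = 1
) -> pd.Series:
    """Pathways sorted ascending by log2(mean network score / mean rest)."""
    df = scores.scores
    in_net = [a for a in partition.labels
              if partition.assignment[a] == network and a in df.index]
    rest = [a for a in df.index if a not in in_net]
    if not in_net or not rest:
        raise ValueError("need areas on both sides of the network split")
    m_in = df.loc[in_net].mean(axis=0)
    m_out = df.loc[rest].mean(axis=0)
    valid = (m_in > 0) & (m_out > 0)
    excluded = df.columns[~valid].tolist()
    if excluded:
        log.warning("excluding pathways with nonpositive means: %s", excluded)
    lfc = np.log2(m_in[valid] / m_out[valid]).sort_values()
    lfc.name = f"log2fc_network{network}_vs_rest"
    return lfc


def mitotype_ratio(
    scores: PathwayScoreMatrix, pathway_a: str, pathway_b: str
) -> pd.DataFrame:
    """Per-area score ratio of two pathways plus its percentage deviation
    from the cohort-mean ratio."""
    df = scores.scores
    for pw in (pathway_a, pathway_b):
        if pw not in df.columns:
            raise ValueError(f"pathway {pw!r} not in score matrix")
    denom = df[pathway_b]
    keep = denom != 0
    if (~keep).any():
        log.warning("skipping areas with zero denominator: %s",
                    df.index[~keep].tolist())
    ratio = df.loc[keep, pathway_a] / denom[keep]
    pct = (ratio / ratio.mean() - 1.0) * 100.0
    return pd.DataFrame({"ratio": ratio, "pct_vs_mean": pct})


@dataclass
class ClusterProjection:
    leaf_order: list
    linkage: np.ndarray
    components: pd.DataFrame
    explained_variance_ratio: np.ndarray


def cluster_and_project(
    data: pd.DataFrame, standardize: bool = False, n_components: int = 3
) -> ClusterProjection:
    """Ward (ward.D2-style, on Euclidean distances) leaf order plus a
    top-``n_components`` PCA projection of the areas."""
    if len(data) < 3:
        raise ValueError("need >=3 areas")
    x = data.astype(float)
    if standardize:
        sd = x.std(axis=0, ddof=0).replace(0.0, np.nan)
        x = ((x - x.mean(axis=0)) / sd).fillna(0.0)
    link = hierarchy.linkage(pdist(x.to_numpy()), method="ward")
    order = [data.index[i] for i in hierarchy.leaves_list(link)]
    n_comp = min(n_components, len(data) - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x.to_numpy() - x.to_numpy().mean(axis=0))
    comp = pd.DataFrame(coords, index=data.index,
                        columns=[f"PC{i + 1}" for i in range(n_comp)])
    return ClusterProjection(order, link, comp, pca.explained_variance_ratio_)
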