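"""Mito-behavior correlation panels, distribution-level tests, and
network-averaged prediction of behavior."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BRAIN_FEATURES, CohortTable, Partition

log = logging.getLogger(__name__)

MIN_N = 4


def _behavior_series(behaviors: pd.DataFrame, test: str) -> pd.Series:
    sub = behaviors[behaviors.test == test]
    if sub.empty:
        raise ValueError(f"no scores for behavioral test {test!r}")
    return sub.set_index("animal_id")["score"]


def mito_behavior_panel(
    cohort: CohortTable,
    behaviors: pd.DataFrame | None = None,
    tests=("OFT", "EPM", "NSF", "SI"),
    features=BRAIN_FEATURES,
    fdr_q: float = 0.01,
) -> pd.DataFrame:
    """Spearman r for every (area, feature, test) with BH-FDR flags.

    Missing animals are dropped pairwise; entries with fewer than 4 matched
    animals are omitted.  The realized BH p-cutoff at ``fdr_q`` is attached
    as ``df.attrs['realized_cutoff']``.
    """
    if behaviors is None:
        behaviors = cohort.behaviors
    if behaviors is None:
        raise ValueError("no behavior table available")
    wide = cohort.wide(sites=cohort.areas, features=features)
    rows = []
    for test in tests:
        score = _behavior_series(behaviors, test)
        for (area, feat) in wide.columns:
            pair = pd.concat([wide[(area, feat)], score], axis=1,
                             join="inner").dropna()
            if len(pair) < MIN_N:
                continue
            r, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append((area, feat, test, float(r), len(pair), float(p)))
    panel = pd.DataFrame(rows, columns=["area", "feature", "test", "r", "n",
                                        "p"])
    if panel.empty:
        return panel
    reject, q, _, _ = multipletests(panel["p"], alpha=fdr_q, method="fdr_bh")
    panel["q"] = q
    panel["significant"] = reject
    rejected = panel.loc[reject, "p"]
    panel.attrs["realized_cutoff"] = float(rejected.max()) if len(rejected) \
        else np.nan
    panel.attrs["fdr_q"] = fdr_q
    return panel


@dataclass
class DistributionFit:
    mean: float
    sd: float
    t: float
    p: float
    n: int
    flagged: bool = False


def distribution_test(values) -> DistributionFit:
    """ML Gaussian fit plus a two-tailed one-sample t-test against 0."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 5:
        raise ValueError("need >=5 values for a distribution test")
    mean, sd = stats.norm.fit(x)
    if np.allclose(x, x[0]):
        log.warning("distribution test on constant input: t undefined")
        return DistributionFit(float(mean), float(sd), np.nan, np.nan,
                               x.size, flagged=True)
    t, p = stats.ttest_1samp(x, 0.0)
    return DistributionFit(float(mean), float(sd), float(t), float(p), x.size)


@dataclass
class NetworkCorrelation:
    r: float
    p: float
    r2: float
    adjusted_r2: float
    n: int
    method: str
    network: int


def network_average_correlation(
    cohort: CohortTable,
    partition: Partition,
    behaviors: pd.DataFrame | None = None,
    test: str = "EPM",
    network: int = 1,
    method: str = "spearman",
    features=BRAIN_FEATURES,
) -> NetworkCorrelation:
    """Correlate the network-average mitochondrial signal with a behavior.

    Per animal: the mean of all (area in network, feature) values after
    standardizing each column across animals (so no feature dominates by
    scale); correlated with the behavior score.  Reports r, p, r^2 and the
    single-predictor sample-size-adjusted r^2 = 1 - (1-r^2)(n-1)/(n-2).
    """
    if behaviors is None:
        behaviors = cohort.behaviors
    areas = [a for a in partition.labels if partition.assignment[a] == network]
    if not areas:
        raise ValueError(f"network {network} has no areas")
    wide = cohort.wide(sites=areas, features=features)
    z = (wide - wide.mean()) / wide.std(ddof=1)
    signal = z.mean(axis=1, skipna=True)
    score = _behavior_series(behaviors, test)
    pair = pd.concat([signal, score], axis=1, join="inner").dropna()
    if len(pair) < MIN_N:
        raise ValueError(f"only {len(pair)} matched animals for {test}")
    if method == "spearman":
        r, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
    elif method == "pearson":
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    n = len(pair)
    r2 = r * r
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return NetworkCorrelation(float(r), float(p), float(r2), float(adj), n,
                              method, network)


def stressor_direction_test(
    cohort: CohortTable,
    group: str,
    naive_group: str = "naive",
    features=BRAIN_FEATURES,
) -> pd.DataFrame:
    """Per feature: count areas where the stress-group mean exceeds the
    naive mean, with a two-tailed exact binomial p against 0.5."""
    groups = cohort.group_of()
    wide = cohort.wide(sites=cohort.areas, features=features)
    in_group = [a for a in wide.index if groups.get(a) == group]
    in_naive = [a for a in wide.index if groups.get(a) == naive_group]
    if not in_naive:
        raise ValueError(f"naive group {naive_group!r} not present")
    gmean = wide.loc[in_group].mean(skipna=True)
    nmean = wide.loc[in_naive].mean(skipna=True)
    rows = []
    for feat in features:
        cols = [c for c in wide.columns if c[1] == feat]
        diff = (gmean[cols] - nmean[cols]).dropna()
        n_above = int((diff > 0).sum())
        n_total = len(diff)
        p = stats.binomtest(n_above, n_total, 0.5).pvalue if n_total else np.nan
        rows.append((feat, n_above, n_total, float(p)))
    return pd.DataFrame(rows, columns=["feature", "n_above", "n_areas", "p"])
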