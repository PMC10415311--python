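"""Synthetic cohort, modality-matrix, and qPCR fixtures.

Generates data with the statistical structure the downstream analysis
assumes: a planted 3-community block structure over 17 brain areas, target
inter-area correlations induced by shared latent factors, opposing stressor
shifts, behavior scores coupled to the network-1 feature mean, cracked-brain
missingness, and triplicate qPCR plates with injected outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assays
from .core import BEHAVIOR_TESTS, SAMPLED_FEATURES, CohortTable, Partition

#: 17 brain areas in atlas (bregma) order.
DEFAULT_AREAS = (
    "mOFC", "mPFC", "CPu", "NAc", "M1", "Hypoth", "Thal", "DGd", "Amyg",
    "CA3", "VTA", "V1", "SN", "DGv", "PAG", "Cereb", "VN",
)
DEFAULT_TISSUES = ("AG", "Liver", "Heart", "Soleus", "WG")

#: Default planted 3-community membership (cortico-striatal / salience /
#: limbic blocks).
DEFAULT_PARTITION = {
    "CPu": 1, "NAc": 1, "mOFC": 1, "mPFC": 1, "M1": 1, "V1": 1,
    "Cereb": 2, "VN": 2, "VTA": 2, "Thal": 2, "CA3": 2, "DGv": 2, "DGd": 2,
    "Amyg": 3, "Hypoth": 3, "PAG": 3, "SN": 3,
}

DEFAULT_GROUPS = ("naive", "CORT", "CSDS", "CSDS_recovered")

#: Arbitrary order-of-magnitude baseline per feature (units are nominal;
#: every downstream statistic is correlation- or ratio-based).
FEATURE_BASELINES = {
    "CI": 200.0, "CII": 150.0, "CIV": 400.0, "CS": 600.0,
    "mtdna_density": 1.0e4,
}


def _default_cort_effect(areas) -> dict[str, float]:
    # positive in ~60% of areas, mild negative elsewhere
    n_pos = round(0.6 * len(areas))
    return {a: (0.5 if i < n_pos else -0.2) for i, a in enumerate(areas)}


def _default_csds_effect(areas) -> dict[str, float]:
    # negative in ~82% of areas
    n_neg = round(0.82 * len(areas))
    return {a: (-0.5 if i < n_neg else 0.2) for i, a in enumerate(areas)}


@dataclass
class SyntheticConfig:
    """Knobs for the cohort generator; defaults mirror the study design."""

    n_per_group: int = 7
    groups: tuple[str, ...] = DEFAULT_GROUPS
    areas: tuple[str, ...] = DEFAULT_AREAS
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    planted_partition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PARTITION))
    within_block_r: float = 0.5
    between_block_r: float = 0.05
    brain_mean_r: float = 0.2
    cort_effect: dict[str, float] | None = None
    csds_effect: dict[str, float] | None = None
    behavior_coupling: dict[str, float] = field(
        default_factory=lambda: {"OFT": 0.4, "EPM": 0.6, "NSF": 0.15, "SI": -0.6})
    noise_cv_brain: float = 0.36
    noise_cv_tissue: float = 0.25
    missing_rate: float = 0.03
    behavior_missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError(
                "n_per_group must be >= 3: correlation stages are undefined "
                "below that"
            )
        part_areas = set(self.planted_partition)
        if part_areas != set(self.areas):
            raise ValueError(
                "planted_partition must cover every area exactly once; "
                f"difference: {sorted(part_areas ^ set(self.areas))}"
            )
        if not (abs(self.within_block_r) < 1 and abs(self.between_block_r) < 1):
            raise ValueError("block correlations must be in (-1, 1)")
        if self.within_block_r <= self.between_block_r:
            raise ValueError("within_block_r must exceed between_block_r")
        if self.between_block_r < 0:
            raise ValueError("between_block_r must be >= 0")
        if self.cort_effect is None:
            self.cort_effect = _default_cort_effect(self.areas)
        if self.csds_effect is None:
            self.csds_effect = _default_csds_effect(self.areas)

    def partition(self) -> Partition:
        return Partition(self.areas, dict(self.planted_partition))


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Sample a cohort with planted block correlation structure.

    Latent-factor construction: per animal, one global brain factor plus one
    factor per planted community; the value of feature f at area i is
    ``baseline_i,f * (1 + cv * u + shift)`` where u is the unit-variance
    combination of the factors whose loadings reproduce within/between-block
    correlation targets, and shift applies the group's per-area effect (in
    between-animal SD units).  Peripheral tissues get independent factors.
    MHI is computed from the five sampled features via
    :func:`mitonet.assays.compute_mhi`, never sampled.
    """
    rng = np.random.default_rng(config.seed)
    areas, tissues = list(config.areas), list(config.tissues)
    blocks = sorted(set(config.planted_partition.values()))
    block_idx = {b: k for k, b in enumerate(blocks)}

    # variance split reproducing the correlation targets
    lam_g2 = config.between_block_r
    lam_b2 = config.within_block_r - config.between_block_r
    resid2 = 1.0 - config.within_block_r
    lam_g, lam_b, lam_e = np.sqrt([lam_g2, lam_b2, resid2])

    animals, group_of = [], {}
    for g in config.groups:
        for i in range(config.n_per_group):
            aid = f"{g}_{i + 1:02d}"
            animals.append(aid)
            group_of[aid] = g
    n_animals = len(animals)

    shift_of = {g: {} for g in config.groups}
    shift_of["CORT"] = dict(config.cort_effect)
    shift_of["CSDS"] = dict(config.csds_effect)
    if "CSDS_recovered" in config.groups:
        # partial persistence of the CSDS shift after recovery
        shift_of["CSDS_recovered"] = {
            a: 0.25 * v for a, v in config.csds_effect.items()}

    global_f = rng.standard_normal(n_animals)
    block_f = rng.standard_normal((n_animals, len(blocks)))

    area_mult = 0.7 + 0.6 * (np.arange(len(areas)) % 7) / 6.0  # placeholders

    rows = []
    brain_values = {}  # (animal, area, feature) -> value, for MHI + behaviors
    for ai, area in enumerate(areas):
        k = block_idx[config.planted_partition[area]]
        for feat in SAMPLED_FEATURES:
            base = FEATURE_BASELINES[feat] * area_mult[ai]
            eps = rng.standard_normal(n_animals)
            u = lam_g * global_f + lam_b * block_f[:, k] + lam_e * eps
            for idx, aid in enumerate(animals):
                shift = shift_of.get(group_of[aid], {}).get(area, 0.0)
                val = base * (1.0 + config.noise_cv_brain * (u[idx] + shift))
                val = max(val, 0.01 * base)
                brain_values[(aid, area, feat)] = val

    for ti, tissue in enumerate(tissues):
        for feat in SAMPLED_FEATURES:
            base = FEATURE_BASELINES[feat] * (0.8 + 0.1 * ti)
            eps = rng.standard_normal(n_animals)
            for idx, aid in enumerate(animals):
                val = base * (1.0 + config.noise_cv_tissue * eps[idx])
                rows.append((aid, group_of[aid], tissue, "tissue", feat,
                             max(val, 0.01 * base)))

    # whole-site missingness (cracked-brain losses) on brain areas
    lost = set()
    if config.missing_rate > 0:
        for aid in animals:
            for area in areas:
                if rng.random() < config.missing_rate:
                    lost.add((aid, area))

    for area in areas:
        site_df = pd.DataFrame(
            {feat: [brain_values[(aid, area, feat)] for aid in animals]
             for feat in SAMPLED_FEATURES},
            index=animals,
        )
        mhi = assays.compute_mhi(site_df)
        for aid in animals:
            missing = (aid, area) in lost
            for feat in SAMPLED_FEATURES:
                v = np.nan if missing else site_df.loc[aid, feat]
                rows.append((aid, group_of[aid], area, "brain", feat, v))
            rows.append((aid, group_of[aid], area, "brain", "MHI",
                         np.nan if missing else mhi[aid]))

    data = pd.DataFrame(
        rows, columns=["animal_id", "group", "site", "site_class", "feature",
                       "value"])

    behaviors = _generate_behaviors(
        config, rng, animals, brain_values, global_f, block_f, block_idx)

    return CohortTable(data=data, behaviors=behaviors,
                       areas=tuple(areas), tissues=tuple(tissues))


def _generate_behaviors(config, rng, animals, brain_values, global_f, block_f,
                        block_idx) -> pd.DataFrame:
    """Behavior scores coupled to the network-1 latent feature mean."""
    net1 = [a for a in config.areas if config.planted_partition[a] == 1]
    k1 = block_idx[config.planted_partition[net1[0]]] if net1 else 0
    # latent that drives network-1 features, standardized across animals
    lam_g, lam_b = np.sqrt([config.between_block_r,
                            config.within_block_r - config.between_block_r])
    latent = lam_g * global_f + lam_b * block_f[:, k1]
    sd = latent.std(ddof=0)
    latent = (latent - latent.mean()) / (sd if sd > 0 else 1.0)

    rows = []
    for test in BEHAVIOR_TESTS:
        rho = float(np.clip(config.behavior_coupling.get(test, 0.0), -1, 1))
        noise = rng.standard_normal(len(animals))
        score = rho * latent + np.sqrt(1.0 - rho ** 2) * noise
        if test == "NSF":
            # right-censored latency in seconds
            score = np.clip(300.0 + 120.0 * score, 30.0, assays.NSF_CAP_SECONDS)
        for idx, aid in enumerate(animals):
            if rng.random() < config.behavior_missing_rate:
                continue  # animal not tested on this behavior
            rows.append((aid, test, float(score[idx])))
    return pd.DataFrame(rows, columns=["animal_id", "test", "score"])


def generate_modal_matrix(
    partition: Partition,
    within_w: float,
    between_w: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "coexpression",
) -> pd.DataFrame:
    """Synthetic cross-modal area x area matrix with planted block weights.

    ``coexpression`` mode yields a correlation-like matrix (unit diagonal,
    possibly negative entries); ``connectome`` clips at zero and has a zero
    diagonal (projection strengths).
    """
    if not (within_w > between_w >= 0):
        raise ValueError("need within_w > between_w >= 0")
    rng = np.random.default_rng(seed)
    labels = list(partition.labels)
    assign = partition.as_array()
    n = len(labels)
    same = assign[:, None] == assign[None, :]
    m = np.where(same, within_w, between_w).astype(float)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = (noise + noise.T) / np.sqrt(2.0)
        m = m + noise
    if kind == "coexpression":
        np.fill_diagonal(m, 1.0)
        m = np.clip(m, -1.0, 1.0)
    elif kind == "connectome":
        m = np.clip(m, 0.0, None)
        np.fill_diagonal(m, 0.0)
    else:
        raise ValueError(f"unknown matrix kind {kind!r}")
    return pd.DataFrame(m, index=labels, columns=labels)


def generate_qpcr_plate(
    n_samples: int,
    true_cn: float | np.ndarray,
    cv: float = 0.0,
    outlier_rate: float = 0.0,
    seed: int = 0,
    n_ct_base: float = 24.0,
) -> pd.DataFrame:
    """Triplicate-Ct qPCR plate whose noiseless dCt inverts mtDNAcn = 2^dCt x 2.

    For copy number c, mt Ct = nDNA Ct - log2(c / 2), so the noiseless
    pipeline recovers c exactly.  Injected outlier replicates (large Ct
    offsets) are flagged in the ``*_outlier`` truth columns.
    """
    true_cn = np.broadcast_to(np.asarray(true_cn, dtype=float), (n_samples,))
    if (true_cn <= 0).any():
        raise ValueError("true_cn must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        n_ct = n_ct_base
        mt_ct = n_ct - np.log2(true_cn[i] / 2.0)
        mt = mt_ct * (1.0 + cv * rng.standard_normal(3))
        nn = n_ct * (1.0 + cv * rng.standard_normal(3))
        mt_out = n_out = -1
        if outlier_rate > 0 and rng.random() < outlier_rate:
            j = int(rng.integers(3))
            mt[j] += rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 4.0)
            mt_out = j
        if outlier_rate > 0 and rng.random() < outlier_rate:
            j = int(rng.integers(3))
            nn[j] += rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 4.0)
            n_out = j
        rows.append({
            "sample_id": f"s{i + 1:03d}", "true_cn": true_cn[i],
            "mt_ct_1": mt[0], "mt_ct_2": mt[1], "mt_ct_3": mt[2],
            "n_ct_1": nn[0], "n_ct_2": nn[1], "n_ct_3": nn[2],
            "mt_outlier": mt_out, "n_outlier": n_out,
        })
    return pd.DataFrame(rows)


def generate_expression_table(
    partition: Partition,
    n_genes: int = 300,
    n_pathways: int = 20,
    effect_log2: float = 1.5,
    frac_marked: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic area x gene expression table plus a gene -> pathway map.

    A fraction of genes is elevated (2^effect_log2) in one planted network;
    pathways group consecutive genes.  Stand-in for atlas expression exports
    so the transcriptional stage is testable offline.
    """
    rng = np.random.default_rng(seed)
    labels = list(partition.labels)
    assign = partition.as_array()
    communities = sorted(set(assign.tolist()))
    genes = [f"gene{g + 1:04d}" for g in range(n_genes)]
    base = rng.uniform(0.5, 2.0, size=n_genes)
    x = np.outer(np.ones(len(labels)), base)
    marked = rng.random(n_genes) < frac_marked
    target = rng.choice(communities, size=n_genes)
    for gi in range(n_genes):
        if marked[gi]:
            x[assign == target[gi], gi] *= 2.0 ** effect_log2
    x *= np.exp(rng.normal(0.0, noise_sd, size=x.shape))
    expr = pd.DataFrame(x, index=labels, columns=genes)
    pathway = [f"pathway{(g % n_pathways) + 1:03d}" for g in range(n_genes)]
    g2p = pd.DataFrame({"gene": genes, "pathway": pathway})
    return expr, g2p
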