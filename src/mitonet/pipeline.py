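"""End-to-end orchestration of the analysis stages on real or synthetic
inputs, with per-stage toggles and explicit seeds throughout."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import behavior_assoc, connectivity, crossmodal, io, mapper, mitotype, \
    multislice, synthetic
from .core import BEHAVIOR_TESTS, CohortTable

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters and input/output paths in one serializable bag.

    Default permutation/run counts are reduced for interactive use;
    ``full_scale=True`` switches to the full-scale counts (10,000
    permutations, 1,000 community-detection runs, 1,000 surrogates).
    """

    out_dir: str = "results"
    synthetic: bool = True
    seed: int = 0
    cohort_path: str | None = None
    behavior_path: str | None = None
    coexpression_path: str | None = None
    connectome_path: str | None = None
    expression_path: str | None = None
    gene_pathway_path: str | None = None
    stages: dict = field(default_factory=lambda: {
        "connectivity": True, "multislice": True, "mapper": True,
        "crossmodal": True, "behavior": True, "mitotype": True,
    })
    n_per_group: int = 7
    n_bins: int = 64
    overlap: float = 0.70
    omega: float = 0.1
    gamma: float = 1.0
    n_runs: int = 200
    n_perm: int = 2000
    n_null: int = 200
    fdr_q: float = 0.01
    full_scale: bool = False

    def __post_init__(self) -> None:
        if self.full_scale:
            self.n_runs, self.n_perm, self.n_null = 1000, 10_000, 1000

    def to_yaml(self, path) -> None:
        io.write_yaml(asdict(self), path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**io.read_yaml(path))


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if config.synthetic:
        sconf = synthetic.SyntheticConfig(n_per_group=config.n_per_group,
                                          seed=config.seed)
        return synthetic.generate_cohort(sconf)
    if not config.cohort_path:
        raise ValueError("stage 'features': cohort_path required when "
                         "synthetic mode is off")
    return io.read_cohort(config.cohort_path, config.behavior_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the machine-readable result bundle (also written to
    ``out_dir/results.json`` along with per-stage files).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": config.seed, "synthetic": config.synthetic}
    stages = config.stages

    cohort = _load_cohort(config)
    io.write_cohort(cohort, out / "cohort.csv", out / "behaviors.csv")
    sconf = synthetic.SyntheticConfig(n_per_group=config.n_per_group,
                                      seed=config.seed) \
        if config.synthetic else None

    partition = None
    network = None

    if stages.get("connectivity", True):
        cm = connectivity.feature_area_matrix(cohort)
        io.write_connectivity(cm, out / "connectivity_site_feature.tsv")
        degree = connectivity.nodal_degree(cm)
        degree.to_csv(out / "nodal_degree.csv")
        wb = connectivity.within_between_permutation(
            cm, n_perm=config.n_perm, seed=config.seed)
        network = connectivity.per_feature_slices(cohort)
        io.write_multilayer(network, out / "slices")
        results["connectivity"] = {
            "within_between_stat": wb["statistic"], "within_between_p": wb["p"],
            "nodal_degree": degree.to_dict(),
        }

    if stages.get("multislice", True):
        if network is None:
            network = connectivity.per_feature_slices(cohort)
        partition = multislice.consensus_communities(
            network, n_runs=config.n_runs, omega=config.omega,
            gamma=config.gamma, seed=config.seed)
        io.write_partition(partition, out / "partition.csv")
        results["multislice"] = {
            "n_communities": partition.n_communities,
            "assignment": {a: int(partition.assignment[a])
                           for a in partition.labels},
        }

    if stages.get("mapper", True):
        mconf = mapper.MapperConfig(n_bins=config.n_bins,
                                    overlap=config.overlap, seed=config.seed)
        groups = set(cohort.groups)
        pair = [g for g in ("CORT", "CSDS") if g in groups]
        if len(pair) == 2 and "naive" in groups:
            d_cort = mapper.delta_matrix(cohort, "CORT")
            d_csds = mapper.delta_matrix(cohort, "CSDS")
            communities = {a: a for a in cohort.areas}  # annotate by area
            null = mapper.phase_randomized_null(
                d_cort, d_csds, communities, mconf, n_null=config.n_null,
                seed=config.seed)
            coords = mapper.embed(d_cort.to_numpy(), mconf)
            graph = mapper.build_mapper(coords, d_cort.to_numpy(), mconf,
                                        row_labels=list(d_cort.index))
            io.write_graphml(graph, out / "mapper_cort.graphml")
            io.write_mapper_csvs(graph, out / "mapper_cort_nodes.csv",
                                 out / "mapper_cort_edges.csv")
            results["mapper"] = {
                "pc_cort": null["pc_a"], "pc_csds": null["pc_b"],
                "relative_change": null["relative_change"], "p": null["p"],
            }
        else:
            log.warning("mapper stage skipped: need naive, CORT and CSDS "
                        "groups")

    if stages.get("crossmodal", True) and partition is not None:
        if config.coexpression_path:
            coexp = crossmodal.ModalityMatrix.from_frame(
                io.read_square_matrix(config.coexpression_path))
        elif config.synthetic:
            coexp = crossmodal.ModalityMatrix.from_frame(
                synthetic.generate_modal_matrix(
                    sconf.partition(), within_w=0.6, between_w=0.2,
                    noise_sd=0.1, seed=config.seed))
        else:
            coexp = None
        if coexp is not None:
            res = {}
            for metric in ("SF", "Q"):
                test = crossmodal.permutation_test(
                    coexp, partition, metric=metric, n_perm=config.n_perm,
                    seed=config.seed)
                res[metric] = {"statistic": test["statistic"], "p": test["p"]}
            results["crossmodal"] = res

    if stages.get("behavior", True) and cohort.behaviors is not None:
        panel = behavior_assoc.mito_behavior_panel(cohort, fdr_q=config.fdr_q)
        panel.to_csv(out / "mito_behavior_panel.csv", index=False)
        results["behavior"] = {
            "n_entries": len(panel),
            "n_significant": int(panel["significant"].sum())
            if len(panel) else 0,
        }
        if partition is not None:
            net_corr = {}
            for test in BEHAVIOR_TESTS:
                try:
                    nc = behavior_assoc.network_average_correlation(
                        cohort, partition, test=test, network=1)
                except ValueError:
                    continue
                net_corr[test] = {"r": nc.r, "p": nc.p, "r2": nc.r2,
                                  "adjusted_r2": nc.adjusted_r2, "n": nc.n}
            results["behavior"]["network1"] = net_corr

    if stages.get("mitotype", True):
        if config.expression_path and config.gene_pathway_path:
            expr = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            g2p = pd.read_csv(config.gene_pathway_path, sep="\t")
        elif config.synthetic and partition is not None:
            expr, g2p = synthetic.generate_expression_table(
                partition, seed=config.seed)
        else:
            expr = None
        if expr is not None and partition is not None:
            scores = mitotype.pathway_scores(expr, g2p)
            scores.scores.to_csv(out / "pathway_scores.csv")
            ranked = mitotype.rank_pathways(scores, partition, network=1)
            ranked.to_csv(out / "ranked_pathways.csv")
            folds = mitotype.network_fold_genes(expr, partition, network=1)
            (out / "network1_over_genes.txt").write_text(
                "\n".join(folds["over"]) + "\n")
            (out / "network1_under_genes.txt").write_text(
                "\n".join(folds["under"]) + "\n")
            results["mitotype"] = {
                "n_pathways": scores.scores.shape[1],
                "n_over": len(folds["over"]), "n_under": len(folds["under"]),
            }

    io.write_json(results, out / "results.json")
    return results
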