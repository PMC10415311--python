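"""Schema-validated readers and writers for the pipeline's file formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from .core import CohortTable, ConnectivityMatrix, MultilayerNetwork, Partition

COHORT_COLUMNS = ["animal_id", "group", "site", "site_class", "feature",
                  "value"]
BEHAVIOR_COLUMNS = ["animal_id", "test", "score"]


def write_cohort(cohort: CohortTable, path, behavior_path=None) -> None:
    cohort.data.to_csv(path, index=False)
    if behavior_path is not None and cohort.behaviors is not None:
        cohort.behaviors.to_csv(behavior_path, index=False)


def read_cohort(path, behavior_path=None) -> CohortTable:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path}: missing columns {missing}")
    bad = set(df["site_class"].unique()) - {"brain", "tissue"}
    if bad:
        raise ValueError(f"cohort file {path}: invalid site_class {sorted(bad)}")
    behaviors = None
    if behavior_path is not None:
        behaviors = read_behaviors(behavior_path)
    return CohortTable(data=df, behaviors=behaviors)


def read_behaviors(path, known_animals=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"behavior file {path}: missing columns {missing}")
    if known_animals is not None:
        unknown = sorted(set(df["animal_id"]) - set(known_animals))
        if unknown:
            raise ValueError(
                f"behavior file {path}: unknown animal ids {unknown}")
    return df


def write_square_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_square_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"matrix file {path}: not square ({df.shape[0]}x{df.shape[1]})")
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix file {path}: row/column labels disagree")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"matrix file {path}: duplicate labels {dup}")
    return df


def write_connectivity(matrix: ConnectivityMatrix, path) -> None:
    write_square_matrix(matrix.to_frame(), path)


def write_multilayer(network: MultilayerNetwork, directory,
                     prefix: str = "slice") -> None:
    """One TSV per slice plus a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for name, a in zip(network.slice_names, network.slices):
        fname = f"{prefix}_{name}.tsv"
        pd.DataFrame(a, index=network.labels,
                     columns=network.labels).to_csv(directory / fname, sep="\t")
        files.append(fname)
    manifest = {"labels": list(network.labels),
                "slice_names": list(network.slice_names), "files": files}
    (directory / f"{prefix}_manifest.json").write_text(
        json.dumps(manifest, indent=2))


def read_multilayer(directory, prefix: str = "slice") -> MultilayerNetwork:
    directory = Path(directory)
    manifest = json.loads((directory / f"{prefix}_manifest.json").read_text())
    slices = []
    for fname in manifest["files"]:
        df = read_square_matrix(directory / fname)
        if list(df.index) != manifest["labels"]:
            raise ValueError(f"slice {fname}: labels disagree with manifest")
        slices.append(df.to_numpy())
    return MultilayerNetwork(labels=tuple(manifest["labels"]), slices=slices,
                             slice_names=tuple(manifest["slice_names"]))


def write_partition(partition: Partition, path) -> None:
    pd.DataFrame({"area": list(partition.labels),
                  "community": [partition.assignment[a]
                                for a in partition.labels]}
                 ).to_csv(path, index=False)


def read_partition(path) -> Partition:
    df = pd.read_csv(path)
    for col in ("area", "community"):
        if col not in df.columns:
            raise ValueError(f"partition file {path}: missing column {col!r}")
    if df["area"].duplicated().any():
        raise ValueError(f"partition file {path}: duplicate areas")
    assignment = dict(zip(df["area"], df["community"].astype(int)))
    return Partition(tuple(df["area"]), assignment)


def write_graphml(graph, path) -> None:
    g = graph.to_networkx() if hasattr(graph, "to_networkx") else graph
    nx.write_graphml(g, path)


def write_mapper_csvs(graph, node_path, edge_path) -> None:
    rows = [{"node": i, "bin": bin_id,
             "members": ";".join(str(m) for m in sorted(members))}
            for i, (bin_id, members) in enumerate(graph.nodes)]
    pd.DataFrame(rows).to_csv(node_path, index=False)
    pd.DataFrame(sorted(graph.edges), columns=["source", "target"]
                 ).to_csv(edge_path, index=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
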