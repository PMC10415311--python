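"""Shared data containers for the mitochondrial phenotyping pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical feature order for brain sites. MHI is derived, never sampled.
BRAIN_FEATURES = ("CI", "CII", "CIV", "CS", "mtdna_density", "MHI")
SAMPLED_FEATURES = ("CI", "CII", "CIV", "CS", "mtdna_density")

BEHAVIOR_TESTS = ("OFT", "EPM", "NSF", "SI")


@dataclass
class CohortTable:
    """Tidy per-animal, per-site feature table plus behavioral scores.

    ``data`` columns: animal_id, group, site, site_class ("brain"/"tissue"),
    feature, value.  Missing measurements are NaN rows (kept, not dropped),
    so the missingness mask survives round trips.
    ``behaviors`` columns: animal_id, test, score.
    """

    data: pd.DataFrame
    behaviors: pd.DataFrame | None = None
    areas: tuple[str, ...] = ()
    tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"animal_id", "group", "site", "site_class", "feature", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if not self.areas:
            self.areas = tuple(
                self.data.loc[self.data.site_class == "brain", "site"].unique()
            )
        if not self.tissues:
            self.tissues = tuple(
                self.data.loc[self.data.site_class == "tissue", "site"].unique()
            )

    @property
    def animals(self) -> list[str]:
        return list(pd.unique(self.data["animal_id"]))

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def group_of(self) -> pd.Series:
        """animal_id -> group label."""
        return self.data.drop_duplicates("animal_id").set_index("animal_id")["group"]

    def wide(self, sites=None, features=None, site_class=None) -> pd.DataFrame:
        """Animals x (site, feature) value matrix."""
        df = self.data
        if site_class is not None:
            df = df[df.site_class == site_class]
        if sites is not None:
            df = df[df.site.isin(sites)]
        if features is not None:
            df = df[df.feature.isin(features)]
        out = df.pivot_table(
            index="animal_id", columns=["site", "feature"], values="value",
            dropna=False,
        )
        return out.reindex(self.animals)


@dataclass
class Partition:
    """Mapping of areas to integer community labels."""

    labels: tuple[str, ...]
    assignment: dict[str, int]
    quality: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        missing = [a for a in self.labels if a not in self.assignment]
        if missing:
            raise ValueError(f"partition does not cover areas: {missing}")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment[a] for a in self.labels))

    def as_array(self) -> np.ndarray:
        return np.array([self.assignment[a] for a in self.labels], dtype=int)

    def community_sizes(self) -> dict[int, int]:
        arr = self.as_array()
        vals, counts = np.unique(arr, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class MultilayerNetwork:
    """Ordered stack of weighted area x area adjacency slices on one node set."""

    labels: tuple[str, ...]
    slices: list[np.ndarray]
    slice_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        n = len(self.labels)
        cleaned = []
        for s, a in enumerate(self.slices):
            a = np.asarray(a, dtype=float)
            if a.shape != (n, n):
                raise ValueError(
                    f"slice {s} has shape {a.shape}, expected ({n}, {n})"
                )
            if not np.allclose(a, a.T, equal_nan=True):
                raise ValueError(f"slice {s} is not symmetric")
            cleaned.append(a)
        self.slices = cleaned
        if not self.slice_names:
            self.slice_names = tuple(f"slice{s}" for s in range(len(self.slices)))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with per-entry sample counts."""

    labels: tuple
    values: np.ndarray
    n_used: np.ndarray
    cluster_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        idx = [("|".join(l) if isinstance(l, tuple) else l) for l in self.labels]
        return pd.DataFrame(self.values, index=idx, columns=idx)
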