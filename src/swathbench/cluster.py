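"""Chain-performance clustering: Ward dendrogram, partitions, CWPACs.

Each chain with a finite PMAD on every dataset forms a performance
vector (one PMAD per dataset).  Complete vectors are Ward-clustered on
Euclidean distances — by default in log10 PMAD space, since raw PMADs
span many orders of magnitude and raw-space distances would be dominated
by the worst chains.  Cutting the dendrogram (default k=6) yields
partitions ordered best to worst by mean log10 PMAD and named
A1, A2, A3, B, C, D; "consistently well-performed" chains (CWPACs) are
flagged both strictly (good precision on every dataset) and by
partition membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .errors import ValidationError
from .precision import GOOD_CUTOFF, PrecisionAssessment

__all__ = [
    "PartitionSet",
    "performance_matrix",
    "euclidean_distance",
    "ward_cluster",
    "cut_partitions",
    "identify_cwpacs",
    "method_contribution",
    "heatmap_frame",
    "to_newick",
]

#: floor applied before log10 so exact-zero PMADs stay finite
LOG_FLOOR = 1e-18

#: heatmap color-scale clamp (log10 PMAD units)
HEATMAP_CLAMP = 5.0


def performance_matrix(
    assessments: Iterable[PrecisionAssessment],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot sweep assessments into a complete chain x dataset PMAD matrix.

    Returns ``(matrix, excluded)``: the matrix keeps only chains with a
    finite PMAD on every dataset; ``excluded`` lists dropped chains with
    the stage of their first failure.
    """
    rows = [
        {
            "chain": a.chain_label,
            "dataset": a.dataset_id,
            "pmad": a.pmad,
            "failure_stage": a.failure_stage,
        }
        for a in assessments
    ]
    if not rows:
        raise ValidationError("no assessments given")
    df = pd.DataFrame(rows)
    datasets = sorted(df["dataset"].unique())
    if len(datasets) < 2:
        raise ValidationError("performance vectors need >= 2 datasets")
    wide = df.pivot(index="chain", columns="dataset", values="pmad")[datasets]
    complete = wide.notna().all(axis=1)

    excluded_rows = []
    for chain in wide.index[~complete]:
        fails = df[(df["chain"] == chain) & df["pmad"].isna()]
        stages = sorted({s for s in fails["failure_stage"] if s})
        excluded_rows.append(
            {
                "chain": chain,
                "n_failed_datasets": int(len(fails)),
                "failure_stages": ";".join(stages),
            }
        )
    excluded = pd.DataFrame(
        excluded_rows, columns=["chain", "n_failed_datasets", "failure_stages"]
    )
    matrix = wide[complete].sort_index()
    if len(matrix) < 2:
        raise ValidationError("fewer than 2 chains with complete performance vectors")
    return matrix, excluded


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """sqrt of the summed squared per-dataset differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _cluster_space(matrix: pd.DataFrame, distance_space: str) -> np.ndarray:
    if distance_space == "log10":
        return np.log10(np.maximum(matrix.to_numpy(dtype=float), LOG_FLOOR))
    if distance_space == "raw":
        return matrix.to_numpy(dtype=float)
    raise ValidationError(f"distance_space must be 'log10' or 'raw', got {distance_space!r}")


def ward_cluster(matrix: pd.DataFrame, distance_space: str = "log10") -> np.ndarray:
    """Ward minimum-variance linkage of the chain performance vectors.

    Agglomerative merging via the Lance-Williams recurrence with Ward
    coefficients on Euclidean distances (squared-distance update
    convention); deterministic given input order.  Returns a scipy
    linkage matrix.
    """
    X = _cluster_space(matrix, distance_space)
    if len(X) < 2:
        raise ValidationError("ward_cluster needs >= 2 vectors")
    return sch.linkage(X, method="ward")


@dataclass
class PartitionSet:
    """A k-way cut of the dendrogram, partitions ordered best -> worst."""

    linkage: np.ndarray
    k: int
    labels: dict[str, str]            # chain -> partition name
    partition_names: list[str]        # best first
    mean_log10_pmad: dict[str, float]  # partition -> mean member log10 PMAD

    def members(self, name: str) -> list[str]:
        return [c for c, p in self.labels.items() if p == name]

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(self.members(name)) for name in self.partition_names}


def _partition_names(k: int) -> list[str]:
    if k == 6:
        return ["A1", "A2", "A3", "B", "C", "D"]
    return [f"P{i + 1}" for i in range(k)]


def cut_partitions(
    linkage: np.ndarray, matrix: pd.DataFrame, k: int = 6
) -> PartitionSet:
    """Cut the dendrogram into exactly k clusters and name them by quality.

    Partitions are ordered by ascending mean log10 PMAD of their members
    (best first); at k=6 the names are A1, A2, A3, B, C, D.
    """
    n = len(matrix)
    if not 2 <= k <= n:
        raise ValidationError(f"k must lie in [2, {n}], got {k}")
    flat = sch.fcluster(linkage, t=k, criterion="maxclust")
    if len(np.unique(flat)) != k:
        raise ValidationError(f"cut produced {len(np.unique(flat))} clusters, wanted {k}")
    log10 = np.log10(np.maximum(matrix.to_numpy(dtype=float), LOG_FLOOR))
    chain_ids = list(matrix.index)

    cluster_mean = {
        c: float(log10[flat == c].mean()) for c in np.unique(flat)
    }
    ordered = sorted(cluster_mean, key=cluster_mean.get)
    names = _partition_names(k)
    rename = {c: names[i] for i, c in enumerate(ordered)}
    labels = {chain_ids[i]: rename[flat[i]] for i in range(n)}
    return PartitionSet(
        linkage=linkage,
        k=k,
        labels=labels,
        partition_names=names,
        mean_log10_pmad={rename[c]: cluster_mean[c] for c in ordered},
    )


def identify_cwpacs(
    partitions: PartitionSet,
    matrix: pd.DataFrame,
    *,
    cutoff: float = GOOD_CUTOFF,
    partition_fraction: float = 0.9,
) -> pd.DataFrame:
    """Flag consistently well-performed chains.

    strict: the chain's PMAD is <= ``cutoff`` on every dataset.
    partition-based: the chain belongs to a partition in which at least
    ``partition_fraction`` of all member PMAD values are <= ``cutoff``.
    """
    pmads = matrix.to_numpy(dtype=float)
    strict = (pmads <= cutoff).all(axis=1)

    partition_ok: dict[str, bool] = {}
    for name in partitions.partition_names:
        members = partitions.members(name)
        if not members:
            partition_ok[name] = False
            continue
        block = matrix.loc[members].to_numpy(dtype=float)
        partition_ok[name] = float((block <= cutoff).mean()) >= partition_fraction

    records = []
    for i, chain in enumerate(matrix.index):
        part = partitions.labels[chain]
        records.append(
            {
                "chain": chain,
                "partition": part,
                "strict_cwpac": bool(strict[i]),
                "partition_cwpac": partition_ok[part],
            }
        )
    return pd.DataFrame(records)


def method_contribution(
    chains: Iterable[str], category: str
) -> dict[str, float]:
    """Percentage of chains in the set using each method of one category.

    Percentages over the methods of one category sum to 100.
    """
    position = {"transformation": 0, "normalization": 1, "imputation": 2}
    if category not in position:
        raise ValidationError(f"unknown category {category!r}")
    codes = [c.split("-")[position[category]] for c in chains]
    if not codes:
        raise ValidationError("empty chain set")
    out: dict[str, float] = {}
    for code in codes:
        out[code] = out.get(code, 0.0) + 1.0
    total = float(len(codes))
    return {code: 100.0 * n / total for code, n in sorted(out.items())}


def heatmap_frame(matrix: pd.DataFrame, clamp: float = HEATMAP_CLAMP) -> pd.DataFrame:
    """Chain x dataset log10 PMAD matrix, clamped to +/- ``clamp`` for display."""
    log10 = np.log10(np.maximum(matrix.to_numpy(dtype=float), LOG_FLOOR))
    return pd.DataFrame(
        np.clip(log10, -clamp, clamp), index=matrix.index, columns=matrix.columns
    )


def to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Export the dendrogram as a Newick string with chain labels."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, list(labels))
    return str(tree).strip()
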