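"""End-to-end pipeline: datasets -> sweep -> assessment -> clustering -> reports.

Configuration is a plain YAML file (see :class:`RunConfig.from_yaml`);
identical config + seed gives byte-identical outputs.  Individual chain
failures are recorded, never fatal; only a whole-stage error aborts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import io as sbio
from .chains import ChainParams, ChainSpec, enumerate_chains, parse_chain_label, sweep
from .cluster import (
    cut_partitions,
    heatmap_frame,
    identify_cwpacs,
    performance_matrix,
    to_newick,
    ward_cluster,
)
from .errors import ValidationError
from .impute import ImputeParams
from .normalize import NormalizeParams
from .precision import assess_sweep, category_frame, ranking_frame
from .simulate import default_benchmark_truths, generate_benchmark_suite
from .table import IntensityTable
from .transform import TransformParams

__all__ = ["RunConfig", "run_pipeline", "load_datasets"]

log = logging.getLogger("swathbench")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, resolvable from a YAML file."""

    out_dir: str = "swathbench_out"
    seed: int = 0
    # dataset sources: list of matrix paths (with optional group files) ...
    dataset_paths: list[str] = field(default_factory=list)
    group_paths: list[str] | None = None
    zero_as_missing: bool = False
    # ... or synthetic-suite parameters
    synthetic: dict[str, Any] | None = None
    # chain selection: "all" or explicit labels
    chains: str | list[str] = "all"
    # per-stage method parameters (keyword overrides)
    transform_params: dict[str, Any] = field(default_factory=dict)
    normalize_params: dict[str, Any] = field(default_factory=dict)
    impute_params: dict[str, Any] = field(default_factory=dict)
    # clustering
    k: int = 6
    distance_space: str = "log10"
    cwpac_cutoff: float = 0.7
    cwpac_partition_fraction: float = 0.9
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_datasets(config: RunConfig) -> list[IntensityTable]:
    """Resolve the config's dataset sources into tables."""
    if config.synthetic is not None and config.dataset_paths:
        raise ValidationError("give either dataset_paths or synthetic, not both")
    if config.synthetic is not None:
        opts = dict(config.synthetic)
        n = int(opts.pop("n_datasets", 7))
        return generate_benchmark_suite(n, seed=config.seed, **opts)
    if not config.dataset_paths:
        raise ValidationError("no dataset source configured")
    tables = []
    for i, path in enumerate(config.dataset_paths):
        group_path = None
        if config.group_paths:
            group_path = config.group_paths[i]
        tables.append(
            sbio.read_intensity_table(
                path, groups=group_path, zero_as_missing=config.zero_as_missing
            )
        )
    return tables


def _resolve_chains(config: RunConfig) -> list[ChainSpec]:
    if config.chains == "all":
        return enumerate_chains()
    if isinstance(config.chains, str):
        return [parse_chain_label(config.chains)]
    return [parse_chain_label(c) for c in config.chains]


def _chain_params(config: RunConfig) -> ChainParams:
    return ChainParams(
        transform=TransformParams(**config.transform_params),
        normalize=NormalizeParams(**config.normalize_params),
        impute=ImputeParams(**config.impute_params),
        base_seed=config.seed,
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full benchmark and write all reports; return the manifest."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    datasets = load_datasets(config)
    timings["load_datasets"] = time.time() - t0
    chains = _resolve_chains(config)
    params = _chain_params(config)

    t1 = time.time()
    results = sweep(datasets, chains, params, n_jobs=config.n_jobs)
    timings["sweep"] = time.time() - t1

    t2 = time.time()
    assessments = assess_sweep(results)
    by_dataset: dict[str, list] = {}
    for a in assessments:
        by_dataset.setdefault(a.dataset_id, []).append(a)
    rankings = {d: ranking_frame(block) for d, block in by_dataset.items()}
    timings["assessment"] = time.time() - t2

    partition_table = None
    heatmap = None
    newick = None
    cluster_info: dict[str, Any] = {}
    if len(datasets) >= 2 and len(chains) >= 2:
        t3 = time.time()
        try:
            matrix, excluded = performance_matrix(assessments)
            linkage = ward_cluster(matrix, config.distance_space)
            k = min(config.k, len(matrix))
            partitions = cut_partitions(linkage, matrix, k=k)
            cwpacs = identify_cwpacs(
                partitions,
                matrix,
                cutoff=config.cwpac_cutoff,
                partition_fraction=config.cwpac_partition_fraction,
            )
            partition_table = cwpacs.merge(
                excluded, how="outer", on="chain"
            ) if len(excluded) else cwpacs
            heatmap = heatmap_frame(matrix)
            newick = to_newick(linkage, list(matrix.index))
            cluster_info = {
                "n_clustered_chains": int(len(matrix)),
                "n_excluded_chains": int(len(excluded)),
                "partition_sizes": partitions.sizes,
                "n_strict_cwpacs": int(cwpacs["strict_cwpac"].sum()),
                "n_partition_cwpacs": int(cwpacs["partition_cwpac"].sum()),
            }
        except ValidationError as exc:
            log.warning("clustering skipped: %s", exc)
            cluster_info = {"skipped": str(exc)}
        timings["clustering"] = time.time() - t3

    manifest_files = sbio.write_results(
        out_dir,
        rankings=rankings,
        categories=category_frame(assessments),
        partition_table=partition_table,
        heatmap=heatmap,
        newick=newick,
    )

    n_failed = sum(1 for a in assessments if a.pmad is None)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_datasets": len(datasets),
        "n_chains": len(chains),
        "n_results": len(results),
        "n_failed_assessments": n_failed,
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "cluster": cluster_info,
        "files": [str(p) for p in manifest_files],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
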