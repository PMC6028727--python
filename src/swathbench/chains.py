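"""Enumeration and execution of analysis chains.

An analysis chain is the ordered triple transformation -> normalization ->
imputation, labeled by three-letter codes (e.g. ``LOG-MED-NON``).  The
full default registry yields 5 x 16 x 7 = 560 chains.  Stage errors are
captured as structured failures — a chain that cannot process a dataset
never aborts a sweep, mirroring real benchmark accounting where a
fraction of chains fails on some datasets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .errors import ChainStageError, NonConvergenceError, ValidationError
from .impute import ImputeParams, apply_imputation
from .normalize import NormalizeParams, apply_normalization
from .registry import DEFAULT_REGISTRY, MethodCode
from .simulate import derive_seed
from .table import IntensityTable
from .transform import TransformParams, apply_transformation

__all__ = [
    "ChainSpec",
    "ChainResult",
    "ChainParams",
    "enumerate_chains",
    "parse_chain_label",
    "apply_chain",
    "sweep",
]

STAGES = ("transformation", "normalization", "imputation")


@dataclass(frozen=True)
class ChainSpec:
    """Ordered method triple; ``label`` is 'TTT-NNN-III'."""

    transformation: str
    normalization: str
    imputation: str

    def __post_init__(self) -> None:
        for cat, code in zip(STAGES, self.codes):
            if code not in {m.code for m in DEFAULT_REGISTRY[cat]}:
                raise ValidationError(f"unknown {cat} code {code!r}")

    @property
    def codes(self) -> tuple[str, str, str]:
        return (self.transformation, self.normalization, self.imputation)

    @property
    def label(self) -> str:
        return "-".join(self.codes)

    def __str__(self) -> str:
        return self.label


def parse_chain_label(label: str) -> ChainSpec:
    parts = label.strip().upper().split("-")
    if len(parts) != 3:
        raise ValidationError(f"chain label must be TTT-NNN-III, got {label!r}")
    return ChainSpec(*parts)


@dataclass
class ChainParams:
    """Per-stage method parameters shared by every chain in a sweep."""

    transform: TransformParams = field(default_factory=TransformParams)
    normalize: NormalizeParams = field(default_factory=NormalizeParams)
    impute: ImputeParams = field(default_factory=ImputeParams)
    base_seed: int = 0

    def for_chain(self, chain: ChainSpec, dataset_id: str) -> "ChainParams":
        """Copy with stage codes set and seeds fanned out deterministically.

        The normalization seed depends only on (dataset, transformation,
        normalization) so prefix caching and per-chain execution agree.
        """
        from dataclasses import replace

        return ChainParams(
            transform=replace(self.transform, code=chain.transformation),
            normalize=replace(
                self.normalize,
                code=chain.normalization,
                seed=derive_seed(
                    self.base_seed, dataset_id, chain.transformation, chain.normalization
                ),
            ),
            impute=replace(
                self.impute,
                code=chain.imputation,
                seed=derive_seed(self.base_seed, dataset_id, chain.label, "impute"),
            ),
            base_seed=self.base_seed,
        )


@dataclass
class ChainResult:
    """Outcome of one chain on one dataset: a table or a structured failure."""

    chain: ChainSpec
    dataset_id: str
    table: IntensityTable | None = None
    failure_stage: str | None = None
    failure_class: str | None = None
    message: str | None = None

    def __post_init__(self) -> None:
        if (self.table is None) == (self.failure_stage is None):
            raise ValidationError("exactly one of table / failure must be set")

    @property
    def ok(self) -> bool:
        return self.table is not None


def enumerate_chains(
    registry: Mapping[str, Sequence[MethodCode]] | None = None,
) -> list[ChainSpec]:
    """Full Cartesian product of the registry, in lexicographic code order."""
    registry = registry or DEFAULT_REGISTRY
    per_cat = []
    for cat in STAGES:
        codes = sorted(m.code for m in registry[cat])
        if "NON" not in codes:
            raise ValidationError(f"category {cat} must contain NON")
        per_cat.append(codes)
    return [ChainSpec(t, n, i) for t, n, i in itertools.product(*per_cat)]


def apply_chain(
    table: IntensityTable,
    chain: ChainSpec,
    params: ChainParams | None = None,
) -> ChainResult:
    """Run one chain on one table, converting stage errors into failures."""
    params = (params or ChainParams()).for_chain(chain, table.dataset_id)
    try:
        out = apply_transformation(table, params.transform)
        out = apply_normalization(out, params.normalize)
        out = apply_imputation(out, params.impute)
    except ChainStageError as exc:
        return ChainResult(
            chain=chain,
            dataset_id=table.dataset_id,
            failure_stage=exc.stage,
            failure_class=exc.failure_class,
            message=str(exc),
        )
    except (np.linalg.LinAlgError, FloatingPointError) as exc:
        return ChainResult(
            chain=chain,
            dataset_id=table.dataset_id,
            failure_stage="imputation",
            failure_class="non-convergence",
            message=str(exc),
        )
    return ChainResult(chain=chain, dataset_id=table.dataset_id, table=out)


def _sweep_one_dataset(
    table: IntensityTable, chains: Sequence[ChainSpec], params: ChainParams
) -> list[ChainResult]:
    """All chains on one dataset, caching shared T and T-N prefixes.

    Chains share stage-1 and stage-1+2 outputs, so each transformation is
    computed once and each (transformation, normalization) pair once; the
    result is identical to running :func:`apply_chain` per chain.
    """

    def fail(chain: ChainSpec, exc: ChainStageError) -> ChainResult:
        return ChainResult(
            chain=chain,
            dataset_id=table.dataset_id,
            failure_stage=exc.stage,
            failure_class=exc.failure_class,
            message=str(exc),
        )

    t_cache: dict[str, IntensityTable | ChainStageError] = {}
    tn_cache: dict[tuple[str, str], IntensityTable | ChainStageError] = {}
    results: list[ChainResult] = []
    for chain in chains:
        p = params.for_chain(chain, table.dataset_id)
        t_key = chain.transformation
        if t_key not in t_cache:
            try:
                t_cache[t_key] = apply_transformation(table, p.transform)
            except ChainStageError as exc:
                t_cache[t_key] = exc
        t_out = t_cache[t_key]
        if isinstance(t_out, ChainStageError):
            results.append(fail(chain, t_out))
            continue

        tn_key = (chain.transformation, chain.normalization)
        if tn_key not in tn_cache:
            try:
                tn_cache[tn_key] = apply_normalization(t_out, p.normalize)
            except ChainStageError as exc:
                tn_cache[tn_key] = exc
            except (np.linalg.LinAlgError, FloatingPointError) as exc:
                tn_cache[tn_key] = NonConvergenceError(str(exc), stage="normalization")
        tn_out = tn_cache[tn_key]
        if isinstance(tn_out, ChainStageError):
            results.append(fail(chain, tn_out))
            continue

        try:
            out = apply_imputation(tn_out, p.impute)
        except ChainStageError as exc:
            results.append(fail(chain, exc))
            continue
        except (np.linalg.LinAlgError, FloatingPointError) as exc:
            results.append(
                fail(chain, NonConvergenceError(str(exc), stage="imputation"))
            )
            continue
        results.append(
            ChainResult(chain=chain, dataset_id=table.dataset_id, table=out)
        )
    return results


def sweep(
    datasets: Sequence[IntensityTable],
    chains: Sequence[ChainSpec] | None = None,
    params: ChainParams | None = None,
    n_jobs: int = 1,
) -> list[ChainResult]:
    """Evaluate every (chain, dataset) pair; failures never abort the sweep.

    Results are ordered dataset-major, chain order as given, regardless
    of ``n_jobs``; parallel execution (one job per dataset) is bit-identical
    to serial because all randomness is derived from per-identifier seeds.
    """
    if len(datasets) < 1:
        raise ValidationError("sweep needs >= 1 dataset")
    ids = [t.dataset_id for t in datasets]
    if len(set(ids)) != len(ids):
        raise ValidationError("dataset_ids must be unique within a sweep")
    chains = list(chains) if chains is not None else enumerate_chains()
    params = params or ChainParams()
    if n_jobs == 1:
        per_dataset = [_sweep_one_dataset(t, chains, params) for t in datasets]
    else:
        per_dataset = Parallel(n_jobs=n_jobs)(
            delayed(_sweep_one_dataset)(t, chains, params) for t in datasets
        )
    return [r for block in per_dataset for r in block]
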