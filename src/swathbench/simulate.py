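"""Synthetic SWATH/DIA-like intensity matrices with known ground truth.

The generator emulates the structure of real label-free benchmark
datasets: two groups of replicates, log-normal raw intensities, a
per-sample multiplicative bias (total-ion-current variation), additive
Gaussian noise on the log scale, and a mixture of intensity-dependent
(MNAR, logistic left-censoring) and completely random (MCAR) missingness.

Raw intensity for protein ``i`` in sample ``j``::

    x_ij = exp( base_i + effect_i * 1[group(j) = B] + log(scale_j) + eps_ij )

with ``eps_ij ~ Normal(0, noise_sd^2)``.  A cell is then set missing with
probability ``mcar_rate + (1 - mcar_rate) * logistic(-steepness * (log x_ij
- midpoint))``.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .table import IntensityTable

__all__ = [
    "SyntheticTruth",
    "generate_dataset",
    "generate_benchmark_suite",
    "default_benchmark_truths",
    "derive_seed",
]


def derive_seed(base_seed: int, *parts: object) -> int:
    """Deterministically fan a base seed out to a sub-seed (< 2**31)."""
    tag = ":".join(str(p) for p in parts)
    return (int(base_seed) ^ zlib.crc32(tag.encode())) % (2**31)


@dataclass
class SyntheticTruth:
    """Ground-truth parameters (and, after generation, realizations).

    ``base_abundance`` and ``sample_scale`` may be given explicitly; when
    None they are drawn (Normal log-abundance; log-uniform scale on
    [scale_low, scale_high]) and the realized arrays are returned on the
    truth object that accompanies the generated table.
    """

    n_proteins: int = 1000
    group_sizes: dict[str, int] = field(default_factory=lambda: {"A": 5, "B": 5})
    abundance_mean: float = 14.0      # natural-log intensity
    abundance_sd: float = 2.0
    scale_low: float = 0.5            # sample bias range (multiplicative)
    scale_high: float = 2.0
    noise_sd: float = 0.1             # additive sd on the natural-log scale
    frac_differential: float = 0.1
    effect_size: float = 0.6931471805599453  # ln 2 == 1 log2-fold change
    mnar_steepness: float = 1.5
    mnar_midpoint: float = 11.0       # natural-log intensity of 50% dropout
    mcar_rate: float = 0.02
    seed: int = 0
    # realized draws (filled by generate_dataset)
    base_abundance: np.ndarray | None = None
    sample_scale: np.ndarray | None = None
    differential_mask: np.ndarray | None = None

    def validate(self) -> None:
        for name in ("frac_differential", "mcar_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if not self.group_sizes:
            raise ValidationError("at least one group required")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValidationError(f"group {g!r} needs >= 2 replicates, got {n}")
        if self.scale_low <= 0 or self.scale_high < self.scale_low:
            raise ValidationError("sample scale range must be positive and ordered")
        if self.noise_sd < 0 or self.mnar_steepness < 0:
            raise ValidationError("noise_sd and mnar_steepness must be >= 0")


def generate_dataset(
    truth: SyntheticTruth, dataset_id: str = "sim"
) -> tuple[IntensityTable, SyntheticTruth]:
    """Draw one dataset; returns the table and the truth with realized draws."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    p = truth.n_proteins
    groups_order = list(truth.group_sizes)
    sample_ids: list[str] = []
    group_map: dict[str, str] = {}
    for g in groups_order:
        for r in range(truth.group_sizes[g]):
            sid = f"{g}{r + 1}"
            sample_ids.append(sid)
            group_map[sid] = g
    s = len(sample_ids)

    base = (
        np.asarray(truth.base_abundance, dtype=float)
        if truth.base_abundance is not None
        else rng.normal(truth.abundance_mean, truth.abundance_sd, size=p)
    )
    if truth.sample_scale is not None:
        scale = np.asarray(truth.sample_scale, dtype=float)
    else:
        scale = np.exp(
            rng.uniform(np.log(truth.scale_low), np.log(truth.scale_high), size=s)
        )
    if np.any(scale <= 0):
        raise ValidationError("sample_scale must be positive")
    diff_mask = (
        np.asarray(truth.differential_mask, dtype=bool)
        if truth.differential_mask is not None
        else rng.random(p) < truth.frac_differential
    )
    # effect applies to every non-first group (two-group designs in practice)
    in_alt_group = np.array([group_map[sid] != groups_order[0] for sid in sample_ids])
    effect = np.where(diff_mask, truth.effect_size, 0.0)

    eps = rng.normal(0.0, truth.noise_sd, size=(p, s)) if truth.noise_sd > 0 else 0.0
    log_x = (
        base[:, None]
        + np.outer(effect, in_alt_group.astype(float))
        + np.log(scale)[None, :]
        + eps
    )
    x = np.exp(log_x)

    # missingness: MCAR floor plus logistic left-censoring in log intensity
    if truth.mnar_steepness > 0:
        p_mnar = 1.0 / (1.0 + np.exp(truth.mnar_steepness * (log_x - truth.mnar_midpoint)))
    else:
        p_mnar = np.zeros_like(log_x)
    p_miss = truth.mcar_rate + (1.0 - truth.mcar_rate) * p_mnar
    if truth.mcar_rate > 0 or truth.mnar_steepness > 0:
        drop = rng.random((p, s)) < p_miss
        x = np.where(drop, np.nan, x)

    table = IntensityTable(
        protein_ids=[f"P{i + 1:05d}" for i in range(p)],
        sample_ids=sample_ids,
        values=x,
        groups=group_map,
        dataset_id=dataset_id,
    )
    realized = replace(
        truth, base_abundance=base, sample_scale=scale, differential_mask=diff_mask
    )
    return table, realized


#: replicate structure of the seven benchmark datasets the suite emulates
_DEFAULT_GROUP_SIZES: list[tuple[int, int]] = [
    (3, 3), (6, 6), (10, 10), (18, 18), (18, 18), (20, 20), (72, 44),
]


def default_benchmark_truths(
    n_datasets: int = 7,
    *,
    n_proteins: int = 1000,
    noise_sd: float = 0.1,
    seed: int = 0,
    mcar_rate: float = 0.02,
    mnar_steepness: float = 1.5,
) -> list[SyntheticTruth]:
    """Per-dataset truth profiles mimicking the benchmark sample sizes.

    The default seven profiles have total sample counts
    6, 12, 20, 36, 36, 40 and 116; beyond seven the profiles cycle.
    """
    truths = []
    for d in range(n_datasets):
        na, nb = _DEFAULT_GROUP_SIZES[d % len(_DEFAULT_GROUP_SIZES)]
        truths.append(
            SyntheticTruth(
                n_proteins=n_proteins,
                group_sizes={"A": na, "B": nb},
                noise_sd=noise_sd,
                mcar_rate=mcar_rate,
                mnar_steepness=mnar_steepness,
                seed=derive_seed(seed, "dataset", d),
            )
        )
    return truths


def generate_benchmark_suite(
    n_datasets: int = 7,
    truths: Sequence[SyntheticTruth] | None = None,
    *,
    seed: int = 0,
    **profile_kwargs,
) -> list[IntensityTable]:
    """Generate a multi-dataset benchmark suite (>= 2 datasets required)."""
    if n_datasets < 2:
        raise ValidationError("a benchmark suite needs >= 2 datasets")
    if truths is None:
        truths = default_benchmark_truths(n_datasets, seed=seed, **profile_kwargs)
    if len(truths) != n_datasets:
        raise ValidationError(f"expected {n_datasets} truth profiles, got {len(truths)}")
    return [
        generate_dataset(t, dataset_id=f"sim{d + 1:02d}")[0]
        for d, t in enumerate(truths)
    ]
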