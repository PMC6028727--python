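"""Precision assessment of processed tables via pooled intragroup MAD.

PMAD summarizes technical reproducibility: for each replicate group and
each protein with at least two observed values in that group, the median
absolute deviation from the within-group median is taken; these MADs are
averaged over eligible proteins within the group, and the group scores
averaged over groups.  No 1.4826 consistency constant is applied — the
statistic is the raw pooled MAD, so PMAD(c*X) = c*PMAD(X) for c > 0.
Lower is better; conventional cutoffs call <= 0.3 superior, <= 0.7 good
and > 0.7 poor precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chains import ChainResult
from .errors import AssessmentError, ValidationError
from .table import IntensityTable

__all__ = [
    "PrecisionAssessment",
    "compute_pmad",
    "classify_precision",
    "rank_chains",
    "assess_sweep",
    "ranking_frame",
    "category_frame",
]

SUPERIOR_CUTOFF = 0.3
GOOD_CUTOFF = 0.7

CATEGORIES = ("superior", "good", "poor", "failed")


def compute_pmad(table: IntensityTable) -> float:
    """Pooled intragroup median absolute deviation of a table.

    Requires every group to have >= 2 samples.  Proteins with fewer than
    two observed values in a group are excluded from that group's mean;
    groups left with no eligible protein are dropped, and if every group
    is empty the table is unassessable.
    """
    group_scores: list[float] = []
    for g in table.group_names:
        cols = table.group_columns(g)
        if cols.size < 2:
            raise ValidationError(f"group {g!r} has < 2 samples; PMAD undefined")
        sub = table.values[:, cols]
        n_obs = np.sum(~np.isnan(sub), axis=1)
        eligible = n_obs >= 2
        if not eligible.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(sub[eligible], axis=1)
            mad = np.nanmedian(np.abs(sub[eligible] - med[:, None]), axis=1)
        group_scores.append(float(np.mean(mad)))
    if not group_scores:
        raise AssessmentError("no protein with >= 2 observed replicates in any group")
    return float(np.mean(group_scores))


def classify_precision(pmad: float | None) -> str:
    """Map a PMAD value to superior / good / poor (failed when unavailable)."""
    if pmad is None:
        return "failed"
    if pmad < 0 or not math.isfinite(pmad):
        raise ValidationError(f"PMAD must be finite and >= 0, got {pmad}")
    if pmad <= SUPERIOR_CUTOFF:
        return "superior"
    if pmad <= GOOD_CUTOFF:
        return "good"
    return "poor"


@dataclass
class PrecisionAssessment:
    """PMAD of one chain on one dataset, with category and (later) rank."""

    chain_label: str
    dataset_id: str
    pmad: float | None
    failure_stage: str | None = None
    failure_class: str | None = None
    rank: int | None = None

    @property
    def log10_pmad(self) -> float | None:
        if self.pmad is None:
            return None
        return math.log10(max(self.pmad, 1e-300))

    @property
    def category(self) -> str:
        return classify_precision(self.pmad)


def rank_chains(
    assessments: Sequence[PrecisionAssessment],
) -> list[PrecisionAssessment]:
    """Order one dataset's assessments by ascending PMAD.

    Ties break by chain label; failed chains carry no rank and are listed
    after the ranked ones.
    """
    datasets = {a.dataset_id for a in assessments}
    if len(datasets) > 1:
        raise ValidationError(f"rank_chains mixes datasets: {sorted(datasets)}")
    available = [a for a in assessments if a.pmad is not None]
    failed = [a for a in assessments if a.pmad is None]
    if not available:
        raise ValidationError("no available PMAD to rank")
    available.sort(key=lambda a: (a.pmad, a.chain_label))
    for pos, a in enumerate(available, start=1):
        a.rank = pos
    failed.sort(key=lambda a: a.chain_label)
    for a in failed:
        a.rank = None
    return available + failed


def assess_sweep(results: Iterable[ChainResult]) -> list[PrecisionAssessment]:
    """PMAD for every chain result; assessment errors become failures too."""
    out: list[PrecisionAssessment] = []
    for r in results:
        if not r.ok:
            out.append(
                PrecisionAssessment(
                    chain_label=r.chain.label,
                    dataset_id=r.dataset_id,
                    pmad=None,
                    failure_stage=r.failure_stage,
                    failure_class=r.failure_class,
                )
            )
            continue
        try:
            pmad = compute_pmad(r.table)
            if not math.isfinite(pmad):
                raise AssessmentError("non-finite PMAD")
            out.append(
                PrecisionAssessment(
                    chain_label=r.chain.label, dataset_id=r.dataset_id, pmad=pmad
                )
            )
        except AssessmentError as exc:
            out.append(
                PrecisionAssessment(
                    chain_label=r.chain.label,
                    dataset_id=r.dataset_id,
                    pmad=None,
                    failure_stage=exc.stage,
                    failure_class=exc.failure_class,
                )
            )
    return out


def category_frame(assessments: Sequence[PrecisionAssessment]) -> pd.DataFrame:
    """Chain x dataset table of precision categories (circle-size view)."""
    rows = [
        {"chain": a.chain_label, "dataset": a.dataset_id, "category": a.category}
        for a in assessments
    ]
    if not rows:
        raise ValidationError("no assessments given")
    return (
        pd.DataFrame(rows)
        .pivot(index="chain", columns="dataset", values="category")
        .sort_index()
    )


def ranking_frame(assessments: Sequence[PrecisionAssessment]) -> pd.DataFrame:
    """Ranked TSV-ready table for one dataset: chain, pmad, log10, category, rank."""
    ranked = rank_chains(list(assessments))
    return pd.DataFrame(
        {
            "chain": [a.chain_label for a in ranked],
            "pmad": [a.pmad for a in ranked],
            "log10_pmad": [a.log10_pmad for a in ranked],
            "category": [a.category for a in ranked],
            "rank": [a.rank for a in ranked],
            "failure_stage": [a.failure_stage or "" for a in ranked],
            "failure_class": [a.failure_class or "" for a in ranked],
        }
    )
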