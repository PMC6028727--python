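"""Core data model: a feature x sample intensity matrix with group labels.

The :class:`IntensityTable` is the object every chain stage maps to itself.
Missing cells are encoded as NaN in ``values``; ``missing_mask`` is derived
from that encoding, so a cell flagged missing can never carry a value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["IntensityTable"]


@dataclass
class IntensityTable:
    """Protein (or peptide) intensities: rows = features, columns = samples.

    Parameters
    ----------
    protein_ids
        Unique row identifiers.
    sample_ids
        Unique column identifiers.
    values
        Real matrix of shape ``(len(protein_ids), len(sample_ids))``.
        NaN marks a missing (unobserved) cell.  Raw intensities are
        nonnegative-or-missing; transformed values may be any real.
    groups
        Mapping from every sample id to its group label.
    dataset_id
        Optional identifier carried through the pipeline for bookkeeping.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        missing = set(self.sample_ids) - set(self.groups)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)}")
        extra = set(self.groups) - set(self.sample_ids)
        if extra:
            raise ValidationError(f"group labels for unknown samples: {sorted(extra)}")
        if not self.groups:
            raise ValidationError("at least one group required")

    # -- shape and masks -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (proteins x samples); True = not observed."""
        return np.isnan(self.values)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def observed_values(self) -> np.ndarray:
        """All observed cell values as a flat array."""
        return self.values[self.observed_mask]

    # -- groups ----------------------------------------------------------
    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of samples belonging to ``group``."""
        return np.array(
            [j for j, s in enumerate(self.sample_ids) if self.groups[s] == group],
            dtype=int,
        )

    # -- functional updates ----------------------------------------------
    def with_values(self, values: np.ndarray) -> "IntensityTable":
        """A copy of this table carrying a new value matrix (same layout)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def copy(self) -> "IntensityTable":
        return replace(self, values=self.values.copy(), groups=dict(self.groups))

    def equals(self, other: "IntensityTable") -> bool:
        """Exact equality: ids, groups, values (NaN == NaN)."""
        return (
            self.protein_ids == other.protein_ids
            and self.sample_ids == other.sample_ids
            and self.groups == other.groups
            and np.array_equal(self.values, other.values, equal_nan=True)
        )
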