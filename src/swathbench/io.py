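"""Readers and writers for delimited intensity matrices and reports.

Layout on disk: row 1 holds sample ids, column 1 holds protein ids.
Group annotation comes from a side file (``sample_id<TAB>group``) or an
inline second header row whose first cell is ``group``.  Missing cells are
written as a configurable token (default ``NA``); an opt-in flag treats
exact 0 as missing on read, matching OpenSWATH-style exports.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .table import IntensityTable

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_group_file",
    "write_group_file",
    "write_results",
]

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_group_file(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (sample_id, group) annotation file."""
    groups: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 1:
            parts = line.split(",")
        if len(parts) < 2:
            raise ValidationError(f"{path}: line {line_no}: expected sample<TAB>group")
        sample, group = parts[0].strip(), parts[1].strip()
        if sample in groups:
            raise ValidationError(f"{path}: duplicate sample id {sample!r}")
        groups[sample] = group
    return groups


def write_group_file(groups: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_intensity_table(
    path: str | os.PathLike,
    *,
    delimiter: str | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    zero_as_missing: bool = False,
    groups: Mapping[str, str] | str | os.PathLike | None = None,
    dataset_id: str | None = None,
) -> IntensityTable:
    """Parse a delimited intensity matrix into an :class:`IntensityTable`.

    ``groups`` may be a mapping, a path to a side annotation file, or None
    when the file carries an inline second header row starting with
    ``group``.  Cells equal to a missing token (and, optionally, exact 0)
    are flagged missing.  Non-numeric non-missing cells raise a parse error
    naming the offending row and column.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValidationError(f"{path}: duplicate sample ids in header")
    raw = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str,
                      keep_default_na=False)
    sample_ids = [str(c) for c in header]

    inline_groups: dict[str, str] | None = None
    if len(raw.index) and str(raw.index[0]).lower() in {"group", "#group"}:
        inline_groups = dict(zip(sample_ids, (str(v).strip() for v in raw.iloc[0])))
        raw = raw.iloc[1:]

    protein_ids = [str(i) for i in raw.index]
    if len(set(protein_ids)) != len(protein_ids):
        raise ValidationError(f"{path}: duplicate protein ids")

    cells = raw.to_numpy(dtype=object)
    values = np.empty(cells.shape, dtype=float)
    token_set = {t.strip() for t in missing_tokens}
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            cell = str(cells[i, j]).strip()
            if cell in token_set:
                values[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at protein "
                    f"{protein_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            values[i, j] = np.nan if (zero_as_missing and v == 0.0) else v

    if groups is None:
        if inline_groups is None:
            raise ValidationError(
                f"{path}: no group annotation (no inline 'group' row and no side file)"
            )
        group_map = inline_groups
    elif isinstance(groups, (str, os.PathLike)):
        group_map = read_group_file(groups)
    else:
        group_map = dict(groups)
    group_map = {s: group_map[s] for s in sample_ids if s in group_map}

    return IntensityTable(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        values=values,
        groups=group_map,
        dataset_id=dataset_id or path.stem,
    )


def write_intensity_table(
    table: IntensityTable,
    path: str | os.PathLike,
    *,
    delimiter: str | None = None,
    missing_token: str = "NA",
    inline_groups: bool = False,
) -> None:
    """Write a table in the same layout readers expect (full precision)."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        fh.write("protein" + sep + sep.join(table.sample_ids) + "\n")
        if inline_groups:
            fh.write("group" + sep + sep.join(table.groups[s] for s in table.sample_ids) + "\n")
        for i, pid in enumerate(table.protein_ids):
            row = [
                missing_token if np.isnan(v) else repr(float(v))
                for v in table.values[i]
            ]
            fh.write(pid + sep + sep.join(row) + "\n")


def write_results(
    out_dir: str | os.PathLike,
    *,
    tables: Mapping[str, IntensityTable] | None = None,
    rankings: Mapping[str, pd.DataFrame] | None = None,
    categories: pd.DataFrame | None = None,
    partition_table: pd.DataFrame | None = None,
    heatmap: pd.DataFrame | None = None,
    newick: str | None = None,
    missing_token: str = "NA",
) -> list[Path]:
    """Write pipeline artifacts as TSV under ``out_dir``; return the manifest.

    ``rankings`` maps dataset id -> per-chain ranking table (chain, pmad,
    log10_pmad, category, rank); ``heatmap`` is the chain x dataset log10
    PMAD matrix behind the clustered-performance view.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    for name, table in (tables or {}).items():
        p = out_dir / f"{name}.tsv"
        write_intensity_table(table, p, missing_token=missing_token, inline_groups=True)
        manifest.append(p)
    for dataset_id, df in (rankings or {}).items():
        p = out_dir / f"ranking_{dataset_id}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep="")
        manifest.append(p)
    if categories is not None:
        p = out_dir / "categories.tsv"
        categories.to_csv(p, sep="\t", index=True, index_label="chain")
        manifest.append(p)
    if partition_table is not None:
        p = out_dir / "partitions.tsv"
        partition_table.to_csv(p, sep="\t", index=False)
        manifest.append(p)
    if heatmap is not None:
        p = out_dir / "heatmap_log10_pmad.tsv"
        heatmap.to_csv(p, sep="\t", index=True, index_label="chain")
        manifest.append(p)
    if newick is not None:
        p = out_dir / "dendrogram.nwk"
        p.write_text(newick)
        manifest.append(p)
    return manifest
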