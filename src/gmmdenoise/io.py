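"""Reading and writing ASV count tables and size-annotated FASTA files.

The central container is :class:`ASVTable`: one row per amplicon sequence
variant (ASV), one column per sample, integer read counts.  Abundance-based
filtering works on the per-ASV total across samples, so rows whose total is
zero are dropped on input (log10 of zero is undefined downstream, and real
ASV tables only contain observed variants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import TableFormatError, TableParseError

logger = logging.getLogger(__name__)

__all__ = [
    "ASVTable",
    "read_count_table",
    "write_count_table",
    "read_fasta_sizes",
    "write_fasta_sizes",
]


@dataclass
class ASVTable:
    """Read counts of unique sequence variants across samples.

    Parameters
    ----------
    asv_ids : list of str
        Unique identifiers, one per row.
    counts : ndarray of shape (n_asvs, n_samples)
        Non-negative integer read counts.
    sample_ids : list of str
        Column identifiers.
    sequences : dict, optional
        Maps an ASV id to its nucleotide string; keys must be a subset of
        ``asv_ids``.
    """

    asv_ids: list[str]
    counts: np.ndarray
    sample_ids: list[str]
    sequences: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        n, m = self.counts.shape
        if len(self.asv_ids) != n:
            raise ValueError(f"{len(self.asv_ids)} ids for {n} count rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} columns")
        if len(set(self.asv_ids)) != n:
            raise TableFormatError("ASV ids are not unique")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if self.sequences is not None:
            extra = set(self.sequences) - set(self.asv_ids)
            if extra:
                raise ValueError(f"sequences keyed by unknown ids: {sorted(extra)[:5]}")

    @property
    def total(self) -> np.ndarray:
        """Per-ASV read count summed over samples."""
        return self.counts.sum(axis=1)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def select(self, index: np.ndarray) -> "ASVTable":
        """Row subset (boolean mask or integer index), preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ids = [self.asv_ids[i] for i in index]
        seqs = None
        if self.sequences is not None:
            seqs = {i: self.sequences[i] for i in ids if i in self.sequences}
        return ASVTable(ids, self.counts[index], list(self.sample_ids), seqs)

    def select_samples(self, sample_ids: list[str], drop_empty: bool = True) -> "ASVTable":
        """Column subset; optionally drop ASVs unobserved in those samples."""
        cols = [self.sample_ids.index(s) for s in sample_ids]
        sub = ASVTable(list(self.asv_ids), self.counts[:, cols], list(sample_ids),
                       dict(self.sequences) if self.sequences else None)
        if drop_empty:
            sub = sub.select(sub.total >= 1)
        return sub

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "asv_id", self.asv_ids)
        return df


def _parse_counts(df: pd.DataFrame, path) -> np.ndarray:
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        as_float = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        nonint = ~np.isnan(as_float) & (np.floor(as_float) != as_float)
        bad = np.isnan(as_float) | nonint
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise TableParseError(
                f"{path}: cell at row {i + 1}, column '{col}' is not a "
                f"non-negative integer: {df[col].iloc[i]!r}"
            )
        col_vals = as_float.astype(np.int64)
        if (col_vals < 0).any():
            i = int(np.flatnonzero(col_vals < 0)[0])
            raise TableParseError(
                f"{path}: negative count at row {i + 1}, column '{col}'"
            )
        values[:, j] = col_vals
    return values


def read_count_table(
    path,
    delimiter: str = "\t",
    id_column: str | None = None,
    sample_columns: list[str] | str = "all-numeric",
) -> ASVTable:
    """Read a delimited ASV-by-sample count table.

    Parameters
    ----------
    path : path-like
    delimiter : str
        Field separator (tab by default, ``","`` for CSV).
    id_column : str, optional
        Name of the identifier column; defaults to the first column.
    sample_columns : list of str or "all-numeric"
        Which columns hold counts; by default every non-id column.

    Rows whose total count is zero are dropped with a logged warning.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] == 0:
        raise TableFormatError(f"{path}: no columns found")
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise TableFormatError(f"{path}: id column '{id_column}' not present")
    if list(df.columns).count(id_column) > 1:
        raise TableFormatError(f"{path}: duplicate id column '{id_column}'")
    ids = df[id_column].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = df[id_column][df[id_column].duplicated()].iloc[0]
        raise TableFormatError(f"{path}: duplicate ASV id {dupes!r}")
    if sample_columns == "all-numeric":
        cols = [c for c in df.columns if c != id_column]
    else:
        missing = [c for c in sample_columns if c not in df.columns]
        if missing:
            raise TableFormatError(f"{path}: sample columns not found: {missing}")
        cols = list(sample_columns)
    if not cols:
        raise TableFormatError(f"{path}: no sample columns")
    counts = _parse_counts(df[cols], path)
    table = ASVTable(ids, counts, cols)
    zero = table.total == 0
    if zero.any():
        logger.warning("%s: dropping %d ASVs with zero total reads", path, int(zero.sum()))
        table = table.select(~zero)
    return table


def write_count_table(table: ASVTable, path, delimiter: str = "\t") -> None:
    """Write a count table; inverse of :func:`read_count_table` (row order kept)."""
    table.to_frame().to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def _parse_size(description: str, path) -> tuple[str, int]:
    fields = [f for f in description.strip().split(";") if f]
    name = fields[0].strip()
    for f in fields[1:]:
        if "=" in f:
            key, _, val = f.partition("=")
            if key.strip() == "size":
                try:
                    size = int(val)
                except ValueError:
                    size = -1
                if size <= 0:
                    raise TableFormatError(
                        f"{path}: header '{description}' has invalid size annotation"
                    )
                return name, size
    raise TableFormatError(f"{path}: header '{description}' lacks a ';size=N' annotation")


def read_fasta_sizes(path) -> ASVTable:
    """Read a dereplicated FASTA whose headers carry usearch-style ``;size=N``.

    Returns a single-pseudo-sample table: sizes become the totals and the
    sequences are stored verbatim (case preserved).
    """
    ids: list[str] = []
    sizes: list[int] = []
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name, size = _parse_size(record.description, path)
        ids.append(name)
        sizes.append(size)
        seqs[name] = str(record.seq)
    counts = np.asarray(sizes, dtype=np.int64)[:, None]
    return ASVTable(ids, counts, ["size"], seqs)


def write_fasta_sizes(table: ASVTable, path) -> None:
    """Write sequences with ``;size=N`` headers; inverse of :func:`read_fasta_sizes`."""
    if table.sequences is None:
        raise ValueError("table carries no sequences")
    totals = table.total
    with open(path, "w", newline="\n") as fh:
        for i, asv in enumerate(table.asv_ids):
            fh.write(f">{asv};size={int(totals[i])}\n{table.sequences[asv]}\n")
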