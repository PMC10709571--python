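"""Count-table and design-table I/O, and stacking of per-aligner tables.

The difficult-gene model works on a single gene x (sample * mapper) matrix
obtained by placing the count tables produced by each read aligner side by
side.  This module provides the containers for plain per-mapper tables
(:class:`CountTable`), the experimental design (:class:`DesignTable`) and
the combined matrix (:class:`StackedCounts`), plus readers/writers for the
featureCounts tab-separated dialect and plain gene x sample matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "DesignTable",
    "StackedCounts",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "stack_mappers",
    "unstack",
]

#: annotation columns of featureCounts v1.x output, dropped on read
FEATURECOUNTS_ANNOT_COLS = ("Chr", "Start", "End", "Strand", "Length")

#: separator joining sample and mapper ids into a stacked column name
DEFAULT_SEP = "__"


def _check_ids_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dup}")


@dataclass
class CountTable:
    """Gene x sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (G, n) integer

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_ids_unique(self.gene_ids, "gene")
        _check_ids_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            g, s = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self.counts = counts

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy())

    def reorder_genes(self, gene_ids: Sequence[str]) -> "CountTable":
        """Return a copy with rows reordered to *gene_ids* (id-keyed join)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise ValueError(f"gene id(s) not in table: {missing[:10]}")
        idx = np.array([pos[g] for g in gene_ids])
        return CountTable(list(gene_ids), list(self.sample_ids), self.counts[idx])

    def select_genes(self, keep: Sequence[str]) -> "CountTable":
        return self.reorder_genes(list(keep))


@dataclass
class DesignTable:
    """Per-sample experimental group assignment.

    Requires at least two groups and at least two samples per group — the
    group factor must be testable.
    """

    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = [str(g) for g in self.groups]
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups have different lengths")
        _check_ids_unique(self.sample_ids, "sample")
        counts = pd.Series(self.groups).value_counts()
        if len(counts) < 2:
            raise ValueError("design must contain at least 2 distinct groups")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"every group needs >= 2 samples; too small: {list(small.index)}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def group_levels(self) -> list[str]:
        return sorted(set(self.groups))

    def group_of(self, sample_id: str) -> str:
        try:
            return self.groups[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in design") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups})


@dataclass
class StackedCounts:
    """Combined gene x (sample * mapper) count matrix.

    ``columns`` holds one ``(sample_id, mapper_id, group)`` triple per matrix
    column, ordered mapper-major.  ``n`` biological samples observed by each
    of ``k`` mappers give ``n * k`` columns.
    """

    gene_ids: list[str]
    columns: list[tuple[str, str, str]]  # (sample_id, mapper_id, group)
    counts: np.ndarray  # (G, n*k)
    sep: str = DEFAULT_SEP

    def __post_init__(self) -> None:
        _check_ids_unique(self.gene_ids, "gene")
        pairs = [(s, m) for s, m, _ in self.columns]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (sample, mapper) column")
        per_mapper: dict[str, set[str]] = {}
        for s, m, _ in self.columns:
            per_mapper.setdefault(m, set()).add(s)
        sets = list(per_mapper.values())
        if any(s != sets[0] for s in sets[1:]):
            raise ValueError("mappers do not cover an identical sample set")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.columns)):
            raise ValueError("count matrix shape does not match ids")

    @property
    def mappers(self) -> list[str]:
        out: list[str] = []
        for _, m, _ in self.columns:
            if m not in out:
                out.append(m)
        return out

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for s, _, _ in self.columns:
            if s not in out:
                out.append(s)
        return out

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_mappers(self) -> int:
        return len(self.mappers)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def column_ids(self) -> list[str]:
        return [f"{s}{self.sep}{m}" for s, m, _ in self.columns]

    @property
    def mapper_labels(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.columns])

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([g for _, _, g in self.columns])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.column_ids)

    def select_genes(self, keep: Sequence[str]) -> "StackedCounts":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in keep], dtype=int)
        return StackedCounts(list(keep), list(self.columns), self.counts[idx],
                             sep=self.sep)


def read_counts(path: str | Path, dialect: str = "featurecounts") -> CountTable:
    """Read a count table.

    ``featurecounts`` dialect: tab-separated, leading ``#`` comment lines,
    header ``Geneid Chr Start End Strand Length <sample...>``; the six
    annotation columns are dropped.  ``matrix`` dialect: first column is the
    gene id, remaining columns are samples (tab- or comma-separated).
    """
    path = Path(path)
    if dialect not in ("featurecounts", "matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "featurecounts" else None
    if sep is None:
        # sniff delimiter for plain matrices: tab wins over comma
        with open(path) as fh:
            first = fh.readline()
            while first.startswith("#"):
                first = fh.readline()
        sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if dialect == "featurecounts":
        if df.columns[0] != "Geneid":
            raise ValueError(
                f"featureCounts dialect requires first column 'Geneid', got "
                f"{df.columns[0]!r}"
            )
        expected = list(FEATURECOUNTS_ANNOT_COLS)
        got = list(df.columns[1:6])
        if got != expected:
            raise ValueError(
                f"featureCounts annotation columns {expected} expected, got {got}"
            )
        gene_col = df.columns[0]
        sample_cols = list(df.columns[6:])
    else:
        gene_col = df.columns[0]
        sample_cols = list(df.columns[1:])
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    gene_ids = df[gene_col].astype(str).tolist()
    _check_ids_unique(gene_ids, "gene")
    counts = np.empty((len(gene_ids), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric count at gene {gene_ids[row]!r}, "
                f"column {col!r}: {df[col].iloc[row]!r}"
            )
        arr = vals.to_numpy()
        if (arr < 0).any():
            row = int(np.argmin(arr))
            raise ValueError(
                f"{path}: negative count at gene {gene_ids[row]!r}, column {col!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            row = int(np.flatnonzero(arr != np.round(arr))[0])
            raise ValueError(
                f"{path}: non-integral count at gene {gene_ids[row]!r}, "
                f"column {col!r}"
            )
        counts[:, j] = np.round(arr).astype(np.int64)
    return CountTable(gene_ids, sample_cols, counts)


def write_counts(table: CountTable, path: str | Path,
                 dialect: str = "matrix") -> None:
    """Write a count table as TSV in either dialect."""
    path = Path(path)
    df = table.to_frame()
    if dialect == "matrix":
        df.to_csv(path, sep="\t")
    elif dialect == "featurecounts":
        out = pd.DataFrame({"Geneid": table.gene_ids})
        out["Chr"] = "NA"
        out["Start"] = 1
        out["End"] = 1
        out["Strand"] = "+"
        out["Length"] = 1
        for s in table.sample_ids:
            out[s] = df[s].to_numpy()
        with open(path, "w") as fh:
            fh.write("# Program:ambigene; synthetic annotation fields\n")
            out.to_csv(fh, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_design(path: str | Path) -> DesignTable:
    """Read a design table (TSV/CSV with columns ``sample_id``, ``group``)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: design table missing column {col!r}")
    return DesignTable(df["sample_id"].tolist(), df["group"].tolist())


def write_design(design: DesignTable, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def stack_mappers(tables: Mapping[str, CountTable], design: DesignTable,
                  sep: str = DEFAULT_SEP) -> StackedCounts:
    """Combine per-mapper count tables into one stacked matrix.

    All tables must share the identical gene set (any row order) and the
    identical sample set; every sample must appear in *design*.  Columns are
    ordered mapper-major (mappers in the given mapping order), samples within
    a mapper following the design order.
    """
    if len(tables) < 1:
        raise ValueError("no tables given")
    mapper_ids = list(tables)
    ref_genes = list(tables[mapper_ids[0]].gene_ids)
    ref_gene_set = set(ref_genes)
    for m in mapper_ids[1:]:
        gset = set(tables[m].gene_ids)
        if gset != ref_gene_set:
            only_ref = sorted(ref_gene_set - gset)
            only_m = sorted(gset - ref_gene_set)
            raise ValueError(
                f"gene sets differ between mappers {mapper_ids[0]!r} and {m!r}; "
                f"only in {mapper_ids[0]!r}: {only_ref[:10]}; "
                f"only in {m!r}: {only_m[:10]}"
            )
    sample_set = set(tables[mapper_ids[0]].sample_ids)
    for m in mapper_ids[1:]:
        if set(tables[m].sample_ids) != sample_set:
            raise ValueError(
                f"sample sets differ across mappers (mapper {m!r})"
            )
    missing = sample_set - set(design.sample_ids)
    if missing:
        raise ValueError(f"sample(s) missing from design: {sorted(missing)}")
    # design order restricted to samples present in the tables
    samples = [s for s in design.sample_ids if s in sample_set]
    columns: list[tuple[str, str, str]] = []
    blocks: list[np.ndarray] = []
    for m in mapper_ids:
        t = tables[m].reorder_genes(ref_genes)
        col_idx = [t.sample_ids.index(s) for s in samples]
        blocks.append(t.counts[:, col_idx])
        for s in samples:
            columns.append((s, m, design.group_of(s)))
    return StackedCounts(ref_genes, columns, np.hstack(blocks), sep=sep)


def unstack(stacked: StackedCounts) -> tuple[dict[str, CountTable], DesignTable]:
    """Split a stacked matrix back into per-mapper tables and a design."""
    tables: dict[str, CountTable] = {}
    samples = stacked.sample_ids
    for m in stacked.mappers:
        idx = [i for i, (_, mm, _) in enumerate(stacked.columns) if mm == m]
        order = {stacked.columns[i][0]: i for i in idx}
        cols = [order[s] for s in samples]
        tables[m] = CountTable(list(stacked.gene_ids), list(samples),
                               stacked.counts[:, cols])
    group_by_sample = {s: g for s, _, g in stacked.columns}
    design = DesignTable(list(samples), [group_by_sample[s] for s in samples])
    return tables, design
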