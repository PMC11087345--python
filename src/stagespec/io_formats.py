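"""Readers and writers for expression matrices, sample metadata, gene sets and result tables.

Every downstream module consumes only the containers defined here. Matrices are
delimited text (TSV by default) with gene ids in the first column and sample ids
in the header; gene sets are standard GMT (``name TAB description TAB member ...``).
Gene identifiers are treated as opaque strings — no symbol/alias resolution is
attempted, and probe-to-gene mapping is the caller's responsibility.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LoadError",
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSetCollection",
    "read_expression",
    "read_metadata",
    "read_gmt",
    "write_gmt",
    "write_table",
]


class LoadError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression grid with a scale flag.

    Parameters
    ----------
    values
        DataFrame with unique gene ids as index and unique sample ids as
        columns; all entries finite numbers.
    scale
        ``"linear"`` (all values must be >= 0) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate gene id(s): {dupes[:5]}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample id(s): {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "linear" and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value on linear scale at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (``2**x`` if currently log2)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(values=np.power(2.0, self.values), scale="linear")

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"sample(s) not in matrix: {missing[:5]}")
        return ExpressionMatrix(values=self.values[sample_ids], scale=self.scale)


@dataclass
class SampleMetadata:
    """Per-sample design labels for a two-group time course.

    ``table`` is indexed by sample id with columns ``group`` (``control`` /
    ``case``), ``time_h`` (positive hours) and ``replicate`` (positive int).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "time_h", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing column(s): {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample id in metadata")
        bad_group = set(self.table["group"]) - {"control", "case"}
        if bad_group:
            raise ValueError(f"unknown group label(s): {sorted(bad_group)}")
        if (self.table["time_h"] <= 0).any():
            raise ValueError("time_h must be positive")
        if (self.table["replicate"] <= 0).any():
            raise ValueError("replicate must be a positive integer")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time_points(self) -> list[float]:
        return sorted(self.table["time_h"].unique())

    def samples(self, group: str | None = None, time_h: float | None = None) -> list[str]:
        """Sample ids matching the given group and/or time point, in table order."""
        mask = pd.Series(True, index=self.table.index)
        if group is not None:
            mask &= self.table["group"] == group
        if time_h is not None:
            mask &= self.table["time_h"] == time_h
        return list(self.table.index[mask])

    def check_matches(self, expr: ExpressionMatrix) -> None:
        """Require exactly one metadata row per expression sample."""
        missing = [s for s in expr.sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"sample(s) without metadata: {missing[:5]}")


@dataclass
class GeneSetCollection:
    """Named gene sets: ``sets`` maps set name -> (description, member list)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name][1]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def items(self):
        for name, (_, members) in self.sets.items():
            yield name, members


def read_expression(path, scale_hint: str = "linear", sep: str = "\t") -> ExpressionMatrix:
    """Load a delimited gene x sample table.

    First column holds gene ids, header row holds sample ids. Duplicate gene
    rows are collapsed by their mean (logged); rows that are entirely missing
    are dropped; any remaining missing cell is an error. Duplicate sample ids
    and non-numeric cells are rejected with the offending row/column named.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    if len(header) < 2:
        raise LoadError(f"{path}: malformed header (need gene-id column plus >=1 sample)")
    counts = Counter(header[1:])
    dupes = sorted(s for s, c in counts.items() if c > 1)
    if dupes:
        raise LoadError(f"{path}: duplicate sample id(s) in header: {dupes}")

    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col][coerced.isna() & df[col].notna()]
            if len(bad):
                raise LoadError(
                    f"{path}: non-numeric value {bad.iloc[0]!r} at gene "
                    f"{bad.index[0]!r}, sample {col!r}"
                )
            df[col] = coerced
    df = df.astype(float)

    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene row(s) by mean", path, n_dup)
        df = df.groupby(level=0, sort=False).mean()

    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        logger.warning("%s: dropping %d all-missing row(s)", path, int(all_missing.sum()))
        df = df.loc[~all_missing]
    if df.isna().any().any():
        g = df.index[df.isna().any(axis=1)][0]
        s = df.columns[df.loc[g].isna()][0]
        raise LoadError(f"{path}: missing value at gene {g!r}, sample {s!r}")

    try:
        return ExpressionMatrix(values=df, scale=scale_hint)
    except ValueError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def read_metadata(path, sep: str = "\t") -> SampleMetadata:
    """Load a sample metadata table with columns sample_id, group, time_h, replicate."""
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise LoadError(f"{path}: metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    try:
        return SampleMetadata(table=df)
    except ValueError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def read_gmt(path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file into a :class:`GeneSetCollection`.

    Members are deduplicated preserving first occurrence; a repeated set name
    or a line with fewer than three fields is an error naming the line.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"{path}:{lineno}: GMT line has {len(fields)} fields (need >=3)")
            name, desc, *members = fields
            if name in sets:
                raise LoadError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen: dict[str, None] = {}
            for m in members:
                if m and m not in seen:
                    seen[m] = None
            if not seen:
                raise LoadError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (desc, list(seen))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write a matrix as delimited text (gene ids first column, header samples)."""
    expr.values.to_csv(path, sep=sep, index_label="gene_id")


def write_metadata(meta: SampleMetadata, path, sep: str = "\t") -> None:
    meta.table.to_csv(path, sep=sep, index_label="sample_id")


def write_table(result: pd.DataFrame, path, sort_by=None, ascending=True) -> None:
    """Write a result table as TSV with header and full float precision.

    ``sort_by`` gives the deterministic row order (documented per result type
    by the caller); without it, input row order is preserved.
    """
    df = result
    if sort_by is not None:
        df = df.sort_values(sort_by, ascending=ascending, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
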