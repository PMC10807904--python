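"""Reading, validation and alignment of count tables and sample metadata.

The canonical in-memory orientation is samples x taxa (one row per
sample).  Files on disk may be stored either way; the reader transposes
as directed by an explicit ``orientation`` flag so no silent guessing
happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pseudonet")

MIN_TAXA = 4
MIN_GROUP_SIZE = 4


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class CountTable:
    """A samples x taxa table of non-negative integer abundances.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by sample identifier, columns by taxon identifier.
        Values must be non-negative and integer-coercible.

    Notes
    -----
    Validation enforces: no duplicate identifiers, all counts >= 0,
    at least 4 taxa (the SparCC basis-variance system is degenerate
    below that), and strictly positive per-sample totals (zero-depth
    samples carry no compositional information and are rejected).
    """

    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon identifiers: {dups}")
        # the 4-taxa floor is a SparCC requirement enforced at estimation
        # time; the container itself only needs a ratio to exist
        if df.shape[1] < 2:
            raise ValidationError(
                f"need at least 2 taxa, got {df.shape[1]}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table contains non-numeric cells")
        if np.isnan(values.astype(float)).any():
            r, c = np.argwhere(np.isnan(values.astype(float)))[0]
            raise ValidationError(
                f"missing value at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        rounded = np.rint(values.astype(float))
        if not np.allclose(values.astype(float), rounded, atol=1e-9):
            r, c = np.argwhere(~np.isclose(values.astype(float), rounded))[0]
            raise ValidationError(
                f"non-integer count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        row_sums = rounded.sum(axis=1)
        if (row_sums <= 0).any():
            bad = df.index[row_sums <= 0].tolist()
            raise ValidationError(f"zero-depth samples rejected: {bad}")
        self.counts = pd.DataFrame(
            rounded.astype(np.int64), index=df.index.astype(str),
            columns=df.columns.astype(str),
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        # contiguous copy: keeps downstream linear algebra bitwise
        # reproducible regardless of how the frame was assembled
        return np.ascontiguousarray(self.counts.to_numpy())

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)])

    def drop_sample(self, i: int) -> "CountTable":
        return CountTable(self.counts.drop(index=self.counts.index[i]))


def read_count_table(path, orientation: str = "samples_by_taxa",
                     id_column: str | int | None = None,
                     sep: str | None = None) -> CountTable:
    """Read a delimited count table into the canonical orientation.

    Parameters
    ----------
    path : str or Path
        TSV/CSV file with one header row and one identifier column.
    orientation : {"samples_by_taxa", "taxa_by_samples"}
        How the file is laid out on disk.  ``taxa_by_samples`` files are
        transposed on read so the returned table is always samples x taxa.
    id_column : str, int or None
        Name or position of the identifier column; default first column.
    sep : str, optional
        Field delimiter; inferred from the file when omitted.
    """
    if orientation not in ("samples_by_taxa", "taxa_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path, id_column, sep)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().all():
            bad = df.index[coerced.isna() & df[col].notna()][0]
            raise ValidationError(
                f"non-numeric cell at row {bad!r}, column {col!r}"
            )
        df[col] = coerced
    if orientation == "taxa_by_samples":
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path, sep: str = "\t") -> None:
    """Write a count table as samples x taxa delimited text."""
    table.counts.to_csv(path, sep=sep, index_label="sample_id")


def read_metadata(path, id_column: str | int | None = None,
                  sep: str | None = None) -> pd.DataFrame:
    """Read a sample metadata table indexed by sample identifier."""
    df = _read_delimited(path, id_column, sep)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample identifiers in metadata: {dups}")
    return df


def _read_delimited(path, id_column, sep) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if id_column is None:
        id_column = df.columns[0]
    elif isinstance(id_column, int):
        id_column = df.columns[id_column]
    df = df.set_index(id_column)
    df.index = df.index.astype(str)
    return df


def align(counts: CountTable, meta: pd.DataFrame,
          variables: list[str] | None = None,
          group_var: str | None = None) -> tuple[CountTable, pd.DataFrame, int]:
    """Restrict counts and metadata to shared samples, in counts order.

    Samples missing from either table, or with a missing value in any of
    the selected model ``variables`` (complete-case), are dropped; the
    number of drops is logged and returned.

    Returns
    -------
    (CountTable, DataFrame, int)
        Aligned counts, aligned metadata (same sample order) and the
        number of samples dropped relative to the counts input.

    Raises
    ------
    ValidationError
        If the sample intersection is empty, fewer than 8 samples
        survive, or (when ``group_var`` is given) a group level is left
        with fewer than 4 samples.
    """
    shared = [s for s in counts.sample_ids if s in meta.index]
    if not shared:
        raise ValidationError("no samples shared between counts and metadata")
    sub_meta = meta.loc[shared]
    check_cols = list(variables) if variables else []
    if group_var is not None and group_var not in check_cols:
        check_cols.append(group_var)
    for col in check_cols:
        if col not in sub_meta.columns:
            raise ValidationError(
                f"variable {col!r} not in metadata columns {list(meta.columns)}"
            )
    if check_cols:
        keep_mask = sub_meta[check_cols].notna().all(axis=1)
        shared = [s for s, k in zip(shared, keep_mask) if k]
    n_dropped = counts.n_samples - len(shared)
    if n_dropped:
        logger.info("align: dropped %d samples (unshared or incomplete)", n_dropped)
    if len(shared) < 8:
        raise ValidationError(
            f"only {len(shared)} samples remain after alignment; need >= 8"
        )
    out_counts = counts.subset_samples(shared)
    out_meta = meta.loc[shared]
    if group_var is not None:
        levels = out_meta[group_var].dropna().unique()
        if len(levels) != 2:
            raise ValidationError(
                f"group variable {group_var!r} must have exactly 2 levels "
                f"after alignment, found {sorted(map(str, levels))}"
            )
        sizes = out_meta[group_var].value_counts()
        small = sizes[sizes < MIN_GROUP_SIZE]
        if not small.empty:
            raise ValidationError(
                f"group level(s) with < {MIN_GROUP_SIZE} samples after "
                f"alignment: {dict(small)}"
            )
    return out_counts, out_meta, n_dropped


def group_indices(meta: pd.DataFrame, group_var: str,
                  level_a=None) -> tuple[np.ndarray, np.ndarray]:
    """Positional indices of the two group levels over aligned samples.

    ``level_a`` selects which observed level defines index set A (and is
    coded Z=1 in the regression); default is the lexically first level.
    """
    if group_var not in meta.columns:
        raise ValidationError(f"group variable {group_var!r} not in metadata")
    col = meta[group_var].astype(str)
    levels = sorted(col.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(
            f"group variable {group_var!r} must be binary, observed levels: {levels}"
        )
    if level_a is None:
        level_a = levels[0]
    level_a = str(level_a)
    if level_a not in levels:
        raise ValidationError(
            f"level {level_a!r} not observed; observed levels: {levels}"
        )
    mask = (col == level_a).to_numpy()
    idx_a = np.flatnonzero(mask)
    idx_b = np.flatnonzero(~mask)
    return idx_a, idx_b
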