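"""Reading and writing delimited feature tables with an explicit modelling schema.

A table has one header row, a sample-identifier column (optional), numeric
predictor columns (cells may be missing), exactly one binary outcome column,
and optional "exploration" columns that are excluded from modelling but kept
for exploratory analysis.  Predictors are strictly numeric: non-numeric
columns are rejected rather than silently encoded, because silent encoding
changes model semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Tokens treated as a missing cell, compared case-insensitively.
DEFAULT_MISSING_MARKERS: tuple[str, ...] = ("", "NA", "NaN", "null")


@dataclass(frozen=True)
class SchemaSpec:
    """Declares how the columns of a delimited file map onto the modelling roles.

    Parameters
    ----------
    outcome_column:
        Name of the binary outcome column.  Must be present in the header.
    positive_class:
        The outcome label treated as the positive class.  The choice matters
        for sensitivity/precision/PR curves and must be explicit.
    id_column:
        Name of the sample-identifier column, or ``None`` to number samples
        ``S1, S2, ...`` in file order.
    exploration_columns:
        Columns excluded from the predictors but retained for exploratory
        analysis (e.g. vaccine arm, batch, sex).
    missing_markers:
        String tokens interpreted as a missing cell (case-insensitive).
    """

    outcome_column: str
    positive_class: str
    id_column: str | None = None
    exploration_columns: tuple[str, ...] = ()
    missing_markers: tuple[str, ...] = DEFAULT_MISSING_MARKERS


@dataclass
class Dataset:
    """An in-memory samples x features table with a binary outcome.

    ``values`` is a float DataFrame (samples on the index, features on the
    columns); missing cells are ``NaN``.  ``outcome`` is a string Series
    aligned to the index.  Column and row order is meaningful and preserved
    by every operation in the package.
    """

    values: pd.DataFrame
    outcome: pd.Series
    positive_class: str
    exploration: pd.DataFrame = field(default_factory=pd.DataFrame)
    id_name: str = "sample_id"
    negative_class: str | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate sample identifiers")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate feature names")
        if not self.outcome.index.equals(self.values.index):
            raise SchemaError("outcome index does not match the value grid")
        if self.outcome.isna().any():
            raise SchemaError("outcome must be defined for every sample")
        levels = set(self.outcome.unique())
        if len(levels) > 2:
            raise SchemaError(f"outcome has {len(levels)} levels; exactly 2 required")
        if self.negative_class is None:
            others = sorted(levels - {self.positive_class})
            self.negative_class = others[0] if others else None
        self.values = self.values.astype(float)

    # -- basic views ------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    @property
    def classes(self) -> tuple[str, str]:
        """(negative, positive) label pair."""
        return (str(self.negative_class), str(self.positive_class))

    def y(self) -> np.ndarray:
        """Outcome as a 0/1 vector (1 = positive class)."""
        return (self.outcome.to_numpy() == self.positive_class).astype(int)

    def select(
        self,
        sample_ids: list[str] | None = None,
        feature_names: list[str] | None = None,
    ) -> "Dataset":
        """Subset rows/columns, preserving the order given (or current order)."""
        rows = self.sample_ids if sample_ids is None else list(sample_ids)
        cols = self.feature_names if feature_names is None else list(feature_names)
        missing_rows = set(rows) - set(self.values.index)
        missing_cols = set(cols) - set(self.values.columns)
        if missing_rows:
            raise SchemaError(f"unknown sample ids: {sorted(missing_rows)}")
        if missing_cols:
            raise SchemaError(f"unknown feature names: {sorted(missing_cols)}")
        expl = self.exploration.loc[rows] if not self.exploration.empty else pd.DataFrame(index=rows)
        return Dataset(
            values=self.values.loc[rows, cols].copy(),
            outcome=self.outcome.loc[rows].copy(),
            positive_class=self.positive_class,
            exploration=expl,
            id_name=self.id_name,
            negative_class=self.negative_class,
        )

    def iselect(self, row_positions) -> "Dataset":
        """Subset rows by integer position."""
        return self.select(sample_ids=[self.sample_ids[i] for i in row_positions])

    def with_values(self, values: pd.DataFrame) -> "Dataset":
        """Replace the value grid (same index), e.g. after a transform."""
        return Dataset(
            values=values,
            outcome=self.outcome.loc[values.index].copy(),
            positive_class=self.positive_class,
            exploration=self.exploration.loc[values.index] if not self.exploration.empty else pd.DataFrame(index=values.index),
            id_name=self.id_name,
            negative_class=self.negative_class,
        )

    def equals(self, other: "Dataset") -> bool:
        """Equality on values (incl. missing positions), ordering and outcome."""
        return (
            list(self.values.columns) == list(other.values.columns)
            and list(self.values.index) == list(other.values.index)
            and self.values.equals(other.values)
            and self.outcome.equals(other.outcome)
            and self.positive_class == other.positive_class
        )


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_dataset(path: str | Path, schema: SchemaSpec, delimiter: str | None = None) -> Dataset:
    """Read a CSV/TSV feature table under the given schema.

    The delimiter is auto-detected from the header (comma vs tab) unless
    given explicitly.  Every predictor cell must parse as a finite number or
    be one of the schema's missing markers; anything else raises
    :class:`~bioautoml.errors.ParseError` naming the offending row/column.
    The outcome must have exactly two observed levels, one of which is the
    schema's positive class.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\r\n")
    if delimiter is None:
        delimiter = _sniff_delimiter(header_line)
    header = header_line.split(delimiter)
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise SchemaError(f"duplicate header names: {dupes}")
    if schema.outcome_column not in header:
        raise SchemaError(f"outcome column {schema.outcome_column!r} not in header")

    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8")
    raw.columns = [str(c) for c in raw.columns]

    if schema.id_column is not None:
        if schema.id_column not in raw.columns:
            raise SchemaError(f"id column {schema.id_column!r} not in header")
        ids = raw[schema.id_column].astype(str).tolist()
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate sample identifiers in id column")
        id_name = schema.id_column
    else:
        ids = [f"S{i + 1}" for i in range(len(raw))]
        id_name = "sample_id"

    markers = {m.lower() for m in schema.missing_markers}

    outcome_raw = raw[schema.outcome_column].astype(str).str.strip()
    if outcome_raw.str.lower().isin(markers).any():
        raise SchemaError("outcome contains missing values")
    levels = sorted(outcome_raw.unique())
    if len(levels) != 2:
        raise SchemaError(f"outcome has {len(levels)} observed levels {levels}; exactly 2 required")
    if schema.positive_class not in levels:
        raise SchemaError(
            f"positive class {schema.positive_class!r} not among observed outcome levels {levels}"
        )
    outcome = pd.Series(outcome_raw.to_numpy(), index=ids, name=schema.outcome_column)

    expl_cols = list(schema.exploration_columns)
    unknown = [c for c in expl_cols if c not in raw.columns]
    if unknown:
        raise SchemaError(f"exploration columns not in header: {unknown}")
    exploration = raw[expl_cols].copy() if expl_cols else pd.DataFrame(index=ids)
    exploration.index = ids

    reserved = {schema.outcome_column, schema.id_column, *expl_cols} - {None}
    predictor_cols = [c for c in raw.columns if c not in reserved]

    parsed = {}
    for col in predictor_cols:
        tokens = raw[col].astype(str).str.strip()
        is_missing = tokens.str.lower().isin(markers).to_numpy()
        numeric = np.full(len(tokens), np.nan)
        for pos, (tok, miss) in enumerate(zip(tokens.to_numpy(), is_missing)):
            if miss:
                continue
            try:
                # Python's float() parses exactly (round-trip safe), unlike
                # pandas' fast to_numeric path
                numeric[pos] = float(tok)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {tok!r} in predictor column {col!r}, "
                    f"row {ids[pos]!r} (file row {pos + 2})"
                ) from None
            if not np.isfinite(numeric[pos]):
                raise ParseError(
                    f"non-finite value {tok!r} in predictor column {col!r}, "
                    f"row {ids[pos]!r} (file row {pos + 2})"
                )
        parsed[col] = numeric

    values = pd.DataFrame(parsed, index=ids, columns=predictor_cols, dtype=float)
    negative = [lv for lv in levels if lv != schema.positive_class][0]
    return Dataset(
        values=values,
        outcome=outcome,
        positive_class=schema.positive_class,
        exploration=exploration,
        id_name=id_name,
        negative_class=negative,
    )


def write_dataset(
    dataset: Dataset,
    path: str | Path,
    delimiter: str = ",",
    missing_marker: str | None = None,
) -> None:
    """Write a dataset back to a delimited file.

    Missing cells are emitted as ``missing_marker`` (default: the first
    default marker, i.e. an empty cell).  The layout is id column,
    predictors in column order, outcome, then exploration columns; reading
    the file back with the matching schema is the identity on values,
    missing mask, outcome and ordering.
    """
    marker = DEFAULT_MISSING_MARKERS[0] if missing_marker is None else missing_marker
    out = dataset.values.copy()
    out.insert(0, dataset.id_name, dataset.sample_ids)
    out[dataset.outcome.name or "outcome"] = dataset.outcome.to_numpy()
    for col in dataset.exploration.columns:
        out[col] = dataset.exploration[col].to_numpy()
    # %.17g guarantees bit-exact float round-trips through the text file
    out.to_csv(path, sep=delimiter, index=False, na_rep=marker, float_format="%.17g")


def drop_incomplete(
    dataset: Dataset, drop_columns: list[str] | tuple[str, ...] = ()
) -> tuple[Dataset, list[str]]:
    """Remove named columns, then every sample that still has a missing cell.

    This is the classical complete-case filter used to prepare clinical
    tables: columns with a high level of missingness are named explicitly
    and dropped first (rescuing their rows), then remaining incomplete rows
    are removed.  Returns the filtered dataset and the removed sample ids.
    The operation is idempotent.
    """
    unknown = [c for c in drop_columns if c not in dataset.feature_names]
    if unknown:
        raise SchemaError(f"drop_columns not in dataset: {unknown}")
    keep_cols = [c for c in dataset.feature_names if c not in set(drop_columns)]
    trimmed = dataset.select(feature_names=keep_cols)
    complete = ~trimmed.values.isna().any(axis=1)
    removed = [s for s, ok in zip(trimmed.sample_ids, complete) if not ok]
    if removed:
        logger.info("drop_incomplete removed %d samples: %s", len(removed), removed)
    kept = [s for s in trimmed.sample_ids if s not in set(removed)]
    return trimmed.select(sample_ids=kept), removed
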