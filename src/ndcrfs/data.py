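"""Tabular dataset container and file I/O (CSV and ARFF).

A :class:`Dataset` is a rectangular sample x feature table with one
categorical class column.  Each feature is flagged ``discrete`` or
``continuous``; the information-theoretic machinery only accepts discrete
columns, so continuous ones must pass through :mod:`ndcrfs.discretization`
first.  Rows containing any missing value are deleted at load time (the
standard incomplete-sample rule for these benchmarks), with the count logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, UnknownFeatureError
from .info_theory import DiscreteColumn

__all__ = ["Dataset", "load_table", "save_table", "infer_kinds", "DEFAULT_DISCRETE_CARDINALITY"]

logger = logging.getLogger("ndcrfs")

#: integer columns with at most this many distinct values are treated as discrete
DEFAULT_DISCRETE_CARDINALITY = 10


def infer_kinds(
    frame: pd.DataFrame,
    class_column: str,
    *,
    discrete_threshold: int = DEFAULT_DISCRETE_CARDINALITY,
) -> dict[str, str]:
    """Guess per-column kind: non-numeric/bool -> discrete; integer-valued
    numeric with few distinct values -> discrete; everything else continuous.
    The class column is always discrete."""
    kinds: dict[str, str] = {}
    for name in frame.columns:
        col = frame[name]
        if name == class_column or not pd.api.types.is_numeric_dtype(col) or col.dtype == bool:
            kinds[name] = "discrete"
            continue
        values = col.to_numpy()
        integral = np.allclose(values, np.round(values), equal_nan=False)
        if integral and np.unique(values).size <= discrete_threshold:
            kinds[name] = "discrete"
        else:
            kinds[name] = "continuous"
    return kinds


class Dataset:
    """Sample x feature table plus class column and per-column kind flags.

    Parameters
    ----------
    frame
        The full table, one sample per row, class column included.
    class_column
        Name of the class column (default ``"class"``).
    kinds
        Optional per-column ``{"name": "discrete"|"continuous"}`` overrides;
        unspecified columns are inferred from dtype and cardinality.
    provenance
        Free-text note about where the table came from.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        class_column: str = "class",
        kinds: dict[str, str] | None = None,
        provenance: str = "",
        *,
        discrete_threshold: int = DEFAULT_DISCRETE_CARDINALITY,
    ) -> None:
        if class_column not in frame.columns:
            raise InputError(
                f"class column {class_column!r} not found; available columns: "
                f"{list(frame.columns)}"
            )
        if frame.columns.duplicated().any():
            raise InputError("feature names must be unique")
        if len(frame) == 0:
            raise InputError("dataset has no rows")
        if frame.isna().any().any():
            raise InputError("dataset contains missing values; drop incomplete rows first")
        self.frame = frame.reset_index(drop=True)
        self.class_column = class_column
        self.provenance = provenance
        inferred = infer_kinds(self.frame, class_column, discrete_threshold=discrete_threshold)
        if kinds:
            unknown = set(kinds) - set(frame.columns)
            if unknown:
                raise InputError(f"kind overrides for unknown columns: {sorted(unknown)}")
            inferred.update(kinds)
        inferred[class_column] = "discrete"
        self.kinds = inferred
        self._encoded: dict[str, DiscreteColumn] = {}

    # -- basic shape -------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.class_column]

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def is_discrete(self, name: str) -> bool:
        return self.kinds[name] == "discrete"

    @property
    def is_fully_discrete(self) -> bool:
        return all(self.kinds[f] == "discrete" for f in self.feature_names)

    # -- encoded views -----------------------------------------------------
    def _encode(self, name: str) -> DiscreteColumn:
        if name not in self._encoded:
            codes, uniques = pd.factorize(self.frame[name], sort=True)
            self._encoded[name] = DiscreteColumn(np.asarray(codes), len(uniques))
        return self._encoded[name]

    def column(self, name: str) -> DiscreteColumn:
        """Integer-coded view of a discrete feature column."""
        if name not in self.frame.columns or name == self.class_column:
            raise UnknownFeatureError(
                f"unknown feature {name!r}; available: {self.feature_names}"
            )
        if not self.is_discrete(name):
            raise InputError(
                f"column {name!r} is continuous; discretize it first "
                "(see ndcrfs.discretization)"
            )
        return self._encode(name)

    @property
    def class_labels(self) -> DiscreteColumn:
        return self._encode(self.class_column)

    # -- derived datasets --------------------------------------------------
    def subset_rows(self, indices) -> "Dataset":
        """Dataset restricted to the given row positions (e.g. a CV fold)."""
        return Dataset(
            self.frame.iloc[np.asarray(indices)].reset_index(drop=True),
            self.class_column,
            kinds=dict(self.kinds),
            provenance=self.provenance,
        )


def load_table(
    path,
    format: str | None = None,
    class_column: str = "class",
    *,
    kinds: dict[str, str] | None = None,
    discrete_threshold: int = DEFAULT_DISCRETE_CARDINALITY,
) -> Dataset:
    """Read a CSV or ARFF table into a :class:`Dataset`.

    Rows with any missing cell (empty or ``NA`` in CSV, ``?`` in ARFF) are
    deleted and the count is logged.  ARFF nominal attributes are marked
    discrete.  The format is inferred from the file suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "arff" if path.suffix.lower() == ".arff" else "csv"
    arff_kinds: dict[str, str] = {}
    if format == "csv":
        frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    elif format == "arff":
        from scipy.io import arff as scipy_arff

        records, meta = scipy_arff.loadarff(path)
        frame = pd.DataFrame.from_records(records)
        for name in meta.names():
            if meta[name][0] == "nominal":
                frame[name] = frame[name].str.decode("utf-8")
                frame.loc[frame[name] == "?", name] = np.nan
                arff_kinds[name] = "discrete"
    else:
        raise InputError(f"unknown format {format!r}; expected 'csv' or 'arff'")

    if class_column not in frame.columns:
        raise InputError(
            f"class column {class_column!r} not found; available columns: "
            f"{list(frame.columns)}"
        )
    complete = frame.dropna()
    dropped = len(frame) - len(complete)
    if dropped:
        logger.info("load_table(%s): deleted %d incomplete sample(s)", path.name, dropped)
    if len(complete) == 0:
        raise InputError(f"{path}: no complete samples remain after row deletion")
    merged = dict(arff_kinds)
    if kinds:
        merged.update(kinds)
    return Dataset(
        complete,
        class_column,
        kinds=merged or None,
        provenance=f"loaded from {path}",
        discrete_threshold=discrete_threshold,
    )


def save_table(dataset: Dataset, path) -> None:
    """Write the table as CSV (header row, one sample per row)."""
    dataset.frame.to_csv(path, index=False)
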