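"""Core containers: a sample-by-feature matrix and aligned sample metadata.

Both wrap :class:`pandas.DataFrame` objects indexed by sample ID and carry
the validation rules the harmonization pipeline relies on (unique IDs,
finite features, batch levels with enough samples to estimate a variance).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "SampleMetadata", "ValidationError"]


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


class FeatureMatrix:
    """Samples x continuous features, indexed by unique sample IDs.

    Parameters
    ----------
    values
        DataFrame with one row per sample and one column per feature.
        The index holds sample IDs. All cells must be finite numbers.
    """

    def __init__(self, values: pd.DataFrame):
        if values.shape[0] < 2:
            raise ValidationError("feature matrix needs at least 2 samples")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature names: {dups}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            # locate the first offending cell for the error message
            for j, col in enumerate(values.columns):
                coerced = pd.to_numeric(values[col], errors="coerce")
                orig_na = values[col].isna()
                bad = coerced.isna() & ~orig_na
                if bad.any():
                    i = int(np.argmax(bad.to_numpy()))
                    raise ValidationError(
                        f"non-numeric feature value at sample "
                        f"{values.index[i]!r}, feature {col!r}: "
                        f"{values.iloc[i, j]!r}"
                    )
            values = values.astype(float)
            arr = values.to_numpy()
        if not np.isfinite(arr).all():
            ii, jj = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite feature value at sample {values.index[ii]!r}, "
                f"feature {values.columns[jj]!r}"
            )
        self._values = values.astype(float)

    # -- accessors -----------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def sample_ids(self) -> pd.Index:
        return self._values.index

    @property
    def feature_names(self) -> pd.Index:
        return self._values.columns

    @property
    def n_samples(self) -> int:
        return self._values.shape[0]

    @property
    def n_features(self) -> int:
        return self._values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self._values.to_numpy(copy=True)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self._values.copy())

    def with_values(self, arr: np.ndarray) -> "FeatureMatrix":
        """New matrix with the same index/columns and replaced values."""
        return FeatureMatrix(
            pd.DataFrame(arr, index=self._values.index, columns=self._values.columns)
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self._values.loc[:, list(names)])

    def reorder(self, sample_ids: Iterable) -> "FeatureMatrix":
        return FeatureMatrix(self._values.loc[list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureMatrix({self.n_samples} samples x {self.n_features} features)"


class SampleMetadata:
    """Per-sample batch variables, protected covariates and survival columns.

    Parameters
    ----------
    table
        DataFrame indexed by sample ID.
    batch_vars
        Names of categorical batch (technical) variables. Each must have at
        least two observed levels and at least two samples per level.
    categorical_covariates, continuous_covariates
        Protected clinical covariates by type.
    time_col, event_col
        Optional right-censored survival columns (time >= 0, event in {0,1}).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        batch_vars: Sequence[str] = (),
        categorical_covariates: Sequence[str] = (),
        continuous_covariates: Sequence[str] = (),
        time_col: str | None = None,
        event_col: str | None = None,
    ):
        if table.index.duplicated().any():
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dups}")
        for name in (
            list(batch_vars)
            + list(categorical_covariates)
            + list(continuous_covariates)
            + [c for c in (time_col, event_col) if c is not None]
        ):
            if name not in table.columns:
                raise ValidationError(f"metadata column {name!r} not found")
        if len(set(batch_vars)) != len(list(batch_vars)):
            raise ValidationError("duplicate batch variable names")

        self._table = table.copy()
        self.batch_vars = list(batch_vars)
        self.categorical_covariates = list(categorical_covariates)
        self.continuous_covariates = list(continuous_covariates)
        self.time_col = time_col
        self.event_col = event_col
        self._validate()

    def _validate(self) -> None:
        for var in self.batch_vars:
            counts = self._table[var].value_counts()
            if len(counts) < 2:
                raise ValidationError(
                    f"batch variable {var!r} has fewer than 2 levels"
                )
            small = counts[counts < 2]
            if len(small):
                lvl = small.index[0]
                raise ValidationError(
                    f"batch variable {var!r} level {lvl!r} has "
                    f"{int(small.iloc[0])} sample(s); at least 2 required"
                )
        for var in self.continuous_covariates:
            col = pd.to_numeric(self._table[var], errors="coerce")
            if col.isna().any():
                raise ValidationError(
                    f"continuous covariate {var!r} has non-numeric entries"
                )
        if self.time_col is not None:
            t = pd.to_numeric(self._table[self.time_col], errors="coerce")
            if t.isna().any() or (t < 0).any():
                raise ValidationError("survival times must be nonnegative numbers")
        if self.event_col is not None:
            e = self._table[self.event_col]
            if not set(pd.unique(e)).issubset({0, 1, 0.0, 1.0, True, False}):
                raise ValidationError("event indicator must be binary (0/1)")

    # -- accessors -----------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def sample_ids(self) -> pd.Index:
        return self._table.index

    @property
    def n_samples(self) -> int:
        return self._table.shape[0]

    def batch_labels(self, var: str) -> pd.Series:
        if var not in self.batch_vars:
            raise KeyError(f"{var!r} is not a batch variable")
        return self._table[var].astype(str)

    def covariate(self, var: str) -> pd.Series:
        return self._table[var]

    @property
    def survival(self) -> tuple[pd.Series, pd.Series]:
        if self.time_col is None or self.event_col is None:
            raise ValidationError("metadata has no survival columns")
        return (
            pd.to_numeric(self._table[self.time_col]),
            pd.to_numeric(self._table[self.event_col]).astype(int),
        )

    # -- derived metadata ---------------------------------------------
    def reorder(self, sample_ids: Iterable) -> "SampleMetadata":
        return SampleMetadata(
            self._table.loc[list(sample_ids)],
            self.batch_vars,
            self.categorical_covariates,
            self.continuous_covariates,
            self.time_col,
            self.event_col,
        )

    def with_batch_var(self, name: str, labels: Mapping | pd.Series) -> "SampleMetadata":
        """Return a copy with an extra batch variable appended."""
        if name in self._table.columns:
            raise ValidationError(f"metadata already has a column {name!r}")
        tab = self._table.copy()
        tab[name] = pd.Series(labels).reindex(tab.index)
        return SampleMetadata(
            tab,
            self.batch_vars + [name],
            self.categorical_covariates,
            self.continuous_covariates,
            self.time_col,
            self.event_col,
        )

    def with_categorical_covariate(
        self, name: str, labels: Mapping | pd.Series
    ) -> "SampleMetadata":
        """Return a copy with an extra protected categorical covariate."""
        if name in self._table.columns:
            raise ValidationError(f"metadata already has a column {name!r}")
        tab = self._table.copy()
        tab[name] = pd.Series(labels).reindex(tab.index)
        return SampleMetadata(
            tab,
            self.batch_vars,
            self.categorical_covariates + [name],
            self.continuous_covariates,
            self.time_col,
            self.event_col,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SampleMetadata({self.n_samples} samples, "
            f"batch={self.batch_vars}, "
            f"cat={self.categorical_covariates}, "
            f"cont={self.continuous_covariates})"
        )
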