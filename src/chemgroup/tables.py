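"""Core tabular containers: feature tables and sample label tables.

A :class:`FeatureTable` is a samples x features matrix of analytical
measurements (e.g. summed PAH analyte intensities from GC-MS, or carbon
number / molecular-class compositions from GC×GC-FID).  Missing entries
are held as NaN until explicitly imputed.  A :class:`LabelTable` carries,
per sample, a manufacturing-category label (the grouping level under
evaluation) and a parent-substance identifier encoding the replicate
structure (triplicate instrument runs of one substance share a
substance id).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

__all__ = ["ScalingState", "FeatureTable", "LabelTable"]


class ScalingState(str, Enum):
    """Which scaling pipeline steps have been applied to a FeatureTable."""

    RAW = "raw"
    ROW_MINMAX = "row_minmax"
    ROW_COL_MINMAX = "row_minmax+col_minmax"
    ROW_ZSCORE = "row_zscore"


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dups}")


@dataclass
class FeatureTable:
    """Samples x features matrix with explicit missing-value state.

    Parameters
    ----------
    data
        DataFrame indexed by sample ID with feature IDs as columns.
        NaN marks a missing measurement.
    scaling_state
        Which scaling steps have been applied; ``raw`` on ingest.
    """

    data: pd.DataFrame
    scaling_state: ScalingState = ScalingState.RAW

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.scaling_state = ScalingState(self.scaling_state)

    # -- basic accessors ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def missing_coordinates(self) -> list[tuple[str, str]]:
        """(sample_id, feature_id) pairs of every missing entry."""
        rows, cols = np.nonzero(self.data.isna().to_numpy())
        return [(self.data.index[r], self.data.columns[c]) for r, c in zip(rows, cols)]

    def with_data(self, data: pd.DataFrame, scaling_state=None) -> "FeatureTable":
        state = self.scaling_state if scaling_state is None else scaling_state
        return FeatureTable(data, scaling_state=state)

    def require_complete(self, op: str) -> None:
        if self.n_missing:
            raise ValueError(
                f"{op} requires a table without missing entries "
                f"({self.n_missing} missing); impute first"
            )


@dataclass
class LabelTable:
    """Per-sample category and parent-substance assignment.

    ``category`` is one grouping level (e.g. the 3-, 9- or 16-class
    manufacturing categorization); ``substance`` identifies the parent
    substance so that replicates can be held out together.
    """

    table: pd.DataFrame  # index = sample, columns = category, substance

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        if "category" not in df.columns:
            raise ValueError("label table must have a 'category' column")
        if "substance" not in df.columns:
            df = df.assign(substance=df.index.astype(str))
        _check_unique(df.index, "sample")
        df.index = df.index.astype(str)
        self.table = df[["category", "substance"]].astype(str)

    @classmethod
    def from_arrays(cls, sample_ids, categories, substances=None) -> "LabelTable":
        df = pd.DataFrame({"category": list(categories)}, index=list(sample_ids))
        if substances is not None:
            df["substance"] = list(substances)
        return cls(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    @property
    def substances(self) -> pd.Series:
        return self.table["substance"]

    @property
    def n_categories(self) -> int:
        return self.table["category"].nunique()

    def aligned_to(self, sample_ids) -> "LabelTable":
        """Reindex to a sample ordering; error on unknown samples."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples without labels: {missing}")
        return LabelTable(self.table.loc[list(sample_ids)])
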