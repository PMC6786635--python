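"""Reading and cleaning of analytical profiles.

Implements the ingest pipeline applied to chromatographic feature tables
before any grouping analysis: reading wide matrices, unfolding long-format
three-dimensional profiles (sample x elution axis x analyte) into 2-D
tables, collapsing the elution axis by summation over selected analytes,
zero-imputation of missing fields, removal of negligible-variation
features (sample SD of 0, or below a threshold), and the row-wise /
column-wise min-max and row z-score scalings.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import FeatureTable, LabelTable, ScalingState

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_label_table",
    "read_long_records",
    "unfold_long_profile",
    "collapse_elution_axis",
    "impute_missing_zero",
    "filter_low_variance",
    "scale_rows_minmax",
    "scale_cols_minmax",
    "standardize_rows_z",
]

MISSING_TOKENS = ["", "NA"]


def read_feature_table(path, fmt: str = "csv") -> FeatureTable:
    """Read a wide samples x features matrix (first column = sample IDs).

    Empty cells and the token ``NA`` are treated as missing; any other
    non-numeric cell raises an error naming its row and column.  Negative
    values only warn: pre-scaled data may legitimately contain them.
    """
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    parsed = raw.apply(
        lambda col: pd.to_numeric(col.replace(MISSING_TOKENS, np.nan), errors="coerce")
    )
    # locate genuinely non-numeric cells: parsed NaN but raw not a missing token
    bad = parsed.isna() & ~raw.isin(MISSING_TOKENS)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at sample "
            f"{raw.index[r]!r}, feature {raw.columns[c]!r}"
        )
    if (parsed.to_numpy() < 0).any():
        warnings.warn("negative values on ingest (expected only for pre-scaled data)")
    return FeatureTable(parsed, scaling_state=ScalingState.RAW)


def write_feature_table(t: FeatureTable, path, fmt: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    t.data.to_csv(path, sep=sep, index_label="sample")


def read_label_table(path) -> LabelTable:
    """Read a labels CSV with columns sample, category[, substance]."""
    df = pd.read_csv(path, dtype=str)
    if "sample" not in df.columns:
        raise ValueError("label file must have a 'sample' column")
    return LabelTable(df.set_index("sample"))


def _as_long_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records), columns=["sample", "axis1", "axis2", "value"])
    required = {"sample", "axis1", "axis2", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long records need columns {sorted(required)}")
    if df.empty:
        raise ValueError("no long-format records provided")
    dup = df.duplicated(subset=["sample", "axis1", "axis2"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["sample", "axis1", "axis2"]].tolist()
        raise ValueError(f"duplicate (sample, axis1, axis2) triple: {first}")
    df["value"] = pd.to_numeric(df["value"])
    return df


def read_long_records(path) -> pd.DataFrame:
    """Read a long CSV with columns sample,axis1,axis2,value."""
    return _as_long_frame(pd.read_csv(path))


def unfold_long_profile(records) -> FeatureTable:
    """Unfold a 3-D profile into a 2-D table.

    Columns are the Cartesian product of observed (axis1, axis2) keys,
    named ``axis1|axis2`` and ordered axis1-major; combinations absent
    from the records stay missing in the corresponding row.
    """
    df = _as_long_frame(records)
    wide = df.pivot(index="sample", columns=["axis1", "axis2"], values="value")
    # full Cartesian product of observed keys, axis1-major then axis2
    a1_keys = sorted(df["axis1"].unique())
    a2_keys = sorted(df["axis2"].unique())
    wide = wide.reindex(columns=pd.MultiIndex.from_product([a1_keys, a2_keys]))
    wide.columns = [f"{a1}|{a2}" for a1, a2 in wide.columns]
    wide.index = wide.index.astype(str)
    return FeatureTable(wide, scaling_state=ScalingState.RAW)


def collapse_elution_axis(records, keep_analytes: Iterable[str]) -> FeatureTable:
    """Sum a long profile over the elution axis, keeping selected analytes.

    Mirrors the reduction of a full chromatographic run to one summed
    intensity per analyte of interest (e.g. 55 PAH-related m/z values).
    """
    keep = list(dict.fromkeys(keep_analytes))
    if not keep:
        raise ValueError("keep_analytes must not be empty")
    df = _as_long_frame(records)
    observed = set(df["axis2"].astype(str))
    unknown = [a for a in keep if str(a) not in observed]
    if unknown:
        raise ValueError(f"analytes not observed in the records: {unknown}")
    df = df[df["axis2"].astype(str).isin([str(a) for a in keep])]
    summed = df.groupby(["sample", "axis2"], sort=False)["value"].sum().unstack("axis2")
    summed = summed[[a for a in keep if a in summed.columns]]
    summed.columns = [str(c) for c in summed.columns]
    summed.index = summed.index.astype(str)
    return FeatureTable(summed, scaling_state=ScalingState.RAW)


def impute_missing_zero(t: FeatureTable) -> FeatureTable:
    """Replace every missing field with exactly zero."""
    return t.with_data(t.data.fillna(0.0))


def filter_low_variance(
    t: FeatureTable, sd_threshold: float = 0.0
) -> tuple[FeatureTable, list[str]]:
    """Drop features with sample SD of 0 or strictly below ``sd_threshold``.

    The sample standard deviation uses denominator n-1.  Returns the
    filtered table and the IDs of removed features, preserving the order
    of retained columns.
    """
    t.require_complete("filter_low_variance")
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be non-negative")
    sd = t.data.std(axis=0, ddof=1)
    drop = (sd == 0) | (sd < sd_threshold)
    removed = list(t.data.columns[drop])
    if len(removed) == t.n_features:
        raise ValueError("no features survive filtering")
    return t.with_data(t.data.loc[:, ~drop]), removed


def scale_rows_minmax(t: FeatureTable) -> FeatureTable:
    """Row-wise min-max scaling: x -> (x - min) / range per sample.

    Constant rows map to all zeros.
    """
    t.require_complete("scale_rows_minmax")
    x = t.values
    lo = x.min(axis=1, keepdims=True)
    rng = x.max(axis=1, keepdims=True) - lo
    out = np.where(rng > 0, (x - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return t.with_data(
        pd.DataFrame(out, index=t.data.index, columns=t.data.columns),
        scaling_state=ScalingState.ROW_MINMAX,
    )


def scale_cols_minmax(t: FeatureTable) -> FeatureTable:
    """Column-wise min-max scaling; constant columns map to zeros.

    Applied after row-wise scaling so that every measurement carries
    approximately equal weight in classifier training.
    """
    t.require_complete("scale_cols_minmax")
    x = t.values
    lo = x.min(axis=0, keepdims=True)
    rng = x.max(axis=0, keepdims=True) - lo
    out = np.where(rng > 0, (x - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    state = (
        ScalingState.ROW_COL_MINMAX
        if t.scaling_state in (ScalingState.ROW_MINMAX, ScalingState.ROW_COL_MINMAX)
        else t.scaling_state
    )
    return t.with_data(
        pd.DataFrame(out, index=t.data.index, columns=t.data.columns),
        scaling_state=state,
    )


def standardize_rows_z(t: FeatureTable) -> FeatureTable:
    """Row-wise z-score normalization (mean 0, sample SD 1 per sample).

    Constant rows map to zeros.  This is the scaling applied before
    singular value decomposition in the de-noising step.
    """
    t.require_complete("standardize_rows_z")
    if t.n_features < 2:
        raise ValueError("row z-scoring needs at least 2 features")
    x = t.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return t.with_data(
        pd.DataFrame(out, index=t.data.index, columns=t.data.columns),
        scaling_state=ScalingState.ROW_ZSCORE,
    )
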