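"""Clean and scale a long-format chromatographic profile.

Builds a small 3-D profile (sample x elution time x analyte), collapses
the elution axis to one summed intensity per analyte, zero-imputes
missing fields, removes negligible-variation features and applies the
row/column min-max scalings used before classification.
"""

import numpy as np
import pandas as pd

import chemgroup as cg
from chemgroup import preprocess as pp

rng = np.random.default_rng(0)
samples = [f"oil{i}" for i in range(6)]
analytes = [f"mz{100 + j}" for j in range(8)]

records = pd.DataFrame(
    [
        (s, t, a, float(rng.gamma(2.0, 1.0)))
        for s in samples
        for t in range(5)          # elution-time index
        for a in analytes
    ],
    columns=["sample", "axis1", "axis2", "value"],
)
# two analytes were never measured for one sample each
records = records[~((records["sample"] == "oil2") & (records["axis2"] == "mz103"))]
records = records[~((records["sample"] == "oil5") & (records["axis2"] == "mz106"))]

table = pp.collapse_elution_axis(records, analytes)
print(f"collapsed profile: {table.n_samples} samples x {table.n_features} analytes, "
      f"{table.n_missing} missing cells")

table = pp.impute_missing_zero(table)
table, removed = pp.filter_low_variance(table, sd_threshold=0.05)
print(f"SD filter removed {len(removed)} features: {removed}")

scaled = pp.scale_cols_minmax(pp.scale_rows_minmax(table))
print(f"scaling state: {scaled.scaling_state.value}; "
      f"value range [{scaled.values.min():.2f}, {scaled.values.max():.2f}]")
# Every analyte now carries comparable weight: each row was scaled to its
# own [min, max] range, then each column to [0, 1] across samples.
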