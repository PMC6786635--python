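"""ToxPi (Toxicological Prioritization Index) profiles of samples.

Each selected analytical feature becomes one "slice" of a radial
profile: its values are min-max scaled to [0, 1] over the sample set,
and the overall score of a sample is the weighted mean of its slice
values — a weight-of-evidence summary that ranks samples by the features
found most informative for class discrimination.  A PCA of the slice
matrix gives a 2-D map of the samples in informative-feature space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .tables import FeatureTable

__all__ = ["toxpi_slices", "toxpi_overall_scores", "pca_of_scores"]


def toxpi_slices(t: FeatureTable, features: list[str]) -> pd.DataFrame:
    """Min-max scale the selected feature columns over the included samples.

    Constant columns map to zeros.  Returns samples x slices in the
    requested feature order.
    """
    t.require_complete("toxpi_slices")
    if t.n_samples < 2:
        raise ValueError("need at least 2 samples")
    unknown = [f for f in features if f not in t.data.columns]
    if unknown:
        raise ValueError(f"unknown feature IDs: {unknown}")
    sub = t.data[list(features)]
    lo = sub.min(axis=0)
    rng = sub.max(axis=0) - lo
    scaled = (sub - lo).div(rng.where(rng > 0, 1.0), axis=1)
    scaled.loc[:, rng == 0] = 0.0
    return scaled


def toxpi_overall_scores(slices: pd.DataFrame, weights=None) -> pd.Series:
    """Weighted mean of slice values per sample (in [0, 1]).

    ``weights`` maps feature -> positive weight; default equal weights.
    Scores are invariant to uniform rescaling of all weights.
    """
    if weights is None:
        w = pd.Series(1.0, index=slices.columns)
    else:
        w = pd.Series(weights, dtype=float).reindex(slices.columns)
        if w.isna().any():
            raise ValueError(f"missing weights for: {list(w.index[w.isna()])}")
    if (w <= 0).any():
        raise ValueError("all slice weights must be positive")
    scores = slices.mul(w, axis=1).sum(axis=1) / w.sum()
    return scores.rename("toxpi_score")


def pca_of_scores(slices: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA of the slice matrix; first two components.

    Returns (coordinates with columns PC1/PC2, explained-variance
    fractions, non-increasing).
    """
    if slices.shape[0] < 3:
        raise ValueError("need at least 3 samples for a PCA map")
    if slices.shape[1] < 2:
        raise ValueError("need at least 2 slices")
    x = slices.to_numpy(dtype=float)
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValueError("slice matrix has no variance to decompose")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    frame = pd.DataFrame(coords, index=slices.index, columns=["PC1", "PC2"])
    return frame, pca.explained_variance_ratio_
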