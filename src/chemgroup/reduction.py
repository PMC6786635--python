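"""Reduced-rank ("de-noised") representation via singular value decomposition.

The row-standardized feature matrix is decomposed as X = U S Vt and the
samples are projected onto the leading right singular vectors.  The rank
r is the smallest number of components whose cumulative share of the
total variation (squared singular values) reaches the requested
threshold — 85% by default, matching common chemometric practice of
discarding the low-energy tail as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable, ScalingState

__all__ = ["ReducedData", "reduced_rank_scores"]

DEFAULT_VARIANCE_THRESHOLD = 0.85


@dataclass
class ReducedData:
    """Sample scores on the leading r singular vectors.

    ``scores`` has one row per sample and one column per retained
    component; column i has Euclidean norm equal to the i-th singular
    value.  ``variance_fractions`` are per-component shares of the total
    squared singular values (non-increasing, summing to 1).
    ``reconstruction`` is the de-noised rank-r matrix U_r S_r Vt_r in the
    original feature space — correlation-based sample distances are
    computed on it, because Pearson correlation over only r score
    coordinates degenerates when r is small.
    """

    scores: pd.DataFrame
    rank_r: int
    variance_fractions: np.ndarray
    threshold: float
    singular_values: np.ndarray
    reconstruction: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy()


def reduced_rank_scores(
    t: FeatureTable, threshold: float = DEFAULT_VARIANCE_THRESHOLD
) -> ReducedData:
    """Project a row-z-scored table onto the smallest rank reaching ``threshold``.

    The variance fraction of component i is s_i^2 / sum(s^2); r is minimal
    with cumulative fraction >= threshold.  Each right singular vector is
    sign-fixed so its largest-magnitude entry is positive, making scores
    reproducible across SVD implementations (up to that convention).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if t.scaling_state is not ScalingState.ROW_ZSCORE:
        raise ValueError(
            "reduced_rank_scores expects a row-z-scored table "
            f"(got scaling_state={t.scaling_state.value!r})"
        )
    if t.n_samples < 2 or t.n_features < 2:
        raise ValueError("need at least 2 samples and 2 features")
    x = t.values
    if not np.any(x):
        raise ValueError("all-zero matrix has no variation to decompose")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|.| entry of each right singular vector positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    energy = s**2
    fractions = energy / energy.sum()
    cumulative = np.cumsum(fractions)
    # tolerance guards against cumsum landing at 1 - eps when threshold = 1
    r = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)

    scores = u[:, :r] * s[:r]
    score_df = pd.DataFrame(
        scores, index=t.data.index, columns=[f"SV{i + 1}" for i in range(r)]
    )
    recon = pd.DataFrame(scores @ vt[:r], index=t.data.index, columns=t.data.columns)
    return ReducedData(
        scores=score_df,
        rank_r=r,
        variance_fractions=fractions,
        threshold=float(threshold),
        singular_values=s,
        reconstruction=recon,
    )
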