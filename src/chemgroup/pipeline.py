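"""End-to-end drivers tying the module stages together.

These are the call sequences the CLI and the worked examples use: the
unsupervised route (row z-score -> optional SVD de-noising -> correlation
distance -> UPGMA -> cut at the known number of classes -> F-M index with
permutation null) and the supervised route (column min-max scaling ->
tuned Random Forest with LOO-CV -> label-permutation significance ->
mean-decrease-in-accuracy ranking).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables import FeatureTable, LabelTable
from . import preprocess, reduction, grouping, classify

__all__ = ["ClusterEvalOutput", "cluster_and_score", "classify_and_rank"]


@dataclass
class ClusterEvalOutput:
    tree: grouping.Dendrogram
    partition: pd.Series
    fm: grouping.FMTestResult
    rank_r: int | None


def cluster_and_score(
    table: FeatureTable,
    labels: LabelTable,
    reduce_threshold: float | None = reduction.DEFAULT_VARIANCE_THRESHOLD,
    n_perm: int = grouping.DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    alpha: float = grouping.DEFAULT_ALPHA,
    permute: str = "samples",
) -> ClusterEvalOutput:
    """Unsupervised workflow on a complete (imputed) feature table.

    ``reduce_threshold=None`` clusters the z-scored data directly;
    otherwise the data are first projected onto the smallest rank
    reaching that share of the variation.
    """
    z = preprocess.standardize_rows_z(table)
    rank_r = None
    if reduce_threshold is None:
        coords = z
    else:
        red = reduction.reduced_rank_scores(z, threshold=reduce_threshold)
        coords = red
        rank_r = red.rank_r
    d = grouping.correlation_distance_matrix(coords)
    tree = grouping.average_linkage_tree(d)
    fm = grouping.fm_permutation_test(
        tree, labels, n_perm=n_perm, seed=seed, alpha=alpha, permute=permute
    )
    part = grouping.cut_tree(tree, fm.k)
    return ClusterEvalOutput(tree=tree, partition=part, fm=fm, rank_r=rank_r)


def classify_and_rank(
    table: FeatureTable,
    labels: LabelTable,
    n_trees: int = classify.DEFAULT_N_TREES,
    n_perm: int = classify.DEFAULT_N_PERMUTATIONS,
    grid: list[int] | None = None,
    seed: int = 0,
    scale: bool = True,
):
    """Supervised workflow: tune/fit, permutation significance, ranking.

    Returns (ForestEvalResult, AccuracyPermutationResult, importance
    Series).  ``scale`` applies column min-max scaling first, as done
    before classifier training.
    """
    t = preprocess.scale_cols_minmax(table) if scale else table
    fit = classify.tune_and_fit_forest(t, labels, grid=grid, n_trees=n_trees, seed=seed)
    perm = classify.permutation_test_accuracy(
        t, labels, n_perm=n_perm, seed=seed, n_trees=n_trees, observed=fit
    )
    importance = classify.rank_features_importance(fit, t, labels, seed=seed)
    return fit, perm, importance
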