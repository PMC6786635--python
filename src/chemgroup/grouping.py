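"""Unsupervised grouping workflow and its quantitative evaluation.

Samples are clustered hierarchically (UPGMA / average linkage) on a
correlation-based distance, a reference ("artificial") dendrogram is
built from the Euclidean distances between one-hot encodings of a known
categorization, both trees are cut into the known number of classes, and
the agreement between the data-driven partition and the categorization
is scored with the Fowlkes-Mallows (F-M) index

    FM = sqrt( TP/(TP+FP) * TP/(TP+FN) )

over all unordered sample pairs (TP: co-clustered in both partitions;
FP: co-clustered only in the data partition; FN: co-clustered only in
the reference).  Significance is assessed against a permutation null
obtained by shuffling the sample labels and recomputing the F-M index,
with the empirical p-value the proportion of permuted values at or above
the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .tables import FeatureTable, LabelTable
from .reduction import ReducedData

__all__ = [
    "Dendrogram",
    "Partition",
    "FMTestResult",
    "correlation_distance_matrix",
    "label_reference_distances",
    "average_linkage_tree",
    "cut_tree",
    "fm_index",
    "partition_from_labels",
    "fm_permutation_test",
]

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERMUTATIONS = 1000


@dataclass
class Dendrogram:
    """Agglomerative merge tree over named leaves.

    ``linkage`` is a scipy linkage matrix (n-1 rows of
    [node_i, node_j, height, size]); ``leaf_ids`` names the original
    observations in matrix order.
    """

    linkage: np.ndarray
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return render(tree, tree.dist) + ";"


Partition = pd.Series  # sample_id -> cluster label


def _distance_input_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, FeatureTable):
        return data.values, data.sample_ids
    if isinstance(data, ReducedData):
        # de-noised data in feature space: correlation over r score
        # coordinates is unstable for small r
        return data.reconstruction.to_numpy(), data.sample_ids
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(i) for i in data.index]
    arr = np.asarray(data, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def correlation_distance_matrix(data) -> pd.DataFrame:
    """Pairwise distance d(i,j) = 1 - Pearson r between sample profiles.

    Accepts a FeatureTable, ReducedData scores, a DataFrame or an array.
    Range [0, 2]; zero diagonal.  Constant rows have no defined
    correlation and raise an error naming the offending sample.
    """
    x, ids = _distance_input_matrix(data)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 columns to correlate profiles")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = ids[int(np.argmax(sd == 0))]
        raise ValueError(f"constant profile for sample {bad!r}: correlation undefined")
    d = 1.0 - np.corrcoef(x)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=ids, columns=ids)


def label_reference_distances(labels: LabelTable) -> pd.DataFrame:
    """Euclidean distances between one-hot (0/1) encodings of a categorization.

    Same-category pairs are at distance 0, different-category pairs at
    sqrt(2) — the two-level structure of the reference ("artificial")
    dendrogram against which data-driven trees are compared.
    """
    cats = labels.categories
    if len(cats) < 2:
        raise ValueError("need at least 2 samples")
    if cats.nunique() < 2:
        raise ValueError("reference categorization is degenerate: a single category")
    same = cats.to_numpy()[:, None] == cats.to_numpy()[None, :]
    d = np.where(same, 0.0, np.sqrt(2.0))
    return pd.DataFrame(d, index=labels.sample_ids, columns=labels.sample_ids)


def _check_square_distances(d: pd.DataFrame) -> np.ndarray:
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return arr


def average_linkage_tree(d) -> Dendrogram:
    """UPGMA agglomeration: clusters merge at the unweighted mean of all
    cross-pair distances."""
    arr = _check_square_distances(d)
    ids = (
        [str(i) for i in d.index]
        if isinstance(d, pd.DataFrame)
        else [str(i) for i in range(arr.shape[0])]
    )
    z = hierarchy.linkage(squareform(arr, checks=False), method="average")
    return Dendrogram(linkage=z, leaf_ids=ids)


def cut_tree(tree: Dendrogram, k: int) -> Partition:
    """Flat partition into exactly k clusters by undoing the k-1 highest merges.

    Cluster labels are integers 1..k in order of first appearance.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        out[i] = relabel.setdefault(int(c), len(relabel) + 1)
    return pd.Series(out, index=tree.leaf_ids, name="cluster")


def partition_from_labels(labels: LabelTable) -> Partition:
    """The categorization itself as a flat partition."""
    codes, _ = pd.factorize(labels.categories)
    return pd.Series(codes + 1, index=labels.sample_ids, name="cluster")


def _pairs(counts: np.ndarray) -> int:
    c = counts.astype(np.int64)
    return int((c * (c - 1) // 2).sum())


def _pair_counts_codes(pc: np.ndarray, qc: np.ndarray, kp: int, kq: int) -> tuple[int, int, int]:
    """TP/FP/FN pair counts from integer-coded partitions (0..kp-1, 0..kq-1)."""
    ct = np.bincount(pc * kq + qc, minlength=kp * kq)
    tp = _pairs(ct)
    fp = _pairs(np.bincount(pc, minlength=kp)) - tp
    fn = _pairs(np.bincount(qc, minlength=kq)) - tp
    return tp, fp, fn


def _fm_from_counts(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        return 0.0
    return float(np.sqrt((tp / (tp + fp)) * (tp / (tp + fn))))


def _pair_counts(p: Partition, q: Partition) -> tuple[int, int, int]:
    if set(p.index) != set(q.index):
        raise ValueError("partitions are over different sample sets")
    q = q.loc[p.index]
    pc, pu = pd.factorize(p.to_numpy())
    qc, qu = pd.factorize(q.to_numpy())
    return _pair_counts_codes(pc, qc, len(pu), len(qu))


def fm_index(p: Partition, q: Partition) -> tuple[float, int, int, int]:
    """Fowlkes-Mallows index between two partitions with its pair counts.

    Returns (fm, tp, fp, fn).  FM is defined as 0 when TP = 0 (e.g. one
    partition is all singletons); it is invariant to cluster relabeling
    and symmetric in its arguments.
    """
    tp, fp, fn = _pair_counts(p, q)
    return _fm_from_counts(tp, fp, fn), tp, fp, fn


@dataclass
class FMTestResult:
    """Observed F-M index with its permutation null."""

    fm_observed: float
    tp: int
    fp: int
    fn: int
    null_values: np.ndarray
    p_value: float
    n_perm: int
    alpha: float
    seed: int
    k: int

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def summary(self) -> dict:
        return {
            "fm_observed": self.fm_observed,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "significant": self.significant,
            "null_mean": float(self.null_values.mean()),
            "null_sd": float(self.null_values.std(ddof=1)) if self.n_perm > 1 else 0.0,
            "k": self.k,
            "seed": self.seed,
        }


def fm_permutation_test(
    data_tree: Dendrogram,
    labels: LabelTable,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    strict_inequality: bool = False,
    permute: str = "samples",
) -> FMTestResult:
    """Score a data-driven tree against a categorization, with significance.

    The tree is cut into k = number of categories; the observed F-M index
    compares that partition with the categorization.  The null shuffles
    the label vector (class sizes preserved) and recomputes the F-M index
    against the same tree cut.  p is the proportion of null values >= the
    observed (ties counted; set ``strict_inequality`` to count only
    strictly greater values).

    ``permute="samples"`` (default) shuffles labels across individual
    samples.  When samples are replicate runs of parent substances,
    replicates are correlated and sample-level shuffling breaks that
    correlation, making the test anti-conservative for the class-level
    question; ``permute="substances"`` instead shuffles the
    substance-to-category assignment, keeping each substance's
    replicates together.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if permute not in ("samples", "substances"):
        raise ValueError("permute must be 'samples' or 'substances'")
    labels = labels.aligned_to(data_tree.leaf_ids)
    k = labels.n_categories
    if k < 2:
        raise ValueError("need at least 2 categories")
    data_part = cut_tree(data_tree, k)
    label_part = partition_from_labels(labels)
    fm_obs, tp, fp, fn = fm_index(data_part, label_part)

    rng = np.random.default_rng(seed)
    pc, pu = pd.factorize(data_part.to_numpy())
    qc, qu = pd.factorize(label_part.to_numpy())
    null = np.empty(n_perm)
    if permute == "samples":
        for i in range(n_perm):
            shuffled = rng.permutation(qc)
            null[i] = _fm_from_counts(*_pair_counts_codes(pc, shuffled, len(pu), len(qu)))
    else:
        sub_codes, sub_uniques = pd.factorize(labels.substances.to_numpy())
        # one category code per substance; substances must be label-pure
        sub_cat = np.full(len(sub_uniques), -1, dtype=int)
        for s_code, cat in zip(sub_codes, qc):
            if sub_cat[s_code] == -1:
                sub_cat[s_code] = cat
            elif sub_cat[s_code] != cat:
                raise ValueError(
                    f"substance {sub_uniques[s_code]!r} spans multiple categories; "
                    "substance-level permutation is undefined"
                )
        for i in range(n_perm):
            shuffled = rng.permutation(sub_cat)[sub_codes]
            null[i] = _fm_from_counts(*_pair_counts_codes(pc, shuffled, len(pu), len(qu)))
    exceed = (null > fm_obs) if strict_inequality else (null >= fm_obs)
    p = float(exceed.sum() / n_perm)
    return FMTestResult(
        fm_observed=fm_obs,
        tp=tp,
        fp=fp,
        fn=fn,
        null_values=null,
        p_value=p,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        k=k,
    )
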