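"""Supervised grouping workflow: Random-Forest classification of samples
into manufacturing categories.

The classifier is tuned by grid search over the number of features
considered per split, with leave-one-out cross validation (LOO-CV) and
500 trees per forest; the headline accuracy is the LOO-CV accuracy at
the tuned value.  Significance is assessed by refitting under label
permutations (class sizes preserved).  Feature importance is the
mean decrease in accuracy: the average, over trees, of the drop in
out-of-bag accuracy when one feature's values are permuted.  A
substance-level generalization test (leave-one-substance-out) withholds
all replicates of one parent substance from training and predicts them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .tables import FeatureTable, LabelTable

__all__ = [
    "ForestEvalResult",
    "AccuracyPermutationResult",
    "LeaveOneSubstanceOutResult",
    "default_mtry_grid",
    "fit_forest",
    "tune_and_fit_forest",
    "accuracy_from_confusion",
    "permutation_test_accuracy",
    "leave_one_substance_out",
    "rank_features_importance",
]

DEFAULT_N_TREES = 500
DEFAULT_N_PERMUTATIONS = 1000


def default_mtry_grid(n_features: int) -> list[int]:
    """Grid over features-per-split: {1, ceil(sqrt p), ceil(p/3), ceil(p/2), p}."""
    p = n_features
    grid = {1, math.ceil(math.sqrt(p)), math.ceil(p / 3), math.ceil(p / 2), p}
    return sorted(v for v in grid if 1 <= v <= p)


def _design(t: FeatureTable, labels: LabelTable) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Align labels to the table and canonicalize feature order.

    Columns are sorted by feature ID so results do not depend on the
    incidental column order of the input file.
    """
    t.require_complete("classification")
    labels = labels.aligned_to(t.sample_ids)
    order = sorted(t.feature_ids)
    x = t.data[order].to_numpy()
    y = labels.categories.to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 categories")
    return x, y, order, classes


def _check_loo_feasible(y: np.ndarray) -> None:
    counts = pd.Series(y).value_counts()
    starved = counts[counts < 2]
    if not starved.empty:
        raise ValueError(
            "leave-one-out split would empty class(es): "
            + ", ".join(starved.index.astype(str))
        )


def _forest(max_features: int, n_trees: int, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=int(seed),
        oob_score=oob,
        n_jobs=1,
    )


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    # independent child seeds, kept below 2**31 for portability
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _loocv_predictions(
    x: np.ndarray, y: np.ndarray, max_features: int, n_trees: int, seed: int
) -> np.ndarray:
    n = len(y)
    seeds = _spawn_seeds(seed, n)
    pred = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = _forest(max_features, n_trees, seeds[i])
        clf.fit(x[mask], y[mask])
        pred[i] = clf.predict(x[i : i + 1])[0]
        mask[i] = True
    return pred


@dataclass
class ForestEvalResult:
    """Tuned Random-Forest classifier with its LOO-CV evaluation."""

    tuned_features_per_split: int
    n_trees: int
    cv_confusion: pd.DataFrame  # rows = true class, columns = predicted
    cv_accuracy: float
    oob_accuracy: float
    grid_accuracies: dict[int, float]
    forest: RandomForestClassifier
    feature_ids: list[str]
    classes: np.ndarray
    seed: int

    def summary(self) -> dict:
        return {
            "tuned_features_per_split": self.tuned_features_per_split,
            "n_trees": self.n_trees,
            "cv_accuracy": self.cv_accuracy,
            "oob_accuracy": self.oob_accuracy,
            "grid_accuracies": {int(k): v for k, v in self.grid_accuracies.items()},
            "confusion": self.cv_confusion.to_dict(),
            "seed": self.seed,
        }


def accuracy_from_confusion(cm) -> float:
    """Fraction of correctly predicted samples: trace over total."""
    arr = cm.to_numpy() if isinstance(cm, pd.DataFrame) else np.asarray(cm)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (arr < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty (zero total)")
    return float(np.trace(arr) / total)


def _confusion(y_true, y_pred, classes) -> pd.DataFrame:
    cm = pd.crosstab(
        pd.Categorical(y_true, categories=classes),
        pd.Categorical(y_pred, categories=classes),
        dropna=False,
    )
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return cm


def tune_and_fit_forest(
    t: FeatureTable,
    labels: LabelTable,
    grid: list[int] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ForestEvalResult:
    """Grid-tune features-per-split by LOO-CV, then refit on all samples.

    For every grid value a forest is trained per held-out sample and the
    LOO-CV accuracy recorded; the tuned value is the argmax (ties toward
    the smallest value).  The final forest is refit on the full data set
    at the tuned value, and the confusion matrix / accuracy reported are
    those of the LOO-CV predictions at the tuned value.
    """
    x, y, order, classes = _design(t, labels)
    _check_loo_feasible(y)
    p = x.shape[1]
    grid = default_mtry_grid(p) if grid is None else sorted(set(int(g) for g in grid))
    if any(g < 1 or g > p for g in grid):
        raise ValueError(f"grid values must lie in [1, {p}]")

    grid_acc: dict[int, float] = {}
    preds: dict[int, np.ndarray] = {}
    for m in grid:
        pred = _loocv_predictions(x, y, m, n_trees, seed)
        preds[m] = pred
        grid_acc[m] = float((pred == y).mean())
    tuned = min(grid, key=lambda m: (-grid_acc[m], m))

    final_seed = int(_spawn_seeds(seed, len(y) + 1)[-1])
    forest = _forest(tuned, n_trees, final_seed, oob=True)
    forest.fit(x, y)
    cm = _confusion(y, preds[tuned], classes)
    return ForestEvalResult(
        tuned_features_per_split=tuned,
        n_trees=n_trees,
        cv_confusion=cm,
        cv_accuracy=grid_acc[tuned],
        oob_accuracy=float(forest.oob_score_),
        grid_accuracies=grid_acc,
        forest=forest,
        feature_ids=order,
        classes=classes,
        seed=seed,
    )


@dataclass
class AccuracyPermutationResult:
    """Observed LOO-CV accuracy against a label-permutation null."""

    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(self.null_accuracies.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_accuracies.std(ddof=1)) if self.n_perm > 1 else 0.0

    def summary(self) -> dict:
        return {
            "observed_accuracy": self.observed_accuracy,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def permutation_test_accuracy(
    t: FeatureTable,
    labels: LabelTable,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    grid: list[int] | None = None,
    retune_per_permutation: bool = False,
    observed: ForestEvalResult | None = None,
) -> AccuracyPermutationResult:
    """Label-permutation significance of the tuned LOO-CV accuracy.

    Each permutation shuffles the label vector (class sizes preserved),
    refits forests and records the LOO-CV accuracy.  By default the
    features-per-split value is frozen at the observed tuned value; pass
    ``retune_per_permutation=True`` to redo the grid search in every
    permutation.  p = proportion of null accuracies >= the observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if observed is None:
        observed = tune_and_fit_forest(t, labels, grid=grid, n_trees=n_trees, seed=seed)
    x, y, _, _ = _design(t, labels)
    tuned = observed.tuned_features_per_split

    rng = np.random.default_rng(seed)
    perm_seeds = _spawn_seeds(seed + 1, n_perm)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        _check_loo_feasible(y_perm)
        if retune_per_permutation:
            lab = LabelTable.from_arrays(t.sample_ids, y_perm)
            res = tune_and_fit_forest(t, lab, grid=grid, n_trees=n_trees, seed=int(perm_seeds[i]))
            null[i] = res.cv_accuracy
        else:
            pred = _loocv_predictions(x, y_perm, tuned, n_trees, int(perm_seeds[i]))
            null[i] = float((pred == y_perm).mean())
    p = float((null >= observed.cv_accuracy).sum() / n_perm)
    return AccuracyPermutationResult(
        observed_accuracy=observed.cv_accuracy,
        null_accuracies=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


@dataclass
class LeaveOneSubstanceOutResult:
    """Substance-level generalization: all replicates of one parent
    substance are withheld from training and then predicted."""

    overall_accuracy: float
    predictions: pd.DataFrame  # sample, substance, true, predicted
    skipped: dict[str, str]  # substance -> reason

    def summary(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "n_predicted": int(len(self.predictions)),
            "skipped": self.skipped,
        }


def leave_one_substance_out(
    t: FeatureTable,
    labels: LabelTable,
    n_trees: int = DEFAULT_N_TREES,
    max_features: int | None = None,
    seed: int = 0,
) -> LeaveOneSubstanceOutResult:
    """Hold out each substance's replicates in turn and predict them.

    Substances whose removal would leave their class with no training
    samples are skipped (and reported): no model can be trained for a
    class it has never seen.  ``max_features`` defaults to ceil(sqrt p).
    """
    x, y, _, _ = _design(t, labels)
    labels = labels.aligned_to(t.sample_ids)
    substances = labels.substances.to_numpy()
    unique_subs = pd.unique(substances)
    if len(unique_subs) < 2:
        raise ValueError("need at least 2 substances")
    if max_features is None:
        max_features = math.ceil(math.sqrt(x.shape[1]))

    seeds = _spawn_seeds(seed, len(unique_subs))
    rows = []
    skipped: dict[str, str] = {}
    for s_i, sub in enumerate(unique_subs):
        test = substances == sub
        train = ~test
        held_classes = set(y[test]) - set(y[train])
        if held_classes:
            skipped[str(sub)] = "class emptied: " + ", ".join(sorted(held_classes))
            continue
        clf = _forest(max_features, n_trees, seeds[s_i])
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        for samp, yt, yp in zip(np.array(t.sample_ids)[test], y[test], pred):
            rows.append({"sample": samp, "substance": sub, "true": yt, "predicted": yp})
    if not rows:
        raise ValueError("all substances skipped: every class has a single substance")
    pred_df = pd.DataFrame(rows)
    acc = float((pred_df["true"] == pred_df["predicted"]).mean())
    return LeaveOneSubstanceOutResult(
        overall_accuracy=acc, predictions=pred_df, skipped=skipped
    )


def fit_forest(
    t: FeatureTable,
    labels: LabelTable,
    max_features: int | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a single forest on all samples (no cross-validation)."""
    x, y, _, _ = _design(t, labels)
    if max_features is None:
        max_features = math.ceil(math.sqrt(x.shape[1]))
    clf = _forest(max_features, n_trees, int(_spawn_seeds(seed, 1)[0]), oob=True)
    clf.fit(x, y)
    return clf


def rank_features_importance(
    result: "ForestEvalResult | RandomForestClassifier",
    t: FeatureTable,
    labels: LabelTable,
    seed: int = 0,
) -> pd.Series:
    """Mean decrease in accuracy, per feature, in descending order.

    For every tree, accuracy is measured on that tree's out-of-bag
    samples before and after permuting one feature's values; the score
    is the mean drop over trees.  Deterministic given ``seed``.  Accepts
    either a tuned evaluation result or a bare fitted forest trained on
    the same (sorted-column) design matrix.
    """
    x, y, order, _ = _design(t, labels)
    if isinstance(result, ForestEvalResult):
        forest = result.forest
        if order != result.feature_ids:
            raise ValueError("table features do not match the fitted forest")
    else:
        forest = result
    if forest.n_features_in_ != x.shape[1]:
        raise ValueError("table features do not match the fitted forest")
    class_codes = {c: i for i, c in enumerate(forest.classes_)}
    y_codes = np.array([class_codes[v] for v in y])
    n, p = x.shape

    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    decreases = []
    for tree, used in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(all_idx, used)
        if oob.size == 0:
            continue
        x_oob = x[oob]
        y_oob = y_codes[oob]
        base = float((tree.predict(x_oob).astype(int) == y_oob).mean())
        drop = np.empty(p)
        for j in range(p):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_perm[rng.permutation(oob.size), j]
            drop[j] = base - float((tree.predict(x_perm).astype(int) == y_oob).mean())
        decreases.append(drop)
    scores = pd.Series(np.mean(decreases, axis=0), index=order, name="mean_decrease_accuracy")
    return scores.sort_values(ascending=False, kind="stable")
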