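"""Supervised grouping with a tuned Random Forest.

Classifies synthetic substance profiles into manufacturing classes with
leave-one-out cross-validation, tests significance by label permutation,
and evaluates generalization to entirely unseen substances
(leave-one-substance-out).
"""

import chemgroup as cg
from chemgroup import preprocess as pp

spec = cg.SyntheticSpec(n_features=20, n_informative=5, seed=42)
table, labels = cg.generate_profiles(spec)
scaled = pp.scale_cols_minmax(pp.scale_rows_minmax(table))

fit = cg.tune_and_fit_forest(scaled, labels, n_trees=100, seed=42)
print(f"tuned features per split: {fit.tuned_features_per_split} "
      f"(grid accuracies: {fit.grid_accuracies})")
print(f"LOO-CV accuracy: {fit.cv_accuracy:.3f}; OOB accuracy: {fit.oob_accuracy:.3f}")
print("confusion matrix (rows true, cols predicted):")
print(fit.cv_confusion.to_string())

perm = cg.permutation_test_accuracy(scaled, labels, n_perm=30, seed=42,
                                    n_trees=60, observed=fit)
print(f"label-permutation null: {perm.null_mean:.3f} +/- {perm.null_sd:.3f}, "
      f"p = {perm.p_value:.4f}")

loso = cg.leave_one_substance_out(scaled, labels, n_trees=100, seed=42)
print(f"leave-one-substance-out accuracy: {loso.overall_accuracy:.3f} "
      f"({len(loso.predictions)} replicates predicted, skipped: {loso.skipped})")
# LOO-CV holds out one replicate at a time; LOSO withholds all replicates
# of a substance, asking whether class membership generalizes to
# substances the model has never seen.
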