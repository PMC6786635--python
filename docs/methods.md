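# Methods

## Problem setting

Each sample is a vector of non-negative analytical measurements —
summed chromatographic intensities per analyte, or carbon-number ×
molecular-class compositions unfolded to one column per combination.
Samples are replicate instrument runs of parent substances, and
substances belong to manufacturing classes (the categorization under
evaluation). The package asks two questions: do the data, left to
themselves, group the samples the way the categorization says
(unsupervised workflow), and can the category of an unknown sample or
substance be predicted from its profile (supervised workflow)?

## Preprocessing

Long-format 3-D profiles (sample × elution axis × analyte) are either
unfolded to one column per (axis1, axis2) combination, or collapsed by
summing over the elution axis for a selected analyte set. Missing
fields are imputed as exact zeros (absence of a measured intensity).
Features with sample standard deviation (denominator n−1) equal to 0,
or below a configurable threshold (0.05 is the conventional choice for
small data sets), are removed. Scalings are explicit pipeline steps,
applied in whatever order the analysis calls for rather than guessed:

* **row min-max** — each sample mapped to [0, 1] by its own range;
  removes gross intensity differences between runs;
* **column min-max** — each feature mapped to [0, 1] across samples;
  applied before classifier training so every measurement carries
  approximately equal weight;
* **row z-score** — mean 0, sample SD 1 per sample; applied before SVD.

Constant rows/columns map to zeros in every scaling (the 0/0 case);
downstream variance filters remove them. A caution learned from the
synthetic studies: when a few features dominate each row's range, row
min-max scaling pins exactly those features to 0/1 in every row and can
erase their between-class signal; column-wise scaling does not have this
failure mode.

## SVD de-noising

The row-z-scored matrix X is decomposed X = U S Vᵀ. "Variation" is
squared singular values; the retained rank r is the smallest whose
cumulative energy fraction reaches the threshold (default 0.85). The
reduced representation exposed to the user is the n × r score matrix
U_r S_r (components-as-features, with per-component variance
fractions), with each right singular vector sign-fixed so its
largest-magnitude entry is positive.

For **clustering**, however, correlation distances on reduced data are
computed on the rank-r reconstruction U_r S_r V_rᵀ — the de-noised data
in the original feature space. Pearson correlation across only r score
coordinates is nearly degenerate for small r (r = 3 leaves one degree
of freedom) and measurably distorts the tree even when the full-space
distances separate the classes perfectly; correlating the de-noised
full-width rows keeps the distance well-conditioned at any r.

## Unsupervised workflow and the Fowlkes–Mallows test

Distances are d = 1 − Pearson r between sample profiles (range [0, 2]).
The reference ("artificial") dendrogram comes from Euclidean distances
between one-hot encodings of the categorization: 0 within a category,
√2 between categories — a two-level structure whose cut at k = number
of categories recovers the categorization for any linkage. Both trees
use average linkage (UPGMA); exactly tied merges follow scipy's
nearest-neighbor-chain order. Cutting retains the first n−k merges.

FM is computed from pair counts over all C(n,2) unordered pairs and is
0 by convention when TP = 0 (e.g. all-singleton partitions). The
permutation null shuffles the label vector (class sizes preserved) and
recomputes FM against the fixed tree cut; p = #(null ≥ observed)/n_perm,
with ties counted (a strict-inequality option exists), and α = 0.05.

**Replicates and exchangeability.** Sample-level shuffling assumes
samples are exchangeable under the null. Replicate runs of one
substance are correlated and share a label, so with replicated designs
the sample-level test reacts to mere replicate clustering: at zero
class effect it still rejects in ~90% of synthetic studies. It is
therefore anti-conservative for the class-level question whenever
replicates are present (including the default 3-replicate layout). The
`permute="substances"` option shuffles the substance-to-category
assignment instead, keeping each substance's replicates together; this
calibrates the class-level null correctly (measured: 100% of
zero-effect studies non-significant). Sample-level remains the default
(matching common practice); substance-level is recommended whenever the
label table carries replicate structure.

## Supervised workflow

Random Forest with 500 trees by default (smaller forests are a
configurable desk-scale knob — results below used 30–100 trees), tuned
over the number of features per split (default grid {1, ⌈√p⌉, ⌈p/3⌉,
⌈p/2⌉, p}) by leave-one-out CV; ties go to the smallest value. The
headline accuracy is LOO-CV accuracy at the tuned value (the OOB
accuracy of the final full-data forest is reported alongside). Feature
columns are sorted by ID internally so results do not depend on input
column order. Classes with fewer than two samples are rejected: LOO
would train without the held-out sample's class.

Label-permutation significance refits forests on shuffled labels
(class sizes preserved), with the tuned split count frozen by default
(re-tuning per permutation is a flag). Note a small systematic effect:
under permuted labels, LOO-CV accuracy sits slightly *below* the
majority-class proportion (~0.26–0.30 vs 1/3 for 27 samples in 3
balanced classes), because the held-out sample's class is always
under-represented in training. Tests compare the null mean to the
majority proportion within 3 binomial standard errors.

Leave-one-substance-out withholds all replicates of one substance,
trains on the rest (features per split defaulting to ⌈√p⌉), and
predicts the withheld replicates; substances whose removal would empty
their class are skipped and reported. Synthetic doping experiments show
that a substance mislabeled into another class is itself predicted
"wrongly" (i.e. by its true profile) and can additionally contaminate
predictions for the class it was mislabeled into — mislabeled training
data costs more than its own replicates.

Importance is the mean decrease in accuracy: per tree, OOB accuracy
before vs after permuting one feature's values, averaged over trees,
using the forest's per-tree bootstrap membership. With replicated
designs, noise features that vary at substance level can proxy class
membership through substance identity and inflate their ranks; the
feature-recovery validation therefore samples one replicate per
substance.

## ToxPi

Selected (typically top-10) features become slices: min-max scaled to
[0, 1] over the visualized sample set (constant slices → 0). The
overall score is the weighted mean of slices (weights default to equal
and are invariant to uniform rescaling). The slice matrix is mapped to
2-D by column-centered PCA with explained-variance fractions.

## Synthetic data generator

Emulates the replicate-in-class structure of reference-material
studies: `n_classes × substances_per_class × replicates_per_substance`
samples over `n_features` features. Informative features carry class
mean vectors placed on random orthogonal directions with per-feature
RMS `class_effect` (so classes are separated by class_effect·√(2·n_inf)
deterministically; independently drawn means can collide by chance and
void the effect-size contract), plus per-substance offsets
(SD `substance_sd`) and per-replicate noise (SD `replicate_sd`). Noise
features carry a per-substance value on a unit common scale plus the
same replicate noise — structureless with respect to class but
non-constant, exercising variance filters and importance ranking. The
matrix is shifted to be non-negative; missing entries are injected
completely at random at `missing_rate`. Same seed ⇒ bit-identical
output.

Defaults (3×3×3, 55 features, 10 informative, effect 5, substance and
replicate SD 0.5) give an effect-to-replicate-noise ratio of 10: the
benchmark condition in which both workflows recover the classes
perfectly. What the generator does *not* emulate: chromatographic peak
shape, retention drift, heteroscedastic intensity noise, correlated
analyte families, batch effects. Passing tests demonstrate correctness
of the statistical machinery under a known truth, not performance on
real instrument data.

## Problem sizes used in validation

Chosen as representative desk-scale studies: benchmark layout 27 × 55
(or 27 × 20 where the feature count is not the point); p-value
uniformity over 200 single-replicate studies (5 classes × 10
substances, 50 samples, 300 permutations each); replicate-count trend
over 10 seeds at class effect 1.5 with substance/replicate SD 1.0
(grid {5}, 60 trees); feature recovery over 20 seeds with 2 informative
+ 18 noise features (100 trees); classifier permutation tests at 20–30
permutations. The acceptance script mirrors these sizes.

## Known limitations

* UPGMA tie-breaking follows scipy's merge order; dendrograms with many
  exactly tied distances (e.g. the two-level reference tree) are
  reported in an implementation-defined but deterministic leaf order.
* The FM permutation test conditions on the fixed tree cut; it does not
  account for the tree having been estimated from the same data.
* Sample-level permutation with replicated designs tests "any structure
  aligned with labels", not "class structure"; see the exchangeability
  note above.
* LOO-CV accuracy on tiny classes is pessimistic (the held-out class is
  under-represented); OOB accuracy is reported as a cross-check.
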