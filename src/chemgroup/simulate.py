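"""Synthetic class- and replicate-structured analytical profiles.

Generates feature tables shaped like the real use case — parent
substances run in replicate, nested in manufacturing classes — with a
known ground truth, so every stage of the grouping framework can be
exercised end to end.  The model is deliberately simple test
scaffolding, not a simulation of chromatography:

* informative features: a per-class mean vector (scale ``class_effect``)
  plus a per-substance offset (SD ``substance_sd``) plus per-replicate
  noise (SD ``replicate_sd``);
* remaining features: a per-substance value on a common unit scale plus
  the same replicate noise — structureless with respect to class, but
  non-constant, so variance filters and feature ranking are exercised;
* the whole matrix is shifted to be non-negative (analytical
  intensities are non-negative) and missing entries are injected
  completely at random at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable, LabelTable, ScalingState

__all__ = ["SyntheticSpec", "generate_profiles"]


@dataclass
class SyntheticSpec:
    """Ground-truth layout of a synthetic study.

    Defaults mirror the benchmark layout used throughout: 3 manufacturing
    classes x 3 substances per class x 3 replicate runs (27 samples) over
    55 analytical features of which 10 carry class information, with a
    class-effect-to-replicate-noise ratio of 10.
    """

    n_classes: int = 3
    substances_per_class: int = 3
    replicates_per_substance: int = 3
    n_features: int = 55
    n_informative: int = 10
    class_effect: float = 5.0
    substance_sd: float = 0.5
    replicate_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.substances_per_class < 1 or self.replicates_per_substance < 1:
            raise ValueError("need at least 1 substance and 1 replicate")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.class_effect < 0 or self.substance_sd < 0 or self.replicate_sd < 0:
            raise ValueError("scales must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.substances_per_class * self.replicates_per_substance


def generate_profiles(spec: SyntheticSpec) -> tuple[FeatureTable, LabelTable]:
    """Draw one synthetic study; bit-identical for a given seed."""
    rng = np.random.default_rng(spec.seed)
    n_sub = spec.n_classes * spec.substances_per_class
    n = spec.n_samples
    p = spec.n_features
    k_inf = spec.n_informative

    # class means sit on random orthogonal directions with per-feature RMS
    # equal to class_effect, so every class pair is separated by
    # class_effect * sqrt(2 * n_informative) regardless of the seed (random
    # independent means can collide by chance and break the effect contract)
    if k_inf >= spec.n_classes:
        q, _ = np.linalg.qr(rng.normal(size=(k_inf, spec.n_classes)))
        class_means = spec.class_effect * np.sqrt(k_inf) * q.T
    else:
        class_means = rng.normal(0.0, spec.class_effect, size=(spec.n_classes, k_inf))

    sample_ids, cats, subs = [], [], []
    base = np.empty((n_sub, p))
    si = 0
    for c in range(spec.n_classes):
        for s in range(spec.substances_per_class):
            sub_id = f"class{c + 1}_sub{s + 1}"
            base[si, :k_inf] = class_means[c] + rng.normal(0.0, spec.substance_sd, k_inf)
            base[si, k_inf:] = rng.normal(0.0, 1.0, p - k_inf)
            for r in range(spec.replicates_per_substance):
                sample_ids.append(f"{sub_id}_rep{r + 1}")
                cats.append(f"class{c + 1}")
                subs.append(sub_id)
            si += 1

    rows = np.repeat(base, spec.replicates_per_substance, axis=0)
    if spec.replicate_sd > 0:
        rows = rows + rng.normal(0.0, spec.replicate_sd, size=rows.shape)

    # shift to non-negative intensities
    lo = rows.min()
    if lo < 0:
        rows = rows - lo

    n_missing = int(round(spec.missing_rate * rows.size))
    if n_missing:
        flat = rng.choice(rows.size, size=n_missing, replace=False)
        rows = rows.copy()
        rows.ravel()[flat] = np.nan

    data = pd.DataFrame(
        rows,
        index=sample_ids,
        columns=[f"feat{j + 1:03d}" for j in range(p)],
    )
    table = FeatureTable(data, scaling_state=ScalingState.RAW)
    labels = LabelTable.from_arrays(sample_ids, cats, subs)
    return table, labels
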