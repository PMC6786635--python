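import numpy as np
import pandas as pd
import pytest

import chemgroup as cg
from chemgroup import preprocess as pp


@pytest.fixture(scope="session")
def separable_study():
    """Well-separated 3-class x 3-substance x 3-replicate study (27 x 20),
    class effect 10x the replicate noise."""
    spec = cg.SyntheticSpec(
        n_classes=3,
        substances_per_class=3,
        replicates_per_substance=3,
        n_features=20,
        n_informative=5,
        class_effect=5.0,
        substance_sd=0.5,
        replicate_sd=0.5,
        seed=11,
    )
    return cg.generate_profiles(spec)


@pytest.fixture(scope="session")
def separable_scaled(separable_study):
    """Row then column min-max scaled version, as fed to the classifier."""
    table, labels = separable_study
    return pp.scale_cols_minmax(pp.scale_rows_minmax(table)), labels


@pytest.fixture()
def small_table():
    return cg.FeatureTable(
        pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]],
            index=["s1", "s2", "s3"],
            columns=["f1", "f2", "f3"],
        )
    )


def fm_bruteforce(p, q):
    """Independent pair-enumeration oracle for the Fowlkes-Mallows index."""
    ids = list(p.index)
    tp = fp = fn = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            in_p = p[a] == p[b]
            in_q = q[a] == q[b]
            tp += in_p and in_q
            fp += in_p and not in_q
            fn += in_q and not in_p
    if tp == 0:
        return 0.0, tp, fp, fn
    return float(np.sqrt(tp / (tp + fp) * tp / (tp + fn))), tp, fp, fn
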