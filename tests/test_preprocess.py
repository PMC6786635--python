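"""Ingest, cleaning and scaling of analytical feature tables."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import chemgroup as cg
from chemgroup import preprocess as pp
from chemgroup.tables import ScalingState


def make_long(rows):
    return pd.DataFrame(rows, columns=["sample", "axis1", "axis2", "value"])


class TestReadFeatureTable:
    def test_wide_csv_roundtrip(self, tmp_path):
        csv = "sample,f1,f2\na,1,2\nb,3,4\nc,5,6\n"
        path = tmp_path / "t.csv"
        path.write_text(csv)
        t = pp.read_feature_table(path)
        assert t.sample_ids == ["a", "b", "c"]
        assert t.feature_ids == ["f1", "f2"]
        assert t.scaling_state is ScalingState.RAW
        out = tmp_path / "o.csv"
        pp.write_feature_table(t, out)
        again = pp.read_feature_table(out)
        pd.testing.assert_frame_equal(t.data, again.data)

    def test_missing_cell_flagged_with_coordinates(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample,f1,f2\na,1,\nb,3,4\n")
        t = pp.read_feature_table(path)
        assert t.n_missing == 1
        assert t.missing_coordinates() == [("a", "f2")]

    def test_na_token_is_missing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample,f1\na,NA\nb,2\n")
        assert pp.read_feature_table(path).n_missing == 1

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample,f1\na,1\na,2\n")
        with pytest.raises(ValueError, match="duplicate sample.*a"):
            pp.read_feature_table(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample,f1,f2\na,1,2\nb,oops,4\n")
        with pytest.raises(ValueError, match="oops.*'b'.*'f1'"):
            pp.read_feature_table(path)

    def test_negative_values_warn_not_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample,f1\na,-1\nb,2\n")
        with pytest.warns(UserWarning, match="negative"):
            pp.read_feature_table(path)


class TestUnfoldLongProfile:
    def test_full_cartesian_product_axis1_major(self):
        rows = [
            (s, c, m, v)
            for v, (s, c, m) in enumerate(
                [(s, c, m) for s in "AB" for c in ["C10", "C11"] for m in ["alkane", "aromatic"]]
            )
        ]
        t = pp.unfold_long_profile(make_long(rows))
        assert t.feature_ids == ["C10|alkane", "C10|aromatic", "C11|alkane", "C11|aromatic"]
        assert t.data.shape == (2, 4)

    def test_absent_combination_is_missing(self):
        rows = [("A", "C10", "alkane", 1.0), ("A", "C11", "alkane", 2.0),
                ("A", "C10", "aromatic", 3.0), ("B", "C10", "alkane", 4.0),
                ("B", "C10", "aromatic", 5.0), ("B", "C11", "aromatic", 7.0),
                ("A", "C11", "aromatic", 6.0)]
        t = pp.unfold_long_profile(make_long(rows))
        assert t.data.loc["B", "C11|alkane"] != t.data.loc["B", "C11|alkane"]  # NaN
        assert t.n_missing == 1

    def test_single_record(self):
        t = pp.unfold_long_profile(make_long([("A", "C10", "alkane", 2.5)]))
        assert t.data.shape == (1, 1)
        assert t.data.iloc[0, 0] == 2.5

    def test_duplicate_triple_rejected(self):
        rows = [("A", "C10", "alkane", 1.0), ("A", "C10", "alkane", 2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            pp.unfold_long_profile(make_long(rows))


class TestCollapseElutionAxis:
    def test_sums_over_elution_axis(self):
        rows = [("A", t, "m1", v) for t, v in [(1, 1.0), (2, 2.0), (3, 3.0)]]
        rows += [("A", 1, "m2", 5.0)]
        t = pp.collapse_elution_axis(make_long(rows), ["m1"])
        assert t.data.loc["A", "m1"] == 6.0
        assert t.feature_ids == ["m1"]

    def test_shape_contract_many_analytes(self):
        # 60 samples x 3 elution times x 301 analytes, keep 55
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(60)]
        analytes = [f"mz{j}" for j in range(301)]
        frames = []
        for el in range(3):
            frames.append(pd.DataFrame({
                "sample": np.repeat(samples, 301),
                "axis1": el,
                "axis2": analytes * 60,
                "value": rng.random(60 * 301),
            }))
        long = pd.concat(frames, ignore_index=True)
        t = pp.collapse_elution_axis(long, analytes[:55])
        assert t.data.shape == (60, 55)

    def test_unknown_analyte_listed(self):
        rows = [("A", 1, "m1", 1.0)]
        with pytest.raises(ValueError, match="m9"):
            pp.collapse_elution_axis(make_long(rows), ["m1", "m9"])

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pp.collapse_elution_axis(make_long([("A", 1, "m1", 1.0)]), [])

    def test_agrees_with_unfold_then_group_sum(self):
        rng = np.random.default_rng(1)
        rows = [
            (s, t, m, float(rng.random()))
            for s in "ABC" for t in range(4) for m in ["m1", "m2", "m3"]
        ]
        long = make_long(rows)
        collapsed = pp.collapse_elution_axis(long, ["m1", "m2", "m3"])
        unfolded = pp.unfold_long_profile(long)
        grouped = unfolded.data.T.groupby(
            [c.split("|")[1] for c in unfolded.feature_ids]
        ).sum().T
        for m in ["m1", "m2", "m3"]:
            np.testing.assert_allclose(collapsed.data[m], grouped[m])


class TestImputeAndFilter:
    def test_impute_replaces_missing_with_zero(self):
        t = cg.FeatureTable(pd.DataFrame([[1.0, np.nan, 3.0]], index=["a"],
                                         columns=["f1", "f2", "f3"]))
        out = pp.impute_missing_zero(t)
        assert out.data.loc["a"].tolist() == [1.0, 0.0, 3.0]
        assert out.n_missing == 0

    def test_impute_identity_when_complete(self, small_table):
        pd.testing.assert_frame_equal(pp.impute_missing_zero(small_table).data,
                                      small_table.data)

    def test_sd_filter_hand_computed(self):
        df = pd.DataFrame({
            "const": [1.0, 1.0, 1.0],          # SD 0 -> removed at any threshold
            "tiny": [0.0, 0.01, 0.02],         # sample SD 0.01 < 0.05 -> removed
            "kept": [0.0, 1.0, 2.0],           # sample SD 1 -> kept
        }, index=list("abc"))
        kept, removed = pp.filter_low_variance(cg.FeatureTable(df), sd_threshold=0.05)
        assert removed == ["const", "tiny"]
        assert kept.feature_ids == ["kept"]

    def test_threshold_zero_removes_exactly_constant_columns(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((5, 4)), columns=list("wxyz"),
                          index=[f"s{i}" for i in range(5)])
        df["w"] = 7.0
        kept, removed = pp.filter_low_variance(cg.FeatureTable(df), sd_threshold=0.0)
        assert removed == ["w"]
        assert kept.feature_ids == ["x", "y", "z"]

    def test_all_removed_is_an_error(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}, index=["x", "y"])
        with pytest.raises(ValueError, match="no features survive"):
            pp.filter_low_variance(cg.FeatureTable(df), 0.0)


class TestScalings:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([2.0, 4.0, 6.0], [0.0, 0.5, 1.0]),
            ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
            ([-1.0, 0.0, 3.0], [0.0, 0.25, 1.0]),
        ],
    )
    def test_row_minmax_values(self, row, expected):
        t = cg.FeatureTable(pd.DataFrame([row], index=["a"], columns=["f1", "f2", "f3"]))
        out = pp.scale_rows_minmax(t)
        assert out.data.loc["a"].tolist() == expected
        assert out.scaling_state is ScalingState.ROW_MINMAX

    def test_col_minmax_values_and_idempotence(self):
        df = pd.DataFrame({"f": [2.0, 4.0, 6.0], "g": [1.0, 1.0, 1.0]},
                          index=list("abc"))
        once = pp.scale_cols_minmax(cg.FeatureTable(df))
        assert once.data["f"].tolist() == [0.0, 0.5, 1.0]
        assert once.data["g"].tolist() == [0.0, 0.0, 0.0]
        twice = pp.scale_cols_minmax(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_col_minmax_single_sample_all_zero(self):
        t = cg.FeatureTable(pd.DataFrame([[3.0, 4.0]], index=["a"], columns=["f", "g"]))
        assert pp.scale_cols_minmax(t).data.loc["a"].tolist() == [0.0, 0.0]

    def test_row_zscore_hand_computed(self):
        t = cg.FeatureTable(pd.DataFrame([[1.0, 2.0, 3.0]], index=["a"],
                                         columns=["f1", "f2", "f3"]))
        out = pp.standardize_rows_z(t)
        np.testing.assert_allclose(out.data.loc["a"], [-1.0, 0.0, 1.0])
        assert out.scaling_state is ScalingState.ROW_ZSCORE

    def test_row_zscore_constant_row_to_zeros(self):
        t = cg.FeatureTable(pd.DataFrame([[4.0, 4.0, 4.0]], index=["a"],
                                         columns=["f1", "f2", "f3"]))
        assert pp.standardize_rows_z(t).data.loc["a"].tolist() == [0.0, 0.0, 0.0]

    @given(
        st.lists(
            st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=6),
            min_size=2, max_size=6,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_row_minmax_range_property(self, rows):
        df = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))],
                          columns=[f"f{j}" for j in range(len(rows[0]))])
        out = pp.scale_rows_minmax(cg.FeatureTable(df)).data.to_numpy()
        assert out.min() >= 0.0 and out.max() <= 1.0
        for i, row in enumerate(rows):
            if max(row) > min(row):
                assert out[i].min() == 0.0 and out[i].max() == 1.0

    def test_row_zscore_moments_property(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(5, 3, (6, 9)),
                          index=[f"s{i}" for i in range(6)],
                          columns=[f"f{j}" for j in range(9)])
        out = pp.standardize_rows_z(cg.FeatureTable(df)).data.to_numpy()
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_scaling_requires_complete_table(self):
        t = cg.FeatureTable(pd.DataFrame([[1.0, np.nan]], index=["a"],
                                         columns=["f", "g"]))
        with pytest.raises(ValueError, match="missing"):
            pp.scale_rows_minmax(t)
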