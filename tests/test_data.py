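"""Trial table I/O, complete-case filtering, encoding and attrition summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbtrial import (
    attrition_summary,
    complete_cases,
    encode_design,
    load_trial_csv,
    write_trial_csv,
)
from nbtrial.data import TrialSchemaError, TrialValidationError

from conftest import make_dataset


class TestCsvRoundTrip:
    def test_write_then_load_preserves_records(self, tiny_dataset, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial_csv(tiny_dataset, path)
        loaded = load_trial_csv(path)
        pd.testing.assert_frame_equal(
            loaded.records, tiny_dataset.records, check_dtype=False
        )

    def test_round_trip_keeps_missing_outcomes(self, small_trial, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial_csv(small_trial, path)
        loaded = load_trial_csv(path)
        assert loaded.records["g_week"].isna().equals(small_trial.records["g_week"].isna())
        pd.testing.assert_frame_equal(loaded.records, small_trial.records, check_dtype=False)

    @given(
        g=st.lists(st.one_of(st.none(), st.integers(min_value=0, max_value=2000)),
                   min_size=1, max_size=12),
    )
    def test_round_trip_any_outcome_pattern(self, g, tmp_path_factory):
        rows = [
            (f"p{i}", "control" if i % 2 else "intervention", "female", 20 + i, "U1", 1.0, v)
            for i, v in enumerate(g)
        ]
        ds = make_dataset(rows)
        path = tmp_path_factory.mktemp("rt") / "t.csv"
        write_trial_csv(ds, path)
        loaded = load_trial_csv(path)
        pd.testing.assert_frame_equal(loaded.records, ds.records, check_dtype=False)

    def test_missing_column_is_schema_error(self, tiny_dataset, tmp_path):
        path = tmp_path / "broken.csv"
        tiny_dataset.records.drop(columns=["g_week"]).to_csv(path, index=False)
        with pytest.raises(TrialSchemaError, match="g_week"):
            load_trial_csv(path)

    def test_negative_outcome_names_the_row(self, tiny_dataset, tmp_path):
        path = tmp_path / "neg.csv"
        df = tiny_dataset.records.copy()
        df.loc[2, "g_week"] = -5
        df.to_csv(path, index=False)
        with pytest.raises(TrialValidationError, match="row 2"):
            load_trial_csv(path)

    def test_non_integer_outcome_rejected(self, tiny_dataset, tmp_path):
        path = tmp_path / "frac.csv"
        df = tiny_dataset.records.astype(object).copy()
        df.loc[1, "g_week"] = 12.5
        df.to_csv(path, index=False)
        with pytest.raises(TrialValidationError, match="row 1"):
            load_trial_csv(path)

    def test_boolean_spellings_accepted(self, tmp_path):
        path = tmp_path / "bools.csv"
        path.write_text(
            "id,group,sex,age,university,hed,followed_up,g_week\n"
            "a,control,female,20,U1,1,1,50\n"
            "b,control,male,21,U1,1,0,\n"
            "c,intervention,female,22,U1,1,true,60\n"
            "d,intervention,male,23,U1,1,false,\n"
        )
        ds = load_trial_csv(path)
        assert ds.records["followed_up"].tolist() == [True, False, True, False]

    def test_schema_mapping_renames_columns(self, tiny_dataset, tmp_path):
        path = tmp_path / "renamed.csv"
        out = tiny_dataset.records.rename(columns={"g_week": "grams"})
        out.to_csv(path, index=False)
        ds = load_trial_csv(path, schema={"g_week": "grams"})
        assert ds.records["g_week"].tolist() == tiny_dataset.records["g_week"].tolist()


class TestDatasetInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(TrialValidationError, match="duplicate"):
            make_dataset(
                [
                    ("x", "control", "female", 20, "U1", 1.0, 10),
                    ("x", "control", "female", 21, "U1", 1.0, 20),
                ]
            )

    def test_unknown_arm_rejected(self):
        with pytest.raises(TrialValidationError, match="group"):
            make_dataset([("x", "placebo", "female", 20, "U1", 1.0, 10)])

    def test_outcome_present_iff_followed(self):
        df = make_dataset([("x", "control", "female", 20, "U1", 1.0, 10)]).records.copy()
        df.loc[0, "followed_up"] = False
        from nbtrial import TrialDataset

        with pytest.raises(TrialValidationError):
            TrialDataset(df)


class TestCompleteCases:
    def test_keeps_only_followed_in_order(self, small_trial):
        cc = complete_cases(small_trial)
        expected = int(small_trial.records["followed_up"].sum())
        assert len(cc) == expected
        assert cc.records["followed_up"].all()
        orig_ids = small_trial.records.loc[small_trial.records["followed_up"], "id"].tolist()
        assert cc.records["id"].tolist() == orig_ids

    def test_all_followed_is_identity(self, tiny_dataset):
        cc = complete_cases(tiny_dataset)
        pd.testing.assert_frame_equal(cc.records, tiny_dataset.records)

    def test_none_followed_is_empty(self):
        ds = make_dataset([("x", "control", "female", 20, "U1", 1.0, None)])
        assert len(complete_cases(ds)) == 0


class TestEncodeDesign:
    def test_column_count_with_two_sexes_nine_universities(self, small_trial):
        cc = complete_cases(small_trial)
        design = encode_design(cc)
        # intercept + group + age + hed + 1 sex indicator + 8 university indicators
        assert design.n_cols == 13
        assert design.column_map[0] == ("intercept", "-")
        assert design.column_map[1] == ("group", "intervention")

    def test_rows_align_with_complete_cases(self, small_trial):
        cc = complete_cases(small_trial)
        design = encode_design(cc)
        assert design.n_rows == len(cc)
        np.testing.assert_array_equal(design.outcome,
                                      cc.records["g_week"].to_numpy(dtype=np.int64))
        assert design.row_ids == cc.records["id"].tolist()

    def test_reference_levels_dropped(self, tiny_dataset):
        design = encode_design(tiny_dataset)
        sources = [lvl for src, lvl in design.column_map if src == "sex"]
        assert sources == ["male"]  # 'female' is the dropped reference

    def test_numeric_untransformed(self, tiny_dataset):
        design = encode_design(tiny_dataset)
        j = [src for src, _ in design.column_map].index("age")
        np.testing.assert_array_equal(design.values[:, j],
                                      tiny_dataset.records["age"].to_numpy(dtype=float))

    def test_single_level_categorical_warns_and_contributes_nothing(self, tiny_dataset):
        df = tiny_dataset.records.copy()
        df["university"] = "U1"
        from nbtrial import TrialDataset

        with pytest.warns(UserWarning, match="university"):
            design = encode_design(TrialDataset(df))
        assert all(src != "university" for src, _ in design.column_map)

    def test_empty_dataset_errors(self, tiny_dataset):
        empty = complete_cases(
            make_dataset([("x", "control", "female", 20, "U1", 1.0, None)])
        )
        with pytest.raises(ValueError, match="no rows"):
            encode_design(empty)

    def test_incomplete_dataset_rejected(self):
        ds = make_dataset(
            [
                ("x", "control", "female", 20, "U1", 1.0, 10),
                ("y", "intervention", "female", 20, "U1", 1.0, None),
            ]
        )
        with pytest.raises(ValueError, match="complete-case"):
            encode_design(ds)

    def test_single_arm_design_fails_downstream_with_rank_error(self):
        rows = [(f"c{i}", "control", "female" if i % 2 else "male",
                 20 + i, "U1" if i % 2 else "U2", 1.0, 30 + 7 * i) for i in range(12)]
        design = encode_design(make_dataset(rows))
        from nbtrial import fit_mle

        with pytest.raises(np.linalg.LinAlgError):
            fit_mle(design)


class TestAttrition:
    @staticmethod
    def _trial_with_followup(n_int_followed):
        rows = []
        for i in range(825):
            rows.append((f"i{i}", "intervention", "female", 20, "U1", 1.0,
                         100 if i < n_int_followed else None))
        for i in range(780):
            rows.append((f"c{i}", "control", "female", 20, "U1", 1.0,
                         100 if i < 529 else None))
        return make_dataset(rows)

    def test_published_arithmetic(self):
        report = attrition_summary(self._trial_with_followup(404))
        assert report.per_arm["intervention"].percent == 49.0
        assert report.per_arm["control"].percent == 67.8
        assert report.overall_randomized == 1605
        assert report.overall_percent == 58

    def test_completer_count_discrepancy_both_readings(self):
        # the source tables report 402 analyzed vs 404 followed up in the
        # intervention arm; both readings give the same overall rate of 58%
        assert self._trial_with_followup(402).records["followed_up"].sum() + 0 == 931
        assert attrition_summary(self._trial_with_followup(402)).overall_percent == 58
        assert attrition_summary(self._trial_with_followup(404)).overall_followed_up == 933

    def test_percentages_recompute_from_counts(self, small_trial):
        report = attrition_summary(small_trial)
        for arm_report in report.per_arm.values():
            assert arm_report.percent == round(
                100 * arm_report.n_followed_up / arm_report.n_randomized, 1
            )
        assert report.overall_percent == round(
            100 * report.overall_followed_up / report.overall_randomized
        )

    def test_empty_arm_reports_missing_with_warning(self):
        ds = make_dataset([("x", "control", "female", 20, "U1", 1.0, 10)])
        with pytest.warns(UserWarning, match="intervention"):
            report = attrition_summary(ds)
        assert report.per_arm["intervention"].percent is None
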