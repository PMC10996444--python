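"""Lesion-table IO, population filtering and cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from dermtriage.fixtures import make_fixture
from dermtriage.io import RowError, SchemaError, read_lesion_table, write_lesion_table
from dermtriage.populations import apply_population_filter, summarize_cohort
from dermtriage.records import LesionRecord, ManagementDecision, PatientRecord


def _roundtrip(lesions, patients, tmp_path, name="t.csv"):
    path = write_lesion_table(lesions, tmp_path / name, patients)
    return read_lesion_table(path)


class TestIO:
    def test_roundtrip_preserves_every_field(self, tiny_lesions, tmp_path):
        lesions, patients = make_fixture("tiny")
        back, pback, errors = _roundtrip(lesions, patients, tmp_path)
        assert errors == []
        pd.testing.assert_frame_equal(
            back, lesions.reset_index(drop=True), check_dtype=False
        )
        pd.testing.assert_frame_equal(
            pback.sort_values("patient_id").reset_index(drop=True),
            patients.sort_values("patient_id").reset_index(drop=True),
            check_dtype=False,
        )

    def test_roundtrip_study_fixture(self, study_lesions, study_patients, tmp_path):
        back, _, errors = _roundtrip(study_lesions, study_patients, tmp_path)
        assert errors == []
        assert len(back) == len(study_lesions)
        pd.testing.assert_frame_equal(
            back, study_lesions.reset_index(drop=True), check_dtype=False
        )

    def test_short_management_tokens_accepted(self, tiny_lesions, tmp_path):
        lesions = tiny_lesions.copy()
        path = write_lesion_table(lesions, tmp_path / "tok.csv")
        text = (
            path.read_text()
            .replace("NON_URGENT_BIOPSY", "NUB")
            .replace("URGENT_BIOPSY", "UB")
            .replace("ROUTINE_F2F", "RF2F")
        )
        path.write_text(text)
        back, _, errors = read_lesion_table(path)
        assert errors == []
        assert (back["soc_management"] == lesions["soc_management"]).all()

    def test_unknown_token_reports_row_and_keeps_others(self, tiny_lesions, tmp_path):
        path = write_lesion_table(tiny_lesions, tmp_path / "bad.csv")
        lines = path.read_text().splitlines()
        # data row 3 is the IEC lesion (line 4 after the header)
        lines[4] = lines[4].replace("IEC", "XYZ")
        path.write_text("\n".join(lines))
        back, _, errors = read_lesion_table(path)
        assert len(back) == len(tiny_lesions) - 1
        assert any(e.row == 3 and e.token == "XYZ" for e in errors)

    def test_missing_mandatory_column_names_it(self, tiny_lesions, tmp_path):
        path = write_lesion_table(tiny_lesions, tmp_path / "cols.csv")
        frame = pd.read_csv(path).drop(columns=["soc_management"])
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="soc_management"):
            read_lesion_table(path)

    def test_schema_mapping_renames_columns(self, tiny_lesions, tmp_path):
        path = write_lesion_table(tiny_lesions, tmp_path / "schema.csv")
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        frame = frame.rename(columns={"final_dx": "diagnosis"})
        frame.to_csv(path, index=False)
        back, _, errors = read_lesion_table(path, schema={"diagnosis": "final_dx"})
        assert errors == []
        assert len(back) == len(tiny_lesions)

    def test_empty_table_roundtrip(self, tiny_lesions, tmp_path):
        empty = tiny_lesions.iloc[0:0]
        back, _, errors = _roundtrip(empty, None, tmp_path)
        assert len(back) == 0 and errors == []

    def test_absent_ai_labels_serialize_empty(self, tmp_path):
        lesions, patients = make_fixture("tiny")
        lesions.loc[0, ["ai_label_a", "ai_label_b", "ai_label_rws"]] = None
        lesions.loc[0, ["image_captured", "image_qc_passed"]] = False
        path = write_lesion_table(lesions, tmp_path / "na.csv")
        first_data_row = path.read_text().splitlines()[1]
        back, _, errors = read_lesion_table(path)
        assert errors == []
        assert back.loc[0, "ai_label_a"] is None


class TestRecordValidation:
    def test_histology_requires_final_dx(self):
        rec = LesionRecord(
            lesion_id="L1", patient_id="P1", attendance_id="A1",
            final_dx=None, dx_basis="histology",
            soc_management=ManagementDecision.DISCHARGE,
        )
        with pytest.raises(ValueError, match="histology"):
            rec.validate()

    def test_ai_labels_require_usable_image(self):
        rec = LesionRecord(
            lesion_id="L1", patient_id="P1", attendance_id="A1",
            final_dx="BENIGN", dx_basis="clinical",
            soc_management=ManagementDecision.DISCHARGE,
            ai_label_a="BENIGN", image_captured=False,
        )
        with pytest.raises(ValueError, match="image"):
            rec.validate()

    def test_adult_age_enforced(self):
        with pytest.raises(ValueError, match="age"):
            PatientRecord(patient_id="P1", age=17, sex="female").validate()


def _flow_cohort():
    """867 recruited lesions: 33 ineligible/withdrawn, then 45 of the
    remainder without a device result."""
    lesions, _ = make_fixture("study_cost")  # 867 rows, all eligible
    lesions = lesions.copy()
    lesions.loc[: 32, "eligible"] = False
    lesions.loc[33:57, "image_captured"] = False
    lesions.loc[33:57, "image_qc_passed"] = False
    lesions.loc[58:77, "image_qc_passed"] = False
    lesions.loc[33:77, ["ai_label_a", "ai_label_b", "ai_label_rws"]] = None
    return lesions


class TestPopulationFilter:
    def test_constructed_ten_lesion_flow(self, tiny_lesions):
        lesions = tiny_lesions.copy()
        lesions.loc[0:1, "eligible"] = False
        lesions.loc[2, ["final_dx", "dx_basis"]] = None
        lesions.loc[3, ["ai_label_a", "ai_label_b", "ai_label_rws"]] = None
        lesions.loc[3, "image_qc_passed"] = False
        itt, _ = apply_population_filter(lesions, "itt")
        pp, _ = apply_population_filter(lesions, "pp")
        assert len(itt) == 7
        assert len(pp) == 6

    def test_study_shaped_flow_867_834_789(self):
        lesions = _flow_cohort()
        itt, _ = apply_population_filter(lesions, "itt")
        pp, excl = apply_population_filter(lesions, "pp")
        assert len(lesions) == 867
        assert len(itt) == 834
        assert len(pp) == 789

    def test_exclusion_reasons_sum_to_dropped(self):
        lesions = _flow_cohort()
        pp, excl = apply_population_filter(lesions, "pp")
        assert sum(excl.values()) == len(lesions) - len(pp)

    def test_no_op_when_all_complete(self, study_lesions):
        for stage in ("recruited", "itt", "pp"):
            out, _ = apply_population_filter(study_lesions, stage)
            assert len(out) == len(study_lesions)

    def test_filtering_is_monotone(self):
        lesions = _flow_cohort()
        rec, _ = apply_population_filter(lesions, "recruited")
        itt, _ = apply_population_filter(lesions, "itt")
        pp, _ = apply_population_filter(lesions, "pp")
        assert set(pp.lesion_id) <= set(itt.lesion_id) <= set(rec.lesion_id)


class TestSummarize:
    def test_study_cohort_female_fraction(self, study_lesions, study_patients):
        summary = summarize_cohort(study_lesions, study_patients)
        assert summary["n_patients"] == 622
        assert summary["sex"]["female"]["pct"] == 63.3

    def test_percentages_sum_to_100(self, study_lesions, study_patients):
        summary = summarize_cohort(study_lesions, study_patients)
        for key in ("sex", "fitzpatrick"):
            total = sum(v["pct"] for v in summary[key].values())
            assert total == pytest.approx(100, abs=0.5)

    def test_empty_cohort(self, tiny_lesions):
        empty = tiny_lesions.iloc[0:0]
        summary = summarize_cohort(empty, pd.DataFrame(columns=["patient_id"]))
        assert summary["n_lesions"] == 0

    def test_single_patient_is_100_percent(self, tiny_lesions, study_patients):
        one = study_patients.iloc[:1]
        summary = summarize_cohort(tiny_lesions.iloc[:1], one)
        assert list(summary["sex"].values())[0]["pct"] == 100.0
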