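import numpy as np
import pandas as pd
import pytest

from hhnet.errors import OrphanRecordError, RosterValidationError, SchemaError
from hhnet.roster import (
    read_analysis_table,
    read_children,
    read_roster,
    write_analysis_table,
)
from tests.conftest import children_csv, member, roster_csv


class TestReadRoster:
    def test_minimal_valid_household(self, minimal_household):
        roster, diags = minimal_household
        assert len(roster) == 3
        assert diags == []
        ego = roster[roster["is_respondent"] == 1]
        assert len(ego) == 1
        assert ego.iloc[0]["relationship_code"] == "spouse"
        assert ego.iloc[0]["sex"] == "female"

    def test_two_respondents_rejected_naming_household(self, tmp_path):
        path = roster_csv(tmp_path, [
            member(line=1, code="head", sex="female", resp=1),
            member(line=2, code="spouse", sex="female", resp=1),
        ])
        with pytest.raises(RosterValidationError, match="hh1"):
            read_roster(path)

    def test_empty_file_with_header(self, tmp_path):
        roster, diags = read_roster(roster_csv(tmp_path, []))
        assert roster.empty
        assert diags == []

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("household_id,line_number\nhh1,1\n")
        with pytest.raises(SchemaError, match="relationship_code"):
            read_roster(path)

    def test_duplicate_line_number_rejected(self, tmp_path):
        path = roster_csv(tmp_path, [
            member(line=1, code="head"),
            member(line=1, code="spouse", sex="female", resp=1),
        ])
        with pytest.raises(RosterValidationError, match="duplicate"):
            read_roster(path)

    def test_over_20_lines_rejected(self, tmp_path):
        rows = [member(line=1, code="head"),
                member(line=2, code="spouse", sex="female", resp=1)]
        rows += [member(line=i, code="son_daughter", age=5) for i in range(3, 23)]
        with pytest.raises(RosterValidationError, match="20"):
            read_roster(roster_csv(tmp_path, rows))

    def test_unknown_code_mapped_with_warning(self, tmp_path):
        path = roster_csv(tmp_path, [
            member(line=1, code="head"),
            member(line=2, code="spouse", sex="female", resp=1),
            member(line=3, code="co_wife", age=30, sex="female"),
        ])
        roster, diags = read_roster(path)
        assert roster.loc[2, "relationship_code"] == "other_relative"
        assert any(d.severity == "warning" and "co_wife" in d.message for d in diags)

    def test_member_neither_de_jure_nor_de_facto_rejected(self, tmp_path):
        path = roster_csv(tmp_path, [
            member(line=1, code="head"),
            member(line=2, code="spouse", sex="female", resp=1, dj=0, df=0),
        ])
        with pytest.raises(RosterValidationError, match="neither"):
            read_roster(path)

    def test_nonpositive_weight_rejected(self, tmp_path):
        path = roster_csv(tmp_path, [
            member(line=1, code="head", w=0),
            member(line=2, code="spouse", sex="female", resp=1, w=0),
        ])
        with pytest.raises(RosterValidationError, match="weight"):
            read_roster(path)

    def test_missing_attributes_propagate_as_missing(self, tmp_path):
        path = roster_csv(tmp_path, [
            member(line=1, code="head", age=".", edu="."),
            member(line=2, code="spouse", sex="female", resp=1),
        ])
        roster, _ = read_roster(path)
        assert np.isnan(roster.loc[0, "age_years"])
        assert pd.isna(roster.loc[0, "education"])


class TestReadChildren:
    def test_yes_response(self, tmp_path, minimal_household):
        roster, _ = minimal_household
        ch = read_children(children_csv(tmp_path, ["hh1,3,7,1,2,2"]), roster)
        assert ch.loc[0, "given_solids_yesterday"] == 1
        assert ch.loc[0, "age_months"] == 7

    def test_blank_response_preserved_missing(self, tmp_path):
        ch = read_children(children_csv(tmp_path, ["hh1,3,7,.,2,2"]))
        assert pd.isna(ch.loc[0, "given_solids_yesterday"])

    def test_negative_age_rejected(self, tmp_path):
        with pytest.raises(RosterValidationError, match="age_months"):
            read_children(children_csv(tmp_path, ["hh1,3,-1,1,2,2"]))

    def test_unknown_household_is_orphan(self, tmp_path, minimal_household):
        roster, _ = minimal_household
        with pytest.raises(OrphanRecordError, match="hh9"):
            read_children(children_csv(tmp_path, ["hh9,3,7,1,2,2"]), roster)

    def test_unknown_caregiver_line_is_orphan(self, tmp_path, minimal_household):
        roster, _ = minimal_household
        with pytest.raises(OrphanRecordError, match="caregiver"):
            read_children(children_csv(tmp_path, ["hh1,3,7,1,9,9"]), roster)


class TestAnalysisTableRoundTrip:
    def test_write_read_identity(self, tmp_path):
        df = pd.DataFrame(
            {
                "household_id": ["a", "b", "c", "d", "e"],
                "estimate": [1.5, np.nan, 0.0, -2.25, 3.125],
                "band": ["low", "high", "low", "high", "low"],
                "flag": [1, 0, 1, 1, 0],
            }
        )
        path = tmp_path / "t.csv"
        write_analysis_table(df, path)
        back = read_analysis_table(path)
        pd.testing.assert_frame_equal(back, df)

    def test_missing_cells_use_explicit_token(self, tmp_path):
        df = pd.DataFrame({"household_id": ["a"], "me_pp": [np.nan]})
        path = tmp_path / "t.csv"
        write_analysis_table(df, path)
        assert path.read_text().splitlines()[1].endswith(",.")

    def test_empty_collection_gives_header_only(self, tmp_path):
        df = pd.DataFrame({"household_id": [], "estimate": []})
        path = tmp_path / "t.csv"
        write_analysis_table(df, path)
        lines = path.read_text().splitlines()
        assert lines == ["household_id,estimate"]

    def test_generated_cohort_round_trips(self, tmp_path, small_cohort):
        paths = small_cohort.write(tmp_path)
        roster, diags = read_roster(paths[0])
        assert diags == []
        children = read_children(paths[1], roster)
        # numeric columns come back bit-identical, strings unchanged
        orig = small_cohort.roster.reset_index(drop=True)
        for col in orig.columns:
            got, want = roster[col], orig[col]
            if want.dtype.kind in "if":
                np.testing.assert_allclose(got.to_numpy(float), want.to_numpy(float))
            else:
                assert (got.astype(str) == want.astype(str)).all()
        assert len(children) == len(small_cohort.children)
        assert (children["given_solids_yesterday"]
                == small_cohort.children["given_solids_yesterday"]).all()
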