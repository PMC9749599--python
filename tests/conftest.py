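import pytest

from hhnet.roster import read_roster
from hhnet.simulate import GeneratorConfig, generate_cohort

ROSTER_HEADER = (
    "household_id,line_number,relationship_code,age_years,sex,education,"
    "de_jure,de_facto,is_respondent,survey_round,cluster_id,weight,"
    "residence,wealth_index,earnings_type"
)
CHILD_HEADER = (
    "household_id,child_line,age_months,given_solids_yesterday,"
    "caregiver_line,mother_line"
)


def roster_csv(tmp_path, rows, name="roster.csv"):
    path = tmp_path / name
    path.write_text(ROSTER_HEADER + "\n" + "\n".join(rows) + ("\n" if rows else "\n"))
    return path


def children_csv(tmp_path, rows, name="children.csv"):
    path = tmp_path / name
    path.write_text(CHILD_HEADER + "\n" + "\n".join(rows) + ("\n" if rows else "\n"))
    return path


def member(hh="hh1", line=1, code="head", age=35, sex="male", edu="none",
           dj=1, df=1, resp=0, rnd="2011", cluster="c1", w=1.0,
           res="rural", wealth="poor", earn="not_working"):
    return f"{hh},{line},{code},{age},{sex},{edu},{dj},{df},{resp},{rnd},{cluster},{w},{res},{wealth},{earn}"


@pytest.fixture
def minimal_household(tmp_path):
    """head(m,35), spouse(f,28,respondent), son(m,1)."""
    path = roster_csv(tmp_path, [
        member(line=1, code="head", age=35, sex="male"),
        member(line=2, code="spouse", age=28, sex="female", resp=1),
        member(line=3, code="son_daughter", age=1, sex="male"),
    ])
    roster, diags = read_roster(path)
    return roster, diags


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-round synthetic cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(seed=5, n_households_per_round=150))
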