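"""Deduplication, cohort construction, seriousness, characteristics."""

import itertools

import pandas as pd
import pytest

from polabr.case_dedup import (CaseData, ReportCase, build_cohort,
                               classify_serious, deduplicate,
                               demographics_summary)
from polabr.faers_tables import DrugEntry, OutcomeEntry, ReactionEntry

from conftest import bundle, demo_row, regimen_drugs


def test_latest_fda_date_version_retained():
    b = bundle(demo=[demo_row(1001, 100, 20210101, caseversion=1),
                     demo_row(1002, 100, 20220301, caseversion=2)],
               reac=[ReactionEntry("1001", "Pyrexia"),
                     ReactionEntry("1002", "Sepsis")])
    cases = deduplicate([b])
    assert len(cases) == 1
    assert cases[0].primaryid == "1002"
    assert cases[0].reactions == frozenset({"Sepsis"})


def test_single_version_case_unchanged():
    b = bundle(demo=[demo_row(1001, 100, 20210101)])
    cases = deduplicate([b])
    assert len(cases) == 1 and cases[0].primaryid == "1001"


def test_equal_dates_tie_break_larger_primaryid():
    """The tie-break is deterministic for either input order."""
    rows = [demo_row(1001, 100, 20210101), demo_row(1002, 100, 20210101)]
    for order in itertools.permutations(rows):
        cases = deduplicate([bundle(demo=list(order))])
        assert [c.primaryid for c in cases] == ["1002"]


def test_dedup_order_independent_and_idempotent():
    b1 = bundle(demo=[demo_row(1001, 100, 20210101),
                      demo_row(2001, 200, 20210505)], label="2021Q1")
    b2 = bundle(demo=[demo_row(1002, 100, 20220301)], label="2022Q1")
    first = deduplicate([b1, b2])
    second = deduplicate([b2, b1])
    assert sorted(c.primaryid for c in first) == \
        sorted(c.primaryid for c in second)
    # idempotence on the frame path: re-deduplicating changes nothing
    demo = pd.DataFrame({
        "primaryid": ["1002", "2001"], "caseid": ["100", "200"],
        "fda_dt": [20220301, 20210505], "sex": ["F", "M"],
        "age_years": [60.0, None], "weight_kg": [None, 80.0],
        "country": ["US", "IT"], "report_year": [2022, 2021]})
    empty_drug = pd.DataFrame(columns=["primaryid", "drug_seq", "role_cod",
                                       "drugname", "prod_ai"])
    empty2 = pd.DataFrame(columns=["primaryid", "pt"])
    empty3 = pd.DataFrame(columns=["primaryid", "outc_cod"])
    empty4 = pd.DataFrame(columns=["primaryid", "indi_drug_seq", "indi_pt"])
    once = CaseData.from_table_frames(demo, empty_drug, empty2, empty3,
                                      empty4)
    assert once.n_duplicates_removed == 0
    assert sorted(once.cases["primaryid"]) == ["1002", "2001"]


def test_dedup_removes_exactly_planted_versions(small_world):
    bundles, truth = small_world
    data = CaseData.from_bundles(bundles)
    assert data.n_cases == truth.n_cases
    assert data.n_duplicates_removed == truth.n_extra_versions
    # retained clinical content identical to the planted base reports
    merged = data.cases.merge(
        truth.demo_truth[["caseid", "primaryid", "sex", "report_year"]],
        on="caseid", suffixes=("", "_truth"))
    assert (merged["primaryid"] == merged["primaryid_truth"]).all()
    assert (merged["sex"] == merged["sex_truth"]).all()


@pytest.mark.parametrize("outcomes,expected", [
    ({"HO"}, True),
    ({"DE"}, True),
    ({"LT", "OT"}, True),
    ({"DS"}, True),
    ({"OT", "CA"}, False),
    ({"RI"}, False),
    (set(), False),
])
def test_classify_serious(outcomes, expected):
    assert classify_serious(outcomes) is expected


def test_serious_flag_set_from_outcomes():
    b = bundle(demo=[demo_row(1, 1, 20210101), demo_row(2, 2, 20210101)],
               outc=[OutcomeEntry("1", "HO"), OutcomeEntry("2", "OT")])
    cases = {c.caseid: c for c in deduplicate([b])}
    assert cases["1"].serious and not cases["2"].serious


def _cohort_world():
    demo = [demo_row(i, i, 20210101) for i in (1, 2, 3, 4)]
    drug = (regimen_drugs(1)                               # full, PS/SS
            + regimen_drugs(2, roles=("PS", "C", "PS"))    # benda only C
            + [DrugEntry("3", 1, "PS", "POLIVY", "polatuzumab vedotin")]
            + [DrugEntry("4", 1, "PS", "ASPIRIN", "aspirin")])
    return bundle(demo=demo, drug=drug)


def test_build_cohort_requires_all_components_as_suspects():
    cohort = build_cohort(deduplicate([_cohort_world()]))
    flags = {c.caseid: c.in_cohort for c in cohort.data.to_cases()}
    assert flags == {"1": True, "2": False, "3": False, "4": False}
    assert cohort.n_cohort == 1 and cohort.n_total_db == 4


def test_build_cohort_relaxed_membership():
    cohort = build_cohort(deduplicate([_cohort_world()]), min_components=2)
    flags = {c.caseid: c.in_cohort for c in cohort.data.to_cases()}
    # case 2 has pola PS and rituximab PS (benda only concomitant)
    assert flags == {"1": True, "2": True, "3": False, "4": False}


def test_build_cohort_empty_regimen_rejected():
    with pytest.raises(ValueError):
        build_cohort(deduplicate([_cohort_world()]), regimen=[])


def test_cohort_monotone_in_synonyms():
    """Enlarging a synonym set never shrinks the cohort."""
    base = deduplicate([_cohort_world()])
    small = [{"polatuzumab vedotin"}, {"bendamustine"}, {"rituximab"}]
    big = [set(s) | {"aspirin"} for s in small]
    n_small = build_cohort(base, regimen=small).n_cohort
    n_big = build_cohort(base, regimen=big).n_cohort
    assert n_big >= n_small


def _cohort_of(cases):
    data = CaseData.from_cases(cases)
    data.cases["in_cohort"] = True
    from polabr.case_dedup import Cohort
    return Cohort(data=data, n_total_db=len(cases), n_cohort=len(cases))


def test_age_bins_inclusive_of_65():
    cases = [ReportCase(primaryid=str(i), caseid=str(i), age_years=a,
                        report_year=2022, in_cohort=True)
             for i, a in enumerate([17, 30, 65, None])]
    table = demographics_summary(_cohort_of(cases))
    age = table[table["block"] == "Age (years)"].set_index("category")["n"]
    assert list(age[["<18", "18<=and<=65", ">65", "Unknown"]]) == [1, 2, 0, 1]


def test_summary_blocks_sum_to_cohort_size(small_world):
    bundles, _ = small_world
    cohort = build_cohort(CaseData.from_bundles(bundles))
    table = demographics_summary(cohort)
    for block in ("Sex", "Age (years)", "Outcomes", "Report year"):
        sub = table[table["block"] == block]
        assert sub["n"].sum() == cohort.n_cohort
        assert sub["pct"].sum() == pytest.approx(100.0, abs=0.1)


def test_empty_cohort_all_zero_table():
    cases = [ReportCase(primaryid="1", caseid="1", in_cohort=False)]
    data = CaseData.from_cases(cases)
    from polabr.case_dedup import Cohort
    table = demographics_summary(Cohort(data=data, n_total_db=1, n_cohort=0))
    assert (table["n"] == 0).all() or table.empty


def test_summary_counts_match_generator_tallies(small_world):
    bundles, truth = small_world
    cohort = build_cohort(CaseData.from_bundles(bundles))
    table = demographics_summary(cohort)
    truth_cohort = truth.demo_truth[truth.demo_truth["cohort"]]
    sex = table[table["block"] == "Sex"].set_index("category")["n"]
    assert sex["Female"] == (truth_cohort["sex"] == "F").sum()
    assert sex["Male"] == (truth_cohort["sex"] == "M").sum()
    out = table[table["block"] == "Outcomes"].set_index("category")["n"]
    assert out["Serious outcome"] == truth_cohort["serious"].sum()
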