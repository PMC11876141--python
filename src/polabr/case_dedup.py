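"""Case deduplication, regimen cohort construction and seriousness.

FAERS cases are revised over time: several report versions share one
``caseid``.  Following standard pharmacovigilance cleaning, only the version
with the most recent FDA acceptance date is retained (ties broken toward the
larger ``primaryid``, i.e. the later database insertion).  The combination
cohort holds every deduplicated case that reports *all* regimen components
— by default polatuzumab, bendamustine and rituximab — as primary or
secondary suspects.  A case is *serious* when any of its outcome codes is
death (DE), life-threatening (LT), hospitalization (HO) or disability (DS).

Internally the module works on a columnar :class:`CaseData` container
(pandas DataFrames) so that cohorts of 10^5–10^6 reports remain fast; the
record-level :class:`ReportCase` API converts to and from it losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .faers_tables import DrugEntry, QuarterBundle

__all__ = [
    "SERIOUS_CODES",
    "DEFAULT_REGIMEN",
    "DEFAULT_ROLES",
    "ReportCase",
    "CaseData",
    "Cohort",
    "deduplicate",
    "classify_serious",
    "build_cohort",
    "demographics_summary",
]

#: Outcome codes defining a serious report: hospitalization, life-threatening
#: illness, disability or death.  Congenital anomaly (CA) and required
#: intervention (RI) are deliberately excluded from the default; pass a
#: different code set to override.
SERIOUS_CODES = frozenset({"DE", "LT", "HO", "DS"})

#: Synonym sets for the pola+BR regimen components.  Matching is a
#: case-insensitive exact comparison of ``drugname`` or ``prod_ai`` against
#: the set — no substring or fuzzy matching (MedDRA-standardized names are a
#: controlled vocabulary; trade-name expansion is the caller's job).
DEFAULT_REGIMEN: tuple[frozenset[str], ...] = (
    frozenset({"polatuzumab vedotin", "polatuzumab", "polivy"}),
    frozenset({"bendamustine", "bendamustine hydrochloride",
               "treanda", "bendeka"}),
    frozenset({"rituximab", "rituxan", "mabthera"}),
)

DEFAULT_ROLES = frozenset({"PS", "SS"})


@dataclass(frozen=True)
class ReportCase:
    """One deduplicated spontaneous report."""

    primaryid: str
    caseid: str
    sex: str = "UNK"
    age_years: float | None = None
    weight_kg: float | None = None
    country: str = ""
    report_year: int = 0
    drugs: tuple[DrugEntry, ...] = ()
    reactions: frozenset[str] = frozenset()
    outcomes: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    serious: bool = False
    in_cohort: bool = False


def classify_serious(outcomes: Iterable[str],
                     serious_codes: frozenset[str] = SERIOUS_CODES) -> bool:
    """True iff any outcome code falls in the serious set."""
    return not serious_codes.isdisjoint(outcomes)


def _norm(s: str) -> str:
    return " ".join(str(s).split()).casefold()


@dataclass
class CaseData:
    """Columnar deduplicated case store.

    ``cases`` has one row per caseid with columns ``caseid, primaryid, sex,
    age_years, weight_kg, country, report_year, serious, in_cohort``;
    ``reactions/outcomes/indications`` are unique (caseid, value) pairs with
    set semantics; ``drugs`` keeps one row per retained drug entry.
    """

    cases: pd.DataFrame
    reactions: pd.DataFrame
    drugs: pd.DataFrame
    outcomes: pd.DataFrame
    indications: pd.DataFrame
    n_duplicates_removed: int = 0

    # -- construction -----------------------------------------------------

    @classmethod
    def from_table_frames(cls, demo: pd.DataFrame, drug: pd.DataFrame,
                          reac: pd.DataFrame, outc: pd.DataFrame,
                          indi: pd.DataFrame,
                          serious_codes: frozenset[str] = SERIOUS_CODES,
                          ) -> "CaseData":
        """Deduplicate raw table frames into one case per ``caseid``.

        ``demo`` must carry caseid, primaryid, fda_dt, sex, age_years,
        weight_kg, country (occr_country accepted), report_year; child frames
        are keyed by primaryid.  The retained version of each case maximizes
        (fda_dt, primaryid), primaryid compared numerically when possible.
        """
        demo = demo.rename(columns={"occr_country": "country"}).copy()
        pid_num = pd.to_numeric(demo["primaryid"], errors="coerce")
        if pid_num.notna().all():
            demo["_pid_key"] = pid_num
        else:
            demo["_pid_key"] = demo["primaryid"].astype(str)
        demo = demo.sort_values(["caseid", "fda_dt", "_pid_key"],
                                kind="mergesort")
        kept = demo.drop_duplicates("caseid", keep="last").drop(
            columns="_pid_key")
        n_dupes = len(demo) - len(kept)
        if "report_year" not in kept.columns:
            kept["report_year"] = (kept["fda_dt"].astype(np.int64)
                                   // 10000).astype(int)
        keep_ids = pd.Index(kept["primaryid"].astype(str))

        def _filt(df: pd.DataFrame, value_col: str,
                  unique: bool = True) -> pd.DataFrame:
            df = df[df["primaryid"].astype(str).isin(keep_ids)].copy()
            df = df.merge(kept[["primaryid", "caseid"]], on="primaryid")
            cols = ["caseid"] + [c for c in df.columns
                                 if c not in ("caseid", "primaryid")]
            df = df[cols]
            if unique:
                df = df.drop_duplicates(["caseid", value_col])
            return df.reset_index(drop=True)

        reactions = _filt(reac, "pt")
        reactions["pt_norm"] = reactions["pt"].map(_norm)
        reactions = reactions.drop_duplicates(["caseid", "pt_norm"])
        outcomes = _filt(outc, "outc_cod")
        indications = _filt(indi, "indi_pt")
        drugs = _filt(drug, "drugname", unique=False)

        serious_ids = set(
            outcomes.loc[outcomes["outc_cod"].isin(serious_codes), "caseid"])
        cases = kept[["caseid", "primaryid", "sex", "age_years", "weight_kg",
                      "country", "report_year"]].copy()
        cases["serious"] = cases["caseid"].isin(serious_ids)
        cases["in_cohort"] = False
        return cls(cases.reset_index(drop=True), reactions, drugs,
                   outcomes, indications, n_duplicates_removed=n_dupes)

    @classmethod
    def from_bundles(cls, bundles: Sequence[QuarterBundle],
                     serious_codes: frozenset[str] = SERIOUS_CODES,
                     ) -> "CaseData":
        demo = pd.DataFrame(
            [(d.primaryid, d.caseid, d.fda_dt, d.sex, d.age_years,
              d.weight_kg, d.occr_country, d.report_year)
             for b in bundles for d in b.demo],
            columns=["primaryid", "caseid", "fda_dt", "sex", "age_years",
                     "weight_kg", "country", "report_year"])
        if demo.empty:
            raise ValueError("no DEMO records in input bundles")
        drug = pd.DataFrame(
            [(e.primaryid, e.drug_seq, e.role_cod, e.drugname, e.prod_ai)
             for b in bundles for e in b.drug],
            columns=["primaryid", "drug_seq", "role_cod", "drugname",
                     "prod_ai"])
        reac = pd.DataFrame(
            [(e.primaryid, e.pt) for b in bundles for e in b.reac],
            columns=["primaryid", "pt"])
        outc = pd.DataFrame(
            [(e.primaryid, e.outc_cod) for b in bundles for e in b.outc],
            columns=["primaryid", "outc_cod"])
        indi = pd.DataFrame(
            [(e.primaryid, e.indi_drug_seq, e.indi_pt)
             for b in bundles for e in b.indi],
            columns=["primaryid", "indi_drug_seq", "indi_pt"])
        return cls.from_table_frames(demo, drug, reac, outc, indi,
                                     serious_codes=serious_codes)

    @classmethod
    def from_cases(cls, cases: Sequence[ReportCase]) -> "CaseData":
        frame = pd.DataFrame(
            [(c.caseid, c.primaryid, c.sex, c.age_years, c.weight_kg,
              c.country, c.report_year, c.serious, c.in_cohort)
             for c in cases],
            columns=["caseid", "primaryid", "sex", "age_years", "weight_kg",
                     "country", "report_year", "serious", "in_cohort"])
        reactions = pd.DataFrame(
            [(c.caseid, pt, _norm(pt)) for c in cases
             for pt in sorted(c.reactions)],
            columns=["caseid", "pt", "pt_norm"])
        drugs = pd.DataFrame(
            [(c.caseid, e.drug_seq, e.role_cod, e.drugname, e.prod_ai)
             for c in cases for e in c.drugs],
            columns=["caseid", "drug_seq", "role_cod", "drugname",
                     "prod_ai"])
        outcomes = pd.DataFrame(
            [(c.caseid, o) for c in cases for o in sorted(c.outcomes)],
            columns=["caseid", "outc_cod"])
        indications = pd.DataFrame(
            [(c.caseid, 1, p) for c in cases for p in sorted(c.indications)],
            columns=["caseid", "indi_drug_seq", "indi_pt"])
        return cls(frame, reactions, drugs, outcomes, indications)

    # -- access -----------------------------------------------------------

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def to_cases(self) -> list[ReportCase]:
        """Materialize record objects (intended for small / test data)."""
        by_case_reac: dict = {k: frozenset(v)
                              for k, v in self.reactions.groupby("caseid")
                              ["pt"].apply(list).items()}
        by_case_outc: dict = {k: frozenset(v)
                              for k, v in self.outcomes.groupby("caseid")
                              ["outc_cod"].apply(list).items()}
        by_case_indi: dict = {k: frozenset(v)
                              for k, v in self.indications.groupby("caseid")
                              ["indi_pt"].apply(list).items()}
        by_case_drug: dict = {}
        for row in self.drugs.itertuples(index=False):
            by_case_drug.setdefault(row.caseid, []).append(
                DrugEntry("", int(row.drug_seq), row.role_cod,
                          row.drugname, row.prod_ai))
        out = []
        for row in self.cases.itertuples(index=False):
            age = None if pd.isna(row.age_years) else float(row.age_years)
            wt = None if pd.isna(row.weight_kg) else float(row.weight_kg)
            out.append(ReportCase(
                primaryid=str(row.primaryid), caseid=str(row.caseid),
                sex=row.sex, age_years=age, weight_kg=wt,
                country=str(row.country), report_year=int(row.report_year),
                drugs=tuple(by_case_drug.get(row.caseid, ())),
                reactions=by_case_reac.get(row.caseid, frozenset()),
                outcomes=by_case_outc.get(row.caseid, frozenset()),
                indications=by_case_indi.get(row.caseid, frozenset()),
                serious=bool(row.serious), in_cohort=bool(row.in_cohort)))
        return out


def as_case_data(cases) -> CaseData:
    """Coerce a CaseData or a sequence of ReportCase to CaseData."""
    if isinstance(cases, CaseData):
        return cases
    return CaseData.from_cases(list(cases))


def deduplicate(bundles: Sequence[QuarterBundle],
                serious_codes: frozenset[str] = SERIOUS_CODES,
                ) -> list[ReportCase]:
    """Merge quarterly bundles and keep one version per ``caseid``.

    The retained version is the one with the maximum FDA acceptance date;
    equal dates are broken toward the larger ``primaryid``.  Idempotent and
    independent of bundle order.
    """
    return CaseData.from_bundles(bundles, serious_codes=serious_codes).to_cases()


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """Deduplicated database with regimen-cohort flags set."""

    data: CaseData
    n_total_db: int
    n_cohort: int
    regimen: tuple[frozenset[str], ...] = DEFAULT_REGIMEN
    roles: frozenset[str] = DEFAULT_ROLES

    @property
    def cases(self) -> list[ReportCase]:
        cohort_ids = set(
            self.data.cases.loc[self.data.cases["in_cohort"], "caseid"])
        return [c for c in self.data.to_cases() if c.caseid in cohort_ids]


def build_cohort(cases, regimen: Sequence[Iterable[str]] = DEFAULT_REGIMEN,
                 roles: Iterable[str] = DEFAULT_ROLES,
                 min_components: int | None = None) -> Cohort:
    """Flag cases reporting the full regimen as suspects.

    A case joins the cohort iff, for at least ``min_components`` of the
    regimen's synonym sets (default: all of them), one of its drug entries
    with a role in *roles* matches that set exactly (case-insensitive, on
    ``drugname`` or ``prod_ai``).
    """
    regimen = tuple(frozenset(_norm(s) for s in comp) for comp in regimen)
    if not regimen or any(not comp for comp in regimen):
        raise ValueError("regimen must be a non-empty list of non-empty "
                         "synonym sets")
    roles = frozenset(roles)
    need = len(regimen) if min_components is None else int(min_components)
    if not (1 <= need <= len(regimen)):
        raise ValueError("min_components out of range")

    data = as_case_data(cases)
    drugs = data.drugs
    suspect = drugs[drugs["role_cod"].isin(roles)]
    name = suspect["drugname"].map(_norm)
    ai = suspect["prod_ai"].map(_norm)

    n_matched = pd.Series(0, index=data.cases["caseid"], dtype=int)
    for comp in regimen:
        hit = name.isin(comp) | ai.isin(comp)
        ids = set(suspect.loc[hit, "caseid"])
        n_matched[n_matched.index.isin(ids)] += 1
    in_cohort = set(n_matched.index[n_matched >= need])
    data.cases["in_cohort"] = data.cases["caseid"].isin(in_cohort)
    return Cohort(data=data, n_total_db=len(data.cases),
                  n_cohort=int(data.cases["in_cohort"].sum()),
                  regimen=regimen, roles=roles)


# ---------------------------------------------------------------------------
# descriptive characteristics


_AGE_BINS = (("<18", lambda a: a < 18),
             ("18<=and<=65", lambda a: (18 <= a) & (a <= 65)),
             (">65", lambda a: a > 65))


def demographics_summary(cohort: Cohort, top_countries: int = 5,
                         top_indications: int = 3) -> pd.DataFrame:
    """Descriptive characteristics of the cohort, one row per category.

    Blocks: sex, age bins (<18 / 18–65 inclusive / >65 / unknown), reporting
    country, indication, seriousness, report year.  Percentages within each
    block sum to 100 up to rounding.
    """
    df = cohort.data.cases[cohort.data.cases["in_cohort"]]
    n = len(df)
    rows: list[tuple[str, str, int]] = []

    for sex_label, sex_code in (("Female", "F"), ("Male", "M"),
                                ("Unknown", "UNK")):
        rows.append(("Sex", sex_label, int((df["sex"] == sex_code).sum())))

    age = df["age_years"]
    known = age.notna()
    for label, pred in _AGE_BINS:
        rows.append(("Age (years)", label,
                     int((known & pred(age.fillna(-1))).sum())))
    rows.append(("Age (years)", "Unknown", int((~known).sum())))

    def _top_block(block: str, series: pd.Series, k: int) -> None:
        filled = series.replace("", "Unknown").fillna("Unknown")
        counts = filled.value_counts()
        head = counts.iloc[:k]
        for value, cnt in head.items():
            rows.append((block, str(value), int(cnt)))
        rest = int(counts.iloc[k:].sum())
        if rest:
            rows.append((block, "Others", rest))

    _top_block("Reported countries", df["country"], top_countries)

    indi = cohort.data.indications
    indi = indi[indi["caseid"].isin(df["caseid"])]
    primary_indi = indi.groupby("caseid")["indi_pt"].first()
    indi_series = df["caseid"].map(primary_indi).fillna("Unknown")
    _top_block("Indications", indi_series, top_indications)

    rows.append(("Outcomes", "Non-serious outcome",
                 int((~df["serious"]).sum())))
    rows.append(("Outcomes", "Serious outcome", int(df["serious"].sum())))

    for year in sorted(df["report_year"].unique()):
        rows.append(("Report year", str(int(year)),
                     int((df["report_year"] == year).sum())))

    out = pd.DataFrame(rows, columns=["block", "category", "n"])
    out["pct"] = np.where(n > 0, 100.0 * out["n"] / n, 0.0).round(2)
    return out
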