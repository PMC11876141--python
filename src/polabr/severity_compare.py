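"""Severe vs non-severe comparisons within the regimen cohort.

Serious and non-serious cohort reports are compared per adverse-event term
with a 2×2 test — Pearson's χ² without continuity correction when every
expected cell count is at least 5, otherwise Fisher's exact test — and per
continuous demographic (age, weight) with an independent-samples t-test
(Welch by default).  All tests are two-sided and no multiplicity adjustment
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .case_dedup import Cohort

__all__ = [
    "SeverityTable",
    "TestResult",
    "pearson_chi2",
    "fisher_exact",
    "choose_test",
    "welch_t",
    "compare_all",
]


@dataclass(frozen=True)
class SeverityTable:
    """2×2 counts: (a, b) serious with/without, (c, d) non-serious."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"negative cell {name}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> tuple[float, float, float, float]:
        """Expected cell counts under independence."""
        n = self.n
        if n == 0:
            raise ValueError("empty table")
        r1, r2 = self.a + self.b, self.c + self.d
        c1, c2 = self.a + self.c, self.b + self.d
        return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    test_used: str               # "pearson" | "fisher" | "t"


def pearson_chi2(table: SeverityTable) -> TestResult:
    """Pearson's χ² on a 2×2 table, no continuity correction, 1 df."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        raise ValueError(f"degenerate table {table}: zero margin")
    chi2, p, dof, _ = stats.chi2_contingency([[a, b], [c, d]],
                                             correction=False)
    assert dof == 1
    return TestResult(statistic=float(chi2), p_value=float(p),
                      test_used="pearson")


def fisher_exact(table: SeverityTable) -> TestResult:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities of
    tables no more likely than the observed one)."""
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]],
                              alternative="two-sided")
    return TestResult(statistic=None, p_value=float(p), test_used="fisher")


def choose_test(table: SeverityTable, min_expected: float = 5.0) -> str:
    """Classical rule: Fisher when any expected count falls below 5."""
    try:
        expected = table.expected()
    except ValueError:
        return "fisher"
    if 0 in ((table.a + table.b), (table.c + table.d),
             (table.a + table.c), (table.b + table.d)):
        return "fisher"
    return "fisher" if min(expected) < min_expected else "pearson"


def run_test(table: SeverityTable) -> TestResult:
    """Apply :func:`choose_test` and run the chosen 2×2 test."""
    if choose_test(table) == "fisher":
        return fisher_exact(table)
    return pearson_chi2(table)


def welch_t(sample_a, sample_b, equal_variance: bool = False) -> TestResult:
    """Independent-samples t-test; missing values dropped per sample."""
    x = np.asarray(pd.Series(sample_a).dropna(), dtype=float)
    y = np.asarray(pd.Series(sample_b).dropna(), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 non-missing values")
    t, p = stats.ttest_ind(x, y, equal_var=equal_variance)
    if math.isnan(p):        # both samples constant and identical
        t, p = 0.0, 1.0
    return TestResult(statistic=float(t), p_value=float(p), test_used="t")


def compare_all(cohort: Cohort, pts: list[str] | None = None,
                continuous: tuple[str, ...] = ("age_years", "weight_kg"),
                ) -> pd.DataFrame:
    """Severity comparison table for a cohort.

    One row per PT (counts in serious/non-serious strata, chosen test,
    statistic, p), preceded by rows for each continuous demographic and the
    sex distribution.  Degenerate PT rows (zero events in both strata) are
    flagged with test ``"degenerate"``.
    """
    cases = cohort.data.cases[cohort.data.cases["in_cohort"]]
    serious_ids = set(cases.loc[cases["serious"], "caseid"])
    nonserious_ids = set(cases.loc[~cases["serious"], "caseid"])
    n_s, n_ns = len(serious_ids), len(nonserious_ids)
    rows: list[dict] = []

    for col in continuous:
        xs = cases.loc[cases["serious"], col]
        ys = cases.loc[~cases["serious"], col]
        try:
            res = welch_t(xs, ys)
            rows.append(dict(variable=col, serious=round(float(xs.mean()), 2),
                             nonserious=round(float(ys.mean()), 2),
                             statistic=res.statistic, p=res.p_value,
                             test=res.test_used))
        except ValueError:
            rows.append(dict(variable=col, serious=np.nan, nonserious=np.nan,
                             statistic=np.nan, p=np.nan, test="degenerate"))

    male_s = int(((cases["serious"]) & (cases["sex"] == "M")).sum())
    male_ns = int((~cases["serious"] & (cases["sex"] == "M")).sum())
    female_s = int(((cases["serious"]) & (cases["sex"] == "F")).sum())
    female_ns = int((~cases["serious"] & (cases["sex"] == "F")).sum())
    sex_table = SeverityTable(male_s, female_s, male_ns, female_ns)
    try:
        res = run_test(sex_table)
        rows.append(dict(variable="sex (male)", serious=male_s,
                         nonserious=male_ns, statistic=res.statistic,
                         p=res.p_value, test=res.test_used))
    except ValueError:
        rows.append(dict(variable="sex (male)", serious=male_s,
                         nonserious=male_ns, statistic=np.nan, p=np.nan,
                         test="degenerate"))

    reac = cohort.data.reactions
    reac = reac[reac["caseid"].isin(set(cases["caseid"]))]
    if pts is None:
        pt_list = sorted(reac["pt"].unique())
    else:
        pt_list = list(pts)
    counts = reac.groupby("pt_norm").agg(
        pt=("pt", "first"),
        s=("caseid", lambda ids: sum(i in serious_ids for i in ids)),
        tot=("caseid", "size"))

    for pt in pt_list:
        key = " ".join(pt.split()).casefold()
        if key in counts.index:
            a = int(counts.loc[key, "s"])
            tot = int(counts.loc[key, "tot"])
        else:
            a, tot = 0, 0
        c = tot - a
        table = SeverityTable(a, n_s - a, c, n_ns - c)
        if tot == 0 or n_s == 0 or n_ns == 0:
            rows.append(dict(variable=pt, serious=a, nonserious=c,
                             statistic=np.nan, p=np.nan, test="degenerate"))
            continue
        res = run_test(table)
        rows.append(dict(variable=pt, serious=a, nonserious=c,
                         statistic=res.statistic, p=res.p_value,
                         test=res.test_used))
    return pd.DataFrame(rows)
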