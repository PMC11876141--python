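"""Reporting odds ratio (ROR) disproportionality analysis.

For each adverse-event Preferred Term the reports are cross-classified as

==============  ============  ================
                with the PT   without the PT
==============  ============  ================
cohort              a               b
all other           c               d
==============  ============  ================

and the reporting odds ratio is ROR = (a·d)/(b·c) with the Woolf
(log-normal) 95% confidence interval

    exp( ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96.

A PT is a *signal* when it has at least ``min_count`` cohort reports
(default 10) and the CI lower bound (ROR025) exceeds 1.  The counting unit
is the deduplicated report: a report listing a PT twice contributes once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .case_dedup import Cohort, as_case_data
from .faers_tables import MedDRAMap

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "ror_ci",
    "pt_contingency",
    "detect_signals",
    "signals_to_frame",
]

Z_95 = 1.96


class DegenerateTableError(ValueError):
    """A contingency cell is zero under the strict zero-cell policy."""


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 report counts (a: cohort with PT … d: comparator without)."""

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

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def swap_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class SignalResult:
    pt: str
    soc: str
    n: int                       # cohort reports with the PT (cell a)
    ror: float
    ror_lo: float
    ror_hi: float
    significant: bool


def ror_ci(table: ContingencyTable, z: float = Z_95,
           zero_cells: str = "strict") -> tuple[float, float, float]:
    """Point estimate and Woolf CI for the reporting odds ratio.

    ``zero_cells`` is ``"strict"`` (raise :class:`DegenerateTableError` on
    any empty cell) or ``"haldane"`` (add 0.5 to every cell, the
    Haldane–Anscombe correction).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if zero_cells == "strict":
            raise DegenerateTableError(
                f"zero cell in table {(a, b, c, d)}; use zero_cells='haldane' "
                "to apply the +0.5 correction")
        if zero_cells != "haldane":
            raise ValueError(f"unknown zero-cell policy {zero_cells!r}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def _counts_frame(data, pts: list[str] | None = None) -> pd.DataFrame:
    """Per-PT (a, c) counts over the deduplicated database."""
    cases = data.cases
    cohort_ids = set(cases.loc[cases["in_cohort"], "caseid"])
    reac = data.reactions
    if pts is not None:
        keys = {" ".join(p.split()).casefold() for p in pts}
        reac = reac[reac["pt_norm"].isin(keys)]
    reac = reac.assign(in_cohort=reac["caseid"].isin(cohort_ids))
    grouped = reac.groupby("pt_norm").agg(
        pt=("pt", "first"),
        a=("in_cohort", "sum"),
        total=("in_cohort", "size"))
    grouped["c"] = grouped["total"] - grouped["a"]
    return grouped.drop(columns="total")


def pt_contingency(cases, pt: str) -> ContingencyTable:
    """Build the 2×2 table for one Preferred Term (report-level counts)."""
    data = as_case_data(cases)
    n_cohort = int(data.cases["in_cohort"].sum())
    n_other = len(data.cases) - n_cohort
    counts = _counts_frame(data, pts=[pt])
    if counts.empty:
        a = c = 0
    else:
        row = counts.iloc[0]
        a, c = int(row["a"]), int(row["c"])
    return ContingencyTable(a, n_cohort - a, c, n_other - c)


def detect_signals(cases, meddra_map: MedDRAMap | None = None,
                   min_count: int = 10, ci_lower_gt: float = 1.0,
                   z: float = Z_95) -> list[SignalResult]:
    """Run the disproportionality scan over every PT with ≥ *min_count*
    cohort reports.

    Returns one :class:`SignalResult` per retained PT, ordered by SOC then
    descending report count; ``significant`` is set when the CI lower bound
    exceeds *ci_lower_gt*.
    """
    data = as_case_data(cases)
    if len(data.cases) == 0:
        raise ValueError("empty database")
    n_cohort = int(data.cases["in_cohort"].sum())
    if n_cohort == 0:
        raise ValueError("cohort is empty; run build_cohort first")
    n_other = len(data.cases) - n_cohort

    counts = _counts_frame(data)
    counts = counts[counts["a"] >= min_count]
    results = []
    for row in counts.itertuples(index=False):
        table = ContingencyTable(int(row.a), n_cohort - int(row.a),
                                 int(row.c), n_other - int(row.c))
        try:
            ror, lo, hi = ror_ci(table, z=z)
        except DegenerateTableError:
            ror, lo, hi = ror_ci(table, z=z, zero_cells="haldane")
        soc = meddra_map.soc(row.pt) if meddra_map is not None else ""
        results.append(SignalResult(
            pt=row.pt, soc=soc, n=int(row.a), ror=ror, ror_lo=lo,
            ror_hi=hi, significant=bool(lo > ci_lower_gt)))
    results.sort(key=lambda s: (s.soc, -s.n, s.pt))
    return results


def signals_to_frame(signals: list[SignalResult]) -> pd.DataFrame:
    """Tidy export mirroring the published signal-table layout."""
    return pd.DataFrame(
        [(s.soc, s.pt, s.n, round(s.ror, 2), round(s.ror_lo, 2),
          round(s.ror_hi, 2), s.significant) for s in signals],
        columns=["soc", "pt", "n", "ror", "ror_lo", "ror_hi", "significant"])
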