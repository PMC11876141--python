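"""Cumulative-by-year ROR sensitivity analysis.

For a given Preferred Term the 2×2 table is rebuilt from all reports with
``report_year`` ≤ each period and the ROR with its 95% CI recomputed.  A
robust signal shows point estimates that stabilize and confidence intervals
that narrow as reports accumulate; the last point reproduces the all-data
signal exactly.  Periods where any cell of the cumulative table is zero are
skipped and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .case_dedup import as_case_data
from .signal_ror import ContingencyTable, SignalResult, ror_ci

__all__ = ["TrendPoint", "cumulative_series", "top_signals_by_count",
           "series_to_frame"]


@dataclass(frozen=True)
class TrendPoint:
    period: int
    table: ContingencyTable
    ror: float
    ror_lo: float
    ror_hi: float


def cumulative_series(cases, pt: str,
                      periods: list[int] | None = None,
                      ) -> tuple[list[TrendPoint], list[int]]:
    """Cumulative ROR series for *pt* over report years.

    Returns (points, skipped_periods).  *periods* defaults to every report
    year present in the data; each point uses all reports up to and
    including that year.
    """
    data = as_case_data(cases)
    cases_df = data.cases
    if periods is None:
        periods = sorted(int(y) for y in cases_df["report_year"].unique())
    key = " ".join(pt.split()).casefold()
    reac = data.reactions
    with_pt = set(reac.loc[reac["pt_norm"] == key, "caseid"])
    if not with_pt:
        return [], list(periods)

    has_pt = cases_df["caseid"].isin(with_pt)
    in_cohort = cases_df["in_cohort"]
    year = cases_df["report_year"]

    points: list[TrendPoint] = []
    skipped: list[int] = []
    for period in periods:
        upto = year <= period
        a = int((upto & in_cohort & has_pt).sum())
        b = int((upto & in_cohort & ~has_pt).sum())
        c = int((upto & ~in_cohort & has_pt).sum())
        d = int((upto & ~in_cohort & ~has_pt).sum())
        if min(a, b, c, d) == 0:
            skipped.append(period)
            continue
        table = ContingencyTable(a, b, c, d)
        ror, lo, hi = ror_ci(table)
        points.append(TrendPoint(period=period, table=table, ror=ror,
                                 ror_lo=lo, ror_hi=hi))
    return points, skipped


def top_signals_by_count(signals: list[SignalResult], k: int) -> list[str]:
    """The *k* PTs with the largest cohort report counts.

    Ties at the cutoff are broken lexicographically (deterministic).  If
    fewer than *k* signals exist, all are returned with a warning.
    """
    ranked = sorted(signals, key=lambda s: (-s.n, s.pt))
    if k > len(ranked):
        warnings.warn(f"requested top {k} signals but only {len(ranked)} "
                      "available; returning all")
        k = len(ranked)
    return [s.pt for s in ranked[:max(k, 0)]]


def series_to_frame(pt: str, points: list[TrendPoint]) -> pd.DataFrame:
    """Tidy (pt, year, a, ror, lo, hi) frame suitable for trend plotting."""
    return pd.DataFrame(
        [(pt, p.period, p.table.a, p.ror, p.ror_lo, p.ror_hi)
         for p in points],
        columns=["pt", "year", "a", "ror", "ror_lo", "ror_hi"])
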