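"""Readers, writers and row types for FAERS-style quarterly ASCII bundles.

The FDA Adverse Event Reporting System distributes each quarter as a set of
dollar-delimited ASCII tables.  This module models the five tables used for
disproportionality analysis — DEMO (report demographics), DRUG (reported
drugs and their suspect roles), REAC (MedDRA reaction Preferred Terms),
OUTC (seriousness outcome codes) and INDI (indication terms) — plus the
Preferred Term → System Organ Class lookup used to group signals.

Parsing is *total*: every input row either becomes a typed, validated record
or is counted as a reasoned rejection in the bundle's :class:`ParseReport`;
nothing is silently dropped.
"""

from __future__ import annotations

import datetime as _dt
import glob as _glob
import gzip
import io
import os
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ROLE_CODES",
    "OUTCOME_CODES",
    "SEX_CODES",
    "DemoRecord",
    "DrugEntry",
    "ReactionEntry",
    "OutcomeEntry",
    "IndicationEntry",
    "MedDRAMap",
    "ParseReport",
    "QuarterBundle",
    "FormatError",
    "normalize_age_years",
    "normalize_weight_kg",
    "read_quarter",
    "write_quarter",
    "load_meddra_map",
    "map_pt_to_soc",
]

#: Closed set of FAERS drug role codes: primary suspect, secondary suspect,
#: concomitant, interacting.
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: Closed set of FAERS outcome codes: death, life-threatening,
#: hospitalization, disability, congenital anomaly, required intervention,
#: other.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

SEX_CODES = frozenset({"F", "M", "UNK"})

#: Sentinel returned for Preferred Terms absent from the SOC map.
UNMAPPED_SOC = "Unmapped"

_TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "INDI")

_DEMO_COLUMNS = [
    "primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
    "age", "age_cod", "sex", "wt", "wt_cod", "occr_country",
]
_DRUG_COLUMNS = ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]
_REAC_COLUMNS = ["primaryid", "pt"]
_OUTC_COLUMNS = ["primaryid", "outc_cod"]
_INDI_COLUMNS = ["primaryid", "indi_drug_seq", "indi_pt"]

_COLUMNS = {
    "DEMO": _DEMO_COLUMNS,
    "DRUG": _DRUG_COLUMNS,
    "REAC": _REAC_COLUMNS,
    "OUTC": _OUTC_COLUMNS,
    "INDI": _INDI_COLUMNS,
}


class FormatError(ValueError):
    """A file-level structural problem (missing table or mandatory column)."""


@dataclass(frozen=True)
class DemoRecord:
    """One DEMO row: demographics and versioning for a spontaneous report."""

    primaryid: str
    caseid: str
    caseversion: int
    fda_dt: int                      # FDA acceptance date, YYYYMMDD
    event_dt: int | None = None
    age: float | None = None
    age_cod: str = ""
    sex: str = "UNK"
    wt: float | None = None
    wt_cod: str = ""
    occr_country: str = ""

    @property
    def report_year(self) -> int:
        """Report year, derived from the FDA acceptance date."""
        return self.fda_dt // 10000

    @property
    def age_years(self) -> float | None:
        return normalize_age_years(self.age, self.age_cod)

    @property
    def weight_kg(self) -> float | None:
        return normalize_weight_kg(self.wt, self.wt_cod)


@dataclass(frozen=True)
class DrugEntry:
    primaryid: str
    drug_seq: int
    role_cod: str
    drugname: str
    prod_ai: str = ""


@dataclass(frozen=True)
class ReactionEntry:
    primaryid: str
    pt: str


@dataclass(frozen=True)
class OutcomeEntry:
    primaryid: str
    outc_cod: str


@dataclass(frozen=True)
class IndicationEntry:
    primaryid: str
    indi_drug_seq: int
    indi_pt: str


@dataclass
class MedDRAMap:
    """Case-insensitive Preferred Term → System Organ Class lookup."""

    entries: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MedDRAMap":
        entries: dict[str, str] = {}
        for pt, soc in pairs:
            key = _norm_pt(pt)
            if key in entries and entries[key] != soc:
                raise ValueError(f"PT {pt!r} mapped to two SOCs")
            entries[key] = soc.strip()
        return cls(entries)

    def soc(self, pt: str) -> str:
        return self.entries.get(_norm_pt(pt), UNMAPPED_SOC)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.entries)


@dataclass
class ParseReport:
    """Bookkeeping for one parsed bundle: every row is accounted for."""

    rows_read: Counter = field(default_factory=Counter)
    rows_kept: Counter = field(default_factory=Counter)
    rejections: list[tuple[str, int, str]] = field(default_factory=list)
    warnings: list[tuple[str, int, str]] = field(default_factory=list)
    orphans_dropped: Counter = field(default_factory=Counter)

    def reject(self, table: str, row: int, reason: str) -> None:
        self.rejections.append((table, row, reason))

    def warn(self, table: str, row: int, reason: str) -> None:
        self.warnings.append((table, row, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def consistent(self) -> bool:
        """record count + rejection count + orphan count == input row count."""
        rej = Counter(t for t, _, _ in self.rejections)
        for table in self.rows_read:
            if (self.rows_kept[table] + rej[table]
                    + self.orphans_dropped[table]) != self.rows_read[table]:
                return False
        return True


@dataclass
class QuarterBundle:
    """Typed contents of one quarterly FAERS extract."""

    demo: list[DemoRecord]
    drug: list[DrugEntry]
    reac: list[ReactionEntry]
    outc: list[OutcomeEntry]
    indi: list[IndicationEntry]
    label: str = ""
    parse_report: ParseReport | None = None


def _norm_pt(pt: str) -> str:
    return " ".join(pt.split()).casefold()


def normalize_age_years(age: float | None, age_cod: str) -> float | None:
    """Convert a FAERS (age, unit) pair to years.

    Units: DEC decades, YR years, MON months, WK weeks, DY days, HR hours.
    A blank unit is read as years. Values outside [0, 120) are treated as
    unusable and return None.
    """
    if age is None:
        return None
    factor = {"DEC": 10.0, "YR": 1.0, "": 1.0, "MON": 1.0 / 12.0,
              "WK": 1.0 / 52.0, "DY": 1.0 / 365.0,
              "HR": 1.0 / (365.0 * 24.0)}.get(age_cod.strip().upper())
    if factor is None:
        return None
    years = age * factor
    if not (0.0 <= years < 120.0):
        return None
    return years


def normalize_weight_kg(wt: float | None, wt_cod: str) -> float | None:
    """Convert a FAERS (weight, unit) pair to kilograms (KG or LBS)."""
    if wt is None:
        return None
    factor = {"KG": 1.0, "": 1.0, "LBS": 0.45359237,
              "LB": 0.45359237}.get(wt_cod.strip().upper())
    if factor is None or wt < 0:
        return None
    return wt * factor


# ---------------------------------------------------------------------------
# reading


def _quarter_filename(table: str, label: str) -> str:
    # "2021Q3" -> "DEMO21Q3.txt"
    year, q = label.upper().split("Q")
    return f"{table}{year[-2:]}Q{q}.txt"


def _open_text(path: str) -> io.TextIOBase:
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _find_table_file(directory: str, table: str, label: str) -> str:
    base = os.path.join(directory, _quarter_filename(table, label))
    for cand in (base, base + ".gz"):
        if os.path.exists(cand):
            return cand
    hits = sorted(_glob.glob(os.path.join(directory, f"{table}*.txt"))) + \
        sorted(_glob.glob(os.path.join(directory, f"{table}*.txt.gz")))
    if len(hits) == 1:
        return hits[0]
    raise FormatError(f"cannot locate {table} file for quarter {label!r} "
                      f"in {directory!r}")


def _read_raw(path: str, table: str, delimiter: str) -> pd.DataFrame:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=delimiter, dtype=str, engine="python",
                         keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _COLUMNS[table] if c not in df.columns]
    if missing:
        raise FormatError(
            f"{table} file {os.path.basename(path)!r} is missing mandatory "
            f"column(s): {', '.join(missing)}")
    return df


def _opt_float(s: str) -> float | None:
    s = s.strip()
    if not s:
        return None
    return float(s)


def _req_int(s: str, what: str) -> int:
    s = s.strip()
    if not s:
        raise ValueError(f"blank {what}")
    return int(s)


def _parse_yyyymmdd(s: str, what: str) -> int:
    s = s.strip()
    if len(s) != 8 or not s.isdigit():
        raise ValueError(f"{what} {s!r} is not YYYYMMDD")
    _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))  # raises on bad date
    return int(s)


def read_quarter(directory: str, label: str, delimiter: str = "$") -> QuarterBundle:
    """Read one quarter's DEMO/DRUG/REAC/OUTC/INDI files into a bundle.

    Files are located as ``DEMOyyQq.txt`` (optionally ``.gz``) under
    *directory*; a single ``DEMO*.txt`` fallback glob is accepted.  Malformed
    rows are rejected with a recorded reason; child-table rows whose
    ``primaryid`` does not appear in DEMO are dropped as orphans, with a
    count.  The returned bundle's :attr:`QuarterBundle.parse_report`
    accounts for every input row.
    """
    report = ParseReport()
    raw = {t: _read_raw(_find_table_file(directory, t, label), t, delimiter)
           for t in _TABLE_NAMES}

    demo: list[DemoRecord] = []
    for i, row in enumerate(raw["DEMO"].itertuples(index=False)):
        report.rows_read["DEMO"] += 1
        d = dict(zip(raw["DEMO"].columns, row))
        try:
            sex = d["sex"].strip().upper()
            if sex not in SEX_CODES:
                if sex:
                    report.warn("DEMO", i, f"sex {sex!r} normalized to UNK")
                sex = "UNK"
            rec = DemoRecord(
                primaryid=_nonblank(d["primaryid"], "primaryid"),
                caseid=_nonblank(d["caseid"], "caseid"),
                caseversion=max(0, _req_int(d["caseversion"] or "0",
                                            "caseversion")),
                fda_dt=_parse_yyyymmdd(d["fda_dt"], "fda_dt"),
                event_dt=(
                    _parse_yyyymmdd(d["event_dt"], "event_dt")
                    if d["event_dt"].strip() else None),
                age=_opt_float(d["age"]),
                age_cod=d["age_cod"].strip().upper(),
                sex=sex,
                wt=_opt_float(d["wt"]),
                wt_cod=d["wt_cod"].strip().upper(),
                occr_country=d["occr_country"].strip(),
            )
        except (ValueError, KeyError) as exc:
            report.reject("DEMO", i, str(exc))
            continue
        demo.append(rec)
        report.rows_kept["DEMO"] += 1

    known = {d.primaryid for d in demo}

    def _child(table: str, build) -> list:
        out = []
        for i, row in enumerate(raw[table].itertuples(index=False)):
            report.rows_read[table] += 1
            d = dict(zip(raw[table].columns, row))
            pid = d["primaryid"].strip()
            try:
                rec = build(pid, d)
            except ValueError as exc:
                report.reject(table, i, str(exc))
                continue
            if pid not in known:
                report.orphans_dropped[table] += 1
                continue
            out.append(rec)
            report.rows_kept[table] += 1
        return out

    def _build_drug(pid, d):
        role = d["role_cod"].strip().upper()
        if role not in ROLE_CODES:
            raise ValueError(f"role_cod {role!r} not in {sorted(ROLE_CODES)}")
        return DrugEntry(_nonblank(pid, "primaryid"),
                         _req_int(d["drug_seq"] or "1", "drug_seq"),
                         role, d["drugname"].strip(), d["prod_ai"].strip())

    def _build_reac(pid, d):
        pt = " ".join(d["pt"].split())
        if not pt:
            raise ValueError("blank pt")
        return ReactionEntry(_nonblank(pid, "primaryid"), pt)

    def _build_outc(pid, d):
        code = d["outc_cod"].strip().upper()
        if code not in OUTCOME_CODES:
            raise ValueError(f"outc_cod {code!r} not in {sorted(OUTCOME_CODES)}")
        return OutcomeEntry(_nonblank(pid, "primaryid"), code)

    def _build_indi(pid, d):
        ipt = " ".join(d["indi_pt"].split())
        if not ipt:
            raise ValueError("blank indi_pt")
        return IndicationEntry(_nonblank(pid, "primaryid"),
                               _req_int(d["indi_drug_seq"] or "1",
                                        "indi_drug_seq"), ipt)

    bundle = QuarterBundle(
        demo=demo,
        drug=_child("DRUG", _build_drug),
        reac=_child("REAC", _build_reac),
        outc=_child("OUTC", _build_outc),
        indi=_child("INDI", _build_indi),
        label=label,
        parse_report=report,
    )
    return bundle


def _nonblank(s: str, what: str) -> str:
    s = s.strip()
    if not s:
        raise ValueError(f"blank {what}")
    return s


# ---------------------------------------------------------------------------
# writing


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_quarter(bundle: QuarterBundle, directory: str,
                  delimiter: str = "$") -> dict[str, str]:
    """Write a bundle back to the five quarterly ASCII files.

    Blank optional fields are written as empty strings (never "nan"), so
    ``read_quarter(write_quarter(b))`` round-trips record-for-record.
    Returns the mapping table name → file path.
    """
    os.makedirs(directory, exist_ok=True)
    label = bundle.label or "0000Q0"
    paths: dict[str, str] = {}

    def _dump(table: str, columns: Sequence[str], rows: Iterable[Sequence]):
        path = os.path.join(directory, _quarter_filename(table, label))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(delimiter.join(columns) + "\n")
            for row in rows:
                fh.write(delimiter.join(_fmt(v) for v in row) + "\n")
        paths[table] = path

    _dump("DEMO", _DEMO_COLUMNS,
          ((d.primaryid, d.caseid, d.caseversion, d.fda_dt, d.event_dt,
            d.age, d.age_cod, "" if d.sex == "UNK" else d.sex, d.wt,
            d.wt_cod, d.occr_country) for d in bundle.demo))
    _dump("DRUG", _DRUG_COLUMNS,
          ((e.primaryid, e.drug_seq, e.role_cod, e.drugname, e.prod_ai)
           for e in bundle.drug))
    _dump("REAC", _REAC_COLUMNS, ((e.primaryid, e.pt) for e in bundle.reac))
    _dump("OUTC", _OUTC_COLUMNS,
          ((e.primaryid, e.outc_cod) for e in bundle.outc))
    _dump("INDI", _INDI_COLUMNS,
          ((e.primaryid, e.indi_drug_seq, e.indi_pt) for e in bundle.indi))
    return paths


# ---------------------------------------------------------------------------
# PT -> SOC map


def load_meddra_map(path: str) -> MedDRAMap:
    """Load a two-column tab-separated PT→SOC table (header optional)."""
    pairs: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"line {line_no + 1}: expected 2 tab-separated fields")
            if line_no == 0 and parts[0].strip().lower() in {"pt", "preferred term"}:
                continue
            pairs.append((parts[0], parts[1]))
    return MedDRAMap.from_pairs(pairs)


def map_pt_to_soc(pt: str, meddra_map: MedDRAMap) -> str:
    """Case-insensitive exact SOC lookup; unmapped PTs yield ``"Unmapped"``."""
    return meddra_map.soc(pt)
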