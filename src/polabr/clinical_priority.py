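"""Semi-quantitative clinical prioritization of significant signals.

Each significant signal is scored on five components and the total (0–10)
is binned into low (0–4), moderate (5–7) or high (8–10) clinical priority:

=====================  ==========================================  ======
component              default thresholds                          points
=====================  ==========================================  ======
report count           10–49 / ≥50                                 1 / 2
ROR CI lower bound     <2 / 2–5 (inclusive) / >5                   0/1/2
fatal-report burden    ≥100 reports with outcome death             1
medical-event lists    DME / IME (DME dominates)                   2 / 1
evidence appraisal     ``++`` / ``+`` / ``-``                      2/1/0
=====================  ==========================================  ======

Every threshold lives in the :class:`Rubric` so an alternative point sheet
can be swapped in without code changes.  Evidence grades are human
literature appraisals supplied as annotations, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .signal_ror import SignalResult

__all__ = [
    "EVIDENCE_GRADES",
    "Rubric",
    "DEFAULT_RUBRIC",
    "PriorityInputs",
    "PriorityResult",
    "priority_score",
    "score_table",
    "load_annotations",
    "load_reference_lists",
]

EVIDENCE_GRADES = ("++", "+", "-")

LEVELS = ("low", "moderate", "high")


@dataclass(frozen=True)
class Rubric:
    """Component thresholds and points for the priority score."""

    min_signal_count: int = 10   # scores apply only to signals at/above this
    case_points: tuple[tuple[int, int], ...] = ((50, 2), (10, 1))
    ror025_low: float = 2.0      # below → 0 points
    ror025_high: float = 5.0     # above → 2 points; in [low, high] → 1
    death_threshold: int = 100   # fatal reports at/above → 1 point
    dme_points: int = 2
    ime_points: int = 1
    evidence_points: dict[str, int] = field(
        default_factory=lambda: {"++": 2, "+": 1, "-": 0})
    moderate_from: int = 5
    high_from: int = 8

    def level(self, score: int) -> str:
        if score >= self.high_from:
            return "high"
        if score >= self.moderate_from:
            return "moderate"
        return "low"


DEFAULT_RUBRIC = Rubric()


@dataclass(frozen=True)
class PriorityInputs:
    """Per-signal facts feeding the rubric."""

    pt: str
    n: int
    ror025: float
    deaths: int
    ime_flag: bool = False
    dme_flag: bool = False
    evidence: str = "-"

    def __post_init__(self):
        if self.deaths > self.n:
            raise ValueError(f"{self.pt}: deaths ({self.deaths}) exceed "
                             f"report count ({self.n})")
        if self.evidence not in EVIDENCE_GRADES:
            raise ValueError(f"{self.pt}: evidence grade {self.evidence!r} "
                             f"not one of {EVIDENCE_GRADES}")


@dataclass(frozen=True)
class PriorityResult:
    pt: str
    components: dict[str, int]
    score: int
    level: str


def priority_score(inputs: PriorityInputs,
                   rubric: Rubric = DEFAULT_RUBRIC) -> PriorityResult:
    """Score one signal; raises if it falls below the signal threshold."""
    if inputs.n < rubric.min_signal_count:
        raise ValueError(
            f"{inputs.pt}: n={inputs.n} is below the minimum signal count; "
            "priority scores apply only to significant signals")
    comps: dict[str, int] = {}

    comps["cases"] = 0
    for threshold, points in sorted(rubric.case_points, reverse=True):
        if inputs.n >= threshold:
            comps["cases"] = points
            break

    if inputs.ror025 > rubric.ror025_high:
        comps["ror025"] = 2
    elif inputs.ror025 >= rubric.ror025_low:
        comps["ror025"] = 1
    else:
        comps["ror025"] = 0

    comps["deaths"] = 1 if inputs.deaths >= rubric.death_threshold else 0

    if inputs.dme_flag:
        comps["medical_event"] = rubric.dme_points
    elif inputs.ime_flag:
        comps["medical_event"] = rubric.ime_points
    else:
        comps["medical_event"] = 0

    comps["evidence"] = rubric.evidence_points[inputs.evidence]

    score = sum(comps.values())
    return PriorityResult(pt=inputs.pt, components=comps, score=score,
                          level=rubric.level(score))


def score_table(signals: list[SignalResult] | list[PriorityInputs],
                annotations: pd.DataFrame | None = None,
                death_counts: dict[str, int] | None = None,
                rubric: Rubric = DEFAULT_RUBRIC,
                ) -> tuple[list[PriorityResult], dict[str, int], list[str]]:
    """Score a batch of signals.

    *signals* may be ready-made :class:`PriorityInputs`, or
    :class:`~polabr.signal_ror.SignalResult` objects joined against an
    *annotations* frame (columns ``pt, evidence, ime, dme``) and a
    ``death_counts`` mapping.  Returns (results, per-level counts,
    unannotated PTs).  Unannotated signals are listed, never silently
    defaulted.
    """
    results: list[PriorityResult] = []
    unannotated: list[str] = []
    ann = None
    if annotations is not None:
        ann = annotations.copy()
        ann["key"] = ann["pt"].str.strip().str.casefold()
        ann = ann.set_index("key")

    for sig in signals:
        if isinstance(sig, PriorityInputs):
            inputs = sig
        else:
            key = sig.pt.strip().casefold()
            if ann is None or key not in ann.index:
                unannotated.append(sig.pt)
                continue
            row = ann.loc[key]
            inputs = PriorityInputs(
                pt=sig.pt, n=sig.n, ror025=sig.ror_lo,
                deaths=int((death_counts or {}).get(sig.pt, 0)),
                ime_flag=bool(row["ime"]), dme_flag=bool(row["dme"]),
                evidence=str(row["evidence"]))
        results.append(priority_score(inputs, rubric))

    counts = {level: 0 for level in LEVELS}
    for r in results:
        counts[r.level] += 1
    return results, counts, unannotated


def load_annotations(path: str) -> pd.DataFrame:
    """Read a ``pt, evidence, ime, dme`` annotation CSV.

    ``ime``/``dme`` columns accept 0/1, true/false or yes/no; an em-dash or
    "NA" evidence grade is read as "-".
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"pt", "evidence", "ime", "dme"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing column(s): {missing}")

    def _flag(s: str) -> bool:
        return s.strip().lower() in {"1", "true", "yes", "y", "dme", "ime"}

    df["ime"] = df["ime"].map(_flag)
    df["dme"] = df["dme"].map(_flag)
    df["evidence"] = (df["evidence"].str.strip()
                      .replace({"—": "-", "−": "-", "": "-", "NA": "-"}))
    return df


def load_reference_lists() -> tuple[frozenset[str], frozenset[str]]:
    """Built-in seed DME and IME Preferred Term lists (casefolded).

    These ship with the package for testing and the worked example; real
    analyses should load the full regulator-published lists.
    """
    def _load(name: str) -> frozenset[str]:
        text = (resources.files("polabr.data") / name).read_text()
        return frozenset(line.strip().casefold()
                         for line in text.splitlines() if line.strip())

    return _load("dme_list.txt"), _load("ime_list.txt")
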