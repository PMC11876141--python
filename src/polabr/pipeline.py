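"""End-to-end orchestration: ingest → dedup → cohort → signals → priority
→ severity → trend, with stage-count logging and CSV exports."""

from __future__ import annotations

import glob as _glob
import logging
import os
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import case_dedup, clinical_priority, sensitivity_trend, signal_ror
from .case_dedup import DEFAULT_REGIMEN, DEFAULT_ROLES
from .faers_tables import MedDRAMap, load_meddra_map, read_quarter
from .severity_compare import compare_all

__all__ = ["PipelineConfig", "validate_config", "run_pipeline",
           "load_config"]

log = logging.getLogger("polabr")

_QUARTER_RE = re.compile(r"DEMO(\d\d)Q([1-4])\.txt(\.gz)?$")


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``validate_config`` for the checks."""

    input_dir: str
    output_dir: str
    meddra_map: str | None = None
    annotations: str | None = None
    regimen: tuple = DEFAULT_REGIMEN
    roles: frozenset = DEFAULT_ROLES
    min_count: int = 10
    ci_lower_gt: float = 1.0
    z: float = signal_ror.Z_95
    top_k_trend: int = 10
    delimiter: str = "$"
    rubric: clinical_priority.Rubric = field(
        default_factory=clinical_priority.Rubric)


def load_config(path: str) -> PipelineConfig:
    """Build a config from a YAML file of the same field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("input_dir", "output_dir", "meddra_map", "annotations",
                "min_count", "ci_lower_gt", "z", "top_k_trend",
                "delimiter"):
        if key in raw:
            kwargs[key] = raw[key]
    if "regimen" in raw:
        kwargs["regimen"] = tuple(frozenset(s) for s in raw["regimen"])
    if "roles" in raw:
        kwargs["roles"] = frozenset(raw["roles"])
    if "rubric" in raw:
        kwargs["rubric"] = clinical_priority.Rubric(**raw["rubric"])
    return PipelineConfig(**kwargs)


def discover_quarters(input_dir: str) -> list[str]:
    """Quarter labels present in *input_dir*, from DEMO file names."""
    labels = []
    for path in sorted(_glob.glob(os.path.join(input_dir, "DEMO*"))):
        m = _QUARTER_RE.search(os.path.basename(path))
        if m:
            yy, q = m.group(1), m.group(2)
            century = "20" if int(yy) < 80 else "19"
            labels.append(f"{century}{yy}Q{q}")
    return sorted(set(labels))


def validate_config(config: PipelineConfig) -> list[str]:
    """Return every problem found (empty list = valid). Never raises."""
    problems = []
    if not os.path.isdir(config.input_dir):
        problems.append(f"input_dir {config.input_dir!r} does not exist")
    elif not discover_quarters(config.input_dir):
        problems.append(f"no DEMOyyQq.txt files found in "
                        f"{config.input_dir!r}")
    if config.min_count < 1:
        problems.append(f"min_count={config.min_count} must be >= 1")
    if config.ci_lower_gt < 0:
        problems.append("ci_lower_gt must be >= 0")
    if not config.regimen:
        problems.append("regimen is empty")
    for path_attr in ("meddra_map", "annotations"):
        path = getattr(config, path_attr)
        if path is not None and not os.path.exists(path):
            problems.append(f"{path_attr} file {path!r} does not exist")
    return problems


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the table exports.

    Writes ``characteristics.csv``, ``signals.csv``, ``priority.csv``,
    ``severity.csv`` and ``trend.csv`` under ``config.output_dir`` plus a
    plain-text ``run_log.txt`` with the stage counts; returns the frames.
    Deterministic for fixed inputs.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    os.makedirs(config.output_dir, exist_ok=True)
    counts: list[str] = []

    labels = discover_quarters(config.input_dir)
    bundles = []
    rows_read = rows_rejected = 0
    for label in labels:
        bundle = read_quarter(config.input_dir, label,
                              delimiter=config.delimiter)
        bundles.append(bundle)
        pr = bundle.parse_report
        rows_read += sum(pr.rows_read.values())
        rows_rejected += pr.n_rejected
    counts.append(f"quarters ingested: {len(bundles)}")
    counts.append(f"table rows read: {rows_read} "
                  f"(rejected: {rows_rejected})")

    data = case_dedup.CaseData.from_bundles(bundles)
    counts.append(f"unique cases after deduplication: {data.n_cases} "
                  f"(duplicate versions removed: "
                  f"{data.n_duplicates_removed})")

    cohort = case_dedup.build_cohort(data, regimen=config.regimen,
                                     roles=config.roles)
    counts.append(f"cohort reports: {cohort.n_cohort} of "
                  f"{cohort.n_total_db}")

    outputs: dict[str, pd.DataFrame] = {}
    outputs["characteristics"] = case_dedup.demographics_summary(cohort)

    meddra = (load_meddra_map(config.meddra_map)
              if config.meddra_map else MedDRAMap({}))
    signals = signal_ror.detect_signals(
        cohort.data, meddra, min_count=config.min_count,
        ci_lower_gt=config.ci_lower_gt, z=config.z)
    significant = [s for s in signals if s.significant]
    counts.append(f"PTs with >= {config.min_count} cohort reports: "
                  f"{len(signals)}; significant signals: "
                  f"{len(significant)}")
    outputs["signals"] = signal_ror.signals_to_frame(signals)

    if config.annotations:
        import dataclasses

        ann = clinical_priority.load_annotations(config.annotations)
        deaths = _death_counts(cohort)
        rubric = dataclasses.replace(
            config.rubric,
            min_signal_count=min(config.rubric.min_signal_count,
                                 config.min_count))
        results, level_counts, unannotated = clinical_priority.score_table(
            significant, annotations=ann, death_counts=deaths,
            rubric=rubric)
        counts.append("priority levels: "
                      + ", ".join(f"{k}={v}" for k, v in
                                  level_counts.items())
                      + (f"; unannotated: {len(unannotated)}"
                         if unannotated else ""))
        outputs["priority"] = pd.DataFrame(
            [(r.pt, r.score, r.level, *r.components.values())
             for r in results],
            columns=["pt", "score", "level",
                     *([] if not results else results[0].components)])
    else:
        outputs["priority"] = pd.DataFrame(
            columns=["pt", "score", "level"])
        counts.append("priority scoring skipped (no annotations file)")

    outputs["severity"] = compare_all(
        cohort, pts=[s.pt for s in significant] or None)

    top = sensitivity_trend.top_signals_by_count(
        significant, config.top_k_trend)
    trend_frames = []
    for pt in top:
        points, skipped = sensitivity_trend.cumulative_series(
            cohort.data, pt)
        frame = sensitivity_trend.series_to_frame(pt, points)
        trend_frames.append(frame)
        if skipped:
            counts.append(f"trend {pt!r}: skipped periods {skipped}")
    outputs["trend"] = (pd.concat(trend_frames, ignore_index=True)
                        if trend_frames else
                        pd.DataFrame(columns=["pt", "year", "a", "ror",
                                              "ror_lo", "ror_hi"]))

    for name, frame in outputs.items():
        frame.to_csv(os.path.join(config.output_dir, f"{name}.csv"),
                     index=False)
    log_path = os.path.join(config.output_dir, "run_log.txt")
    with open(log_path, "w") as fh:
        fh.write("\n".join(counts) + "\n")
    for line in counts:
        log.info(line)
    return outputs


def _death_counts(cohort: case_dedup.Cohort) -> dict[str, int]:
    """Per-PT count of cohort reports carrying outcome DE."""
    data = cohort.data
    cohort_ids = set(data.cases.loc[data.cases["in_cohort"], "caseid"])
    dead = set(data.outcomes.loc[data.outcomes["outc_cod"] == "DE",
                                 "caseid"]) & cohort_ids
    reac = data.reactions
    reac = reac[reac["caseid"].isin(dead)]
    return reac.groupby("pt")["caseid"].nunique().to_dict()
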