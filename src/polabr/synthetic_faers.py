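"""Synthetic FAERS-style world with known ground truth.

The generator emulates the statistical structure a spontaneous-reporting
disproportionality analysis relies on: a large background database, a small
cohort reporting the full polatuzumab + bendamustine + rituximab regimen as
primary/secondary suspects, partial-regimen decoys, per-PT reaction
sparsity, report-level seriousness outcomes, demographic missingness, and
duplicate case versions that deduplication must remove.

Drug–event associations are injected on the *odds* scale: a PT with
background per-report probability p0 and target reporting odds ratio ρ is
drawn in cohort reports with

    p1 = ρ·p0 / (1 − p0 + ρ·p0),

the unique probability whose exposure odds are ρ times the background odds,
making the injected ρ the exact estimand of the ROR pipeline.  Reports are
emitted as the same five quarterly tables the readers ingest, and a
:class:`GroundTruth` sidecar carries the planted cohort flags, p0/p1, the
per-PT generator tallies, and analytic expected contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .case_dedup import CaseData
from .faers_tables import (DemoRecord, DrugEntry, IndicationEntry,
                           OutcomeEntry, QuarterBundle, ReactionEntry)
from .signal_ror import ContingencyTable

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "injected_probability",
    "default_quarters",
    "generate",
    "generate_frames",
    "expected_tables",
]

_QUARTER_START_MONTH = {1: 1, 2: 4, 3: 7, 4: 10}

#: Regimen rows planted on cohort reports (name, active ingredient, role).
_REGIMEN_ROWS = (
    ("POLIVY", "polatuzumab vedotin", "PS"),
    ("BENDAMUSTINE HYDROCHLORIDE", "bendamustine", "SS"),
    ("RITUXAN", "rituximab", "SS"),
)

_BACKGROUND_DRUGS = ("METHOTREXATE", "ASPIRIN", "ATORVASTATIN",
                     "METFORMIN", "LISINOPRIL", "IBUPROFEN")


def default_quarters(start: str = "2019Q1", end: str = "2023Q3",
                     ) -> tuple[str, ...]:
    """Quarter labels from *start* to *end* inclusive."""
    y0, q0 = int(start[:4]), int(start[5])
    y1, q1 = int(end[:4]), int(end[5])
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return tuple(out)


def injected_probability(p0: float, rho: float) -> float:
    """Exposure-conditional probability giving exposure odds ρ × background
    odds: p1 = ρp0 / (1 − p0 + ρp0)."""
    if not (0.0 <= p0 < 1.0):
        raise ValueError("p0 must be in [0, 1)")
    if rho <= 0:
        raise ValueError("target ROR must be positive")
    return rho * p0 / (1.0 - p0 + rho * p0)


def _default_catalog() -> tuple[tuple[str, float], ...]:
    nulls = tuple((f"Background reaction {i:02d}", 0.01)
                  for i in range(1, 51))
    return nulls + (("Pancytopenia", 0.01),)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic reporting world.

    Defaults describe the standard validation scenario: 200,000 reports
    over 2019Q1–2023Q3, a 1% regimen cohort, 50 null background PTs at
    p0 = 0.01 and one injected signal (Pancytopenia) at true ROR 5.
    """

    n_reports: int = 200_000
    quarters: tuple[str, ...] = field(default_factory=default_quarters)
    cohort_fraction: float = 0.01
    partial_regimen_fraction: float = 0.02
    pt_catalog: tuple[tuple[str, float], ...] = field(
        default_factory=_default_catalog)
    injected_signals: tuple[tuple[str, float], ...] = (("Pancytopenia", 5.0),)
    #: report-level probabilities over outcome codes; the remainder is "no
    #: outcome row".  Defaults give ≈27% serious (DE+LT+HO+DS).
    serious_outcome_distribution: tuple[tuple[str, float], ...] = (
        ("DE", 0.03), ("LT", 0.02), ("HO", 0.20), ("DS", 0.02),
        ("CA", 0.005), ("RI", 0.01), ("OT", 0.30))
    duplicate_case_fraction: float = 0.05
    #: probabilities of 1, 2, ... extra earlier versions per duplicate case
    extra_version_distribution: tuple[float, ...] = (0.8, 0.2)
    sex_distribution: tuple[tuple[str, float], ...] = (
        ("F", 0.31), ("M", 0.44), ("UNK", 0.25))
    age_mean: float = 60.0
    age_sd: float = 14.0
    age_missing: float = 0.50
    weight_mean: float = 74.0
    weight_sd: float = 15.0
    weight_missing: float = 0.55
    country_distribution: tuple[tuple[str, float], ...] = (
        ("GB", 0.20), ("DE", 0.16), ("IT", 0.13), ("US", 0.10),
        ("FR", 0.08), ("JP", 0.08), ("CA", 0.05), ("", 0.20))
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        for name in ("cohort_fraction", "partial_regimen_fraction",
                     "duplicate_case_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cohort_fraction + self.partial_regimen_fraction > 1.0:
            raise ValueError("cohort + partial fractions exceed 1")
        for pt, p0 in self.pt_catalog:
            if not (0.0 <= p0 < 1.0):
                raise ValueError(f"catalog probability for {pt!r} "
                                 "outside [0, 1)")
        catalog = {pt for pt, _ in self.pt_catalog}
        for pt, rho in self.injected_signals:
            if rho <= 0:
                raise ValueError(f"injected ROR for {pt!r} must be > 0")
            if pt not in catalog:
                raise ValueError(f"injected PT {pt!r} missing from catalog")
        total = sum(p for _, p in self.serious_outcome_distribution)
        if total > 1.0 + 1e-9:
            raise ValueError("outcome probabilities sum past 1")
        if abs(sum(p for _, p in self.sex_distribution) - 1.0) > 1e-9:
            raise ValueError("sex probabilities must sum to 1")
        if abs(sum(p for _, p in self.country_distribution) - 1.0) > 1e-9:
            raise ValueError("country probabilities must sum to 1")
        if not self.quarters:
            raise ValueError("at least one quarter required")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic tables."""

    cohort_caseids: frozenset[str]
    probabilities: dict[str, tuple[float, float]]   # pt -> (p0, p1)
    expected: dict[str, ContingencyTable]           # analytic E[cell] (rounded)
    tallies: dict[str, tuple[int, int]]             # pt -> drawn (a, c)
    demo_truth: pd.DataFrame                        # one row per unique case
    n_cases: int = 0
    n_cohort: int = 0
    n_extra_versions: int = 0


def expected_tables(config: GeneratorConfig) -> dict[str, ContingencyTable]:
    """Analytic expected 2×2 cell counts for every catalog PT.

    Cells are rounded to the nearest report; observed tallies fall within a
    few binomial standard deviations of these.
    """
    config.validate()
    rho_by_pt = dict(config.injected_signals)
    n = config.n_reports
    f = config.cohort_fraction
    out = {}
    for pt, p0 in config.pt_catalog:
        p1 = injected_probability(p0, rho_by_pt.get(pt, 1.0))
        ea = n * f * p1
        ec = n * (1 - f) * p0
        out[pt] = ContingencyTable(round(ea), round(n * f - ea),
                                   round(ec), round(n * (1 - f) - ec))
    return out


def _quarter_dates(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    """A YYYYMMDD int inside each report's quarter (day 1–28)."""
    years = np.array([int(lb[:4]) for lb in labels])
    months = np.array([_QUARTER_START_MONTH[int(lb[5])] for lb in labels])
    months = months + rng.integers(0, 3, size=len(labels))
    days = rng.integers(1, 29, size=len(labels))
    return years * 10000 + months * 100 + days


def generate_frames(config: GeneratorConfig,
                    ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Draw the synthetic world as five typed table frames plus truth.

    The frames carry the same columns the quarterly readers produce (with
    age/weight already in years/kg) and include the planted duplicate
    versions; a ``quarter`` column on ``demo`` supports per-quarter export.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    caseid_num = np.arange(1, n + 1)
    caseid = np.char.add("C", np.char.zfill(caseid_num.astype(str), 8))

    u = rng.random(n)
    in_cohort = u < config.cohort_fraction
    partial = (~in_cohort) & (u < config.cohort_fraction
                              + config.partial_regimen_fraction)

    q_idx = np.sort(rng.choice(
        len(config.quarters), size=n,
        p=_growth_weights(len(config.quarters))))
    q_labels = np.array(config.quarters, dtype=object)[q_idx]
    fda_dt = _quarter_dates(rng, q_labels)

    sexes, sex_p = zip(*config.sex_distribution)
    sex = rng.choice(np.array(sexes, dtype=object), size=n, p=np.array(sex_p))
    age = rng.normal(config.age_mean, config.age_sd, size=n).clip(0.5, 110)
    age[rng.random(n) < config.age_missing] = np.nan
    weight = rng.normal(config.weight_mean, config.weight_sd,
                        size=n).clip(30, 200)
    weight[rng.random(n) < config.weight_missing] = np.nan
    countries, country_p = zip(*config.country_distribution)
    country = rng.choice(np.array(countries, dtype=object), size=n,
                         p=np.array(country_p))

    # outcome codes (at most one per report; remainder -> no OUTC row)
    codes, code_p = zip(*config.serious_outcome_distribution)
    code_p = np.array(code_p)
    none_p = 1.0 - code_p.sum()
    outcome = rng.choice(np.array(codes + ("",), dtype=object), size=n,
                         p=np.append(code_p, none_p))
    serious = np.isin(outcome, ("DE", "LT", "HO", "DS"))

    # reactions: Bernoulli per (report, PT); injected PTs use p1 in cohort
    rho_by_pt = dict(config.injected_signals)
    probabilities: dict[str, tuple[float, float]] = {}
    tallies: dict[str, tuple[int, int]] = {}
    reac_case: list[np.ndarray] = []
    reac_pt: list[np.ndarray] = []
    for pt, p0 in config.pt_catalog:
        p1 = injected_probability(p0, rho_by_pt.get(pt, 1.0))
        probabilities[pt] = (p0, p1)
        p_vec = np.where(in_cohort, p1, p0)
        hit = rng.random(n) < p_vec
        tallies[pt] = (int((hit & in_cohort).sum()),
                       int((hit & ~in_cohort).sum()))
        reac_case.append(caseid[hit])
        reac_pt.append(np.full(int(hit.sum()), pt, dtype=object))

    demo = pd.DataFrame({
        "primaryid": np.char.add(caseid.astype(str), "1"),
        "caseid": caseid,
        "caseversion": 1,
        "fda_dt": fda_dt,
        "sex": sex,
        "age_years": age,
        "weight_kg": weight,
        "country": country,
        "report_year": fda_dt // 10000,
        "quarter": q_labels,
    })

    # drug rows
    drug_parts = []
    cohort_ids = caseid[in_cohort]
    for name, ai, role in _REGIMEN_ROWS:
        drug_parts.append(pd.DataFrame({
            "caseid": cohort_ids, "role_cod": role,
            "drugname": name, "prod_ai": ai}))
    partial_ids = caseid[partial]
    if len(partial_ids):
        # strict subsets: drop one or two regimen components
        n_keep = rng.integers(1, len(_REGIMEN_ROWS), size=len(partial_ids))
        for j, (name, ai, role) in enumerate(_REGIMEN_ROWS):
            mask = n_keep > j
            drug_parts.append(pd.DataFrame({
                "caseid": partial_ids[mask], "role_cod": role,
                "drugname": name, "prod_ai": ai}))
    other_ids = caseid[~in_cohort]
    bg = rng.choice(np.array(_BACKGROUND_DRUGS, dtype=object),
                    size=len(other_ids))
    drug_parts.append(pd.DataFrame({
        "caseid": other_ids, "role_cod": "PS", "drugname": bg,
        "prod_ai": bg}))
    drug = pd.concat(drug_parts, ignore_index=True)
    drug = drug.sort_values("caseid", kind="mergesort").reset_index(drop=True)
    drug["drug_seq"] = drug.groupby("caseid").cumcount() + 1

    reac = pd.DataFrame({
        "caseid": np.concatenate(reac_case) if reac_case else [],
        "pt": np.concatenate(reac_pt) if reac_pt else []})

    outc = pd.DataFrame({"caseid": caseid[outcome != ""],
                         "outc_cod": outcome[outcome != ""]})

    indi_pt = np.where(in_cohort, "Diffuse large B-cell lymphoma",
                       "Product used for unknown indication")
    indi = pd.DataFrame({"caseid": caseid, "indi_drug_seq": 1,
                         "indi_pt": indi_pt})

    # planted duplicate versions: same clinical content, earlier fda_dt,
    # lower caseversion, distinct primaryid
    n_dupes = int(round(config.duplicate_case_fraction * n))
    extras = None
    if n_dupes:
        dup_rows = rng.choice(n, size=n_dupes, replace=False)
        vdist = np.array(config.extra_version_distribution)
        vdist = vdist / vdist.sum()
        n_extra = rng.choice(np.arange(1, len(vdist) + 1), size=n_dupes,
                             p=vdist)
        base = demo.iloc[dup_rows]
        extras = base.loc[base.index.repeat(n_extra)].copy()
        # per-extra version numbers 1..k, oldest first
        version = np.concatenate([np.arange(1, k + 1) for k in n_extra])
        back = np.repeat(n_extra, n_extra) - version + 1   # steps back
        date = pd.to_datetime(extras["fda_dt"].astype(str), format="%Y%m%d")
        early = date - pd.to_timedelta(30 * back, unit="D")
        extras["caseversion"] = version
        extras["primaryid"] = (extras["caseid"].to_numpy()
                               + version.astype(str).astype(object))
        extras["fda_dt"] = early.dt.strftime("%Y%m%d").astype(int).to_numpy()
        extras["report_year"] = extras["fda_dt"] // 10000
        # retained version must sort above its extras
        demo.loc[demo.index[dup_rows], "caseversion"] = n_extra + 1
        demo.loc[demo.index[dup_rows], "primaryid"] = (
            demo.loc[demo.index[dup_rows], "caseid"]
            + (n_extra + 1).astype(str))

    demo_truth = demo.copy()
    demo_truth["cohort"] = in_cohort
    demo_truth["serious"] = serious

    if extras is not None:
        demo = pd.concat([demo, extras], ignore_index=True)

    # child tables reference the retained primaryid; duplicate versions get
    # copies of the same clinical content under their own primaryid
    pid_of = pd.Series(demo_truth["primaryid"].to_numpy(),
                       index=demo_truth["caseid"].to_numpy())
    dup_pids = (extras[["caseid", "primaryid"]]
                .rename(columns={"primaryid": "dup_pid"})
                if extras is not None else None)

    def _attach_pids(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["primaryid"] = df["caseid"].map(pid_of)
        if dup_pids is not None:
            extra = df.merge(dup_pids, on="caseid")
            extra["primaryid"] = extra["dup_pid"]
            extra = extra.drop(columns="dup_pid")
            df = pd.concat([df, extra], ignore_index=True)
        return df.drop(columns="caseid")

    frames = {
        "demo": demo.reset_index(drop=True),
        "drug": _attach_pids(drug)[
            ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]],
        "reac": _attach_pids(reac)[["primaryid", "pt"]],
        "outc": _attach_pids(outc)[["primaryid", "outc_cod"]],
        "indi": _attach_pids(indi)[["primaryid", "indi_drug_seq",
                                    "indi_pt"]],
    }

    truth = GroundTruth(
        cohort_caseids=frozenset(caseid[in_cohort]),
        probabilities=probabilities,
        expected=expected_tables(config),
        tallies=tallies,
        demo_truth=demo_truth,
        n_cases=n,
        n_cohort=int(in_cohort.sum()),
        n_extra_versions=0 if extras is None else len(extras),
    )
    return frames, truth


def _growth_weights(k: int) -> np.ndarray:
    """Linearly increasing quarter weights (reporting grows over time)."""
    w = np.arange(1, k + 1, dtype=float)
    return w / w.sum()


def to_case_data(frames: dict[str, pd.DataFrame]) -> CaseData:
    """Deduplicate generated table frames into the analysis container."""
    demo = frames["demo"].drop(columns=["quarter"], errors="ignore")
    return CaseData.from_table_frames(demo, frames["drug"], frames["reac"],
                                      frames["outc"], frames["indi"])


def generate(config: GeneratorConfig,
             ) -> tuple[list[QuarterBundle], GroundTruth]:
    """Materialize the synthetic world as per-quarter record bundles."""
    frames, truth = generate_frames(config)
    demo = frames["demo"].copy()

    # duplicate versions may predate the retained quarter; assign each demo
    # row to the quarter containing its own fda_dt
    def _label_for(dt: int) -> str:
        y, m = dt // 10000, (dt // 100) % 100
        return f"{y}Q{(m - 1) // 3 + 1}"

    demo["quarter"] = [_label_for(int(d)) for d in demo["fda_dt"]]
    labels = sorted(set(demo["quarter"]))

    bundles = []
    for label in labels:
        d_rows = demo[demo["quarter"] == label]
        pids = set(d_rows["primaryid"])
        demo_records = [
            DemoRecord(primaryid=str(r.primaryid), caseid=str(r.caseid),
                       caseversion=int(r.caseversion), fda_dt=int(r.fda_dt),
                       age=(None if pd.isna(r.age_years)
                            else round(float(r.age_years), 1)),
                       age_cod="YR", sex=str(r.sex),
                       wt=(None if pd.isna(r.weight_kg)
                           else round(float(r.weight_kg), 1)),
                       wt_cod="KG", occr_country=str(r.country))
            for r in d_rows.itertuples(index=False)]
        drug_df = frames["drug"][frames["drug"]["primaryid"].isin(pids)]
        reac_df = frames["reac"][frames["reac"]["primaryid"].isin(pids)]
        outc_df = frames["outc"][frames["outc"]["primaryid"].isin(pids)]
        indi_df = frames["indi"][frames["indi"]["primaryid"].isin(pids)]
        bundles.append(QuarterBundle(
            demo=demo_records,
            drug=[DrugEntry(str(r.primaryid), int(r.drug_seq),
                            str(r.role_cod), str(r.drugname),
                            str(r.prod_ai))
                  for r in drug_df.itertuples(index=False)],
            reac=[ReactionEntry(str(r.primaryid), str(r.pt))
                  for r in reac_df.itertuples(index=False)],
            outc=[OutcomeEntry(str(r.primaryid), str(r.outc_cod))
                  for r in outc_df.itertuples(index=False)],
            indi=[IndicationEntry(str(r.primaryid), int(r.indi_drug_seq),
                                  str(r.indi_pt))
                  for r in indi_df.itertuples(index=False)],
            label=label))
    return bundles, truth
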