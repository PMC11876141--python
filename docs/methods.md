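# Methods

## Data model and cleaning

The unit of analysis is the deduplicated spontaneous report. FAERS-style
quarterly extracts arrive as five dollar-delimited tables keyed by
`primaryid`; several `primaryid`s may be versions of one `caseid`.
Cleaning follows standard pharmacovigilance practice:

- **Deduplication** keeps, per `caseid`, the version with the latest FDA
  acceptance date (`fda_dt`). Equal dates are broken toward the larger
  `primaryid` (the later database insertion); the source convention is
  not documented anywhere we know of, and any fixed rule suffices — what
  matters is that the choice is deterministic, so reruns and permuted
  inputs give identical cohorts.
- **Parsing is total**: every row becomes a typed record, a counted
  rejection with a reason (bad date, role code outside {PS, SS, C, I},
  outcome code outside the seven-code set, blank PT), or a counted orphan
  (child row whose `primaryid` is absent from DEMO). Record + rejection +
  orphan counts always equal the input row count. Silent drops would
  corrupt the denominators of every later statistic.
- **Seriousness**: a report is serious iff any outcome code is DE, LT, HO
  or DS. Congenital anomaly (CA) and required intervention (RI) are
  treated as non-serious by default — regulatory practice differs, so the
  code set is a parameter.
- **Ages** are normalized to years (DEC/YR/MON/WK/DY/HR); values outside
  [0, 120) become missing rather than rejecting the whole report.
  Missing age/weight are excluded pairwise from t-tests, never imputed.

## Cohort definition

A report joins the pola+BR cohort iff, for **each** of the three regimen
components, at least one drug entry with role PS or SS matches that
component's synonym set (case-insensitive exact match on drug name or
active ingredient — MedDRA-standardized names are a controlled
vocabulary, so no fuzzy matching; trade-name expansion is a user-supplied
synonym table). The all-of-three rule treats the combination as a single
entity; `min_components` relaxes it to any-k-of-n where a looser
definition is wanted. The comparator for disproportionality is every
other deduplicated report in the ingested window, not an active
comparator.

## Reporting odds ratio

For each PT with at least `min_count = 10` cohort reports (a report
contributes once however many times it lists the PT):

    ROR = (a·d) / (b·c)
    95% CI = exp( ln ROR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d) )

the Woolf (log-normal) interval — the standard form in ROR
pharmacovigilance and the only one consistent with a "CI lower bound > 1"
signal criterion. A signal requires ROR₀₂₅ > 1. Zero cells raise an error
under the default strict policy (the ≥ 10-report filter precludes a = 0;
a zero comparator cell is rare and usually means the window is too
narrow); the Haldane–Anscombe +0.5 correction is available as a flag and
is what the batch scan falls back to. PRR, EBGM and Bayesian shrinkage
methods are deliberately out of scope: this is a single-method pipeline.

## Clinical priority rubric

Each significant signal is scored 0–10 as the sum of five components:

| component | thresholds | points |
|---|---|---|
| case count | 10–49 / ≥ 50 | 1 / 2 |
| ROR₀₂₅ | < 2 / 2–5 (inclusive) / > 5 | 0 / 1 / 2 |
| fatal burden | ≥ 100 reports with outcome DE | 1 |
| medical-event lists | DME / IME (DME dominates) | 2 / 1 |
| evidence grade | ++ / + / − | 2 / 1 / 0 |

binned low (0–4), moderate (5–7), high (8–10). The published point sheet
for this rubric is not reproduced in the main text of the source
analysis; these thresholds were reconstructed from the 58 printed
(inputs → score) rows and reproduce all 58 exactly, including the
boundary cases that pin them down: ROR₀₂₅ = 2.00 scores 1, 4.90 scores 1,
5.40 scores 2, and the death/disease-progression rows require the
≥ 100-fatal-reports component. Every threshold lives in the `Rubric`
dataclass, so the official sheet can be swapped in if it surfaces.
Evidence grades are human literature appraisals and are always supplied
as annotations; an unannotated signal is reported as such, never
silently defaulted. The shipped DME/IME lists are seeds for testing and
the worked example — real analyses should load the full EMA lists.

## Severity comparison

Serious vs non-serious cohort reports are compared per PT on a 2×2 table
with Pearson's χ² **without** continuity correction, switching to
Fisher's exact test (two-sided, hypergeometric) when any expected cell
count is below 5; expected exactly 5 stays Pearson. The no-correction
choice is not arbitrary: the published statistics recompute to the
printed third decimal only without Yates' correction. Continuous
demographics use the Welch t-test by default (pooled-variance optional);
the published age/weight rows do not constrain this choice because the
per-group n behind them is unknown. All tests are two-sided, and no
multiplicity adjustment is applied across the per-PT tests, matching the
source analysis — interpret the per-PT p-values accordingly.

Two published χ² values are irreconcilable with their own printed counts
under any standard 2×2 formula (febrile neutropenia printed 33.710,
recomputed 17.515; pancytopenia printed 3.706, recomputed 20.587). They
are excluded from validation; the other 36 recomputable rows agree to the
printed precision.

## Cumulative sensitivity analysis

For each top-k signal (k largest cohort counts, ties lexicographic), the
2×2 table is rebuilt from all reports with `report_year ≤ T` for each
year T and the ROR/CI recomputed. Report year derives from `fda_dt`, the
same field the descriptive table stratifies on. Years where any cell is
zero are skipped and reported (early years often lack comparator events
for rare PTs), so a series starts at the first year with a complete
table. The final point reproduces the all-data signal exactly, which the
tests assert.

## Synthetic world

The generator emulates what the estimators rely on, with every parameter
in `GeneratorConfig`:

- **Associations on the odds scale.** A PT with background per-report
  probability p₀ and injected ROR ρ is drawn Bernoulli(p₁) in cohort
  reports with p₁ = ρp₀/(1 − p₀ + ρp₀), making ρ the exact estimand. The
  default world has 200,000 reports, a 1% cohort, 50 null PTs at
  p₀ = 0.01 and one injected signal at ρ = 5 — a cohort-to-database ratio
  and event sparsity of the same order as the real pola+BR analysis.
- **Duplicates** (5% of cases) get 1–2 extra earlier versions differing
  only in `primaryid`, `caseversion` and `fda_dt`, so deduplication
  correctness is checkable by identity of retained clinical content.
- **Partial-regimen decoys** (2%) carry strict subsets of the regimen as
  suspects and must stay out of the cohort.
- **Seriousness** is a per-report categorical draw (≈ 27% serious),
  independent of every PT, so the severity module's null calibration is
  testable. Demographics mirror the published cohort's marginals (sex
  31/44/25 F/M/unknown, age ≈ N(60, 14²) with 50% missing, weight
  ≈ N(74, 15²), country mix, linearly growing quarterly volume).

What it does **not** emulate — and what passing tests therefore do not
certify about real data: drug-name misspellings and free-text noise,
correlated PT co-occurrence, reporting biases that vary jointly with
seriousness and drug, true incidence (spontaneous data never yields
incidence), or duplicate reports with *divergent* clinical content that
only probabilistic record linkage would catch.

Validation at the default conditions (100 seeds): the 95% CI covers the
injected ρ = 5 within ±4 points of nominal, the signal criterion fires on
≤ 5% of null PTs (+ Monte-Carlo error), and mean log-ROR bias is below
0.05. The cumulative-trend property uses 50 seeds of a 50,000-report,
five-year world — large enough that yearly tables are complete from 2020
on while keeping the whole suite in a few CPU-minutes; the worked example
in `analysis/` uses 20,000 reports with a 5% cohort so that null PTs
clear the ≥ 10-report filter and the false-positive behaviour is visible.

## Numerical and design notes

- χ², Fisher and t-tests are delegated to scipy; the test suite
  cross-checks Fisher against an exact rational-arithmetic enumeration
  oracle (agreement to 1e-10 for N ≤ 60) and χ² against the closed-form
  2×2 formula. The ROR/Woolf computation is implemented here and checked
  against an independent hand evaluation.
- Record dataclasses are the public API; all heavy operations run on a
  columnar pandas container (`CaseData`) behind the same functions, which
  is what makes the 100-seed × 200,000-report validation study cheap.
  Both paths are tested for equality.
- Percentages in the descriptive table are computed per block and sum to
  100 up to rounding; the per-block "Others" rows keep country/indication
  tables bounded.
- Determinism: one `numpy` Generator seeded from `GeneratorConfig.seed`
  drives all sampling; equal seeds give byte-identical quarterly files.

## Limitations

Spontaneous-report caveats apply throughout: no denominators, reporting
bias, confounding by indication; a "signal" is a disproportionality
flag, not causation. The cohort rule cannot distinguish which component
of the combination drives a signal. The PT→SOC map ships only the terms
needed for the examples; real analyses need a licensed MedDRA
distribution. Database-level published figures (total reports, cohort
size, signal RORs) are not reproducible without the real FAERS download
and are therefore validated only behaviourally, on synthetic data.
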