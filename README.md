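# polabr

Pharmacovigilance signal detection for the **pola+BR** regimen
(polatuzumab vedotin + bendamustine + rituximab), built as a reusable,
tested pipeline over FAERS-style spontaneous-report data.

Polatuzumab-based combinations are second-line therapy for relapsed or
refractory diffuse large B-cell lymphoma. Post-marketing safety assessment
of such a regimen relies on spontaneous-report databases such as the FDA
Adverse Event Reporting System (FAERS), which distributes quarterly
dollar-delimited tables (DEMO, DRUG, REAC, OUTC, INDI). This package
implements the full analysis chain a pharmacovigilance team runs over
those tables — for epidemiologists, clinical pharmacists and method
developers who want each step scriptable and testable:

1. **Ingestion & deduplication** — parse the five quarterly tables, keep
   one version per case (latest FDA acceptance date, ties to the larger
   `primaryid`), and drop orphan child rows with full row accounting.
2. **Cohort construction** — reports listing *all* regimen components as
   primary/secondary suspects, with descriptive characteristics.
3. **Disproportionality analysis** — per Preferred Term (PT) 2×2 table

   |            | with PT | without PT |
   |------------|---------|------------|
   | cohort     | a       | b          |
   | all others | c       | d          |

   with the reporting odds ratio ROR = (a·d)/(b·c) and the Woolf 95% CI
   `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`. A **signal** needs
   ≥ 10 cohort reports and a CI lower bound (ROR₀₂₅) above 1.
4. **Clinical prioritization** — a semi-quantitative 0–10 score over five
   components (report count, ROR₀₂₅, fatal-report burden, DME/IME
   membership, evidence appraisal), binned low (0–4) / moderate (5–7) /
   high (8–10).
5. **Severity comparison** — serious vs non-serious reports per PT
   (uncorrected Pearson χ², or Fisher's exact test when an expected cell
   count falls below 5) and Welch t-tests for age and weight.
6. **Sensitivity analysis** — cumulative-by-year ROR series for the top
   signals; robust signals show narrowing CIs as reports accumulate.
7. **Synthetic FAERS generator** — a reporting world with known ground
   truth, where a PT with background probability p₀ is injected into the
   cohort at `p₁ = ρp₀ / (1 − p₀ + ρp₀)` so the true reporting odds ratio
   is exactly ρ. Every stage of the pipeline is validated against it.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (20,000 reports, a 5% regimen cohort, Pancytopenia injected at true
ROR 5, 5% duplicated case versions):

```sh
cd analysis
python 01_simulate.py && python 02_ingest_dedup.py && python 03_signals.py
python 04_priority.py && python 05_severity.py && python 06_trend.py
```

which prints, among other things:

```
deduplicated reports: 20000 (duplicate versions removed: 1197)
cohort reports: 1018 of 20000
PTs with >= 10 cohort reports: 29; significant signals: 2
  Pancytopenia: n=41 ROR=3.86 (2.75-5.44)
  Background reaction 25: n=17 ROR=1.74 (1.06-2.88)
scored 58 signals: low=30, moderate=27, high=1
high priority: Pancytopenia
Pancytopenia: ROR 7.69 (1.51-39.19) in 2019 -> 3.86 (2.75-5.44) in 2023
```

Deduplication removed exactly the 1,197 planted duplicate versions. The
scan retains 29 PTs with ≥ 10 cohort reports and flags the injected
association (its CI covers the true ρ = 5) plus one of 28 null background
PTs — a false-positive rate consistent with the 95% interval criterion.
Applying the default rubric to the 58 published pola+BR signals
reproduces the published 30/27/1 low/moderate/high split, with
pancytopenia the single high-priority signal (score 8). The cumulative
series shows the planted signal's CI narrowing from (1.51–39.19) to
(2.75–5.44) as five years of reports accumulate. Tables land in
`results/`.

The same pipeline runs from a shell against any directory of quarterly
files via the `polabr` CLI (`polabr simulate`, `polabr all --config
config.yaml`, …).

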