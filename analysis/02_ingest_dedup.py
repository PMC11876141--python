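"""Ingest the simulated quarters, deduplicate case versions and profile the
pola+BR cohort.

Deduplication keeps the version with the latest FDA acceptance date per
caseid; the cohort requires all three regimen components as primary or
secondary suspects.  Writes the descriptive characteristics table
(sex, age bins, country, indication, seriousness, report year) to
results/characteristics.csv.
"""

from _common import load_cohort, results_path

from polabr.case_dedup import demographics_summary

cohort, data = load_cohort()
print(f"deduplicated reports: {data.n_cases} "
      f"(duplicate versions removed: {data.n_duplicates_removed})")
print(f"cohort reports: {cohort.n_cohort} of {cohort.n_total_db}")

table = demographics_summary(cohort)
table.to_csv(results_path("characteristics.csv"), index=False)

serious = table[(table["block"] == "Outcomes")
                & (table["category"] == "Serious outcome")]
print(f"serious outcomes: {int(serious['n'].iloc[0])} "
      f"({float(serious['pct'].iloc[0])}% of the cohort)")
print("wrote results/characteristics.csv")
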