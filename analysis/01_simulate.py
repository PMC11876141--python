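"""Simulate a FAERS-style reporting world with one planted signal.

Writes quarterly DEMO/DRUG/REAC/OUTC/INDI ASCII files (2019Q1–2023Q3) to
scratch/synthetic_faers/ and records the planted truth so later drivers can
be judged against it: 20,000 reports, a 5% pola+BR cohort, 50 null
background PTs at p0 = 0.01, Pancytopenia injected at true ROR 5, 5%
duplicated case versions.
"""

import json
import os

from polabr.faers_tables import write_quarter
from polabr.synthetic_faers import GeneratorConfig, generate

from _common import COHORT_FRACTION, DATA_DIR, N_REPORTS, SEED, results_path

config = GeneratorConfig(n_reports=N_REPORTS,
                         cohort_fraction=COHORT_FRACTION, seed=SEED)
bundles, truth = generate(config)
os.makedirs(DATA_DIR, exist_ok=True)
for bundle in bundles:
    write_quarter(bundle, DATA_DIR)

summary = {
    "n_reports": truth.n_cases,
    "n_cohort": truth.n_cohort,
    "n_planted_duplicate_versions": truth.n_extra_versions,
    "injected": {pt: {"p0": p0, "p1": round(p1, 5)}
                 for pt, (p0, p1) in truth.probabilities.items()
                 if p1 != p0},
    "quarters": len(bundles),
}
with open(results_path("simulation_truth.json"), "w") as fh:
    json.dump(summary, fh, indent=1)

print(f"wrote {len(bundles)} quarters to {DATA_DIR}")
print(f"{truth.n_cases} unique reports, {truth.n_cohort} in the pola+BR "
      f"cohort, {truth.n_extra_versions} duplicate versions planted")
print("injected:", summary["injected"])
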