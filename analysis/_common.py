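"""Shared paths and loaders for the numbered analysis drivers."""

import os

from polabr.case_dedup import CaseData, build_cohort
from polabr.faers_tables import read_quarter
from polabr.pipeline import discover_quarters

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
DATA_DIR = os.path.join(ROOT, "scratch", "synthetic_faers")
RESULTS = os.path.join(ROOT, "results")

#: synthetic study conditions used throughout the drivers: 20,000 reports,
#: 5% regimen cohort, one injected signal (Pancytopenia) at true ROR 5
N_REPORTS = 20_000
COHORT_FRACTION = 0.05
SEED = 20190101 % (2**31)


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def load_cohort():
    """Read the simulated quarterly files, deduplicate, build the cohort."""
    labels = discover_quarters(DATA_DIR)
    if not labels:
        raise SystemExit(
            f"no quarterly files under {DATA_DIR}; run 01_simulate.py first")
    bundles = [read_quarter(DATA_DIR, label) for label in labels]
    data = CaseData.from_bundles(bundles)
    return build_cohort(data), data
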