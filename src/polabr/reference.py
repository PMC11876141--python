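"""Published pola+BR signal tables, shipped as validation inputs.

These loaders expose the printed results of the published pola+BR FAERS
analysis — the per-signal priority inputs (report count, ROR CI lower
bound, fatal reports, DME/IME flag, evidence grade), the serious /
non-serious event counts, the PT → SOC assignments, and the seed DME/IME
lists.  They are *inputs* for validation and the worked example: the
package recomputes statistics from them and compares against the printed
values; nothing here feeds back into the estimators.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "SERIOUS_TOTAL",
    "NONSERIOUS_TOTAL",
    "SEX_BY_SERIOUSNESS",
    "load_priority_inputs",
    "load_severity_counts",
    "priority_annotations",
]

#: Cohort seriousness strata of the published analysis (1,597 reports).
SERIOUS_TOTAL = 474
NONSERIOUS_TOTAL = 1123

#: Published sex × seriousness counts: (male, female) per stratum.
SEX_BY_SERIOUSNESS = {"serious": (225, 129), "nonserious": (473, 367)}


def _data(name: str):
    return resources.files("polabr.data") / name


def load_priority_inputs() -> pd.DataFrame:
    """The 58 published signals with their priority-rubric inputs.

    Columns: soc, pt, n, ror025, deaths, medical_event (DME/IME/NA),
    evidence (``++``/``+``/``-``).
    """
    with resources.as_file(_data("pola_br_priority_inputs.csv")) as path:
        df = pd.read_csv(path, keep_default_na=False)
    df["n"] = df["n"].astype(int)
    df["deaths"] = df["deaths"].astype(int)
    df["ror025"] = df["ror025"].astype(float)
    return df


def load_severity_counts() -> pd.DataFrame:
    """Published per-PT serious / non-serious report counts.

    Columns: pt, n_serious, n_nonserious, printed_test, printed_statistic
    (blank where the source prints none).
    """
    with resources.as_file(_data("pola_br_severity_counts.csv")) as path:
        df = pd.read_csv(path, keep_default_na=False)
    df["n_serious"] = df["n_serious"].astype(int)
    df["n_nonserious"] = df["n_nonserious"].astype(int)
    df["printed_statistic"] = pd.to_numeric(df["printed_statistic"],
                                            errors="coerce")
    return df


def priority_annotations() -> pd.DataFrame:
    """The published inputs reshaped as a ``pt, evidence, ime, dme``
    annotation frame consumable by :func:`polabr.clinical_priority.score_table`."""
    df = load_priority_inputs()
    return pd.DataFrame({
        "pt": df["pt"],
        "evidence": df["evidence"],
        "ime": df["medical_event"] == "IME",
        "dme": df["medical_event"] == "DME",
    })
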