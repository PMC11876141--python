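"""Semi-quantitative priority rubric against the published signal table."""

import pytest

from polabr.clinical_priority import (DEFAULT_RUBRIC, PriorityInputs,
                                      Rubric, priority_score, score_table)
from polabr.reference import load_priority_inputs, priority_annotations
from polabr.signal_ror import SignalResult

# (score, level) printed for all 58 published pola+BR signals
PUBLISHED = {
    "Neutropenia": (7, "moderate"), "Pancytopenia": (8, "high"),
    "Thrombocytopenia": (6, "moderate"), "Anaemia": (5, "moderate"),
    "Febrile neutropenia": (7, "moderate"), "Cytopenia": (5, "moderate"),
    "Blood disorder": (5, "moderate"), "Leukopenia": (4, "low"),
    "Haematotoxicity": (5, "moderate"), "Myelosuppression": (5, "moderate"),
    "Intestinal obstruction": (4, "low"),
    "Disease progression": (5, "moderate"), "Death": (4, "low"),
    "Pyrexia": (3, "low"), "Ill-defined disorder": (2, "low"),
    "General physical health deterioration": (3, "low"),
    "Mucosal inflammation": (4, "low"), "Oedema": (3, "low"),
    "Cytokine release syndrome": (5, "moderate"),
    "Immunosuppression": (5, "moderate"), "COVID-19": (4, "low"),
    "Sepsis": (5, "moderate"),
    "Cytomegalovirus infection reactivation": (5, "moderate"),
    "Infection": (4, "low"), "Septic shock": (6, "moderate"),
    "Urosepsis": (5, "moderate"), "Bacterial infection": (4, "low"),
    "Fungal infection": (3, "low"),
    "Cytomegalovirus infection": (5, "moderate"),
    "Neutropenic sepsis": (7, "moderate"),
    "Neutropenic infection": (7, "moderate"),
    "Candida infection": (3, "low"), "Bacteraemia": (5, "moderate"),
    "Tooth abscess": (5, "moderate"), "COVID-19 pneumonia": (5, "moderate"),
    "Candida pneumonia": (5, "moderate"), "Infected skin ulcer": (4, "low"),
    "Varicella zoster virus infection": (4, "low"),
    "Blood lactate dehydrogenase increased": (5, "moderate"),
    "C-reactive protein increased": (3, "low"),
    "Haemoglobin decreased": (3, "low"),
    "Aspartate aminotransferase increased": (4, "low"),
    "Blood bilirubin increased": (3, "low"),
    "Alanine aminotransferase increased": (4, "low"),
    "Glomerular filtration rate decreased": (4, "low"),
    "Inflammatory marker increased": (4, "low"),
    "Hypercalcaemia": (4, "low"), "Neuropathy peripheral": (5, "moderate"),
    "Confusional state": (2, "low"), "Neurotoxicity": (6, "moderate"),
    "Polyneuropathy": (5, "moderate"),
    "Immune effector cell-associated neurotoxicity syndrome": (5, "moderate"),
    "Epilepsy": (4, "low"), "Disturbance in attention": (2, "low"),
    "Renal failure": (4, "low"), "Respiratory failure": (3, "low"),
    "Deep vein thrombosis": (4, "low"), "Haemorrhage": (4, "low"),
}


def _published_inputs():
    rows = load_priority_inputs()
    return [PriorityInputs(pt=r.pt, n=int(r.n), ror025=float(r.ror025),
                           deaths=int(r.deaths),
                           ime_flag=r.medical_event == "IME",
                           dme_flag=r.medical_event == "DME",
                           evidence=r.evidence)
            for r in rows.itertuples(index=False)]


def test_all_58_published_rows_reproduce():
    inputs = _published_inputs()
    assert len(inputs) == 58
    for inp in inputs:
        result = priority_score(inp)
        assert (result.score, result.level) == PUBLISHED[inp.pt], inp.pt
        assert result.score == sum(result.components.values())


def test_level_counts_30_27_1():
    results, counts, unannotated = score_table(_published_inputs())
    assert counts == {"low": 30, "moderate": 27, "high": 1}
    assert not unannotated
    assert sum(counts.values()) == len(results) == 58


def test_pancytopenia_high_priority():
    result = priority_score(PriorityInputs(
        pt="Pancytopenia", n=54, ror025=11.12, deaths=17, dme_flag=True,
        evidence="++"))
    assert result.score == 8 and result.level == "high"


def test_neutropenia_moderate():
    result = priority_score(PriorityInputs(
        pt="Neutropenia", n=102, ror025=7.19, deaths=20, ime_flag=True,
        evidence="++"))
    assert result.score == 7 and result.level == "moderate"


def test_minimum_rubric_case():
    result = priority_score(PriorityInputs(pt="x", n=10, ror025=1.01,
                                           deaths=0, evidence="-"))
    assert result.score == 1 and result.level == "low"


@pytest.mark.parametrize("ror025,points", [
    (1.99, 0), (2.00, 1), (4.90, 1), (5.00, 1), (5.40, 2),
])
def test_ror025_boundaries(ror025, points):
    result = priority_score(PriorityInputs(pt="x", n=10, ror025=ror025,
                                           deaths=0, evidence="-"))
    assert result.components["ror025"] == points


@pytest.mark.parametrize("deaths,points", [(99, 0), (100, 1), (120, 1)])
def test_fatal_burden_threshold(deaths, points):
    result = priority_score(PriorityInputs(pt="x", n=200, ror025=1.0,
                                           deaths=deaths, evidence="-"))
    assert result.components["deaths"] == points


def test_dme_dominates_ime():
    both = priority_score(PriorityInputs(pt="x", n=10, ror025=1.0, deaths=0,
                                         ime_flag=True, dme_flag=True,
                                         evidence="-"))
    assert both.components["medical_event"] == 2


def test_score_monotone_in_each_factor():
    base = PriorityInputs(pt="x", n=200, ror025=3.0, deaths=0,
                          ime_flag=False, dme_flag=False, evidence="+")
    s0 = priority_score(base).score
    for kw in (dict(n=600), dict(ror025=6.0), dict(deaths=150),
               dict(ime_flag=True), dict(dme_flag=True),
               dict(evidence="++")):
        bumped = PriorityInputs(**{**base.__dict__, **kw})
        assert priority_score(bumped).score >= s0


def test_below_signal_threshold_rejected():
    with pytest.raises(ValueError, match="significant signals"):
        priority_score(PriorityInputs(pt="x", n=9, ror025=2.0, deaths=0,
                                      evidence="-"))


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        PriorityInputs(pt="x", n=10, ror025=2.0, deaths=11, evidence="-")
    with pytest.raises(ValueError):
        PriorityInputs(pt="x", n=10, ror025=2.0, deaths=0, evidence="?")


def test_unannotated_signals_listed_never_defaulted():
    signals = [SignalResult(pt="Pancytopenia", soc="", n=54, ror=14.59,
                            ror_lo=11.12, ror_hi=19.15, significant=True),
               SignalResult(pt="Mystery PT", soc="", n=12, ror=3.0,
                            ror_lo=1.5, ror_hi=6.0, significant=True)]
    ann = priority_annotations()
    results, counts, unannotated = score_table(
        signals, annotations=ann, death_counts={"Pancytopenia": 17})
    assert unannotated == ["Mystery PT"]
    assert [r.pt for r in results] == ["Pancytopenia"]
    assert results[0].score == 8


def test_empty_signal_list():
    results, counts, unannotated = score_table([])
    assert results == [] and sum(counts.values()) == 0


def test_custom_rubric_swappable():
    strict = Rubric(high_from=6)
    result = priority_score(PriorityInputs(
        pt="Septic shock", n=30, ror025=6.56, deaths=15, ime_flag=True,
        evidence="++"), rubric=strict)
    assert result.score == 6 and result.level == "high"
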