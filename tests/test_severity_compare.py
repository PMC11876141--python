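"""Severe vs non-severe tests against published statistics and exact
oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polabr.reference import (NONSERIOUS_TOTAL, SERIOUS_TOTAL,
                              SEX_BY_SERIOUSNESS, load_severity_counts)
from polabr.severity_compare import (SeverityTable, choose_test,
                                     fisher_exact, pearson_chi2, run_test,
                                     welch_t)


def chi2_oracle(a, b, c, d):
    """Closed-form uncorrected Pearson χ² for a 2×2 table."""
    n = a + b + c + d
    return (n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d)))


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by exhaustive enumeration with rational
    arithmetic: sum of P(table) over all tables with the observed margins
    whose probability does not exceed the observed table's."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x),
                         math.comb(n, c1)))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs:
            total += p
    return float(total)


def _pt_table(n_serious_with, n_nonserious_with):
    return SeverityTable(n_serious_with, SERIOUS_TOTAL - n_serious_with,
                         n_nonserious_with,
                         NONSERIOUS_TOTAL - n_nonserious_with)


# published statistics that recompute exactly from their printed counts
PUBLISHED_CHI2 = [
    ("Anaemia", 26, 26, 10.633),
    ("Thrombocytopenia", 26, 27, 9.861),
    ("Neutropenia", 37, 65, 2.270),
    ("Death", 109, 0, 277.160),
    ("COVID-19", 79, 79, 34.687),
    ("Sepsis", 32, 15, 34.220),
    ("Septic shock", 28, 2, 59.353),
    ("Cytokine release syndrome", 17, 3, 29.697),
    ("Blood lactate dehydrogenase increased", 48, 124, 0.291),
    ("Aspartate aminotransferase increased", 5, 17, 0.517),
    ("Cytopenia", 14, 17, 3.630),
    ("Neurotoxicity", 2, 15, 2.643),
]


@pytest.mark.parametrize("pt,a,c,printed", PUBLISHED_CHI2)
def test_published_chi2_reproduce_to_third_decimal(pt, a, c, printed):
    result = pearson_chi2(_pt_table(a, c))
    assert result.statistic == pytest.approx(printed, abs=5e-4)
    assert result.test_used == "pearson"


def test_sex_by_seriousness_chi2():
    male_s, female_s = SEX_BY_SERIOUSNESS["serious"]
    male_ns, female_ns = SEX_BY_SERIOUSNESS["nonserious"]
    result = pearson_chi2(SeverityTable(male_s, female_s, male_ns,
                                        female_ns))
    assert result.statistic == pytest.approx(5.39, abs=5e-3)
    assert result.p_value == pytest.approx(0.020, abs=5e-4)


def test_chi2_zero_when_independent():
    result = pearson_chi2(SeverityTable(10, 90, 20, 180))
    assert result.statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


@settings(deadline=None, max_examples=50)
@given(*(st.integers(1, 200) for _ in range(4)))
def test_chi2_equals_closed_form_and_symmetries(a, b, c, d):
    t = SeverityTable(a, b, c, d)
    got = pearson_chi2(t).statistic
    assert got == pytest.approx(chi2_oracle(a, b, c, d), rel=1e-12)
    # transposition and row/column exchanges leave χ² unchanged
    for other in (SeverityTable(a, c, b, d), SeverityTable(c, d, a, b),
                  SeverityTable(b, a, d, c)):
        assert pearson_chi2(other).statistic == pytest.approx(got, rel=1e-12)


def test_chi2_zero_margin_degenerate():
    with pytest.raises(ValueError):
        pearson_chi2(SeverityTable(0, 0, 5, 7))


def test_intestinal_obstruction_fisher():
    # all 16 events non-serious
    result = fisher_exact(SeverityTable(0, 474, 16, 1107))
    assert result.p_value < 0.01
    assert result.p_value == pytest.approx(0.005, abs=5e-4)


def test_fisher_empty_event_row():
    assert fisher_exact(SeverityTable(0, 30, 0, 70)).p_value == 1.0


@settings(deadline=None, max_examples=80)
@given(*(st.integers(0, 15) for _ in range(4)))
def test_fisher_matches_exhaustive_enumeration(a, b, c, d):
    got = fisher_exact(SeverityTable(a, b, c, d)).p_value
    assert got == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)


def test_fisher_pearson_agree_on_large_balanced_tables():
    t = SeverityTable(500, 4500, 540, 4460)
    pf = fisher_exact(t).p_value
    pp = pearson_chi2(t).p_value
    assert pf == pytest.approx(pp, rel=0.10)


def test_choose_test_expected_count_rule():
    # PT total 10 on the published strata: expected serious cell ~2.97
    assert choose_test(_pt_table(3, 7)) == "fisher"
    assert choose_test(_pt_table(26, 26)) == "pearson"
    # expected exactly 5.0 stays Pearson
    t = SeverityTable(5, 45, 5, 45)
    assert min(t.expected()) == 5.0
    assert choose_test(t) == "pearson"


def test_published_fisher_rows_have_small_totals():
    """Every published row printed without a χ² statistic triggers the
    expected-count rule."""
    counts = load_severity_counts()
    fisher_rows = counts[counts["printed_test"] == "fisher"]
    assert len(fisher_rows) > 10
    for r in fisher_rows.itertuples(index=False):
        assert choose_test(_pt_table(r.n_serious, r.n_nonserious)) == "fisher"


def welch_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist
    return t, 2 * tdist.sf(abs(t), df)


def test_welch_t_matches_textbook_formula():
    rng = np.random.default_rng(5)
    x = rng.normal(60, 14, size=40)
    y = rng.normal(58, 13, size=90)
    result = welch_t(x, y)
    t_ref, p_ref = welch_oracle(x, y)
    assert result.statistic == pytest.approx(t_ref, rel=1e-12)
    assert result.p_value == pytest.approx(p_ref, rel=1e-9)


def test_welch_identical_samples():
    result = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert result.statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_welch_drops_missing():
    x = [60.0, float("nan"), 62.0, 58.0]
    full = welch_t([60.0, 62.0, 58.0], [50.0, 55.0])
    with_nan = welch_t(x, [50.0, 55.0, float("nan")])
    assert with_nan.statistic == pytest.approx(full.statistic)


def test_welch_insufficient_data():
    with pytest.raises(ValueError):
        welch_t([1.0], [2.0, 3.0])


def test_run_test_dispatch():
    assert run_test(_pt_table(3, 7)).test_used == "fisher"
    assert run_test(_pt_table(26, 26)).test_used == "pearson"
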