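"""Statistical procedures against closed-form, enumeration and library oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2_contingency, fisher_exact

from amblyref import (
    McNemarMethod,
    cochran_q,
    fisher_exact_2x2,
    low_expected_rule,
    mcnemar,
    min_sample_size,
    pearson_chi2_2x2,
    percent_round,
    percent_str,
    two_by_two_test,
    welch_t_from_summary,
)


# -- Cochran's Q -------------------------------------------------------------


def test_cochran_q_hand_example():
    # rows (1,1,0),(1,0,0),(1,1,1),(0,0,0): column totals (3,2,1), T=6,
    # sum R_i^2 = 14, denominator 3*6-14 = 4, numerator 3*2*((1)^2+0+(1)^2).
    rows = [(1, 1, 0), (1, 0, 0), (1, 1, 1), (0, 0, 0)]
    res = cochran_q(rows)
    assert res.statistic == pytest.approx(3.0)
    assert res.df == 2


def test_cochran_q_degenerate_rows():
    res = cochran_q([[1, 1, 1, 1, 1, 1]] * 4)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_cochran_q_rejects_non_binary():
    with pytest.raises(ValueError):
        cochran_q([[0, 2], [1, 0]])


@given(st.integers(0, 2**31 - 1))
def test_cochran_k2_equals_uncorrected_mcnemar(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=(40, 2))
    b = int(((x[:, 0] == 1) & (x[:, 1] == 0)).sum())
    c = int(((x[:, 0] == 0) & (x[:, 1] == 1)).sum())
    expected = (b - c) ** 2 / (b + c) if b + c else 0.0
    assert cochran_q(x).statistic == pytest.approx(expected, abs=1e-10)


# -- McNemar -----------------------------------------------------------------


def _paired(b, c, both=0, neither=0):
    a = [True] * b + [False] * c + [True] * both + [False] * neither
    bb = [False] * b + [True] * c + [True] * both + [False] * neither
    return a, bb


def test_mcnemar_no_discordance():
    res = mcnemar(*_paired(0, 0, both=5, neither=5))
    assert res.p_value == 1.0


def test_mcnemar_exact_tail():
    res = mcnemar(*_paired(5, 0), McNemarMethod.EXACT)
    assert res.p_value == pytest.approx(0.0625)  # 2 * (1/2)^5


def test_mcnemar_symmetry():
    assert mcnemar(*_paired(3, 8)).p_value == mcnemar(*_paired(8, 3)).p_value


def test_mcnemar_auto_switches_at_25_discordant():
    assert mcnemar(*_paired(12, 12)).method == "mcnemar_exact"
    assert mcnemar(*_paired(13, 12)).method == "mcnemar_cc_chi2"


def test_mcnemar_cc_statistic():
    res = mcnemar(*_paired(20, 10), McNemarMethod.CC_CHI2)
    assert res.statistic == pytest.approx((abs(20 - 10) - 1) ** 2 / 30)


def test_mcnemar_length_mismatch():
    with pytest.raises(ValueError):
        mcnemar([True], [True, False])


# -- 2x2 tests ---------------------------------------------------------------


def test_chi2_closed_form_matches_scipy():
    ours = pearson_chi2_2x2(41, 73, 28, 166)
    ref = chi2_contingency([[41, 73], [28, 166]], correction=False)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue)
    assert ours.statistic == pytest.approx(19.15, abs=0.01)
    assert ours.p_value == pytest.approx(1.21e-5, rel=1e-2)


def test_chi2_independence_and_symmetry():
    assert pearson_chi2_2x2(10, 10, 10, 10).p_value == 1.0
    a = pearson_chi2_2x2(3, 9, 14, 6)
    b = pearson_chi2_2x2(14, 6, 3, 9)  # row swap
    c = pearson_chi2_2x2(6, 14, 9, 3)  # row+column swap
    assert a.statistic == pytest.approx(b.statistic) == pytest.approx(c.statistic)


def test_chi2_zero_margin_rejected():
    with pytest.raises(ValueError):
        pearson_chi2_2x2(0, 0, 5, 5)


def test_fisher_small_table_enumeration():
    assert fisher_exact_2x2(0, 5, 5, 0).p_value == pytest.approx(2 / 252)
    assert fisher_exact_2x2(1, 1, 1, 1).p_value == 1.0


@given(st.integers(0, 2**31 - 1))
def test_fisher_matches_scipy_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
    ours = fisher_exact_2x2(a, b, c, d).p_value
    ref = fisher_exact([[a, b], [c, d]]).pvalue
    assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)


def test_low_expected_rule_boundary():
    # expecteds (2, 8, 8, 32): exactly 25% of cells below 5 -> chi-square kept
    assert not low_expected_rule([[2, 8], [8, 32]])
    # expecteds (1, 9, 1, 9): 50% below 5 -> Fisher
    assert low_expected_rule([[1, 9], [1, 9]])
    # stratified referral table of the study: all expecteds >= 25.5
    assert not low_expected_rule([[41, 73], [28, 166]])


def test_two_by_two_dispatch():
    assert two_by_two_test(41, 73, 28, 166).method == "pearson_chi2"
    assert two_by_two_test(1, 9, 1, 9).method == "fisher_exact"


# -- t test, sample size, rounding -------------------------------------------


def test_welch_t_from_published_moments():
    res = welch_t_from_summary(0.82, 1.00, 114, 0.45, 0.67, 194)
    assert res.statistic == pytest.approx(3.514, abs=0.005)
    assert res.df == pytest.approx(173.4, abs=0.5)
    assert res.p_value == pytest.approx(5.6e-4, rel=0.02)
    assert res.p_value < 0.001


def test_welch_null_and_antisymmetry():
    assert welch_t_from_summary(1.0, 0.5, 10, 1.0, 0.7, 12).p_value == pytest.approx(1.0)
    a = welch_t_from_summary(1.2, 0.5, 10, 0.8, 0.7, 12)
    b = welch_t_from_summary(0.8, 0.7, 12, 1.2, 0.5, 10)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_pooled_t_variant():
    res = welch_t_from_summary(0.82, 1.00, 114, 0.45, 0.67, 194, pooled=True)
    assert res.df == 306 and res.p_value < 0.001


def test_welch_validation():
    with pytest.raises(ValueError):
        welch_t_from_summary(1, 0.5, 1, 0, 0.5, 10)
    with pytest.raises(ValueError):
        welch_t_from_summary(1, 0.0, 10, 0, 0.5, 10)


def test_min_sample_size_published_scenario():
    res = min_sample_size(0.17, 0.05, 0.95)
    assert res.n_raw == pytest.approx(216.8, abs=0.1)
    assert res.floor == 216 and res.ceil == 217


def test_min_sample_size_scaling():
    base = min_sample_size(0.5, 0.05, 0.95)
    assert base.n_raw == pytest.approx(384.1, abs=0.1)
    halved = min_sample_size(0.5, 0.025, 0.95)
    assert halved.n_raw == pytest.approx(4 * base.n_raw)


@pytest.mark.parametrize(
    "count, total, decimals, expected",
    [
        (129, 308, 1, 41.9),
        (41, 114, 0, 36.0),
        (69, 308, 0, 22.0),
        (1, 3, 1, 33.3),
        (1, 16, 1, 6.3),  # half-up, not banker's
        (0, 10, 1, 0.0),
    ],
)
def test_percent_round_half_up(count, total, decimals, expected):
    assert percent_round(count, total, decimals) == expected


def test_percent_str_and_validation():
    assert percent_str(93, 308, 1) == "30.2"
    with pytest.raises(ValueError):
        percent_round(1, 0)
    with pytest.raises(ValueError):
        percent_round(5, 3)
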