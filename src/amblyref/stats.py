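"""Paired-proportion and between-group statistics, from first principles.

The analysis compares referral rates produced by several rule sets on the
*same* children, so the omnibus test is Cochran's Q over the N x k binary
flag matrix, with pairwise McNemar tests as post hoc comparisons.  School
strata are compared with the Pearson chi-square on 2x2 count tables, falling
back to Fisher's exact test when more than 25% of expected cell counts are
below 5, and a Welch t test for continuous summaries.  Only distribution
tail functions are delegated to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Optional[float]
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df <= 0:
            raise ValueError("df must be positive where defined")


class McNemarMethod(str, Enum):
    AUTO = "auto"
    EXACT = "exact"
    CC_CHI2 = "cc_chi2"


def cochran_q(responses) -> TestResult:
    """Cochran's Q test over an N x k binary response matrix.

    ``Q = k(k-1) * sum_j (C_j - T/k)^2 / (k*T - sum_i R_i^2)`` with column
    totals ``C_j``, row totals ``R_i`` and grand total ``T``; ``df = k - 1``
    and the p-value comes from the chi-square upper tail.  When every row is
    constant the denominator vanishes and ``Q = 0, p = 1`` by convention.
    """
    x = np.asarray(responses)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an N x k matrix with k >= 2")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("responses must be binary")
    x = x.astype(float)
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    t = x.sum()
    denom = k * t - (row**2).sum()
    df = k - 1
    if denom <= 0:
        return TestResult(0.0, df, 1.0, "cochran_q")
    q = k * (k - 1) * ((col - t / k) ** 2).sum() / denom
    return TestResult(float(q), df, float(sps.chi2.sf(q, df)), "cochran_q")


def mcnemar(
    flags_a: Sequence[bool],
    flags_b: Sequence[bool],
    method: McNemarMethod = McNemarMethod.AUTO,
) -> TestResult:
    """McNemar test on two paired binary vectors.

    With discordant counts ``b`` (a-only) and ``c`` (b-only): the exact
    two-sided p-value is ``min(1, 2 P(X <= min(b, c)))`` for
    ``X ~ Binomial(b+c, 1/2)``; the continuity-corrected chi-square statistic
    is ``(|b-c| - 1)^2 / (b+c)`` on 1 df.  AUTO uses the exact form below 25
    discordant pairs.  ``b + c = 0`` gives ``p = 1``.
    """
    a = np.asarray(flags_a, dtype=bool)
    b_vec = np.asarray(flags_b, dtype=bool)
    if a.shape != b_vec.shape:
        raise ValueError("paired vectors must have equal length")
    b = int((a & ~b_vec).sum())
    c = int((~a & b_vec).sum())
    n_disc = b + c
    method = McNemarMethod(method)
    if method is McNemarMethod.AUTO:
        method = McNemarMethod.EXACT if n_disc < 25 else McNemarMethod.CC_CHI2
    if n_disc == 0:
        return TestResult(0.0, None, 1.0, f"mcnemar_{method.value}")
    if method is McNemarMethod.EXACT:
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n_disc, 0.5)))
        return TestResult(float(min(b, c)), None, p, "mcnemar_exact")
    stat = (abs(b - c) - 1) ** 2 / n_disc
    return TestResult(float(stat), 1.0, float(sps.chi2.sf(stat, 1)), "mcnemar_cc_chi2")


def pearson_chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> TestResult:
    """Pearson chi-square for a 2x2 table ``[[a, b], [c, d]]`` on 1 df.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; no continuity
    correction by default (Yates available via ``correction=True``).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or 0 in margins:
        raise ValueError("table has a zero margin")
    num = abs(a * d - b * c)
    if correction:
        num = max(0.0, num - n / 2)
    stat = n * num**2 / math.prod(margins)
    method = "pearson_chi2_yates" if correction else "pearson_chi2"
    return TestResult(float(stat), 1.0, float(sps.chi2.sf(stat, 1)), method)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher's exact test (two-sided) by full hypergeometric enumeration.

    Sums the probabilities of all tables sharing the observed margins whose
    probability does not exceed that of the observed table (within a 1e-7
    relative tolerance), using exact integer arithmetic.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")
    # P(table with top-left = k) proportional to C(r1, k) * C(r2, c1 - k).
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    observed = weights[a]
    cutoff = observed + observed * 1e-7
    p = sum(w for w in weights.values() if w <= cutoff) / total
    return TestResult(float(a), None, min(1.0, float(p)), "fisher_exact")


def expected_counts(table) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    n = x.sum()
    if n <= 0:
        raise ValueError("table total must be positive")
    return np.outer(x.sum(axis=1), x.sum(axis=0)) / n


def low_expected_rule(table) -> bool:
    """True iff strictly more than 25% of expected cell counts are below 5.

    This is the published switch from the chi-square test to Fisher's exact
    test for sparse tables.
    """
    exp = expected_counts(table)
    return (exp < 5).sum() > 0.25 * exp.size


def two_by_two_test(a: int, b: int, c: int, d: int) -> TestResult:
    """Chi-square with the Fisher fallback applied per :func:`low_expected_rule`."""
    if low_expected_rule([[a, b], [c, d]]):
        return fisher_exact_2x2(a, b, c, d)
    return pearson_chi2_2x2(a, b, c, d)


def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, pooled: bool = False
) -> TestResult:
    """Two-sided t test from group summary statistics.

    Welch's form by default: ``t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)`` with
    Welch-Satterthwaite degrees of freedom; ``pooled=True`` gives the classic
    equal-variance form.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if pooled:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
        method = "t_pooled"
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        method = "t_welch"
    t = (m1 - m2) / se
    return TestResult(float(t), float(df), float(2 * sps.t.sf(abs(t), df)), method)


@dataclass(frozen=True)
class SampleSize:
    n_raw: float
    floor: int
    ceil: int


def min_sample_size(p: float, e: float, conf: float = 0.95) -> SampleSize:
    """Single-proportion sample size ``n = z^2 p (1 - p) / e^2``.

    ``z`` is the two-sided normal quantile for confidence level ``conf``.
    Both the floor (the "at least n" phrasing) and the ceiling are reported
    alongside the raw value.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if e <= 0 or not (0 < conf < 1):
        raise ValueError("invalid margin or confidence level")
    z = float(sps.norm.ppf(1 - (1 - conf) / 2))
    n_raw = z**2 * p * (1 - p) / e**2
    return SampleSize(n_raw, math.floor(n_raw), math.ceil(n_raw))


def percent_round(count: int, total: int, decimals: int = 0) -> float:
    """``100 * count / total`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches how screening reports print
    rates; the division is done in decimal arithmetic so printed-precision
    comparisons are exact.
    """
    count, total = int(count), int(total)
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    quant = Decimal(1).scaleb(-decimals)
    value = (Decimal(count) * 100 / Decimal(total)).quantize(quant, rounding=ROUND_HALF_UP)
    return float(value)


def percent_str(count: int, total: int, decimals: int = 0) -> str:
    """Formatted percentage string at the requested precision."""
    return f"{percent_round(count, total, decimals):.{decimals}f}"


def bonferroni(p_values: Sequence[float]) -> list[float]:
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
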