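"""Pipeline orchestration: criteria comparison and school stratification.

``run_criteria_comparison`` applies every rule set to a cohort, tabulates
counts and rates, runs Cochran's Q per column (overall referral and the four
categories), and fills the pairwise McNemar post-hoc matrix.  Raw p-values
are always reported; an optional Bonferroni-adjusted matrix is available.

``run_school_stratification`` reproduces the public-vs-private comparison
under one reference criterion: per-stratum referral/category counts with the
chi-square test (Fisher's exact when the sparse-table rule fires), spectacle
wear among referred children, and a Welch t test on the per-child spherical
equivalents of the two strata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .criteria import (
    CATEGORIES,
    CriterionSpec,
    FlagsMatrix,
    apply_criteria,
    builtin_criteria,
    tabulate_rates,
)
from .refraction import (
    ChildRecord,
    DEFAULT_CONVENTION,
    MetricConvention,
    SchoolType,
)
from .stats import (
    McNemarMethod,
    TestResult,
    bonferroni,
    mcnemar,
    cochran_q,
    percent_round,
    two_by_two_test,
    welch_t_from_summary,
)

ALPHA = 0.05
_COLUMNS = ("referred",) + CATEGORIES


def _result_dict(r: TestResult) -> dict:
    return {
        "statistic": r.statistic,
        "df": r.df,
        "p_value": r.p_value,
        "method": r.method,
        "significant": bool(r.p_value < ALPHA),
    }


@dataclass
class ComparisonReport:
    n_children: int
    rates: pd.DataFrame  # per-criterion counts + half-up percentages
    cochran: dict[str, TestResult]  # per column
    mcnemar_p: dict[str, pd.DataFrame]  # per column, criteria x criteria
    mcnemar_method: dict[str, pd.DataFrame]
    mcnemar_p_bonferroni: Optional[dict[str, pd.DataFrame]] = None

    def to_dict(self) -> dict:
        out = {
            "n_children": self.n_children,
            "alpha": ALPHA,
            "rates": self.rates.to_dict(orient="index"),
            "cochran_q": {col: _result_dict(r) for col, r in self.cochran.items()},
            "mcnemar": {
                col: {
                    "p_values": frame.to_dict(orient="index"),
                    "methods": self.mcnemar_method[col].to_dict(orient="index"),
                }
                for col, frame in self.mcnemar_p.items()
            },
        }
        if self.mcnemar_p_bonferroni is not None:
            out["mcnemar_bonferroni"] = {
                col: frame.to_dict(orient="index")
                for col, frame in self.mcnemar_p_bonferroni.items()
            }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def run_criteria_comparison(
    cohort: Sequence[ChildRecord],
    criteria: Optional[Sequence[CriterionSpec]] = None,
    convention: MetricConvention = DEFAULT_CONVENTION,
    decimals: int = 1,
    method: McNemarMethod = McNemarMethod.AUTO,
    with_bonferroni: bool = False,
) -> ComparisonReport:
    """Rates per criterion with omnibus and pairwise paired-proportion tests."""
    criteria = list(criteria) if criteria is not None else builtin_criteria()
    matrix = apply_criteria(cohort, criteria, convention)
    names = matrix.criteria_names
    rates = tabulate_rates(matrix, decimals=decimals)
    cochran: dict[str, TestResult] = {}
    pair_p: dict[str, pd.DataFrame] = {}
    pair_m: dict[str, pd.DataFrame] = {}
    pair_b: dict[str, pd.DataFrame] = {}
    for col in _COLUMNS:
        table = matrix.table(col)
        cochran[col] = cochran_q(table.to_numpy().astype(int))
        p = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
        meth = pd.DataFrame("", index=names, columns=names, dtype=object)
        cells = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                res = mcnemar(table[a], table[b], method)
                p.loc[a, b] = p.loc[b, a] = res.p_value
                meth.loc[a, b] = meth.loc[b, a] = res.method
                cells.append((a, b, res.p_value))
        pair_p[col] = p
        pair_m[col] = meth
        if with_bonferroni:
            adj = bonferroni([pv for _, _, pv in cells])
            b_frame = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
            for (a, b, _), pv in zip(cells, adj):
                b_frame.loc[a, b] = b_frame.loc[b, a] = pv
            pair_b[col] = b_frame
    return ComparisonReport(
        n_children=matrix.n_children,
        rates=rates,
        cochran=cochran,
        mcnemar_p=pair_p,
        mcnemar_method=pair_m,
        mcnemar_p_bonferroni=pair_b if with_bonferroni else None,
    )


@dataclass
class StratifiedReport:
    criterion: str
    n: dict[str, int]  # all/public/private
    referred: dict[str, int]
    referred_pct: dict[str, float]
    referral_test: TestResult
    categories: dict[str, dict]  # per category: counts, pcts, test
    glasses: dict[str, int]
    glasses_referred: dict[str, int]
    glasses_referred_pct: dict[str, float]
    se_moments: dict[str, dict]  # per school: mean/sd/n over numeric children
    se_test: TestResult

    def to_dict(self) -> dict:
        out = {
            "criterion": self.criterion,
            "alpha": ALPHA,
            "n": self.n,
            "referred": self.referred,
            "referred_pct": self.referred_pct,
            "referral_test": _result_dict(self.referral_test),
            "categories": {
                cat: {**entry, "test": _result_dict(entry["test"])}
                for cat, entry in self.categories.items()
            },
            "glasses": self.glasses,
            "glasses_referred": self.glasses_referred,
            "glasses_referred_pct": self.glasses_referred_pct,
            "spherical_equivalent": self.se_moments,
            "se_test": _result_dict(self.se_test),
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def run_school_stratification(
    cohort: Sequence[ChildRecord],
    criterion: Optional[CriterionSpec] = None,
    convention: MetricConvention = DEFAULT_CONVENTION,
) -> StratifiedReport:
    """Public-vs-private comparison under one reference criterion."""
    if criterion is None:
        criterion = builtin_criteria()[0]  # AAPOS 2021
    groups = {
        school: [c for c in cohort if c.school_type is school] for school in SchoolType
    }
    if any(not members for members in groups.values()):
        missing = [s.value for s, m in groups.items() if not m]
        raise ValueError(f"cohort must contain both school strata; missing {missing}")

    matrix = apply_criteria(cohort, [criterion], convention)
    flags = {c.child_id: matrix.flags(c.child_id, criterion.name) for c in cohort}

    def count(members, pred) -> int:
        return sum(1 for c in members if pred(c))

    n = {s.value: len(groups[s]) for s in SchoolType}
    n["all"] = len(cohort)
    referred = {
        s.value: count(groups[s], lambda c: flags[c.child_id].referred) for s in SchoolType
    }
    referred["all"] = sum(referred[s.value] for s in SchoolType)
    referred_pct = {
        key: percent_round(referred[key], n[key], 0) for key in ("all", "public", "private")
    }
    pub, priv = groups[SchoolType.PUBLIC], groups[SchoolType.PRIVATE]
    referral_test = two_by_two_test(
        referred["public"],
        len(pub) - referred["public"],
        referred["private"],
        len(priv) - referred["private"],
    )

    categories = {}
    for cat in CATEGORIES:
        cnt = {
            s.value: count(groups[s], lambda c: flags[c.child_id].get(cat)) for s in SchoolType
        }
        cnt["all"] = cnt["public"] + cnt["private"]
        categories[cat] = {
            "counts": cnt,
            "pct": {k: percent_round(cnt[k], n[k], 0) for k in cnt},
            "test": two_by_two_test(
                cnt["public"],
                len(pub) - cnt["public"],
                cnt["private"],
                len(priv) - cnt["private"],
            ),
        }

    glasses = {s.value: count(groups[s], lambda c: c.wears_spectacles) for s in SchoolType}
    glasses["all"] = glasses["public"] + glasses["private"]
    glasses_ref = {
        s.value: count(
            groups[s], lambda c: c.wears_spectacles and flags[c.child_id].referred
        )
        for s in SchoolType
    }
    glasses_ref["all"] = glasses_ref["public"] + glasses_ref["private"]
    glasses_ref_pct = {
        key: percent_round(glasses_ref[key], referred[key], 1) if referred[key] else float("nan")
        for key in ("all", "public", "private")
    }

    moments = {}
    for s in SchoolType:
        ses = [
            (c.right_eye.se + c.left_eye.se) / 2
            for c in groups[s]
            if c.right_eye.is_numeric and c.left_eye.is_numeric
        ]
        arr = np.asarray(ses)
        moments[s.value] = {
            "n": len(ses),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
        }
    se_test = welch_t_from_summary(
        moments["public"]["mean"],
        moments["public"]["sd"],
        moments["public"]["n"],
        moments["private"]["mean"],
        moments["private"]["sd"],
        moments["private"]["n"],
    )
    return StratifiedReport(
        criterion=criterion.name,
        n=n,
        referred=referred,
        referred_pct=referred_pct,
        referral_test=referral_test,
        categories=categories,
        glasses=glasses,
        glasses_referred=glasses_ref,
        glasses_referred_pct=glasses_ref_pct,
        se_moments=moments,
        se_test=se_test,
    )
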