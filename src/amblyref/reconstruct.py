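"""Deterministic cohort reconstruction from published marginal counts.

The study deposited no per-child data, only count tables: for each of the six
referral rule sets the number of children flagged per refractive-error
category, the overall referral count, device code counts, and demographic
margins.  This module synthesizes a concrete cohort whose classification
under the built-in criteria reproduces every per-criterion category count
*exactly*, and the overall (union) referral counts as closely as an exact
integer program can achieve, providing an acceptance fixture without any
external data.

The construction exploits the nesting structure of the thresholds: for a
fixed category and age band the criteria sort into a *threshold chain*, and
the half-open interval between two adjacent thresholds (a *region*) is
flagged by a fixed set of criteria.  Choosing how many children fall in each
region fixes every criterion's category count; choosing which categories
co-occur in the same child fixes the union counts.  Both choices are made
jointly by a single integer program over physically realizable "child types"
(per-band combinations of region values that can be expressed as two in-range
sphere/cylinder readings without flagging any unintended category).  Category
and code counts are hard equality constraints; union counts are soft with
penalized slack, and residuals are always reported.

Joint per-child structure beyond these constraints is unidentifiable from the
published marginals; the fixture is one deterministic member of the
feasible set, not a recovery of the true cohort.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import Bounds, LinearConstraint, milp

from .criteria import (
    CATEGORIES,
    BandThresholds,
    CategoryFlags,
    CriterionSpec,
    apply_criteria,
    builtin_criteria,
    classify_child,
)
from .refraction import (
    EPS,
    AgeBand,
    ChildRecord,
    DEFAULT_CONVENTION,
    EyeReading,
    Grade,
    MetricConvention,
    ReadingStatus,
    SchoolType,
    Sex,
)


class ReconstructionError(RuntimeError):
    """Raised when the fixture cannot be built or fails verification."""


class InfeasibleTargetsError(ReconstructionError):
    """Raised when no integer allocation can reproduce the target counts."""


# ---------------------------------------------------------------------------
# Targets


@dataclass(frozen=True)
class ReconstructionTargets:
    """Published count tables driving the reconstruction."""

    cohort_size: int
    band_sizes: Mapping[AgeBand, int]
    codes: Mapping[str, int]  # hyp / myo / unreadable children
    reference_criterion: str
    category_counts: Mapping[str, Mapping[str, int]]
    union_counts: Mapping[str, int]
    school_sizes: Mapping[SchoolType, int]
    school_band_sizes: Mapping[SchoolType, Mapping[AgeBand, int]]
    referred_by_school: Mapping[SchoolType, int]
    glasses_referred: Mapping[SchoolType, int]
    referred_public_categories: Mapping[str, int]
    females: Mapping[SchoolType, int]
    grades: Mapping[SchoolType, Mapping[AgeBand, Sequence[tuple[Grade, int]]]]

    def __post_init__(self) -> None:
        if sum(self.band_sizes.values()) != self.cohort_size:
            raise ValueError("band sizes must sum to cohort size")
        for counts in self.category_counts.values():
            if any(v < 0 for v in counts.values()):
                raise ValueError("counts must be nonnegative")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ReconstructionTargets":
        schools = payload["schools"]
        return cls(
            cohort_size=int(payload["cohort_size"]),
            band_sizes={AgeBand(k): int(v) for k, v in payload["band_sizes"].items()},
            codes={k: int(v) for k, v in payload["codes"].items()},
            reference_criterion=payload["reference_criterion"],
            category_counts={
                name: {k: int(v) for k, v in cats.items()}
                for name, cats in payload["category_counts"].items()
            },
            union_counts={k: int(v) for k, v in payload["union_counts"].items()},
            school_sizes={SchoolType(k): int(v) for k, v in schools["sizes"].items()},
            school_band_sizes={
                SchoolType(s): {AgeBand(b): int(v) for b, v in bands.items()}
                for s, bands in schools["band_sizes"].items()
            },
            referred_by_school={SchoolType(k): int(v) for k, v in schools["referred"].items()},
            glasses_referred={
                SchoolType(k): int(v) for k, v in schools["glasses_referred"].items()
            },
            referred_public_categories={
                k: int(v) for k, v in schools["referred_public_categories"].items()
            },
            females={SchoolType(k): int(v) for k, v in schools["females"].items()},
            grades={
                SchoolType(s): {
                    AgeBand(b): [(Grade(g), int(n)) for g, n in quotas]
                    for b, quotas in bands.items()
                }
                for s, bands in schools["grades"].items()
            },
        )


def load_targets_yaml(path) -> ReconstructionTargets:
    with open(path, encoding="utf-8") as fh:
        return ReconstructionTargets.from_dict(yaml.safe_load(fh))


def default_targets() -> ReconstructionTargets:
    """The packaged count-table targets of the 308-child study."""
    ref = resources.files("amblyref.data").joinpath("reconstruction_targets.yaml")
    return ReconstructionTargets.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Threshold chains


def _threshold_magnitude(th: BandThresholds, category: str) -> float:
    value = th.threshold(category)
    return -value if category == "myopia" else value


@dataclass(frozen=True)
class Region:
    """Half-open magnitude interval ``[lower, upper)`` between thresholds."""

    lower: float
    upper: Optional[float]  # None for the unbounded top region
    active: frozenset[str]  # criteria flagging a value in this region
    rep: float  # representative magnitude used for materialization

    def contains(self, value: float) -> bool:
        return value >= self.lower - EPS and (self.upper is None or value < self.upper - EPS)


@dataclass(frozen=True)
class ThresholdChain:
    category: str
    band: AgeBand
    thresholds: tuple[float, ...]  # distinct magnitudes, strictly increasing
    regions: tuple[Region, ...]


def threshold_chain(
    criteria: Sequence[CriterionSpec], category: str, band: AgeBand
) -> ThresholdChain:
    """Sorted distinct thresholds of one category/band with active criteria.

    Thresholds are expressed as positive magnitudes (myopia thresholds by
    absolute value); criterion activity is monotone along the chain.  The
    representative value of each region is its lower edge, which for the
    built-in rule sets is always an exact quarter-diopter.
    """
    if not criteria:
        raise ValueError("need at least one criterion")
    mags = {c.name: _threshold_magnitude(c.bands[band], category) for c in criteria}
    thresholds = tuple(sorted(set(mags.values())))
    regions = []
    for i, lower in enumerate(thresholds):
        upper = thresholds[i + 1] if i + 1 < len(thresholds) else None
        active = frozenset(name for name, m in mags.items() if m <= lower + EPS)
        regions.append(Region(lower, upper, active, lower))
    return ThresholdChain(category, band, thresholds, tuple(regions))


# ---------------------------------------------------------------------------
# Per-category allocation (standalone marginal solver)


@dataclass(frozen=True)
class CategoryAllocation:
    """Integer child counts per (band, region) for one category."""

    category: str
    counts: Mapping[tuple[AgeBand, float], int]  # keyed by (band, region lower)
    code_count: int

    def band_region_count(self, band: AgeBand, lower: float) -> int:
        return self.counts.get((band, lower), 0)

    def region_totals(self) -> dict[float, int]:
        out: dict[float, int] = {}
        for (_, lower), n in self.counts.items():
            out[lower] = out.get(lower, 0) + n
        return out


def _check_monotone(
    criteria: Sequence[CriterionSpec], category: str, targets: Mapping[str, int]
) -> None:
    """Name a violated cumulative constraint if targets break nesting."""
    for x, y in itertools.permutations(criteria, 2):
        stricter_both = all(
            _threshold_magnitude(x.bands[b], category)
            >= _threshold_magnitude(y.bands[b], category) - EPS
            for b in AgeBand
        )
        if stricter_both and targets[x.name] > targets[y.name]:
            raise InfeasibleTargetsError(
                f"{category}: criterion {x.name!r} is at least as strict as {y.name!r} "
                f"in both age bands but has a larger target count "
                f"({targets[x.name]} > {targets[y.name]})"
            )


def solve_category_allocation(
    criteria: Sequence[CriterionSpec],
    category: str,
    targets: Mapping[str, int],
    band_sizes: Mapping[AgeBand, int],
    code_count: int = 0,
) -> CategoryAllocation:
    """Allocate children to chain regions so cumulative sums hit every target.

    Coded readings (HYP / MYO) flag their category under every criterion and
    occupy a dedicated bucket, so the numeric targets are the printed counts
    minus ``code_count``.  Where the two age bands decouple the criteria
    ordering (e.g. myopia) a small integer program finds the allocation;
    ties break toward the >= 4 band, then toward the smallest magnitudes.
    """
    _check_monotone(criteria, category, targets)
    numeric_targets = {name: targets[name] - code_count for name in targets}
    if any(v < 0 for v in numeric_targets.values()):
        raise InfeasibleTargetsError(
            f"{category}: code count {code_count} exceeds a criterion target"
        )
    variables: list[tuple[AgeBand, Region]] = []
    cost: list[float] = []
    for band in (AgeBand.GE4, AgeBand.UNDER4):
        chain = threshold_chain(criteria, category, band)
        for rank, region in enumerate(chain.regions):
            variables.append((band, region))
            cost.append(1000.0 * (band is AgeBand.UNDER4) + rank)
    names = [c.name for c in criteria]
    a_eq = np.zeros((len(names), len(variables)))
    rhs = np.array([numeric_targets[n] for n in names], dtype=float)
    for j, (band, region) in enumerate(variables):
        for i, name in enumerate(names):
            if name in region.active:
                a_eq[i, j] = 1.0
    res = milp(
        c=np.array(cost),
        constraints=[LinearConstraint(a_eq, rhs, rhs)],
        integrality=np.ones(len(variables)),
        bounds=Bounds(0, max(band_sizes.values())),
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleTargetsError(
            f"{category}: no nonnegative integer region allocation reproduces the "
            f"cumulative targets {dict(numeric_targets)}"
        )
    counts = {
        (band, region.lower): int(round(x))
        for (band, region), x in zip(variables, res.x)
        if round(x) > 0
    }
    return CategoryAllocation(category, counts, code_count)


# ---------------------------------------------------------------------------
# Child types: realizable per-band combinations of region values


@dataclass(frozen=True)
class ChildType:
    """A realizable child archetype: band, category values, concrete eyes."""

    band: AgeBand
    kind: str  # numeric | hyp_code | myo_code | unreadable
    values: tuple[Optional[float], ...]  # (hyperopia, myopia, astig, aniso)
    right: EyeReading
    left: EyeReading

    @property
    def sort_key(self):
        return (
            self.band.value,
            self.kind,
            tuple(-1.0 if v is None else v for v in self.values),
        )


def _probe_child(band: AgeBand, right: EyeReading, left: EyeReading) -> ChildRecord:
    return ChildRecord(
        child_id="probe",
        age_years=3.5 if band is AgeBand.UNDER4 else 5.0,
        school_type=SchoolType.PUBLIC,
        grade=Grade.KG2,
        sex=Sex.F,
        wears_spectacles=False,
        right_eye=right,
        left_eye=left,
    )


def _intended_flags(
    criteria: Sequence[CriterionSpec],
    band: AgeBand,
    h: Optional[float],
    m: Optional[float],
    a: Optional[float],
    d: Optional[float],
) -> dict[str, CategoryFlags]:
    out = {}
    for crit in criteria:
        th = crit.bands[band]
        out[crit.name] = CategoryFlags(
            hyperopia=h is not None and h >= th.hyperopia_ge - EPS,
            myopia=m is not None and m >= -th.myopia_le - EPS,
            astigmatism=a is not None and a >= th.astigmatism_ge - EPS,
            anisometropia=d is not None and d >= th.anisometropia_ge - EPS,
            unreadable=False,
        )
    return out


def _quarter(value: float) -> bool:
    return abs(value * 4 - round(value * 4)) < 1e-6


_SPHERE_GRID = [i / 4 for i in range(-16, 21)]  # -4.00 .. +5.00 D
_SMALL_CYL = (0.0, -0.25, -0.5, -0.75)


def _construct_eyes(
    h: Optional[float],
    m: Optional[float],
    a: Optional[float],
    d: Optional[float],
    band: AgeBand,
    criteria: Sequence[CriterionSpec],
    convention: MetricConvention,
    intended: dict[str, CategoryFlags],
) -> Optional[tuple[EyeReading, EyeReading]]:
    """Find two in-range readings realizing exactly the requested values.

    The child's most-plus meridian must equal ``h`` (else stay below every
    hyperopia threshold), its worst spherical equivalent ``-m`` (else above
    every myopia threshold), its largest cylinder magnitude ``a``, and its
    interocular SE difference ``d``.  The first candidate on a deterministic
    quarter-diopter scan whose classification matches the intended flags
    under every criterion is returned; ``None`` if no candidate exists.
    """
    c1_opts = (-a,) if a else (0.0,)
    c2_opts = ((-a,) + _SMALL_CYL) if a else _SMALL_CYL
    for c1 in c1_opts:
        for s1 in _SPHERE_GRID:
            se1 = s1 + c1 / 2
            se2_opts = (se1,) if d is None else (se1 - d, se1 + d)
            for se2 in se2_opts:
                for c2 in c2_opts:
                    s2 = se2 - c2 / 2
                    if not _quarter(s2) or not (-4.0 - EPS <= s2 <= 5.0 + EPS):
                        continue
                    most_plus = max(s1, s2)
                    se_min = min(se1, se2)
                    cyl_max = max(-c1, -c2)
                    aniso = abs(se1 - se2)
                    if h is not None:
                        if abs(most_plus - h) > EPS:
                            continue
                    elif most_plus > 1.0 + EPS:
                        continue
                    if m is not None:
                        if abs(se_min + m) > EPS:
                            continue
                    elif se_min < -0.75 - EPS:
                        continue
                    if a is not None:
                        if abs(cyl_max - a) > EPS:
                            continue
                    elif cyl_max > 0.75 + EPS:
                        continue
                    if d is not None:
                        if abs(aniso - d) > EPS:
                            continue
                    elif aniso > EPS:
                        continue
                    right = EyeReading.numeric(s1, c1, 180.0 if c1 else None)
                    left = EyeReading.numeric(s2, c2, 180.0 if c2 else None)
                    probe = _probe_child(band, right, left)
                    flags = {c.name: classify_child(probe, c, convention) for c in criteria}
                    if flags == intended:
                        return right, left
    return None


_TYPE_CACHE: dict[tuple, list["ChildType"]] = {}


def enumerate_child_types(
    criteria: Optional[Sequence[CriterionSpec]] = None,
    convention: MetricConvention = DEFAULT_CONVENTION,
) -> list[ChildType]:
    """All realizable child archetypes over the chain regions of both bands."""
    criteria = list(criteria) if criteria is not None else builtin_criteria()
    cache_key = (tuple(repr(c) for c in criteria), repr(convention))
    cached = _TYPE_CACHE.get(cache_key)
    if cached is not None:
        return list(cached)
    types: list[ChildType] = []
    for band in (AgeBand.UNDER4, AgeBand.GE4):
        reps = {
            cat: [None] + [r.rep for r in threshold_chain(criteria, cat, band).regions]
            for cat in CATEGORIES
        }
        for h, m, a, d in itertools.product(
            reps["hyperopia"], reps["myopia"], reps["astigmatism"], reps["anisometropia"]
        ):
            if h is None and m is None and a is None and d is None:
                continue
            intended = _intended_flags(criteria, band, h, m, a, d)
            eyes = _construct_eyes(h, m, a, d, band, criteria, convention, intended)
            if eyes is not None:
                types.append(ChildType(band, "numeric", (h, m, a, d), *eyes))
        for kind, status in (
            ("hyp_code", ReadingStatus.HYP),
            ("myo_code", ReadingStatus.MYO),
            ("unreadable", ReadingStatus.UNREADABLE),
        ):
            eye = EyeReading.coded(status)
            types.append(ChildType(band, kind, (None, None, None, None), eye, eye))
    types.sort(key=lambda t: t.sort_key)
    _TYPE_CACHE[cache_key] = list(types)
    return types


# ---------------------------------------------------------------------------
# Joint allocation + overlap plan


@dataclass
class FixturePlan:
    """Solved child-type counts plus achieved-vs-target bookkeeping."""

    assignments: list[tuple[ChildType, int]]
    flags: Mapping[ChildType, Mapping[str, CategoryFlags]]
    union_targets: Mapping[str, int]
    union_achieved: Mapping[str, int]

    @property
    def union_residuals(self) -> dict[str, int]:
        return {
            name: self.union_achieved[name] - self.union_targets[name]
            for name in self.union_targets
        }

    @property
    def n_children(self) -> int:
        return sum(n for _, n in self.assignments)


_SLACK_PENALTY = 1e7


def plan_overlaps(
    targets: ReconstructionTargets,
    criteria: Optional[Sequence[CriterionSpec]] = None,
    convention: MetricConvention = DEFAULT_CONVENTION,
    types: Optional[Sequence[ChildType]] = None,
) -> FixturePlan:
    """Jointly choose region placement and category co-occurrence.

    One integer program over all realizable child types: per-criterion
    category counts and device-code counts are equality constraints; union
    (overall referral) counts are equalities with penalized slack so that any
    shortfall is reported, never silently dropped; band totals are capped by
    the published band sizes.  The overlap structure (which categories share
    a child) is exactly what makes a criterion's union smaller than the sum
    of its category counts, so it is recovered here rather than invented.
    """
    criteria = list(criteria) if criteria is not None else builtin_criteria()
    names = [c.name for c in criteria]
    if types is None:
        types = enumerate_child_types(criteria, convention)
    types = list(types)
    flags = {
        t: {c.name: classify_child(_probe_child(t.band, t.right, t.left), c, convention) for c in criteria}
        for t in types
    }

    n_t = len(types)
    n_slack = 2 * len(names)  # (plus, minus) per criterion
    n_vars = n_t + n_slack

    cost = np.zeros(n_vars)
    for j, t in enumerate(types):
        magnitude = sum(v for v in t.values if v is not None)
        cost[j] = 1000.0 + 100.0 * (t.band is AgeBand.UNDER4) + magnitude
    cost[n_t:] = _SLACK_PENALTY

    rows: list[np.ndarray] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add_row(coeffs: np.ndarray, lb: float, ub: float) -> None:
        rows.append(coeffs)
        lbs.append(lb)
        ubs.append(ub)

    # 24 per-criterion category counts (hard).
    for name in names:
        for cat in CATEGORIES:
            row = np.zeros(n_vars)
            for j, t in enumerate(types):
                if flags[t][name].get(cat):
                    row[j] = 1.0
            target = float(targets.category_counts[name][cat])
            add_row(row, target, target)

    # Device code and unreadable counts (hard).
    for kind, key in (("hyp_code", "hyp"), ("myo_code", "myo"), ("unreadable", "unreadable")):
        row = np.zeros(n_vars)
        for j, t in enumerate(types):
            if t.kind == kind:
                row[j] = 1.0
        add_row(row, float(targets.codes[key]), float(targets.codes[key]))

    # Union counts (soft): achieved - plus + minus = target.
    for i, name in enumerate(names):
        row = np.zeros(n_vars)
        for j, t in enumerate(types):
            if flags[t][name].referred:
                row[j] = 1.0
        row[n_t + 2 * i] = -1.0  # plus slack (overshoot)
        row[n_t + 2 * i + 1] = 1.0  # minus slack (shortfall)
        target = float(targets.union_counts[name])
        add_row(row, target, target)

    # Band capacities.
    for band in (AgeBand.UNDER4, AgeBand.GE4):
        row = np.zeros(n_vars)
        for j, t in enumerate(types):
            if t.band is band:
                row[j] = 1.0
        add_row(row, 0.0, float(targets.band_sizes[band]))

    res = milp(
        c=cost,
        constraints=[LinearConstraint(np.vstack(rows), np.array(lbs), np.array(ubs))],
        integrality=np.ones(n_vars),
        bounds=Bounds(0, float(targets.cohort_size)),
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleTargetsError(
            "no child-type allocation satisfies the category/code count constraints"
        )
    x = np.round(res.x[:n_t]).astype(int)
    assignments = [(t, int(n)) for t, n in zip(types, x) if n > 0]
    achieved = {
        name: int(sum(n for t, n in assignments if flags[t][name].referred)) for name in names
    }
    return FixturePlan(assignments, flags, dict(targets.union_counts), achieved)


# ---------------------------------------------------------------------------
# Materialization


@dataclass
class ReconstructionReport:
    """Achieved vs target counts and the demographic assignment outcome."""

    category_counts: dict[str, dict[str, tuple[int, int]]]  # name -> cat -> (target, achieved)
    union_counts: dict[str, tuple[int, int]]  # name -> (target, achieved)
    code_counts: dict[str, tuple[int, int]]
    referred_by_school: dict[str, tuple[int, int]]
    glasses_referred: dict[str, tuple[int, int]]
    referred_public_categories: dict[str, tuple[int, int]]
    band_sizes: dict[str, tuple[int, int]]
    feasible: bool

    @property
    def union_residuals(self) -> dict[str, int]:
        return {name: ach - tgt for name, (tgt, ach) in self.union_counts.items()}

    @property
    def category_exact(self) -> bool:
        return all(
            tgt == ach for cats in self.category_counts.values() for tgt, ach in cats.values()
        )

    def to_dict(self) -> dict:
        def pairs(d):
            return {k: {"target": t, "achieved": a} for k, (t, a) in d.items()}

        return {
            "feasible": self.feasible,
            "category_counts": {n: pairs(c) for n, c in self.category_counts.items()},
            "union_counts": pairs(self.union_counts),
            "union_residuals": self.union_residuals,
            "code_counts": pairs(self.code_counts),
            "referred_by_school": pairs(self.referred_by_school),
            "glasses_referred": pairs(self.glasses_referred),
            "referred_public_categories": pairs(self.referred_public_categories),
            "band_sizes": pairs(self.band_sizes),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


_FILLER_EYE = EyeReading.numeric(0.5, 0.0)


def materialize_fixture(
    plan: FixturePlan,
    targets: ReconstructionTargets,
    criteria: Optional[Sequence[CriterionSpec]] = None,
    convention: MetricConvention = DEFAULT_CONVENTION,
) -> tuple[list[ChildRecord], ReconstructionReport]:
    """Expand a solved plan into concrete child records and verify them.

    Demographics are filled deterministically against the published margins:
    school assignment reproduces the referred-by-school split of the
    reference criterion exactly (with a greedy affinity pass toward the
    stratified per-category counts, which are best-effort), spectacle wear is
    placed among referred children per stratum, and grade/sex quotas are
    filled in band order.  The finished cohort is re-classified and the
    category counts asserted against the targets: a mismatch is a hard error
    because the fixture is the acceptance surface.
    """
    criteria = list(criteria) if criteria is not None else builtin_criteria()
    ref = targets.reference_criterion

    # Expand plan children (deterministic plan order), then per-band fillers.
    specs: list[dict] = []
    for t, n in plan.assignments:
        for _ in range(n):
            specs.append(
                {
                    "band": t.band,
                    "right": t.right,
                    "left": t.left,
                    "ref_flags": plan.flags[t][ref],
                }
            )
    no_flags = CategoryFlags(False, False, False, False, False)
    for band in (AgeBand.UNDER4, AgeBand.GE4):
        n_band = sum(1 for s in specs if s["band"] is band)
        fill = targets.band_sizes[band] - n_band
        if fill < 0:
            raise ReconstructionError(
                f"plan places {n_band} referred children in band {band.value}, "
                f"exceeding the band size {targets.band_sizes[band]}"
            )
        for _ in range(fill):
            specs.append(
                {"band": band, "right": _FILLER_EYE, "left": _FILLER_EYE, "ref_flags": no_flags}
            )

    # School assignment.  Referred children are ranked by affinity for the
    # public stratum (stratified category counts) and assigned until the
    # public referred quota is filled, respecting school x band capacities.
    capacity = {
        (school, band): targets.school_band_sizes[school][band]
        for school in SchoolType
        for band in AgeBand
    }
    referred_idx = [i for i, s in enumerate(specs) if s["ref_flags"].referred]
    non_referred_idx = [i for i, s in enumerate(specs) if not s["ref_flags"].referred]

    # Fill the public referred quota greedily toward the stratified
    # per-category counts (best-effort: overlaps make them unattainable in
    # general); everyone else referred goes private.
    remaining_pub = dict(targets.referred_public_categories)
    quota = dict(targets.referred_by_school)
    unassigned = list(referred_idx)
    while quota[SchoolType.PUBLIC] > 0 and unassigned:
        def gain(i: int) -> tuple:
            fl = specs[i]["ref_flags"]
            hit = sum(1 for cat in CATEGORIES if fl.get(cat) and remaining_pub[cat] > 0)
            overshoot = sum(1 for cat in CATEGORIES if fl.get(cat) and remaining_pub[cat] <= 0)
            return (hit - overshoot, -i)

        best = max(
            (i for i in unassigned if capacity[(SchoolType.PUBLIC, specs[i]["band"])] > 0),
            key=gain,
            default=None,
        )
        if best is None:
            break
        unassigned.remove(best)
        specs[best]["school"] = SchoolType.PUBLIC
        quota[SchoolType.PUBLIC] -= 1
        capacity[(SchoolType.PUBLIC, specs[best]["band"])] -= 1
        for cat in CATEGORIES:
            if specs[best]["ref_flags"].get(cat):
                remaining_pub[cat] -= 1
    for i in unassigned:
        band = specs[i]["band"]
        if quota[SchoolType.PRIVATE] > 0 and capacity[(SchoolType.PRIVATE, band)] > 0:
            specs[i]["school"] = SchoolType.PRIVATE
            quota[SchoolType.PRIVATE] -= 1
            capacity[(SchoolType.PRIVATE, band)] -= 1
        elif capacity[(SchoolType.PUBLIC, band)] > 0 and quota[SchoolType.PUBLIC] > 0:
            specs[i]["school"] = SchoolType.PUBLIC
            quota[SchoolType.PUBLIC] -= 1
            capacity[(SchoolType.PUBLIC, band)] -= 1
        else:
            raise ReconstructionError("school quotas cannot place a referred child")
    for i in non_referred_idx:
        band = specs[i]["band"]
        school = (
            SchoolType.PUBLIC if capacity[(SchoolType.PUBLIC, band)] > 0 else SchoolType.PRIVATE
        )
        if capacity[(school, band)] <= 0:
            raise ReconstructionError("school x band capacities exhausted")
        specs[i]["school"] = school
        capacity[(school, band)] -= 1

    # Spectacle wear: only referred children wear glasses, per stratum quota.
    glasses_left = dict(targets.glasses_referred)
    for i in referred_idx:
        school = specs[i]["school"]
        specs[i]["glasses"] = glasses_left[school] > 0
        if specs[i]["glasses"]:
            glasses_left[school] -= 1
    for i in non_referred_idx:
        specs[i]["glasses"] = False

    # Grades and sex per school, filled in deterministic cohort order.
    grade_quota = {
        (school, band): list(quotas)
        for school, bands in targets.grades.items()
        for band, quotas in bands.items()
    }
    female_left = dict(targets.females)
    for i, s in enumerate(specs):
        key = (s["school"], s["band"])
        quotas = grade_quota.get(key, [])
        while quotas and quotas[0][1] <= 0:
            quotas.pop(0)
        if quotas:
            grade, left = quotas[0]
            quotas[0] = (grade, left - 1)
        else:  # margins exhausted: fall back to a band-appropriate grade
            grade = Grade.KG1 if s["band"] is AgeBand.UNDER4 else Grade.KG2
        s["grade"] = grade
        s["sex"] = Sex.F if female_left[s["school"]] > 0 else Sex.M
        if s["sex"] is Sex.F:
            female_left[s["school"]] -= 1

    width = len(str(len(specs)))
    cohort = [
        ChildRecord(
            child_id=f"c{i + 1:0{width}d}",
            age_years=3.5 if s["band"] is AgeBand.UNDER4 else 5.0,
            school_type=s["school"],
            grade=s["grade"],
            sex=s["sex"],
            wears_spectacles=s["glasses"],
            right_eye=s["right"],
            left_eye=s["left"],
        )
        for i, s in enumerate(specs)
    ]

    report = _verify(cohort, plan, targets, criteria, convention)
    if not report.category_exact:
        raise ReconstructionError(
            "materialized cohort does not reproduce the target category counts:\n"
            + report.to_json()
        )
    return cohort, report


def _verify(
    cohort: Sequence[ChildRecord],
    plan: FixturePlan,
    targets: ReconstructionTargets,
    criteria: Sequence[CriterionSpec],
    convention: MetricConvention,
) -> ReconstructionReport:
    matrix = apply_criteria(cohort, criteria, convention)
    counts = matrix.counts()
    ref = targets.reference_criterion

    category_counts = {
        name: {
            cat: (targets.category_counts[name][cat], int(counts.loc[name, cat]))
            for cat in CATEGORIES
        }
        for name in targets.category_counts
    }
    union_counts = {
        name: (targets.union_counts[name], int(counts.loc[name, "referred"]))
        for name in targets.union_counts
    }
    achieved_codes = {
        "hyp": sum(
            1 for c in cohort if any(e.status is ReadingStatus.HYP for e in c.eyes)
        ),
        "myo": sum(
            1 for c in cohort if any(e.status is ReadingStatus.MYO for e in c.eyes)
        ),
        "unreadable": sum(
            1
            for c in cohort
            if any(e.status is ReadingStatus.UNREADABLE for e in c.eyes)
            and all(e.status is not ReadingStatus.HYP and e.status is not ReadingStatus.MYO for e in c.eyes)
        ),
    }
    code_counts = {k: (targets.codes[k], achieved_codes[k]) for k in targets.codes}

    ref_table = matrix.table("referred")[ref]
    by_school = {s: 0 for s in SchoolType}
    glasses = {s: 0 for s in SchoolType}
    pub_cats = {cat: 0 for cat in CATEGORIES}
    for child in cohort:
        if ref_table[child.child_id]:
            by_school[child.school_type] += 1
            if child.wears_spectacles:
                glasses[child.school_type] += 1
            if child.school_type is SchoolType.PUBLIC:
                for cat in CATEGORIES:
                    if matrix.flags(child.child_id, ref).get(cat):
                        pub_cats[cat] += 1
    band_achieved = {b: sum(1 for c in cohort if c.age_band is b) for b in AgeBand}

    return ReconstructionReport(
        category_counts=category_counts,
        union_counts=union_counts,
        code_counts=code_counts,
        referred_by_school={
            s.value: (targets.referred_by_school[s], by_school[s]) for s in SchoolType
        },
        glasses_referred={
            s.value: (targets.glasses_referred[s], glasses[s]) for s in SchoolType
        },
        referred_public_categories={
            cat: (targets.referred_public_categories[cat], pub_cats[cat]) for cat in CATEGORIES
        },
        band_sizes={
            b.value: (targets.band_sizes[b], band_achieved[b]) for b in AgeBand
        },
        feasible=all(t == a for cats in category_counts.values() for t, a in cats.values()),
    )


def reconstruct_cohort(
    targets: Optional[ReconstructionTargets] = None,
    criteria: Optional[Sequence[CriterionSpec]] = None,
    convention: MetricConvention = DEFAULT_CONVENTION,
) -> tuple[list[ChildRecord], ReconstructionReport]:
    """Full pipeline: plan against the (packaged) targets and materialize."""
    targets = targets or default_targets()
    criteria = list(criteria) if criteria is not None else builtin_criteria()
    plan = plan_overlaps(targets, criteria, convention)
    return materialize_fixture(plan, targets, criteria, convention)
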