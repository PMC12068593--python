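"""Referral criteria registry, per-child classification and tabulation.

Six published rule sets are built in: the AAPOS 2021 age-based examination
failure levels and the Arthur examination failure criteria (both applied here
as instrument referral criteria), and four instrument referral criteria
proper: Arnold Medium, Arnold Specific, Matta & Silbert, and the Alaska Blind
Child Discovery (ABCD) project.  Each rule set carries four positive
thresholds per age band (< 4 years and >= 4 years; non-age-based sets repeat
the same values in both bands):

* hyperopia flagged when the configured metric is ``>= hyperopia_ge``;
* myopia when ``<= myopia_le``;
* astigmatism when ``|cylinder| >= astigmatism_ge`` in either eye;
* anisometropia when the interocular difference is ``>= anisometropia_ge``.

A child is flagged per the worse eye (either eye meeting a monocular
threshold flags the child).  An eye showing the device's ``HYP`` code flags
hyperopia, ``MYO`` flags myopia; a child with an unreadable eye and no other
finding is referred as unreadable.  Criteria are plain data and can be
round-tripped through YAML, so new device firmware rule sets need no code
change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .refraction import (
    EPS,
    AgeBand,
    AnisoMetric,
    ChildRecord,
    DEFAULT_CONVENTION,
    HyperopiaMetric,
    MetricConvention,
    MyopiaMetric,
    ReadingStatus,
    anisometropia_value,
)

CATEGORIES = ("hyperopia", "myopia", "astigmatism", "anisometropia")


@dataclass(frozen=True)
class BandThresholds:
    hyperopia_ge: float
    myopia_le: float
    astigmatism_ge: float
    anisometropia_ge: float

    def __post_init__(self) -> None:
        if self.hyperopia_ge <= 0 or self.astigmatism_ge <= 0 or self.anisometropia_ge <= 0:
            raise ValueError("hyperopia/astigmatism/anisometropia thresholds must be > 0")
        if self.myopia_le >= 0:
            raise ValueError("myopia threshold must be < 0")

    def threshold(self, category: str) -> float:
        return {
            "hyperopia": self.hyperopia_ge,
            "myopia": self.myopia_le,
            "astigmatism": self.astigmatism_ge,
            "anisometropia": self.anisometropia_ge,
        }[category]


@dataclass(frozen=True)
class CriterionSpec:
    """One referral rule set: age-banded thresholds for the four categories."""

    name: str
    display_name: str
    bands: Mapping[AgeBand, BandThresholds]

    def __post_init__(self) -> None:
        if set(self.bands) != {AgeBand.UNDER4, AgeBand.GE4}:
            raise ValueError("both age bands must be present")


def builtin_criteria() -> list[CriterionSpec]:
    """The six built-in rule sets (see module docstring)."""

    def crit(name, display, under4, ge4=None):
        ge4 = ge4 or under4
        return CriterionSpec(
            name,
            display,
            {
                AgeBand.UNDER4: BandThresholds(*under4),
                AgeBand.GE4: BandThresholds(*ge4),
            },
        )

    return [
        crit("aapos_2021", "AAPOS 2021", (4.00, -3.00, 3.00, 1.25), (4.00, -2.00, 1.75, 1.25)),
        crit("arthur", "Arthur", (3.50, -3.00, 1.25, 1.00)),
        crit("arnold_medium", "Arnold Medium", (3.00, -3.50, 3.50, 1.75), (3.00, -2.50, 2.50, 1.75)),
        crit("arnold_specific", "Arnold Specific", (3.50, -3.50, 3.75, 1.75), (3.50, -2.50, 2.75, 1.75)),
        crit("matta_silbert", "Matta & Silbert", (1.25, -1.00, 1.00, 1.25)),
        crit("abcd", "Alaska Blind Child Discovery", (2.50, -2.25, 2.25, 1.00)),
    ]


def criteria_by_name(criteria: Optional[Iterable[CriterionSpec]] = None) -> dict[str, CriterionSpec]:
    return {c.name: c for c in (criteria if criteria is not None else builtin_criteria())}


@dataclass(frozen=True)
class CategoryFlags:
    """Per-child, per-criterion flags for the four categories + unreadability."""

    hyperopia: bool
    myopia: bool
    astigmatism: bool
    anisometropia: bool
    unreadable: bool

    def __post_init__(self) -> None:
        if self.unreadable and any(
            (self.hyperopia, self.myopia, self.astigmatism, self.anisometropia)
        ):
            raise ValueError("unreadable excludes category flags")

    @property
    def referred(self) -> bool:
        return (
            self.hyperopia
            or self.myopia
            or self.astigmatism
            or self.anisometropia
            or self.unreadable
        )

    def get(self, name: str) -> bool:
        return getattr(self, name)


FLAG_FIELDS = ("referred",) + CATEGORIES + ("unreadable",)


def classify_child(
    child: ChildRecord,
    criterion: CriterionSpec,
    convention: MetricConvention = DEFAULT_CONVENTION,
) -> CategoryFlags:
    """Apply one rule set to one child using the thresholds of its age band."""
    th = criterion.bands[child.age_band]
    hyperopia = myopia = astigmatism = False
    unreadable_seen = False
    for eye in child.eyes:
        if eye.status is ReadingStatus.HYP:
            hyperopia = True
        elif eye.status is ReadingStatus.MYO:
            myopia = True
        elif eye.status is ReadingStatus.UNREADABLE:
            unreadable_seen = True
        else:
            sphere, cylinder, _ = eye.minus_cylinder()
            se = eye.se
            hyp_val = sphere if convention.hyperopia_metric is HyperopiaMetric.SPHERE_MOST_PLUS else se
            if hyp_val >= th.hyperopia_ge - EPS:
                hyperopia = True
            myo_val = se if convention.myopia_metric is MyopiaMetric.SE else sphere + cylinder
            if myo_val <= th.myopia_le + EPS:
                myopia = True
            if abs(cylinder) >= th.astigmatism_ge - EPS:
                astigmatism = True
    aniso_val = anisometropia_value(child.right_eye, child.left_eye, convention)
    anisometropia = aniso_val is not None and aniso_val >= th.anisometropia_ge - EPS
    unreadable = unreadable_seen and not (hyperopia or myopia or astigmatism or anisometropia)
    return CategoryFlags(hyperopia, myopia, astigmatism, anisometropia, unreadable)


class FlagsMatrix:
    """Complete children x criteria grid of :class:`CategoryFlags`."""

    def __init__(
        self,
        child_ids: Sequence[str],
        criteria_names: Sequence[str],
        flags: Mapping[tuple[str, str], CategoryFlags],
    ):
        self.child_ids = list(child_ids)
        self.criteria_names = list(criteria_names)
        self._flags = dict(flags)
        for cid in self.child_ids:
            for name in self.criteria_names:
                if (cid, name) not in self._flags:
                    raise ValueError(f"missing cell ({cid}, {name})")

    @property
    def n_children(self) -> int:
        return len(self.child_ids)

    def flags(self, child_id: str, criterion_name: str) -> CategoryFlags:
        return self._flags[(child_id, criterion_name)]

    def table(self, field: str) -> pd.DataFrame:
        """Boolean children x criteria table for one flag field."""
        if field not in FLAG_FIELDS:
            raise KeyError(field)
        data = {
            name: [getattr(self._flags[(cid, name)], field) for cid in self.child_ids]
            for name in self.criteria_names
        }
        return pd.DataFrame(data, index=self.child_ids, dtype=bool)

    def counts(self) -> pd.DataFrame:
        """Per-criterion counts of flagged children for every field."""
        return pd.DataFrame(
            {field: self.table(field).sum(axis=0) for field in FLAG_FIELDS},
            index=pd.Index(self.criteria_names),
        )


def apply_criteria(
    cohort: Sequence[ChildRecord],
    criteria: Optional[Sequence[CriterionSpec]] = None,
    convention: MetricConvention = DEFAULT_CONVENTION,
) -> FlagsMatrix:
    """Classify every child under every criterion (input order preserved)."""
    criteria = list(criteria) if criteria is not None else builtin_criteria()
    if not cohort:
        raise ValueError("empty cohort")
    if not criteria:
        raise ValueError("no criteria supplied")
    flags = {
        (child.child_id, crit.name): classify_child(child, crit, convention)
        for child in cohort
        for crit in criteria
    }
    return FlagsMatrix([c.child_id for c in cohort], [c.name for c in criteria], flags)


def tabulate_rates(matrix: FlagsMatrix, decimals: int = 1) -> pd.DataFrame:
    """Per-criterion counts and half-up rounded percentages of all children.

    Percentages use the total number of screened children as denominator.
    """
    from .stats import percent_round

    counts = matrix.counts()
    n = matrix.n_children
    out = {}
    for field in FLAG_FIELDS:
        out[field] = counts[field]
        out[f"{field}_pct"] = [
            percent_round(int(v), n, decimals) for v in counts[field]
        ]
    frame = pd.DataFrame(out, index=counts.index)
    frame.attrs["n_children"] = n
    return frame


# ---------------------------------------------------------------------------
# YAML round trip


def dump_criteria_yaml(criteria: Sequence[CriterionSpec], path) -> None:
    payload = [
        {
            "name": c.name,
            "display_name": c.display_name,
            "bands": {
                band.value: {
                    "hyperopia_ge": th.hyperopia_ge,
                    "myopia_le": th.myopia_le,
                    "astigmatism_ge": th.astigmatism_ge,
                    "anisometropia_ge": th.anisometropia_ge,
                }
                for band, th in c.bands.items()
            },
        }
        for c in criteria
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_criteria_yaml(path) -> list[CriterionSpec]:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    out = []
    for entry in payload:
        out.append(
            CriterionSpec(
                entry["name"],
                entry.get("display_name", entry["name"]),
                {AgeBand(b): BandThresholds(**th) for b, th in entry["bands"].items()},
            )
        )
    return out
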