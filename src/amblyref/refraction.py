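"""Photorefraction data model and refractive algebra.

A non-cycloplegic photoscreener (e.g. the Plusoptix A12) reports one reading
per eye as sphere / cylinder / axis in diopters and degrees, or a device
status code when the refraction is outside the measurable range (``HYP`` for
hyperopia beyond the device ceiling, ``MYO`` for high myopia) or when no
reading could be obtained (``UNREADABLE``).

All internal computation uses minus-cylinder notation; readings supplied in
plus-cylinder form are transposed on the fly.  The spherical equivalent is
``SE = sphere + cylinder / 2`` and is invariant under transposition, as are
the two principal meridional powers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

EPS = 1e-9

#: Measurable range of the device, diopters (configurable at the module level).
SPHERE_RANGE = (-7.0, 5.0)
CYLINDER_MAX = 7.0


class ReadingStatus(str, Enum):
    NUMERIC = "numeric"
    HYP = "hyp"
    MYO = "myo"
    UNREADABLE = "unreadable"


class AgeBand(str, Enum):
    UNDER4 = "under4"
    GE4 = "ge4"


class SchoolType(str, Enum):
    PUBLIC = "public"
    PRIVATE = "private"


class Grade(str, Enum):
    NURSERY = "nursery"
    KG1 = "kg1"
    KG2 = "kg2"
    KG3 = "kg3"
    GRADE1 = "grade1"


class Sex(str, Enum):
    F = "f"
    M = "m"


class HyperopiaMetric(str, Enum):
    SPHERE_MOST_PLUS = "sphere_most_plus"
    SE = "se"


class MyopiaMetric(str, Enum):
    SE = "se"
    MOST_MINUS_MERIDIAN = "most_minus_meridian"


class AnisoMetric(str, Enum):
    SE_DIFF = "se_diff"
    SPHERE_DIFF = "sphere_diff"
    MAX_MERIDIAN_DIFF = "max_meridian_diff"


def normalize_to_minus_cylinder(
    sphere: float, cylinder: float, axis: Optional[float]
) -> tuple[float, float, Optional[float]]:
    """Return the minus-cylinder form of a refraction.

    A plus-cylinder refraction ``(S, +C, ax)`` is transposed to
    ``(S + C, -C, ax +/- 90)`` with the axis mapped back into ``(0, 180]``;
    minus-cylinder input is returned unchanged.  The set of meridional powers
    is preserved.
    """
    if cylinder != 0:
        if axis is None:
            raise ValueError("axis required when cylinder is nonzero")
        if not (0 < axis <= 180):
            raise ValueError(f"axis must lie in (0, 180], got {axis}")
    if cylinder <= 0:
        return sphere, cylinder, axis
    new_axis = axis + 90 if axis <= 90 else axis - 90
    return sphere + cylinder, -cylinder, new_axis


def spherical_equivalent(sphere: float, cylinder: float) -> float:
    """``SE = sphere + cylinder / 2`` (transposition invariant)."""
    return sphere + cylinder / 2.0


def meridional_powers(sphere: float, cylinder: float) -> tuple[float, float]:
    """Return ``(most_plus, most_minus)`` principal meridian powers.

    In minus-cylinder form the most-plus meridian equals the sphere and the
    most-minus meridian equals ``sphere + cylinder``.
    """
    if cylinder > 0:
        sphere, cylinder = sphere + cylinder, -cylinder
    return sphere, sphere + cylinder


@dataclass(frozen=True)
class EyeReading:
    """One eye's photorefraction result: numeric values or a status code."""

    status: ReadingStatus
    sphere: Optional[float] = None
    cylinder: Optional[float] = None
    axis: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status is ReadingStatus.NUMERIC:
            if self.sphere is None or self.cylinder is None:
                raise ValueError("numeric reading requires sphere and cylinder")
            if not (SPHERE_RANGE[0] - EPS <= self.sphere <= SPHERE_RANGE[1] + EPS):
                raise ValueError(f"sphere {self.sphere} outside device range {SPHERE_RANGE}")
            if abs(self.cylinder) > CYLINDER_MAX + EPS:
                raise ValueError(f"|cylinder| {abs(self.cylinder)} exceeds {CYLINDER_MAX}")
            if self.cylinder != 0:
                if self.axis is None:
                    raise ValueError("axis required when cylinder is nonzero")
                if not (0 < self.axis <= 180):
                    raise ValueError(f"axis must lie in (0, 180], got {self.axis}")
            elif self.axis is not None:
                raise ValueError("axis must be absent when cylinder is zero")
        else:
            if any(v is not None for v in (self.sphere, self.cylinder, self.axis)):
                raise ValueError("coded reading must not carry numeric fields")

    @classmethod
    def numeric(
        cls, sphere: float, cylinder: float = 0.0, axis: Optional[float] = None
    ) -> "EyeReading":
        return cls(ReadingStatus.NUMERIC, sphere, cylinder, axis)

    @classmethod
    def coded(cls, status: ReadingStatus) -> "EyeReading":
        if status is ReadingStatus.NUMERIC:
            raise ValueError("use EyeReading.numeric for numeric readings")
        return cls(status)

    @property
    def is_numeric(self) -> bool:
        return self.status is ReadingStatus.NUMERIC

    def minus_cylinder(self) -> tuple[float, float, Optional[float]]:
        self._require_numeric()
        return normalize_to_minus_cylinder(self.sphere, self.cylinder, self.axis)

    @property
    def se(self) -> float:
        self._require_numeric()
        return spherical_equivalent(self.sphere, self.cylinder)

    @property
    def most_plus(self) -> float:
        self._require_numeric()
        return meridional_powers(self.sphere, self.cylinder)[0]

    @property
    def most_minus(self) -> float:
        self._require_numeric()
        return meridional_powers(self.sphere, self.cylinder)[1]

    def _require_numeric(self) -> None:
        if not self.is_numeric:
            raise ValueError(f"no numeric refraction for status {self.status.value}")


@dataclass(frozen=True)
class MetricConvention:
    """Which refraction component each threshold class is applied to.

    The referral rule sets publish thresholds but not the component of the
    non-cycloplegic reading they are applied to, so the mapping is
    configurable.  Defaults: hyperopia on the most-plus meridian (= sphere in
    minus-cylinder form), myopia on the spherical equivalent, anisometropia
    on the interocular SE difference.  The code surrogates are numeric
    stand-ins used only where a coded reading must be materialized as a
    number; classification treats codes categorically.
    """

    hyperopia_metric: HyperopiaMetric = HyperopiaMetric.SPHERE_MOST_PLUS
    myopia_metric: MyopiaMetric = MyopiaMetric.SE
    aniso_metric: AnisoMetric = AnisoMetric.SE_DIFF
    hyp_code_surrogate: float = 5.50
    myo_code_surrogate: float = -7.50


DEFAULT_CONVENTION = MetricConvention()


def anisometropia_value(
    right: EyeReading, left: EyeReading, convention: MetricConvention = DEFAULT_CONVENTION
) -> Optional[float]:
    """Absolute interocular difference of the configured quantity.

    Returns ``None`` (undefined, distinguishable from 0) when either eye has
    no numeric reading.
    """
    if not (right.is_numeric and left.is_numeric):
        return None
    if convention.aniso_metric is AnisoMetric.SE_DIFF:
        return abs(right.se - left.se)
    if convention.aniso_metric is AnisoMetric.SPHERE_DIFF:
        return abs(right.most_plus - left.most_plus)
    return max(
        abs(right.most_plus - left.most_plus),
        abs(right.most_minus - left.most_minus),
    )


@dataclass(frozen=True)
class ChildRecord:
    """Demographics plus the two per-eye readings for one screened child."""

    child_id: str
    age_years: float
    school_type: SchoolType
    grade: Grade
    sex: Sex
    wears_spectacles: bool
    right_eye: EyeReading
    left_eye: EyeReading

    def __post_init__(self) -> None:
        if not (2.0 <= self.age_years <= 8.0):
            raise ValueError(f"age_years {self.age_years} outside [2, 8]")

    @property
    def age_band(self) -> AgeBand:
        # Exactly 4.0 years classifies as the >=4 band.
        return AgeBand.GE4 if self.age_years >= 4.0 else AgeBand.UNDER4

    @property
    def eyes(self) -> tuple[EyeReading, EyeReading]:
        return (self.right_eye, self.left_eye)


CSV_COLUMNS = [
    "child_id",
    "age_years",
    "school_type",
    "grade",
    "sex",
    "wears_spectacles",
    "od_status",
    "od_sphere",
    "od_cylinder",
    "od_axis",
    "os_status",
    "os_sphere",
    "os_cylinder",
    "os_axis",
]


class CohortParseError(ValueError):
    """Raised with per-row diagnostics when a cohort CSV fails validation."""

    def __init__(self, diagnostics: Sequence[tuple[int, str, str]]):
        self.diagnostics = list(diagnostics)
        lines = [f"row {r}: {field}: {msg}" for r, field, msg in self.diagnostics]
        super().__init__("cohort CSV validation failed:\n" + "\n".join(lines))


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else f"{value:g}"


def _parse_eye(
    row: dict, prefix: str, rownum: int, errors: list
) -> Optional[EyeReading]:
    status_raw = row.get(f"{prefix}_status", "").strip().lower()
    try:
        status = ReadingStatus(status_raw)
    except ValueError:
        errors.append((rownum, f"{prefix}_status", f"unknown status {status_raw!r}"))
        return None
    fields = {}
    for name in ("sphere", "cylinder", "axis"):
        raw = row.get(f"{prefix}_{name}", "").strip()
        if raw == "":
            fields[name] = None
            continue
        try:
            fields[name] = float(raw)
        except ValueError:
            errors.append((rownum, f"{prefix}_{name}", f"unparsable number {raw!r}"))
            return None
    try:
        if status is ReadingStatus.NUMERIC:
            return EyeReading.numeric(fields["sphere"], fields["cylinder"], fields["axis"])
        if any(fields[n] is not None for n in fields):
            raise ValueError("numeric fields must be blank for coded status")
        return EyeReading.coded(status)
    except (TypeError, ValueError) as exc:
        errors.append((rownum, f"{prefix}_status", str(exc)))
        return None


def parse_cohort_csv(path) -> list[ChildRecord]:
    """Read a cohort CSV (see :data:`CSV_COLUMNS`) into validated records.

    Status codes are parsed case-insensitively; blank numeric fields are
    permitted only for coded readings.  All row-level problems are collected
    and raised together as :class:`CohortParseError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise CohortParseError([(0, "file", "empty file")])
    header = [h.strip() for h in rows[0]]
    missing = [c for c in CSV_COLUMNS if c not in header]
    if missing:
        raise CohortParseError([(1, c, "missing required column") for c in missing])

    errors: list[tuple[int, str, str]] = []
    records: list[ChildRecord] = []
    seen_ids: set[str] = set()
    for rownum, raw in enumerate(rows[1:], start=2):
        row = dict(zip(header, (v.strip() for v in raw)))
        cid = row.get("child_id", "")
        if not cid:
            errors.append((rownum, "child_id", "blank child_id"))
            continue
        if cid in seen_ids:
            errors.append((rownum, "child_id", f"duplicate child_id {cid!r}"))
            continue
        seen_ids.add(cid)
        try:
            age = float(row["age_years"])
        except ValueError:
            errors.append((rownum, "age_years", f"unparsable number {row['age_years']!r}"))
            continue
        right = _parse_eye(row, "od", rownum, errors)
        left = _parse_eye(row, "os", rownum, errors)
        if right is None or left is None:
            continue
        try:
            records.append(
                ChildRecord(
                    child_id=cid,
                    age_years=age,
                    school_type=SchoolType(row["school_type"].lower()),
                    grade=Grade(row["grade"].lower()),
                    sex=Sex(row["sex"].lower()),
                    wears_spectacles=row["wears_spectacles"] in ("1", "true"),
                    right_eye=right,
                    left_eye=left,
                )
            )
        except ValueError as exc:
            errors.append((rownum, "row", str(exc)))
    if errors:
        raise CohortParseError(errors)
    return records


def write_cohort_csv(cohort: Iterable[ChildRecord], path, header_comment: Optional[str] = None) -> None:
    """Write records in the canonical cohort CSV schema (deterministic bytes)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for child in cohort:
            row = [
                child.child_id,
                f"{child.age_years:g}",
                child.school_type.value,
                child.grade.value,
                child.sex.value,
                "1" if child.wears_spectacles else "0",
            ]
            for eye in child.eyes:
                row += [eye.status.value, _fmt(eye.sphere), _fmt(eye.cylinder), _fmt(eye.axis)]
            writer.writerow(row)
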