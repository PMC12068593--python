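"""Threshold chains, marginal allocation, joint planning and materialization."""

import dataclasses

import pytest

from amblyref import (
    AgeBand,
    ChildRecord,
    EyeReading,
    Grade,
    InfeasibleTargetsError,
    SchoolType,
    Sex,
    apply_criteria,
    classify_child,
    enumerate_child_types,
    materialize_fixture,
    plan_overlaps,
    reconstruct_cohort,
    solve_category_allocation,
    threshold_chain,
    write_cohort_csv,
)
from amblyref.criteria import CATEGORIES, criteria_by_name


@pytest.fixture(scope="module")
def child_types(criteria):
    return enumerate_child_types(criteria)


def test_hyperopia_chain_ge4_is_nested(criteria):
    chain = threshold_chain(criteria, "hyperopia", AgeBand.GE4)
    assert chain.thresholds == (1.25, 2.50, 3.00, 3.50, 4.00)
    active = [r.active for r in chain.regions]
    assert active[0] == {"matta_silbert"}
    assert active[1] == {"matta_silbert", "abcd"}
    assert active[2] == {"matta_silbert", "abcd", "arnold_medium"}
    assert active[3] == {"matta_silbert", "abcd", "arnold_medium", "arnold_specific", "arthur"}
    assert active[4] == {c.name for c in criteria}
    for smaller, larger in zip(active, active[1:]):
        assert smaller < larger


def test_astigmatism_chain_under4(criteria):
    chain = threshold_chain(criteria, "astigmatism", AgeBand.UNDER4)
    assert chain.thresholds == (1.00, 1.25, 2.25, 3.00, 3.50, 3.75)
    # AAPOS joins at 3.00 D in the under-4 band
    assert "aapos_2021" not in chain.regions[2].active
    assert "aapos_2021" in chain.regions[3].active


def test_single_criterion_chain(criteria):
    (ms,) = [c for c in criteria if c.name == "matta_silbert"]
    chain = threshold_chain([ms], "myopia", AgeBand.GE4)
    assert chain.thresholds == (1.00,)
    assert chain.regions[0].active == {"matta_silbert"}
    assert chain.regions[0].upper is None


def test_region_activity_matches_classification(criteria):
    """A child placed at a region's representative cylinder is flagged for
    astigmatism by exactly the region's active criteria (sensitivity)."""
    for band, age in ((AgeBand.UNDER4, 3.5), (AgeBand.GE4, 5.0)):
        chain = threshold_chain(criteria, "astigmatism", band)
        for region in chain.regions:
            child = ChildRecord(
                "probe", age, SchoolType.PUBLIC, Grade.KG2, Sex.F, False,
                EyeReading.numeric(0.5, -region.rep, 90.0), EyeReading.numeric(0.5),
            )
            flagged = {c.name for c in criteria if classify_child(child, c).astigmatism}
            assert flagged == region.active


BAND_SIZES = {AgeBand.UNDER4: 106, AgeBand.GE4: 202}


def test_hyperopia_allocation_by_interval_differences(criteria):
    targets = {
        "matta_silbert": 38,
        "abcd": 11,
        "arnold_medium": 11,
        "arnold_specific": 10,
        "arthur": 10,
        "aapos_2021": 7,
    }
    alloc = solve_category_allocation(criteria, "hyperopia", targets, BAND_SIZES, code_count=7)
    totals = alloc.region_totals()
    assert totals.get(1.25, 0) == 27
    assert totals.get(2.50, 0) == 0
    assert totals.get(3.00, 0) == 1
    assert totals.get(3.50, 0) == 3
    assert totals.get(4.00, 0) == 0  # the device codes cover every count >= 4 D
    assert alloc.code_count == 7


def test_anisometropia_allocation(criteria):
    targets = {
        "arthur": 17,
        "abcd": 17,
        "aapos_2021": 14,
        "matta_silbert": 14,
        "arnold_medium": 5,
        "arnold_specific": 5,
    }
    alloc = solve_category_allocation(criteria, "anisometropia", targets, BAND_SIZES)
    assert alloc.region_totals() == {1.00: 3, 1.25: 9, 1.75: 5}


def test_myopia_allocation_reproduces_banded_cumulative_counts(criteria, targets):
    published = {name: targets.category_counts[name]["myopia"] for name in targets.category_counts}
    alloc = solve_category_allocation(criteria, "myopia", published, BAND_SIZES, code_count=1)
    for crit in criteria:
        achieved = alloc.code_count
        for band in AgeBand:
            chain = threshold_chain(criteria, "myopia", band)
            for region in chain.regions:
                if crit.name in region.active:
                    achieved += alloc.band_region_count(band, region.lower)
        assert achieved == published[crit.name], crit.name


def test_infeasible_targets_name_violation(criteria):
    targets = {
        "arthur": 17,
        "abcd": 17,
        "aapos_2021": 14,
        "matta_silbert": 14,
        "arnold_medium": 20,  # stricter threshold than AAPOS but larger count
        "arnold_specific": 5,
    }
    with pytest.raises(InfeasibleTargetsError, match="arnold_medium"):
        solve_category_allocation(criteria, "anisometropia", targets, BAND_SIZES)


def test_child_types_realize_their_flags(criteria, child_types):
    """Every enumerated archetype classifies exactly as its region values say."""
    from amblyref.reconstruct import _intended_flags, _probe_child

    numeric = [t for t in child_types if t.kind == "numeric"]
    assert len(numeric) > 300
    for t in numeric[::7]:
        intended = _intended_flags(criteria, t.band, *t.values)
        probe = _probe_child(t.band, t.right, t.left)
        assert {c.name: classify_child(probe, c) for c in criteria} == intended


def test_plan_hits_all_union_targets_exactly(targets, criteria, child_types):
    plan = plan_overlaps(targets, criteria, types=child_types)
    assert plan.union_residuals == {name: 0 for name in targets.union_counts}


def test_plan_additive_unions_without_overlaps(targets, criteria, child_types):
    """With union targets set to category sums + unreadable children, the
    planner needs no category co-occurrence and still lands exactly."""
    additive = {
        name: sum(cats.values()) + targets.codes["unreadable"]
        for name, cats in targets.category_counts.items()
    }
    tweaked = dataclasses.replace(targets, union_counts=additive)
    plan = plan_overlaps(tweaked, criteria, types=child_types)
    assert plan.union_residuals == {name: 0 for name in additive}
    # additive unions mean no criterion may flag two categories on one child
    for t, _ in plan.assignments:
        for flags in plan.flags[t].values():
            assert sum(flags.get(cat) for cat in CATEGORIES) <= 1


def test_unattainable_union_reports_residual(targets, criteria, child_types):
    """A union target below a category count is impossible; the shortfall is
    reported as a residual, never silently absorbed."""
    broken = dict(targets.union_counts)
    broken["matta_silbert"] = 50  # < astigmatism count 93
    tweaked = dataclasses.replace(targets, union_counts=broken)
    plan = plan_overlaps(tweaked, criteria, types=child_types)
    assert plan.union_residuals["matta_silbert"] > 0


def test_materialized_fixture_counts_and_demographics(fixture_cohort, fixture_report, targets):
    assert len(fixture_cohort) == 308
    bands = {b: sum(1 for c in fixture_cohort if c.age_band is b) for b in AgeBand}
    assert bands == {AgeBand.UNDER4: 106, AgeBand.GE4: 202}
    schools = {s: sum(1 for c in fixture_cohort if c.school_type is s) for s in SchoolType}
    assert schools == {SchoolType.PUBLIC: 114, SchoolType.PRIVATE: 194}
    assert fixture_report.category_exact
    assert fixture_report.union_residuals == {name: 0 for name in targets.union_counts}
    assert sum(1 for c in fixture_cohort if c.wears_spectacles) == 28
    ids = [c.child_id for c in fixture_cohort]
    assert len(set(ids)) == len(ids)


def test_fixture_reclassification_matches_published_counts(
    fixture_cohort, criteria, targets
):
    counts = apply_criteria(fixture_cohort, criteria).counts()
    for name, cats in targets.category_counts.items():
        for cat, expected in cats.items():
            assert int(counts.loc[name, cat]) == expected, (name, cat)
    for name, expected in targets.union_counts.items():
        assert int(counts.loc[name, "referred"]) == expected, name
    assert int(counts.loc["matta_silbert", "astigmatism"]) == 93


def test_reconstruction_is_deterministic(tmp_path, fixture_cohort, targets):
    cohort2, _ = reconstruct_cohort(targets)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_csv(fixture_cohort, p1)
    write_cohort_csv(cohort2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_report_serializes(fixture_report):
    import json

    payload = json.loads(fixture_report.to_json())
    assert payload["feasible"] is True
    assert payload["union_residuals"]["aapos_2021"] == 0
    assert payload["code_counts"]["hyp"] == {"target": 7, "achieved": 7}
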