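"""EQ-5D-5L profiles, value-set scoring, problem dichotomization and
cohort summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crccea import (
    DIMENSIONS,
    EQ5DProfile,
    PatientRecord,
    has_problem,
    linear_toy_value_set,
    load_value_set,
    summarize_outcomes,
    utility_index,
)
from crccea.errors import InvalidInputError

levels = st.integers(min_value=1, max_value=5)
profiles = st.builds(EQ5DProfile, levels, levels, levels, levels, levels)


def _patient(pid, profile, arm="iFOBT", stage="II", vas=70.0, value_set=None):
    vs = value_set or linear_toy_value_set()
    return PatientRecord(
        id=pid, arm=arm, stage=stage, profile=profile, vas=vas, utility=vs.utility(profile)
    )


@pytest.mark.parametrize(
    "profile,expected",
    [
        ((1, 1, 1, 1, 1), 1.0),  # full-health anchor
        ((5, 5, 5, 5, 5), 0.0),  # worst state under the 0.05-step toy set
        ((1, 1, 1, 2, 1), 0.95),
    ],
)
def test_toy_value_set_scoring(profile, expected, toy_value_set):
    assert utility_index(EQ5DProfile(*profile), toy_value_set) == pytest.approx(expected)


def test_profile_rejects_out_of_range_levels():
    with pytest.raises(InvalidInputError):
        EQ5DProfile(0, 1, 1, 1, 1)
    with pytest.raises(InvalidInputError):
        EQ5DProfile(1, 1, 6, 1, 1)


@given(profiles)
@settings(max_examples=100, deadline=None)
def test_full_health_anchor_and_bound(profile):
    vs = linear_toy_value_set()
    u = utility_index(profile, vs)
    assert u <= 1.0
    if profile.as_tuple() == (1, 1, 1, 1, 1):
        assert u == 1.0


@given(profiles, st.sampled_from(DIMENSIONS))
@settings(max_examples=100, deadline=None)
def test_monotone_in_each_dimension(profile, dim):
    """Raising a single dimension level never increases the toy index."""
    vs = linear_toy_value_set()
    level = profile.level(dim)
    if level == 5:
        return
    worse = EQ5DProfile(**{d: profile.level(d) + (1 if d == dim else 0) for d in DIMENSIONS})
    assert utility_index(worse, vs) <= utility_index(profile, vs)


@pytest.mark.parametrize(
    "profile,dim,expected",
    [
        ((1, 1, 1, 1, 1), "mobility", False),
        ((2, 1, 1, 1, 1), "mobility", True),
        ((1, 1, 1, 5, 1), "pain_discomfort", True),
    ],
)
def test_has_problem_dichotomization(profile, dim, expected):
    assert has_problem(EQ5DProfile(*profile), dim) is expected


def test_has_problem_unknown_dimension():
    with pytest.raises(InvalidInputError):
        has_problem(EQ5DProfile(1, 1, 1, 1, 1), "stamina")


def test_summary_on_toy_cohort():
    cohort = [
        _patient("a", EQ5DProfile(1, 1, 1, 1, 1)),
        _patient("b", EQ5DProfile(2, 1, 1, 1, 1)),
        _patient("c", EQ5DProfile(1, 1, 1, 1, 1)),
        _patient("d", EQ5DProfile(3, 1, 2, 1, 1)),
    ]
    summary = summarize_outcomes(cohort, "all")
    assert summary.problem_proportions["mobility"] == pytest.approx(0.50)
    assert summary.problem_proportions["usual_activities"] == pytest.approx(0.25)
    assert summary.n == 4


def test_summary_full_health_cohort():
    cohort = [_patient(f"p{i}", EQ5DProfile(1, 1, 1, 1, 1)) for i in range(5)]
    summary = summarize_outcomes(cohort, "all")
    assert all(p == 0.0 for p in summary.problem_proportions.values())
    assert summary.utility_mean == pytest.approx(1.0)
    assert summary.utility_sd == pytest.approx(0.0)


def test_summary_empty_group_rejected():
    cohort = [_patient("a", EQ5DProfile(1, 1, 1, 1, 1), arm="iFOBT")]
    with pytest.raises(InvalidInputError):
        summarize_outcomes(cohort, "genetic_testing")
    with pytest.raises(InvalidInputError):
        summarize_outcomes([], "all")


@given(st.lists(profiles, min_size=1, max_size=20), st.randoms(use_true_random=False))
@settings(max_examples=30, deadline=None)
def test_proportions_permutation_and_duplication(profs, rnd):
    """Proportions are order-invariant and unchanged under cohort
    duplication (while n doubles)."""
    cohort = [_patient(f"p{i}", p) for i, p in enumerate(profs)]
    shuffled = list(cohort)
    rnd.shuffle(shuffled)
    s1, s2 = summarize_outcomes(cohort, "all"), summarize_outcomes(shuffled, "all")
    assert s1.problem_proportions == s2.problem_proportions
    doubled = summarize_outcomes(cohort + cohort, "all")
    assert doubled.n == 2 * s1.n
    for dim in DIMENSIONS:
        assert doubled.problem_proportions[dim] == pytest.approx(
            s1.problem_proportions[dim]
        )


def test_published_summary_is_stored_as_published(fixture):
    """The published HRQoL table is carried as-is (its respondent
    denominators cannot be reconstructed at the patient level)."""
    df = fixture.outcome_summaries
    all_row = df[df["group"] == "all"].iloc[0]
    assert all_row["utility_mean"] == pytest.approx(0.787)
    assert all_row["utility_sd"] == pytest.approx(0.273)
    assert all_row["pain_discomfort_pct"] == pytest.approx(51.4)
    gt_row = df[df["group"] == "genetic_testing"].iloc[0]
    assert gt_row["pain_discomfort_pct"] == pytest.approx(74.1)


def test_value_set_loader_roundtrip(tmp_path):
    import pandas as pd

    rows = [
        {"dimension": d, "level": lvl, "decrement": 0.05 * (lvl - 1)}
        for d in DIMENSIONS
        for lvl in range(2, 6)
    ]
    path = tmp_path / "vs.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    vs = load_value_set(path, name="linear")
    assert vs.utility(EQ5DProfile(1, 1, 1, 2, 1)) == pytest.approx(0.95)
    assert vs.utility(EQ5DProfile(1, 1, 1, 1, 1)) == 1.0


def test_patient_record_validation():
    profile = EQ5DProfile(1, 1, 1, 1, 1)
    with pytest.raises(InvalidInputError):
        PatientRecord("x", "iFOBT", "II", profile, vas=101.0, utility=0.9)
    with pytest.raises(InvalidInputError):
        PatientRecord("x", "iFOBT", "II", profile, vas=50.0, utility=1.2)
    with pytest.raises(InvalidInputError):
        PatientRecord("x", "iFOBT", "V", profile, vas=50.0, utility=0.9)
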