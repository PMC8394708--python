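"""Synthetic cohort generator and the packaged study tables."""

import hashlib

import numpy as np
import pytest
from scipy import stats

import crccea
from crccea import (
    CohortParams,
    cohort_to_stage_table,
    generate_cohort,
    stage_lys,
    stage_qalys,
)
from crccea.errors import IntegrityError, InvalidInputError
from crccea.simulate import (
    DEFAULT_STAGE_PROBS,
    DEFAULT_SURVIVAL_MEANS,
    DEFAULT_UTILITY_MEANS,
    _largest_remainder_counts,
)


def _cohort_hash(cohort):
    text = "|".join(
        f"{p.id},{p.arm},{p.stage},{p.utility:.12f},{p.vas:.10f},{p.profile.as_tuple()}"
        for p in cohort
    )
    return hashlib.sha256(text.encode()).hexdigest()


def test_seed_determinism_and_divergence():
    params = CohortParams(n_per_arm=50, seed=7)
    a, b = generate_cohort(params), generate_cohort(params)
    assert _cohort_hash(a) == _cohort_hash(b)
    c = generate_cohort(CohortParams(n_per_arm=50, seed=8))
    assert _cohort_hash(a) != _cohort_hash(c)


def test_generated_values_respect_bounds():
    cohort = generate_cohort(CohortParams(n_per_arm=200, seed=3))
    assert all(p.utility <= 1.0 for p in cohort)
    assert all(0.0 <= p.vas <= 100.0 for p in cohort)
    assert all(1 <= lvl <= 5 for p in cohort for lvl in p.profile.as_tuple())


def test_zero_noise_recovers_stage_utility_means():
    cohort = generate_cohort(
        CohortParams(n_per_arm=100, utility_sd=0.0, seed=1, deterministic_allocation=True)
    )
    gt_stage_ii = [
        p for p in cohort if p.arm == "genetic_testing" and p.stage == "II"
    ]
    assert len(gt_stage_ii) == 60
    assert all(p.utility == 0.82 for p in gt_stage_ii)


def test_stage_counts_calibrated_to_multinomial_bounds():
    """GT stage counts behave like multinomial draws around
    (10, 60, 25, 5) per 100: across many seeds roughly 95% of marginal
    counts fall inside the central 95% binomial bounds."""
    probs = DEFAULT_STAGE_PROBS["genetic_testing"]
    n_seeds, inside = 25, 0
    for seed in range(n_seeds):
        cohort = generate_cohort(CohortParams(n_per_arm=100, seed=seed))
        counts = [
            sum(1 for p in cohort if p.arm == "genetic_testing" and p.stage == s)
            for s in ("I", "II", "III", "IV")
        ]
        for count, prob in zip(counts, probs):
            lo, hi = stats.binom.ppf([0.025, 0.975], 100, prob)
            inside += lo <= count <= hi
    # 100 marginal draws at ~95% coverage; 85 allows sampling slack
    assert inside >= 85


def test_stage_marginals_converge():
    n = 10_000
    cohort = generate_cohort(CohortParams(n_per_arm=n, seed=5))
    for arm, probs in DEFAULT_STAGE_PROBS.items():
        for stage, prob in zip(("I", "II", "III", "IV"), probs):
            observed = sum(1 for p in cohort if p.arm == arm and p.stage == stage) / n
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(observed - prob) <= 3 * se


def test_deterministic_allocation_full_pipeline_parameter_recovery():
    """Zero-noise, exact-allocation cohorts pushed through the LY/QALY
    chain reproduce the study's per-patient values exactly."""
    cohort = generate_cohort(
        CohortParams(n_per_arm=100, utility_sd=0.0, seed=1, deterministic_allocation=True)
    )
    for arm, (ly_pp, qaly_pp) in (
        ("iFOBT", (5.21, 3.44)),
        ("genetic_testing", (6.13, 4.97)),
    ):
        table = cohort_to_stage_table(cohort, DEFAULT_SURVIVAL_MEANS, arm)
        result = stage_qalys(table)
        assert round(result.per_patient_ly, 2) == ly_pp
        assert round(result.per_patient_qaly, 2) == qaly_pp


def test_stochastic_large_n_recovery_within_two_percent():
    cohort = generate_cohort(CohortParams(n_per_arm=10_000, seed=42))
    for arm in ("iFOBT", "genetic_testing"):
        table = cohort_to_stage_table(cohort, DEFAULT_SURVIVAL_MEANS, arm)
        result = stage_qalys(table)
        analytic_ly = sum(
            p * DEFAULT_SURVIVAL_MEANS[s]
            for p, s in zip(DEFAULT_STAGE_PROBS[arm], ("I", "II", "III", "IV"))
        )
        assert result.per_patient_ly == pytest.approx(analytic_ly, rel=0.02)
        # truncation at 1 biases the mean below the nominal arm×stage
        # means, so compare against the truncated-normal expectation
        analytic_qaly = 0.0
        for prob, stage in zip(DEFAULT_STAGE_PROBS[arm], ("I", "II", "III", "IV")):
            mu, sd = DEFAULT_UTILITY_MEANS[arm][stage], 0.273
            mean_u = stats.truncnorm.mean(-np.inf, (1 - mu) / sd, loc=mu, scale=sd)
            analytic_qaly += prob * DEFAULT_SURVIVAL_MEANS[stage] * mean_u
        assert result.per_patient_qaly == pytest.approx(analytic_qaly, rel=0.02)


def test_largest_remainder_is_exact():
    counts = _largest_remainder_counts(np.array([0.06, 0.17, 0.54, 0.23]), 100)
    assert counts.tolist() == [6, 17, 54, 23]
    counts = _largest_remainder_counts(np.array([1 / 3, 1 / 3, 1 / 3, 0.0]), 100)
    assert counts.sum() == 100


def test_invalid_params_rejected():
    with pytest.raises(InvalidInputError):
        CohortParams(n_per_arm=0)
    with pytest.raises(InvalidInputError):
        CohortParams(stage_probs={"iFOBT": (0.5, 0.5, 0.1, 0.1), "genetic_testing": (0.25,) * 4})
    with pytest.raises(InvalidInputError):
        CohortParams(utility_sd=-0.1)


def test_cohort_to_stage_table_errors_and_empty_stage():
    cohort = generate_cohort(
        CohortParams(n_per_arm=10, seed=2, deterministic_allocation=True)
    )
    with pytest.raises(InvalidInputError):
        cohort_to_stage_table(cohort, {"I": 6.71}, "iFOBT")
    only_two_stages = [p for p in cohort if p.stage in ("II", "III")]
    table = cohort_to_stage_table(only_two_stages, DEFAULT_SURVIVAL_MEANS, "iFOBT")
    assert table.rows["IV"].n == 0 and table.rows["IV"].utility_mean is None


def test_fixture_values(fixture):
    gt_ii = fixture.stage_tables["genetic_testing"].rows["II"]
    assert (gt_ii.survival_mean, gt_ii.n, gt_ii.utility_mean) == (6.51, 60, 0.82)
    assert fixture.stage_tables["iFOBT"].rows["IV"].treatment_cost == 6612.80
    assert fixture.cost_profiles["iFOBT"].total == pytest.approx(372.83, abs=0.005)
    assert fixture.cost_profiles["genetic_testing"].total == pytest.approx(976.26, abs=0.005)
    assert fixture.published_total_cost_difference == pytest.approx(603.424)
    assert fixture.screening_costs["genetic_testing"] == pytest.approx(97626.33)


def test_fixture_checksum_guard(monkeypatch):
    import crccea.fixtures as fx

    real = fx._data_path

    class Tampered:
        def __init__(self, path):
            self._path = path

        def read_bytes(self):
            return self._path.read_bytes() + b"corruption"

        def read_text(self):
            return real("manifest.json").read_text()

    def tampered_path(name):
        if name == "stage_tables.csv":
            return Tampered(real(name))
        return real(name)

    monkeypatch.setattr(fx, "_data_path", tampered_path)
    with pytest.raises(IntegrityError):
        fx.load_paper_fixture()


def test_cohort_frame_roundtrip(tmp_path):
    cohort = generate_cohort(CohortParams(n_per_arm=20, seed=9))
    path = tmp_path / "cohort.csv"
    crccea.cohort_to_frame(cohort).to_csv(path, index=False)
    loaded = crccea.cohort_from_csv(path)
    assert len(loaded) == len(cohort)
    assert loaded[0].profile == cohort[0].profile
    assert loaded[0].utility == pytest.approx(cohort[0].utility)
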