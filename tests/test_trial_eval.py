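import numpy as np
import pytest

from recistvar import (
    CoverageReport,
    ErrorDistribution,
    ProbabilityTable,
    SimStudyConfig,
    TrialDataset,
    bootstrap_orr_coverage,
    burden_second_reading_ranges,
    clopper_pearson,
    coverage_of_second_readings,
    evaluate_trial,
    generate_second_readings,
    generate_trial,
    observed_orr,
    run_simulation_study,
    summarize_burden,
    TrialGenConfig,
)
from recistvar.io import Lesion, TrialRecord


def _single_lesion_trial(changes, baseline=30.0, n_def=0):
    records = [
        TrialRecord(f"P{i}", [Lesion("solid", baseline, baseline * (1 + c))])
        for i, c in enumerate(changes)
    ]
    return TrialDataset(records=records, n_definitive_progression=n_def)


@pytest.fixture
def manual_table():
    """Hand-built table: c=-1 certain response, c=+0.5 certain progression,
    c=-0.3 a coin flip."""
    return ProbabilityTable(
        entries={
            (1, 0, 30, -100, "inter"): (1.0, 0.0),
            (1, 0, 30, 50, "inter"): (0.0, 1.0),
            (1, 0, 30, -30, "inter"): (0.5, 0.5),
        }
    )


def test_certain_probabilities_give_degenerate_range(manual_table, rng):
    trial = _single_lesion_trial([-1.0, -1.0, -1.0])
    orr, prog = evaluate_trial(trial, manual_table, "inter", n_reps=500, rng=rng)
    assert orr.central_range_95 == (100.0, 100.0)
    assert orr.median == 100.0
    assert prog.central_range_95 == (0.0, 0.0)


def test_orr_distribution_matches_poisson_binomial(manual_table):
    """Response probabilities (1, 0, 0.5, 0.5) put exact mass (0.25, 0.5, 0.25)
    on counts (1, 2, 3); the simulated counts must agree within 3 SE per cell."""
    trial = _single_lesion_trial([-1.0, 0.5, -0.3, -0.3])
    n_reps = 10_000
    orr, _ = evaluate_trial(trial, manual_table, "inter", n_reps=n_reps,
                            rng=np.random.default_rng(31))
    counts = np.round(orr.rates * 4 / 100).astype(int)
    exact = {1: 0.25, 2: 0.5, 3: 0.25}
    for k, p in exact.items():
        freq = np.mean(counts == k)
        se = np.sqrt(p * (1 - p) / n_reps)
        assert abs(freq - p) <= 3 * se
    assert not np.isin(counts, [0, 4]).any()


def test_definitive_only_trial(manual_table, rng):
    trial = TrialDataset(records=[], n_definitive_progression=5)
    orr, prog = evaluate_trial(trial, manual_table, "inter", n_reps=200, rng=rng)
    assert orr.central_range_95 == (0.0, 0.0)
    assert prog.central_range_95 == (100.0, 100.0)
    assert prog.median == 100.0


def test_definitive_patient_shifts_rates(manual_table):
    """Adding a definitive-progression patient weakly lowers every simulated
    ORR (denominator) and raises every progression rate (numerator + denom)."""
    trial0 = _single_lesion_trial([-1.0, -0.3, -0.3])
    trial1 = _single_lesion_trial([-1.0, -0.3, -0.3], n_def=1)
    orr0, prog0 = evaluate_trial(trial0, manual_table, "inter", n_reps=400,
                                 rng=np.random.default_rng(32))
    orr1, prog1 = evaluate_trial(trial1, manual_table, "inter", n_reps=400,
                                 rng=np.random.default_rng(32))
    assert np.all(orr1.rates <= orr0.rates)
    assert np.all(prog1.rates >= prog0.rates)


def test_rate_distribution_invariant_to_patient_order(manual_table):
    trial = _single_lesion_trial([-1.0, 0.5, -0.3, -0.3])
    reversed_trial = TrialDataset(records=trial.records[::-1],
                                  n_definitive_progression=0)
    a, _ = evaluate_trial(trial, manual_table, "inter", n_reps=8000,
                          rng=np.random.default_rng(33))
    b, _ = evaluate_trial(reversed_trial, manual_table, "inter", n_reps=8000,
                          rng=np.random.default_rng(34))
    assert a.median == b.median
    assert a.central_range_95 == b.central_range_95
    assert abs(a.rates.mean() - b.rates.mean()) < 1.5  # percent, MC tolerance


def test_unmatched_composition_names_patient(manual_table, rng):
    trial = TrialDataset(
        records=[TrialRecord("P7", [Lesion("solid", 30, 21), Lesion("solid", 20, 14)])]
    )
    with pytest.raises(KeyError):
        evaluate_trial(trial, manual_table, "inter", n_reps=10, rng=rng)


# ---------------------------------------------------------------------------
# second-reading ranges and coverage
# ---------------------------------------------------------------------------


def test_zero_error_ranges_are_degenerate(zero_err, rng):
    trial = _single_lesion_trial([-0.3, 0.1], baseline=40.0)
    ranges = burden_second_reading_ranges(trial, zero_err, n_sims=200, rng=rng)
    assert len(ranges) == 4  # one row per patient and phase
    for row in ranges.itertuples():
        assert row.lower_mm == pytest.approx(row.observed_mm)
        assert row.upper_mm == pytest.approx(row.observed_mm)


def test_interval_width_grows_with_burden_size(inter_err, rng):
    trial = TrialDataset(
        records=[
            TrialRecord("small", [Lesion("solid", 30, 30)]),
            TrialRecord("large", [Lesion("solid", 120, 120)]),
        ]
    )
    ranges = burden_second_reading_ranges(trial, inter_err, n_sims=2000, rng=rng)
    width = {
        (r.patient_id, r.phase): r.upper_mm - r.lower_mm for r in ranges.itertuples()
    }
    assert width[("large", "baseline")] > width[("small", "baseline")]
    assert width[("large", "post")] > width[("small", "post")]


def test_coverage_self_reading_with_small_error(inter_err, rng):
    trial = _single_lesion_trial([-0.4, -0.1, 0.3], baseline=50.0)
    tiny = ErrorDistribution(mode="inter", cov=inter_err.cov * 1e-6)
    ranges = burden_second_reading_ranges(trial, inter_err, n_sims=500, rng=rng)
    # "actual" second readings equal to the first lie inside every range
    report = coverage_of_second_readings(ranges, trial)
    assert report.coverage_percent == 100.0
    assert report.n_total == 6
    # ranges built from a near-zero error model miss readings drawn with the
    # full error: miscalibration is detectable
    second = generate_second_readings(trial, inter_err, rng)
    narrow = burden_second_reading_ranges(trial, tiny, n_sims=500, rng=rng)
    assert coverage_of_second_readings(narrow, second).coverage_percent < 50.0


def test_overdispersed_second_readings_break_coverage(true_vc, inter_err, rng):
    trial = generate_trial(TrialGenConfig(n_patients=60, change_sd=20.0), rng)
    ranges = burden_second_reading_ranges(trial, inter_err, n_sims=500, rng=rng)
    inflated = ErrorDistribution(mode="inter", cov=inter_err.cov * 9.0)  # 3x SD
    second = generate_second_readings(trial, inflated, rng)
    report = coverage_of_second_readings(ranges, second)
    assert report.coverage_percent < 90.0


def test_coverage_requires_matching_patients(inter_err, rng):
    trial = _single_lesion_trial([-0.3])
    other = TrialDataset(records=[TrialRecord("Q1", [Lesion("solid", 30, 21)])])
    ranges = burden_second_reading_ranges(trial, inter_err, n_sims=100, rng=rng)
    with pytest.raises(ValueError, match="lacks patients"):
        coverage_of_second_readings(ranges, other)


# ---------------------------------------------------------------------------
# bootstrap ORR coverage
# ---------------------------------------------------------------------------


def test_bootstrap_identical_second_reading_always_covered(manual_table, rng):
    trial = _single_lesion_trial([-1.0, -0.3, -0.3, 0.5])
    report = bootstrap_orr_coverage(trial, trial, manual_table, "inter",
                                    n_boot=20, n_reps=400, rng=rng)
    assert report.n_total == 20
    assert report.coverage_percent == 100.0


def test_bootstrap_single_resample(manual_table, rng):
    trial = _single_lesion_trial([-1.0, -0.3])
    report = bootstrap_orr_coverage(trial, trial, manual_table, "inter",
                                    n_boot=1, n_reps=200, rng=rng)
    assert report.n_total == 1


def test_bootstrap_requires_shared_patients(manual_table, rng):
    a = _single_lesion_trial([-1.0])
    b = TrialDataset(records=[TrialRecord("other", [Lesion("solid", 30, 21)])])
    with pytest.raises(ValueError, match="same patients"):
        bootstrap_orr_coverage(a, b, manual_table, "inter", rng=rng)


# ---------------------------------------------------------------------------
# simulation-study runner
# ---------------------------------------------------------------------------


def test_observed_orr_is_a_recount(rng):
    trial = generate_trial(TrialGenConfig(n_patients=50, change_sd=20.0), rng)
    manual = sum(
        summarize_burden(rec).percent_change <= -30.0 + 1e-9 for rec in trial.records
    )
    assert observed_orr(trial) == pytest.approx(100.0 * manual / 50)


def test_clopper_pearson_degenerate_ends():
    lo, hi = clopper_pearson(0, 50)
    assert lo == 0.0 and 0 < hi < 15
    lo, hi = clopper_pearson(50, 50)
    assert hi == 100.0 and 85 < lo < 100


def test_all_complete_responses_reproduce_perfectly(zero_err, rng):
    cfg = SimStudyConfig(name="all_cr", n_patients=20, baseline=30.0,
                         change_mean=-100.0, change_sd=0.0, n_replicates=2)
    res = run_simulation_study([cfg], zero_err, rng=rng, n_reps=300)
    assert (res["observed_orr"] == 100.0).all()
    assert (res["range_lower"] == 100.0).all()
    assert (res["range_upper"] == 100.0).all()


def test_simulation_study_emits_tidy_rows(inter_err, rng):
    cfgs = [
        SimStudyConfig(name="a", n_patients=10, n_replicates=3),
        SimStudyConfig(name="b", n_patients=10, baseline=(3.55, 0.53),
                       true_orr=50.0, n_replicates=2),
    ]
    res = run_simulation_study(cfgs, inter_err, rng=rng, n_reps=200, n_burdens=50)
    assert len(res) == 5
    assert set(res["config"]) == {"a", "b"}
    assert ((0 <= res["range_lower"]) & (res["range_lower"] <= res["range_upper"])
            & (res["range_upper"] <= 100)).all()
    assert (res["ci_lower"] <= res["observed_orr"] + 1e-9).all()
    assert (res["observed_orr"] <= res["ci_upper"] + 1e-9).all()


def test_coverage_report_percent():
    rep = CoverageReport(n_total=22 + 20, n_covered=19 + 20)
    assert rep.coverage_percent == pytest.approx(92.857, abs=1e-3)
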