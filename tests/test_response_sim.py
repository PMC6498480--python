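import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from recistvar import (
    ErrorDistribution,
    PosteriorDraws,
    ProbabilityTable,
    ResponseCategory,
    Scenario,
    TumorBurden,
    build_probability_table,
    categorize_response,
    estimate_probabilities,
    intra_error_cov,
    inter_error_cov,
    lookup_probability,
    perturb_burden,
    sample_burden_set,
    summarize_burden,
)
from recistvar.io import Lesion, TrialRecord


class _OnesRng:
    """Stub generator whose standard normals are all 1 (forces eps = chol @ 1)."""

    def standard_normal(self, shape):
        return np.ones(shape)


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "c, expected",
    [
        (-1.0, ResponseCategory.CR),
        (-0.999, ResponseCategory.PR),
        (-0.30, ResponseCategory.PR),
        (-0.31, ResponseCategory.PR),
        (-0.299, ResponseCategory.SD),
        (0.0, ResponseCategory.SD),
        (0.199, ResponseCategory.SD),
        (0.20, ResponseCategory.PD),
        (1.5, ResponseCategory.PD),
    ],
)
def test_recist_category_boundaries(c, expected):
    assert categorize_response(c) is expected


def test_category_below_minus_one_rejected():
    with pytest.raises(ValueError):
        categorize_response(-1.01)


@given(st.floats(-1.0, 3.0))
def test_categories_partition_the_change_axis(c):
    assert categorize_response(c) in ResponseCategory


# ---------------------------------------------------------------------------
# burden construction
# ---------------------------------------------------------------------------


def test_single_lesion_burden_is_deterministic(rng):
    sc = Scenario(n_solid=1, n_lymph=0, c=-0.3, reader_mode="inter", baseline_mm=30)
    burdens = sample_burden_set(sc, n_burdens=20, rng=rng)
    for b in burdens:
        assert b.lesions == (("solid", 30.0, 21.0),)


def test_multi_lesion_weighted_change_constraint(rng):
    sc = Scenario(n_solid=3, n_lymph=0, c=-0.3, reader_mode="inter")
    for b in sample_burden_set(sc, n_burdens=50, rng=rng):
        yb = np.array([l[1] for l in b.lesions])
        yp = np.array([l[2] for l in b.lesions])
        cx = yp / yb - 1.0
        # clamping at 0 (c_x < -1) can break the identity; none expected here
        assert (cx * yb).sum() / yb.sum() == pytest.approx(-0.3, abs=1e-9)


def test_burden_sizes_respect_truncation(rng):
    sc = Scenario(n_solid=2, n_lymph=2, c=0.1, reader_mode="inter")
    for b in sample_burden_set(sc, n_burdens=100, rng=rng):
        for organ, yb, _ in b.lesions:
            if organ == "lymph":
                assert 10.0 <= yb <= 80.0
            else:
                assert 10.0 <= yb <= 150.0


def test_burden_composition_limits():
    with pytest.raises(ValueError):
        TumorBurden(tuple(("lymph", 20.0, 20.0) for _ in range(3)))
    with pytest.raises(ValueError):
        Scenario(n_solid=4, n_lymph=2, c=0.0, reader_mode="inter")


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------


def test_zero_error_perturbation_is_identity(zero_err, rng):
    b = TumorBurden((("solid", 100.0, 49.0), ("solid", 30.0, 21.0)))
    out = perturb_burden(b, zero_err, rng)
    assert out == b


def test_forced_half_unit_error_squares_correctly():
    # cov with chol rows (0.5, 0) / (0.5, 0): z = (1, 1) forces eps = +0.5
    cov = np.array([[0.25, 0.25], [0.25, 0.25]])
    err = ErrorDistribution(mode="intra", cov=cov)
    b = TumorBurden((("solid", 100.0, 100.0),))
    out = perturb_burden(b, err, _OnesRng())
    assert out.lesions[0][1] == pytest.approx(10.5**2)
    assert out.lesions[0][2] == pytest.approx(110.25)


def test_vanished_lesion_never_goes_negative(inter_err, rng):
    b = TumorBurden((("solid", 30.0, 0.0),))
    for _ in range(50):
        out = perturb_burden(b, inter_err, rng)
        assert out.lesions[0][2] >= 0.0


# ---------------------------------------------------------------------------
# probability estimation
# ---------------------------------------------------------------------------


def test_no_variability_gives_certain_designation(zero_err, rng):
    sc = Scenario(n_solid=1, n_lymph=0, c=-0.5, reader_mode="inter", baseline_mm=40)
    assert estimate_probabilities(sc, zero_err, rng=rng) == (1.0, 0.0)
    sc_pd = Scenario(n_solid=1, n_lymph=0, c=0.4, reader_mode="inter", baseline_mm=40)
    assert estimate_probabilities(sc_pd, zero_err, rng=rng) == (0.0, 1.0)


def test_complete_disappearance_nearly_always_response(inter_err, rng):
    sc = Scenario(n_solid=1, n_lymph=0, c=-1.0, reader_mode="inter", baseline_mm=30)
    p_resp, _ = estimate_probabilities(sc, inter_err, n_burdens=2000, rng=rng)
    assert p_resp >= 0.99


def test_estimate_consistent_with_large_sample_rerun(inter_err):
    sc = Scenario(n_solid=1, n_lymph=0, c=-0.33, reader_mode="inter", baseline_mm=30)
    p_big, _ = estimate_probabilities(sc, inter_err, n_burdens=100_000,
                                      rng=np.random.default_rng(21))
    p_small, _ = estimate_probabilities(sc, inter_err, n_burdens=2000,
                                        rng=np.random.default_rng(22))
    se = np.sqrt(p_big * (1 - p_big) / 2000)
    assert abs(p_small - p_big) <= 3 * se


# ---------------------------------------------------------------------------
# probability table
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_table(true_vc):
    post = PosteriorDraws(draws=[true_vc], n_chains=1)
    cs = [-1.0, -0.5, -0.35, -0.3, -0.25, 0.0, 0.2, 0.5, 1.0]
    grid = [
        Scenario(n_solid=1, n_lymph=0, c=c, reader_mode=mode, baseline_mm=b)
        for c in cs
        for b in (30, 120)
        for mode in ("intra", "inter")
    ]
    return build_probability_table(grid, post, n_iter=5, n_burdens=1500,
                                   rng=np.random.default_rng(23))


def test_zero_covariance_posterior_reduces_to_deterministic_rule(rng):
    z = np.zeros((2, 2))
    from recistvar import VarianceComponents

    vc0 = VarianceComponents(mu=[5, 5], cov_lesion=z, cov_reader=z,
                             cov_interaction=z, cov_residual=z)
    post = PosteriorDraws(draws=[vc0], n_chains=1)
    grid = [
        Scenario(n_solid=1, n_lymph=0, c=-0.5, reader_mode="inter", baseline_mm=30),
        Scenario(n_solid=2, n_lymph=0, c=-0.5, reader_mode="inter"),
    ]
    tbl = build_probability_table(grid, post, n_iter=3, n_burdens=50, rng=rng)
    for entry in tbl.entries.values():
        assert entry == (1.0, 0.0)


def test_table_probabilities_are_coherent(small_table):
    for p_resp, p_prog in small_table.entries.values():
        assert 0.0 <= p_resp <= 1.0 and 0.0 <= p_prog <= 1.0
        assert p_resp + p_prog <= 1.0 + 1e-12


def test_larger_lesion_has_steeper_transition(small_table):
    """Percent-change noise shrinks with size, so the response curve of a
    120 mm lesion falls from ~1 to ~0 more sharply around -30% than a 30 mm one."""
    def steepness(baseline):
        keys = {c: (1, 0, baseline, c, "inter") for c in (-35, -25)}
        p = {c: small_table.entries[k][0] for c, k in keys.items()}
        return p[-35] - p[-25]

    assert steepness(120) > steepness(30)


def test_intra_probabilities_at_least_as_extreme_as_inter(small_table):
    for b in (30, 120):
        for c_centi, hi in ((-50, True), (0, False)):
            p_intra = small_table.entries[(1, 0, b, c_centi, "intra")][0]
            p_inter = small_table.entries[(1, 0, b, c_centi, "inter")][0]
            if hi:  # deep response: intra closer to 1
                assert p_intra >= p_inter - 1e-9
            else:  # no change: intra closer to 0
                assert p_intra <= p_inter + 1e-9


def test_lymph_scenarios_need_short_axis_posterior(true_vc, rng):
    post = PosteriorDraws(draws=[true_vc], n_chains=1)
    grid = [Scenario(n_solid=1, n_lymph=1, c=-0.3, reader_mode="inter")]
    with pytest.raises(ValueError, match="short-axis"):
        build_probability_table(grid, post, n_iter=2, n_burdens=20, rng=rng)


def test_table_csv_roundtrip(small_table, tmp_path):
    path = tmp_path / "table.csv"
    small_table.to_csv(path)
    back = ProbabilityTable.read_csv(path)
    assert back.entries == small_table.entries


# ---------------------------------------------------------------------------
# lookup
# ---------------------------------------------------------------------------


def _summary(baseline, post):
    return summarize_burden(TrialRecord("P1", [Lesion("solid", baseline, post)]))


def test_lookup_complete_response_entry(small_table):
    p_resp, _ = lookup_probability(small_table, _summary(30, 0), "inter")
    assert p_resp >= 0.99


def test_lookup_rounds_change_to_grid(small_table):
    # -30.4% rounds to the -0.30 grid point
    expected = small_table.entries[(1, 0, 30, -30, "inter")]
    assert lookup_probability(small_table, _summary(30.0, 20.88), "inter") == expected


def test_lookup_clamps_small_baseline_with_warning(small_table):
    with pytest.warns(RuntimeWarning, match="clamped"):
        got = lookup_probability(small_table, _summary(7.0, 3.5), "inter")
    assert got == small_table.entries[(1, 0, 30, -50, "inter")]


def test_lookup_unknown_composition_lists_available(small_table):
    rec = TrialRecord("P9", [Lesion("solid", 30, 21), Lesion("solid", 20, 14)])
    with pytest.raises(KeyError, match="available compositions"):
        lookup_probability(small_table, summarize_burden(rec), "inter")


def test_lookup_clamps_growth_beyond_doubling(small_table):
    with pytest.warns(RuntimeWarning, match="clamped"):
        p_resp, p_prog = lookup_probability(small_table, _summary(30.0, 75.0), "inter")
    assert p_prog == small_table.entries[(1, 0, 30, 100, "inter")][1]
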