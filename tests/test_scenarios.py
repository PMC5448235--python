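"""Simulation scenarios: generators, permutations and scenario runners."""

import numpy as np
import pytest
from scipy.special import gammaln

from lltmval import (
    ScenarioConfig,
    ValidationError,
    WeightMatrix,
    run_scenario1,
    run_scenario2,
    run_scenario3,
    sample_row_permutations,
    simulate_lltm_data,
    simulate_random_q,
    simulate_rasch_data,
    spread_difficulties,
    synthetic_qmatrix,
)
from lltmval.scenarios import _size_class


def expected_null_mean(k: int, p: int) -> float:
    """E[sqrt(R^2)] with R^2 ~ Beta(p/2, (k-1-p)/2).

    Analytic approximation for the correlation between a fixed vector and its
    projection onto a random p-dimensional subspace of the (k-1)-dimensional
    contrast space: E[X^(1/2)] = B(a+1/2, b)/B(a, b).
    """
    a, b = p / 2.0, (k - 1 - p) / 2.0
    return float(np.exp(gammaln(a + 0.5) + gammaln(a + b) - gammaln(a) - gammaln(a + b + 0.5)))


# ---------------------------------------------------------------------------
# random Q generation
# ---------------------------------------------------------------------------


def test_degenerate_probabilities(rng):
    all_zero = simulate_random_q(6, 3, 0.0, rng)
    assert not all_zero.weights.any()
    assert not all_zero.is_identifiable
    all_one = simulate_random_q(6, 3, 1.0, rng)
    assert all_one.weights.all()
    assert not all_one.is_identifiable  # rank 1, collinear with intercept


def test_bernoulli_proportion(rng):
    """Sample proportion of ones within 3 binomial SEs of prop_ones."""
    draws = [simulate_random_q(23, 6, 0.5, rng) for _ in range(100)]
    ones = np.mean([q.weights.mean() for q in draws])
    n = 100 * 23 * 6
    assert abs(ones - 0.5) < 3 * np.sqrt(0.25 / n)


def test_exact_quota_mode(rng):
    q = simulate_random_q(10, 4, 0.3, rng, exact_quota=True)
    assert q.weights.sum() == round(0.3 * 40)


def test_invalid_arguments(rng):
    with pytest.raises(ValidationError):
        simulate_random_q(1, 1, 0.5, rng)
    with pytest.raises(ValidationError):
        simulate_random_q(5, 5, 0.5, rng)
    with pytest.raises(ValidationError):
        simulate_random_q(5, 2, 1.5, rng)


# ---------------------------------------------------------------------------
# row permutations
# ---------------------------------------------------------------------------


def test_swap_is_small_everywhere(theoretical_q_12):
    for k in (17, 23, 12):
        assert _size_class(k, 2) == "small"


def test_paper_sized_cutoffs():
    assert _size_class(23, 7) == "small"
    assert _size_class(23, 8) == "medium"
    assert _size_class(23, 15) == "medium"
    assert _size_class(23, 16) == "large"
    assert _size_class(17, 6) == "small"
    assert _size_class(17, 7) == "medium"
    assert _size_class(17, 12) == "medium"
    assert _size_class(17, 13) == "large"


def test_permutation_bookkeeping(rng, theoretical_q_12):
    perturbed = sample_row_permutations(theoretical_q_12, 200, rng)
    assert len(perturbed) == 200
    identity = np.arange(12)
    for pq in perturbed:
        assert not np.array_equal(pq.permutation, identity)
        assert pq.n_misplaced == np.sum(pq.permutation != identity)
        assert pq.n_misplaced >= 2  # a permutation cannot displace exactly one row
        np.testing.assert_array_equal(
            pq.Q_perturbed.weights, theoretical_q_12.weights[pq.permutation]
        )


def test_identity_never_sampled_small_k(rng):
    Q = WeightMatrix(weights=np.array([[1, 0], [0, 1], [1, 1]]))
    perturbed = sample_row_permutations(Q, 300, rng)  # 3! - 1 = 5 possibilities
    identity = np.arange(3)
    assert all(not np.array_equal(p.permutation, identity) for p in perturbed)


# ---------------------------------------------------------------------------
# response generators
# ---------------------------------------------------------------------------


def test_rasch_generator_grand_mean(rng):
    """With beta = 0 and symmetric theta, cell probability is 1/2."""
    data = simulate_rasch_data(np.zeros(10), 1000, rng=rng)
    n_cells = 10000
    assert abs(data.data.mean() - 0.5) < 3 * np.sqrt(0.25 / n_cells)


def test_item_means_decrease_with_difficulty(rng):
    data = simulate_rasch_data(np.array([-2.0, 0.0, 2.0]), 20000, rng=rng)
    means = data.data.mean(axis=0)
    assert means[0] > means[1] > means[2]


def test_lltm_generator_equals_rasch_at_zero_eta(theoretical_q_12):
    d1 = simulate_lltm_data(theoretical_q_12, np.zeros(4), 50,
                            rng=np.random.default_rng(3))
    d2 = simulate_rasch_data(np.zeros(12), 50, rng=np.random.default_rng(3))
    np.testing.assert_array_equal(d1.data, d2.data)


def test_generator_validation(rng):
    with pytest.raises(ValidationError):
        simulate_rasch_data([0.0, np.inf], 10, rng=rng)
    with pytest.raises(ValidationError):
        simulate_rasch_data([0.0, 0.0], 0, rng=rng)
    with pytest.raises(ValidationError):
        simulate_rasch_data([0.0, 0.0], 10, theta_sd=0.0, rng=rng)


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def scenario1_run(medium_rasch_data):
    cfg = ScenarioConfig(scenario=1, reps=300, prop_ones=0.5, seed=42)
    return run_scenario1(medium_rasch_data, 10, 3, cfg)


def test_scenario1_invariants(scenario1_run):
    dist = scenario1_run
    assert dist.n_converged <= dist.n_requested == 300
    r = dist.correlations
    assert np.all((r >= -1) & (r <= 1))
    s = dist.summary()
    assert s["min"] <= s["p5"] <= s["q1"] <= s["median"] <= s["q3"] <= s["p95"] <= s["max"]
    # summary statistics are recomputable from the stored correlations
    assert s["mean"] == pytest.approx(float(r.mean()))
    assert s["p95"] == pytest.approx(float(np.percentile(r, 95)))
    # random weight matrices fit far worse than the Rasch model
    assert dist.lr_reject_rate > 0.95
    assert dist.ic_summary()["aic"]["percent_favor_lltm"] < 5.0


def test_scenario1_mean_matches_projection_theory(scenario1_run):
    """The null mean tracks E[sqrt(Beta(p/2,(k-1-p)/2))] in (k, p)."""
    assert abs(scenario1_run.summary()["mean"] - expected_null_mean(10, 3)) < 0.05


def test_scenario1_reproducible(medium_rasch_data):
    cfg = ScenarioConfig(scenario=1, reps=40, prop_ones=0.5, seed=7)
    a = run_scenario1(medium_rasch_data, 10, 3, cfg)
    b = run_scenario1(medium_rasch_data, 10, 3, cfg)
    np.testing.assert_array_equal(a.correlations, b.correlations)
    assert a.summary_dict() == b.summary_dict()


def test_scenario1_insensitive_to_prop_ones(medium_rasch_data):
    means = []
    for prop in (0.3, 0.5, 0.7):
        cfg = ScenarioConfig(scenario=1, reps=150, prop_ones=prop, seed=5)
        means.append(run_scenario1(medium_rasch_data, 10, 3, cfg).summary()["mean"])
    assert max(means) - min(means) < 0.08


@pytest.fixture(scope="module")
def scenario2_run(lltm_data_17, theoretical_q_17):
    # the graded decay presumes a Q-matrix that actually explains the data,
    # so the fixture responses are generated from the LLTM with this Q
    cfg = ScenarioConfig(scenario=2, reps=250, seed=21)
    return run_scenario2(lltm_data_17, theoretical_q_17, cfg)


def test_scenario2_ordering(scenario2_run):
    """Correlations decay as more rows are misplaced."""
    med = {name: d.summary()["median"] for name, d in scenario2_run.items()}
    assert med["small"] > med["medium"] > med["large"]


def test_scenario2_small_class_is_tighter(scenario2_run, lltm_data_17):
    """Mild perturbations disperse less than fully random matrices.

    Compared on the 5th-95th percentile spread: the min/max range is
    extreme-value noise at a few hundred replicates.
    """
    cfg1 = ScenarioConfig(scenario=1, reps=250, prop_ones=0.35, seed=21)
    s1 = run_scenario1(lltm_data_17, 17, 5, cfg1).summary()
    small = scenario2_run["small"].summary()
    assert (small["p95"] - small["p5"]) < (s1["p95"] - s1["p5"])


def test_scenario2_class_counts(scenario2_run):
    total = sum(d.n_requested for name, d in scenario2_run.items() if name != "all")
    assert total == scenario2_run["all"].n_requested == 250


@pytest.fixture(scope="module")
def scenario3_run():
    Q = synthetic_qmatrix(8, 3, prop_ones=0.45, seed=5)
    eta = np.array([-1.0, 0.2, 1.0])
    cfg = ScenarioConfig(scenario=3, reps=150, seed=99, persons=300)
    return run_scenario3(Q, eta, cfg)


def test_scenario3_upper_benchmark(scenario3_run):
    dist = scenario3_run
    assert dist.n_converged > 140
    assert dist.summary()["mean"] > 0.9
    # type-I error near the nominal 5% level (loose band at 150 replicates)
    assert dist.lr_reject_rate < 0.12
    recs = [r for r in dist.records if r.converged]
    assert all(np.isfinite(r.aic_lltm) and np.isfinite(r.bic_lltm) for r in recs)


def test_scenario3_reproducible():
    Q = synthetic_qmatrix(8, 3, prop_ones=0.45, seed=5)
    cfg = ScenarioConfig(scenario=3, reps=20, seed=4, persons=200)
    a = run_scenario3(Q, [0.5, -0.5, 1.0], cfg)
    b = run_scenario3(Q, [0.5, -0.5, 1.0], cfg)
    np.testing.assert_array_equal(a.correlations, b.correlations)


def test_config_validation():
    with pytest.raises(ValidationError):
        ScenarioConfig(scenario=4)
    with pytest.raises(ValidationError):
        ScenarioConfig(reps=0)
    with pytest.raises(ValidationError):
        ScenarioConfig(alpha=1.0)
    with pytest.raises(ValidationError):
        ScenarioConfig(prop_ones=0.0)
    with pytest.raises(ValidationError):
        ScenarioConfig(theta_sd=-1.0)


def test_replicate_frame_columns(scenario1_run, tmp_path):
    df = scenario1_run.to_frame()
    for col in ("replicate", "converged", "r", "lr_statistic", "lr_p",
                "aic_rm", "bic_rm", "aic_lltm", "bic_lltm"):
        assert col in df.columns
    out = tmp_path / "reps.csv"
    scenario1_run.to_csv(out)
    assert out.exists()
    json_out = tmp_path / "summary.json"
    scenario1_run.to_json(json_out)
    assert json_out.exists()
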