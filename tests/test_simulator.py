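import numpy as np
import pytest
from scipy import stats

from shoredep import (
    DepositionSchedule,
    SimulationConfig,
    run_bounding_experiment,
    run_experiment,
    run_trial,
    simulate_interval,
)
from shoredep.simulator import trial_rng

from oracles import exact_collection_pmf


class TestDepositionSchedule:
    def test_constant_and_bounding_builders(self):
        const = DepositionSchedule.constant(10)
        assert const.per_day == (10,) * 12 and const.total_deposited == 120
        first = DepositionSchedule.first_day(10, s=4)
        assert first.per_day == (40, 0, 0, 0) * 3
        last = DepositionSchedule.last_day(10, s=4)
        assert last.per_day == (0, 0, 0, 40) * 3

    def test_interval_must_divide_period(self, beach):
        with pytest.raises(ValueError):
            DepositionSchedule.first_day(10, s=5)
        with pytest.raises(ValueError):
            SimulationConfig(
                DepositionSchedule.constant(10), 5, beach, n_trials=10, rng_seed=0
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DepositionSchedule((-1, 0, 0))


class TestSimulateInterval:
    def test_no_thinning_collects_everything(self, ideal):
        rng = np.random.default_rng(0)
        assert simulate_interval([3, 5, 2], ideal, rng) == 10

    def test_zero_deposits_collect_nothing(self, beach):
        rng = np.random.default_rng(0)
        assert simulate_interval([0, 0, 0], beach, rng) == 0

    def test_lag_beyond_curve_support_errors(self, beach):
        with pytest.raises(ValueError):
            simulate_interval([0] * 13, beach, np.random.default_rng(0))

    def test_single_day_mean_matches_binomial(self, beach):
        """s=1, D=10 on beach: N_C ~ Binomial(10, 0.86), mean 8.6."""
        rng = np.random.default_rng(1)
        reps = 10_000
        draws = [simulate_interval([10], beach, rng) for _ in range(reps)]
        se = np.sqrt(10 * 0.86 * 0.14 / reps)
        assert np.mean(draws) == pytest.approx(8.6, abs=3 * se)

    def test_small_instance_matches_enumeration(self, marsh):
        """Simulated N_C frequencies match the brute-force joint-outcome pmf."""
        deposits = [2, 2]
        pmf = exact_collection_pmf(deposits, marsh)
        rng = np.random.default_rng(7)
        reps = 20_000
        counts = np.bincount(
            [simulate_interval(deposits, marsh, rng) for _ in range(reps)],
            minlength=len(pmf),
        )
        expected = np.array([pmf[k] * reps for k in range(len(pmf))])
        _, p_value = stats.chisquare(counts, expected)
        assert p_value > 0.001


class TestTrials:
    def test_deterministic_identity_trial(self, ideal):
        config = SimulationConfig(
            DepositionSchedule.constant(10), 1, ideal, n_trials=1, rng_seed=0
        )
        result = run_trial(config, trial_rng(0, 0))
        assert result.total_estimate == pytest.approx(120.0)
        assert result.collected == (10,) * 12

    def test_zero_deposition_trial(self, beach):
        config = SimulationConfig(
            DepositionSchedule.constant(0), 3, beach, n_trials=1, rng_seed=0
        )
        assert run_trial(config, trial_rng(0, 0)).total_estimate == 0.0

    def test_single_search_trial_algebra(self, beach):
        """With one 12-day interval the estimate is 12 * N_C / (E * sum P)."""
        config = SimulationConfig(
            DepositionSchedule.constant(10), 12, beach, n_trials=1, rng_seed=3
        )
        result = run_trial(config, trial_rng(3, 0))
        n_c = result.collected[0]
        assert result.total_estimate == pytest.approx(12 * n_c / (0.86 * 6.12))


class TestExperiments:
    def test_sd_requires_at_least_two_trials(self, beach):
        config = SimulationConfig(
            DepositionSchedule.constant(10), 1, beach, n_trials=1, rng_seed=0
        )
        with pytest.raises(ValueError):
            run_experiment(config)

    def test_reproducible_for_identical_seed_and_config(self, marsh):
        def summary():
            return run_experiment(
                SimulationConfig(
                    DepositionSchedule.constant(10), 4, marsh, n_trials=200, rng_seed=42
                )
            )

        assert summary() == summary()

    def test_unbiased_under_constant_deposition(self, beach):
        config = SimulationConfig(
            DepositionSchedule.constant(10), 6, beach, n_trials=1000, rng_seed=5
        )
        summary = run_experiment(config)
        se = summary.sd / np.sqrt(summary.n_trials)
        assert abs(summary.mean - 120.0) <= 4 * se

    def test_bounding_requires_bounding_pattern(self, beach):
        config = SimulationConfig(
            DepositionSchedule.constant(10), 2, beach, n_trials=10, rng_seed=0
        )
        with pytest.raises(ValueError):
            run_bounding_experiment(config)

    def test_one_day_interval_bounding_bias_vanishes(self, beach):
        """With s=1 the bounding patterns coincide with constant deposition."""
        for pattern in (DepositionSchedule.first_day, DepositionSchedule.last_day):
            config = SimulationConfig(
                pattern(10, s=1), 1, beach, n_trials=500, rng_seed=11
            )
            res = run_bounding_experiment(config)
            se = res.summary.sd / np.sqrt(res.summary.n_trials)
            assert abs(res.bias) <= 4 * se
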