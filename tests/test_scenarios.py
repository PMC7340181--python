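"""Scenario runners: conflict experiment, two-agent demo, compromise
distance, and the therapy cohort."""

import numpy as np
import pytest

from pctsim import (
    CohortConfig,
    detect_early_response,
    detect_sudden_gains,
    run_approach_avoidance,
    run_conflict_reorg_experiment,
    run_two_agent_conflict,
    simulate_therapy_cohort,
    summarize_trajectories,
)
from pctsim.scenarios import (
    CohortResult,
    HIGH_GAIN,
    LOW_GAIN,
    run_single_conflict_agent,
)


class TestConflictExperiment:
    def test_shapes_pairing_and_determinism(self):
        res = run_conflict_reorg_experiment(n_agents=4, n_windows=6, window=80, base_seed=3)
        assert set(res.trajectories) == {"none", "mid", "top"}
        for cond in res.conditions:
            assert res.trajectories[cond].shape == (6, 4)
            assert res.final_wmrse[cond].shape == (4,)
            assert np.all(res.final_wmrse[cond] >= 0)
        res2 = run_conflict_reorg_experiment(n_agents=4, n_windows=6, window=80, base_seed=3)
        for cond in res.conditions:
            assert np.array_equal(res.trajectories[cond], res2.trajectories[cond])
        # paired design: one architecture per agent reused across conditions
        assert np.array_equal(res.agent_seeds, res2.agent_seeds)

    def test_vectorized_ensemble_matches_network_simulator(self):
        """The array-based ensemble and the general per-agent simulator agree."""
        res = run_conflict_reorg_experiment(n_agents=2, n_windows=5, window=60, base_seed=1)
        for cond in ("none", "mid", "top"):
            for i in range(2):
                traj, final, _ = run_single_conflict_agent(
                    int(res.agent_seeds[i]), int(res.reorg_seeds[i]), cond,
                    n_windows=5, window=60,
                )
                assert np.allclose(traj, res.trajectories[cond][:, i], atol=1e-12)
                assert final == pytest.approx(res.final_wmrse[cond][i], abs=1e-10)

    def test_no_reorganization_means_no_learning(self):
        """Under the none condition windowed error is flat once settled."""
        res = run_conflict_reorg_experiment(n_agents=6, n_windows=10, window=200,
                                            base_seed=5, conditions=("none",))
        traj = res.trajectories["none"]
        settled = traj[2]     # after the start-up transient
        final = traj[-1]
        assert np.all(np.abs(final - settled) <= 0.10 * np.abs(settled))

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            run_conflict_reorg_experiment(n_agents=2, conditions=("none", "sideways"))

    def test_events_logged_for_reorg_conditions(self):
        res = run_conflict_reorg_experiment(n_agents=2, n_windows=4, window=60, base_seed=2)
        frame = res.events_frame()
        assert set(frame.columns) == {
            "condition", "window", "agent", "window_error", "delta_e", "tumbled",
            "step_size",
        }
        assert (frame["condition"] == "none").sum() == 0
        assert len(frame) > 0


class TestTwoAgent:
    @pytest.mark.parametrize(
        "gain_a, gain_b, expected",
        [
            (LOW_GAIN, LOW_GAIN, "goals_met"),
            (LOW_GAIN, HIGH_GAIN, "blocked"),
            (HIGH_GAIN, HIGH_GAIN, "oscillation"),
        ],
    )
    def test_gain_regimes(self, gain_a, gain_b, expected):
        result = run_two_agent_conflict(gain_a, gain_b, seed=0)
        assert result.outcome == expected

    def test_blocked_means_a_displaced_b_satisfied(self):
        result = run_two_agent_conflict(LOW_GAIN, HIGH_GAIN, seed=0)
        assert result.final_error_a > 0.05 * result.goal_separation
        assert result.final_error_b < 0.05 * result.goal_separation

    def test_deterministic_for_fixed_seed(self):
        r1 = run_two_agent_conflict(LOW_GAIN, LOW_GAIN, seed=4)
        r2 = run_two_agent_conflict(LOW_GAIN, LOW_GAIN, seed=4)
        assert np.array_equal(r1.x_a, r2.x_a)
        assert np.array_equal(r1.x_b, r2.x_b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            run_two_agent_conflict(gain_a=0.0)
        with pytest.raises(ValueError):
            run_two_agent_conflict(nonsense=1.0)


class TestApproachAvoidance:
    def test_worked_example_compromise(self):
        """g_safe=3 @ 10 vs g_approach=1 @ 2 settles at (30+2)/4 = 8."""
        result = run_approach_avoidance(g_safe=3, r_safe=10, g_approach=1, r_approach=2)
        assert result.predicted_equilibrium == pytest.approx(8.0)
        assert result.equilibrium == pytest.approx(8.0, abs=1e-3)

    def test_equal_references_no_conflict(self):
        result = run_approach_avoidance(g_safe=3, r_safe=6.0, g_approach=1,
                                        r_approach=5.9999999)
        assert result.equilibrium == pytest.approx(6.0, abs=1e-3)

    def test_dominant_defense_sits_near_safe_distance(self):
        result = run_approach_avoidance(g_safe=10, r_safe=10, g_approach=0.2, r_approach=2)
        assert abs(result.equilibrium - 10.0) < abs(result.equilibrium - 2.0)
        assert result.equilibrium < 10.0  # still a compromise, not the pure goal

    def test_constant_disturbance_is_absorbed(self):
        """Integrating outputs cancel a constant disturbance completely."""
        result = run_approach_avoidance(disturbance=3.0, iterations=4000)
        assert result.equilibrium == pytest.approx(result.predicted_equilibrium, abs=1e-3)

    def test_randomized_draws_match_closed_form(self, rng):
        for _ in range(25):
            ga = rng.uniform(0.5, 5.0)
            gs = rng.uniform(0.5, 5.0)
            ra = rng.uniform(0.0, 5.0)
            rs = ra + rng.uniform(0.5, 10.0)
            result = run_approach_avoidance(g_safe=gs, r_safe=rs, g_approach=ga,
                                            r_approach=ra, iterations=4000, rate=0.02)
            assert result.equilibrium == pytest.approx(
                (gs * rs + ga * ra) / (gs + ga), abs=1e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            run_approach_avoidance(r_safe=1.0, r_approach=2.0)
        with pytest.raises(ValueError):
            run_approach_avoidance(g_safe=-1.0)
        with pytest.raises(ValueError):
            run_approach_avoidance(rate=1.0)  # unstable discrete update


class TestTherapyCohort:
    def test_zero_baseline_stays_zero(self):
        config = CohortConfig(n_cases=50, n_sessions=10, baseline_mean=0.0,
                              baseline_sd=0.0, rng_seed=2)
        result = simulate_therapy_cohort(config)
        assert np.all(result.scores == 0.0)

    def test_default_cohort_size_matches_reference_study(self):
        assert CohortConfig().n_cases == 5613

    def test_scores_bounded_and_deterministic(self):
        config = CohortConfig(n_cases=300, n_sessions=26, rng_seed=9)
        r1 = simulate_therapy_cohort(config)
        r2 = simulate_therapy_cohort(config)
        assert np.array_equal(r1.scores, r2.scores)
        lo, hi = config.score_scale
        assert r1.scores.min() >= lo and r1.scores.max() <= hi
        assert r1.scores.shape == (300, 26)

    def test_change_decelerates_over_sessions(self):
        config = CohortConfig(n_cases=1000, rng_seed=1)
        result = simulate_therapy_cohort(config)
        d = np.abs(np.diff(result.scores, axis=1)).mean(axis=0)
        assert d[:3].mean() > d[-3:].mean()

    def test_summary_prefers_exponential_fit(self):
        config = CohortConfig(n_cases=1000, rng_seed=1)
        summary = summarize_trajectories(simulate_therapy_cohort(config))
        assert summary.exponential_rmse < summary.linear_rmse
        assert not summary.degenerate

    def test_degenerate_constant_cohort_flagged(self):
        scores = np.full((10, 8), 5.0)
        result = CohortResult(
            scores=scores, mean_trajectory=scores.mean(axis=0),
            sudden_gain=np.zeros(10, bool), early_response=np.zeros(10, bool),
            config=CohortConfig(n_cases=10, n_sessions=8),
        )
        summary = summarize_trajectories(result)
        assert summary.degenerate
        assert summary.exponential_rmse == 0.0 and summary.linear_rmse == 0.0

    def test_exact_exponential_curve_fit_preference(self):
        t = np.arange(12)
        curve = 15.0 * np.exp(-0.3 * t) + 5.0
        scores = np.tile(curve, (6, 1))
        result = CohortResult(
            scores=scores, mean_trajectory=curve,
            sudden_gain=np.zeros(6, bool), early_response=np.zeros(6, bool),
            config=CohortConfig(n_cases=6, n_sessions=12),
        )
        summary = summarize_trajectories(result)
        assert summary.exponential_rmse < 1e-6 < summary.linear_rmse

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_sessions=1)
        with pytest.raises(ValueError):
            CohortConfig(baseline_mean=50.0)
        with pytest.raises(ValueError):
            CohortConfig(score_scale=(5.0, 5.0))


class TestChangePatternDetectors:
    def test_flat_series_has_no_gains(self):
        assert detect_sudden_gains(np.full(10, 20.0)) == []

    def test_constructed_single_gain(self):
        series = np.array([30, 29, 28, 27, 17, 16, 16, 16], dtype=float)
        assert detect_sudden_gains(series, drop_threshold=8, stability_window=2) == [3]

    def test_rebound_cancels_gain(self):
        series = np.array([30, 20, 30, 25, 25], dtype=float)
        assert detect_sudden_gains(series, drop_threshold=8, stability_window=2) == []

    def test_short_series_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_sudden_gains(np.array([30.0, 20.0]), stability_window=2) == []

    def test_early_response_rule(self):
        assert detect_early_response(np.array([30, 29, 23, 22, 22.0]))
        assert not detect_early_response(np.array([30, 29, 28, 27, 26.0]))
        # drop only after the early window does not count
        assert not detect_early_response(np.array([30, 29, 28, 28, 28, 10.0]))

    def test_default_cohort_carries_both_patterns(self):
        result = simulate_therapy_cohort(CohortConfig(n_cases=500, rng_seed=0))
        assert 0.0 < result.sudden_gain.mean()
        assert 0.0 < result.early_response.mean()
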