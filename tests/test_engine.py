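import numpy as np
import pytest

from igtsim.agent import AgentParams, ParameterError, net_gain
from igtsim.engine import (
    SweepCombo,
    parameter_sweep,
    relative_preference,
    run_agent,
    simulate_block_preferences,
    trials_to_frame,
)
from igtsim.task import ConfigError, DeckSpec, TaskConfig, standard_decks


class TestRunAgent:
    def test_full_memory_values_constant(self, task):
        params = AgentParams(1.0, 0.5, 0.5)
        result = run_agent(params, task, seed=3)
        for trial in result.trials:
            assert trial.values_after == (0.25, 0.25, 0.25, 0.25)

    def test_determinism(self, task, learner_params):
        a = run_agent(learner_params, task, seed=11)
        b = run_agent(learner_params, task, seed=11)
        assert a.trials == b.trials
        np.testing.assert_array_equal(a.block_preferences, b.block_preferences)

    def test_different_seeds_differ(self, task, learner_params):
        a = run_agent(learner_params, task, seed=11)
        b = run_agent(learner_params, task, seed=12)
        assert a.trials != b.trials

    def test_memoryless_single_deck_tracks_net_gain(self):
        # M=0 with only deck C available: the (single) value after each
        # trial must equal that trial's subjective net gain, hand-computed
        # from the logged raw outcome and the normalizer.
        deck_c = standard_decks()[2]
        task = TaskConfig(decks=(deck_c,), n_trials=5, block_size=5)
        params = AgentParams(0.0, 0.9, 0.1)
        result = run_agent(params, task, seed=21)
        for trial in result.trials:
            expected = net_gain(
                trial.gain / task.normalizer, trial.loss / task.normalizer, params
            )
            assert trial.values_after[0] == pytest.approx(expected)
            assert trial.deck == "C"

    def test_block_preferences_match_trial_log(self, task, learner_params):
        result = run_agent(learner_params, task, seed=5)
        recomputed = relative_preference(result.trials, task.block_size)
        np.testing.assert_allclose(result.block_preferences, recomputed)

    def test_money_conservation(self, task, learner_params):
        result = run_agent(learner_params, task, seed=5)
        assert result.accumulated_money == pytest.approx(
            sum(t.gain - t.loss for t in result.trials)
        )

    def test_overall_is_mean_of_blocks(self, task, learner_params):
        result = run_agent(learner_params, task, seed=5)
        assert result.overall_preference == pytest.approx(
            float(np.mean(result.block_preferences))
        )

    def test_record_false_matches_recorded_run(self, task, learner_params):
        full = run_agent(learner_params, task, seed=9)
        bare = run_agent(learner_params, task, seed=9, record=False)
        assert bare.trials == []
        np.testing.assert_array_equal(full.block_preferences, bare.block_preferences)

    def test_probabilities_sum_to_one(self, task, learner_params):
        result = run_agent(learner_params, task, seed=5)
        for trial in result.trials:
            assert sum(trial.probabilities_used) == pytest.approx(1.0, abs=1e-9)
            assert trial.deck in "ABCD"

    def test_softmax_rule_runs(self, task, learner_params):
        result = run_agent(
            learner_params, task, seed=5, decision_rule="softmax", temperature=0.5
        )
        assert len(result.trials) == task.n_trials

    def test_invalid_lapse_rejected(self, task, learner_params):
        with pytest.raises(ParameterError):
            run_agent(learner_params, task, seed=1, lapse=1.5)

    def test_frame_layout(self, task, learner_params):
        frame = run_agent(learner_params, task, seed=5).to_frame()
        assert list(frame.columns) == [
            "trial", "deck", "gain", "loss", "net_gain",
            "vA", "vB", "vC", "vD", "pA", "pB", "pC", "pD",
        ]
        assert len(frame) == 100


class TestRelativePreference:
    def test_all_advantageous(self):
        assert relative_preference(["A"] * 20, 20)[0] == 1.0

    def test_none_advantageous(self):
        assert relative_preference(["C"] * 20, 20)[0] == 0.0

    def test_mixed_counting(self):
        labels = ["A"] * 10 + ["C"] * 5 + ["D"] * 5
        assert relative_preference(labels, 20)[0] == pytest.approx(0.5)

    def test_indivisible_rejected(self):
        with pytest.raises(ConfigError):
            relative_preference(["A"] * 21, 20)


class TestSimulateBlockPreferences:
    def test_shape_and_bounds(self, task, learner_params):
        prefs = simulate_block_preferences(learner_params, task, n_agents=10, rng=0)
        assert prefs.shape == (10, 5)
        assert np.all((prefs >= 0) & (prefs <= 1))

    def test_determinism(self, task, learner_params):
        a = simulate_block_preferences(learner_params, task, n_agents=10, rng=4)
        b = simulate_block_preferences(learner_params, task, n_agents=10, rng=4)
        np.testing.assert_array_equal(a, b)

    def test_full_memory_uniform(self, task):
        # M=1: values frozen, choice uniform -> mean pref 0.5 within 3 sigma
        params = AgentParams(1.0, 0.5, 0.5)
        prefs = simulate_block_preferences(params, task, n_agents=200, rng=0)
        n_choices = 200 * 100
        sigma = 0.5 / np.sqrt(n_choices)
        assert abs(prefs.mean() - 0.5) < 3 * sigma

    def test_agrees_with_scalar_path(self, task, learner_params):
        # the batch and scalar paths are different RNG streams but must
        # agree in distribution; compare means at moderate n
        batch = simulate_block_preferences(
            learner_params, task, n_agents=300, rng=1
        ).mean()
        scalar = np.mean(
            [
                run_agent(learner_params, task, seed=10_000 + i, record=False)
                .block_preferences.mean()
                for i in range(300)
            ]
        )
        assert abs(batch - scalar) < 0.03


class TestParameterSweep:
    def test_small_grid_shape(self, task):
        res = parameter_sweep((0.2, 0.8), (0.3,), (0.4, 0.6), n_agents=5,
                              task=task, seed=0)
        assert len(res.table) == 4
        assert set(res.table.columns) == {
            "M", "Gs", "Ls", "mean_preference", "sd_preference", "n_agents"
        }
        assert res.table["mean_preference"].between(0, 1).all()
        assert isinstance(res.argmax_combo, SweepCombo)

    def test_determinism(self, task):
        kw = dict(n_agents=20, task=task, seed=77)
        a = parameter_sweep((0.5,), (0.5,), (0.5,), **kw)
        b = parameter_sweep((0.5,), (0.5,), (0.5,), **kw)
        assert a.table.equals(b.table)

    def test_full_memory_grid_near_half(self, task):
        res = parameter_sweep((1.0,), (0.2, 0.8), (0.2, 0.8), n_agents=50,
                              task=task, seed=3)
        sigma = 0.5 / np.sqrt(50 * 100)
        assert np.all(np.abs(res.table["mean_preference"] - 0.5) < 3 * sigma)

    def test_empty_grid_rejected(self, task):
        with pytest.raises(ParameterError):
            parameter_sweep((), (0.5,), (0.5,), task=task)

    def test_grand_mean_combo_is_nearest_row(self, task):
        res = parameter_sweep((0.2, 0.8), (0.2, 0.8), (0.2, 0.8), n_agents=10,
                              task=task, seed=5)
        gaps = (res.table["mean_preference"] - res.grand_mean).abs()
        assert res.grand_mean_combo.mean_preference == pytest.approx(
            res.table.loc[gaps.idxmin(), "mean_preference"]
        )

    def test_directional_low_gain_sensitivity(self, task):
        # At low gain sensitivity, the high-memory/high-loss-sensitivity
        # corner prefers the A+B decks more than the low/low corner.
        hi = simulate_block_preferences(
            AgentParams(0.9, 0.1, 0.9), task, n_agents=400, rng=0
        ).mean()
        lo = simulate_block_preferences(
            AgentParams(0.1, 0.1, 0.1), task, n_agents=400, rng=1
        ).mean()
        assert hi > lo
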