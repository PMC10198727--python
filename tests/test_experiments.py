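"""Episode harness, AUC statistics, paired sweeps and mechanism metrics."""

import numpy as np
import pytest

import opalstar as op
from opalstar.bandit_envs import BanditEnv, ReplaySequence
from opalstar.baseline_agents import QAgent
from opalstar.experiments import (
    ParamGrid,
    action_gap,
    auc,
    make_replay,
    paired_grid_comparison,
    percent_improvement,
    policy_fluctuation,
    ranking_proportion,
    replay_run,
    run_episode,
    sweep_opal,
)
from opalstar.opal_core import OpalAgent, OpalConfig


class TestRunEpisode:
    def test_deterministic_env_greedy_agent_saturates(self):
        env = BanditEnv(probs=np.array([1.0, 0.0]))
        agent = QAgent(2, alpha=0.5, beta=20.0)
        res = run_episode(agent, env, 60, seed=1)
        assert res.p_best[-1] > 0.99

    def test_same_seed_reproduces_run(self, rich2):
        runs = [
            run_episode(OpalAgent(OpalConfig.for_variant("opal_star", 2)), rich2, 80, seed=42)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].choices, runs[1].choices)
        assert np.array_equal(runs[0].rewards, runs[1].rewards)
        assert np.allclose(runs[0].p_best, runs[1].p_best)

    def test_to_frame_columns(self, rich2):
        res = run_episode(OpalAgent(OpalConfig.for_variant("opal_star", 2)), rich2, 10, seed=0)
        df = res.to_frame()
        assert {"trial", "choice", "reward", "p_best", "rho"} <= set(df.columns)
        assert len(df) == 10


class TestAuc:
    def test_constant_curves(self):
        assert auc(np.full(300, 0.8), 250) == pytest.approx(200.0)
        assert auc(np.ones(300), 250) == pytest.approx(250.0)

    def test_linear_ramp_triangle_area(self):
        curve = np.linspace(0, 1, 100)
        assert auc(curve, 100) == pytest.approx(50.0, abs=1.0)

    def test_horizon_beyond_curve(self):
        with pytest.raises(ValueError):
            auc(np.ones(10), 11)

    def test_monotone_under_pointwise_dominance(self, rng):
        a = rng.uniform(0.2, 0.8, size=100)
        b = a + 0.1
        assert auc(b, 100) > auc(a, 100)


class TestGrids:
    def test_canonical_grid_sizes(self):
        assert ParamGrid.opal_full().size == 3 * 20 * 19
        assert ParamGrid.q_full().size == 20 * 50
        assert ParamGrid.ucb_full().size == 201

    def test_combo_table(self):
        grid = ParamGrid.opal_reduced()
        combos = grid.combos()
        assert len(combos) == grid.size
        assert not combos.duplicated().any()


_TINY = ParamGrid({"alpha_c": np.array([0.05]),
                   "alpha_a": np.array([0.1, 0.5]),
                   "beta": np.array([2.0, 5.0])})


class TestPairedComparison:
    def test_model_against_itself_is_identically_zero(self, lean2):
        report = paired_grid_comparison(
            "opal_star", "opal_star", lean2, _TINY,
            horizons=(50,), n_sims=10, base_seed=3,
        )
        assert np.all(report.table["diff_50"] == 0.0)
        assert report.tests[50] == (0.0, 1.0)

    def test_sweep_shapes_and_bounds(self, lean2):
        table = sweep_opal("opal_plus", lean2, _TINY, n_trials=50, n_sims=10,
                           seed=1, horizons=(25, 50))
        assert len(table) == _TINY.size
        assert (table["auc_50"] <= 50).all() and (table["auc_50"] >= 0).all()
        assert (table["auc_25"] <= table["auc_50"]).all()

    def test_percent_improvement(self):
        assert percent_improvement([110.0], [100.0]) == pytest.approx(10.0)
        assert percent_improvement([100.0], [100.0]) == 0.0
        with pytest.raises(ValueError):
            percent_improvement([1.0], [0.0])


class TestMechanismMetrics:
    def test_action_gap_values(self):
        assert action_gap(np.array([0.8, 0.7])) == pytest.approx(0.1)
        assert action_gap(np.array([0.2, 0.3, 0.25]), invert=True) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            action_gap(np.array([0.5]))

    def test_ranking_proportion(self):
        traces = np.array(
            [[[0.8, 0.2]], [[0.1, 0.9]], [[0.5, 0.4]]]
        )  # (3 sims, 1 trial, 2 arms)
        assert ranking_proportion(traces)[0] == pytest.approx(2 / 3)

    def test_policy_fluctuation_limits(self):
        assert policy_fluctuation(np.full(100, 0.9)) == 0.0
        alternating = np.tile([0.9, 0.1], 50)
        assert policy_fluctuation(alternating) == pytest.approx(1.0)


class TestReplay:
    def test_identical_agents_identical_traces(self, lean2):
        rep = make_replay(lean2, 100, seed=5)
        agents = {"a": QAgent(2, alpha=0.2), "b": QAgent(2, alpha=0.2)}
        out = replay_run(agents, rep)
        assert np.array_equal(out["a"]["Q"], out["b"]["Q"])
        assert np.array_equal(out["a"]["policy"], out["b"]["policy"])

    def test_opal_critic_tracks_q_under_matched_replay(self, lean2):
        """With matched learning rates, the critic of the opponent model
        follows the Q-learner exactly under identical forced experience."""
        rep = make_replay(lean2, 120, seed=9)
        out = replay_run(
            {
                "opal": OpalAgent(OpalConfig.for_variant("opal_star", 2, alpha_c=0.1)),
                "q": QAgent(2, alpha=0.1),
            },
            rep,
        )
        assert np.allclose(out["opal"]["V"], out["q"]["Q"], atol=1e-12)

    def test_replay_policies_are_distributions(self, lean2):
        rep = make_replay(lean2, 50, seed=2)
        out = replay_run({"opal": OpalAgent(OpalConfig.for_variant("opal_star", 2))}, rep)
        assert np.allclose(out["opal"]["policy"].sum(axis=1), 1.0)
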