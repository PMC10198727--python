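"""Simulation experiments: episodes, grid sweeps, and mechanism diagnostics.

The central performance statistic throughout is the *learning curve*: the
policy's softmax probability of the optimal action on each trial (recorded
before the choice), averaged over simulations, and summarized by its area
under the curve (AUC, a plain trial-indexed sum, so a horizon of 250 trials
has maximum AUC 250).  Model comparisons pair simulations by random seed and
test per-parameter AUC differences against zero with one-sample t-tests.

Mechanism diagnostics quantify why models differ: the *action gap* (value of
the best arm minus the best suboptimal arm), the proportion of simulations
ranking the arms correctly, a policy-fluctuation index (within-run
variability of the sign of the policy preference), and fixed-replay runs
that drive several agents through identical experience.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bandit_envs import BanditEnv, ReplaySequence, outcome_from_uniform
from .opal_core import OpalAgent, run_opal_batch
from .baseline_agents import run_q_batch

__all__ = [
    "RunResult",
    "ParamGrid",
    "ComparisonReport",
    "run_episode",
    "auc",
    "sweep_opal",
    "paired_grid_comparison",
    "percent_improvement",
    "action_gap",
    "ranking_proportion",
    "policy_fluctuation",
    "make_replay",
    "replay_run",
]

OPAL_VARIANTS = ("opal_star", "opal_plus", "no_hebb")


# ---------------------------------------------------------------------------
# single episodes


@dataclass
class RunResult:
    """Per-trial record of one simulation."""

    p_best: np.ndarray
    choices: np.ndarray
    rewards: np.ndarray
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any((self.p_best < 0) | (self.p_best > 1)):
            raise ValueError("p_best values must lie in [0, 1]")

    @property
    def n_trials(self) -> int:
        return int(self.p_best.size)

    def to_frame(self) -> pd.DataFrame:
        """Tabular per-trial export (trial, choice, reward, p_best + traces)."""
        df = pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "choice": self.choices,
                "reward": self.rewards,
                "p_best": self.p_best,
            }
        )
        for key, arr in self.traces.items():
            if arr.ndim == 1:
                df[key] = arr
            else:
                for j in range(arr.shape[1]):
                    df[f"{key}{j}"] = arr[:, j]
        return df


def run_episode(
    agent,
    env: BanditEnv,
    n_trials: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    full_info: bool = False,
) -> RunResult:
    """Drive one agent through the choose/sample/learn loop.

    Each trial consumes one block of ``n_actions + 1`` uniforms (one
    counterfactual outcome draw per arm, then the choice draw), so agents
    run with the same seed experience identical randomness.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = env.best_action
    p_best = np.empty(n_trials)
    choices = np.empty(n_trials, dtype=int)
    rewards = np.empty(n_trials)
    for t in range(n_trials):
        u = rng.uniform(size=env.n_actions + 1)
        p = agent.policy()
        p_best[t] = p[best]
        a = agent.choose_from_uniform(u[-1])
        if full_info:
            outcomes = np.where(u[: env.n_actions] < env.probs, env.r_mag, env.l_mag)
            agent.observe_all(outcomes)
            reward = outcomes[a]
        else:
            reward = outcome_from_uniform(env, a, u[a])
            agent.learn(a, reward)
        choices[t] = a
        rewards[t] = reward
    return RunResult(p_best=p_best, choices=choices, rewards=rewards, traces=agent.trace())


# ---------------------------------------------------------------------------
# grids and AUC


@dataclass(frozen=True)
class ParamGrid:
    """A cartesian hyperparameter grid (named axes)."""

    axes: dict[str, np.ndarray]

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.axes.values()]))

    def combos(self) -> pd.DataFrame:
        """One row per grid point."""
        names = list(self.axes)
        prod = list(itertools.product(*(self.axes[n] for n in names)))
        return pd.DataFrame(prod, columns=names)

    @classmethod
    def opal_full(cls) -> "ParamGrid":
        """Canonical OpAL-family grid: critic rate {0.025, 0.05, 0.1},
        actor rate 0.05..1 step 0.05, softmax gain 1..10 step 0.5."""
        return cls(
            {
                "alpha_c": np.array([0.025, 0.05, 0.1]),
                "alpha_a": np.round(np.arange(0.05, 1.0001, 0.05), 3),
                "beta": np.round(np.arange(1.0, 10.0001, 0.5), 2),
            }
        )

    @classmethod
    def opal_reduced(cls) -> "ParamGrid":
        """Desk-scale OpAL grid (coarser actor-rate and gain axes)."""
        return cls(
            {
                "alpha_c": np.array([0.025, 0.05, 0.1]),
                "alpha_a": np.round(np.arange(0.1, 1.0001, 0.1), 3),
                "beta": np.round(np.arange(1.0, 10.0001, 1.5), 2),
            }
        )

    @classmethod
    def q_full(cls) -> "ParamGrid":
        """Q-learner grid: rate 0.05..1 step 0.05, gain 2..100 step 2."""
        return cls(
            {
                "alpha": np.round(np.arange(0.05, 1.0001, 0.05), 3),
                "beta": np.round(np.arange(2.0, 100.0001, 2.0), 1),
            }
        )

    @classmethod
    def ucb_full(cls) -> "ParamGrid":
        """UCB exploration constant 0..2 step 0.01."""
        return cls({"c": np.round(np.arange(0.0, 2.0001, 0.01), 3)})


def auc(curve: np.ndarray, horizon: int) -> float:
    """Area under the averaged learning curve: the sum of the mean
    per-trial probability over the first ``horizon`` trials."""
    curve = np.asarray(curve, dtype=float)
    if horizon > curve.size:
        raise ValueError(f"horizon {horizon} exceeds curve length {curve.size}")
    return float(curve[:horizon].sum())


# ---------------------------------------------------------------------------
# grid sweeps and paired comparisons


def sweep_opal(
    variant: str,
    env: BanditEnv,
    grid: ParamGrid,
    n_trials: int = 250,
    n_sims: int = 100,
    seed: int | np.random.SeedSequence = 0,
    horizons: tuple[int, ...] = (250,),
    T: float = 10.0,
    k: float = 20.0,
    phi: float = 1.0,
) -> pd.DataFrame:
    """AUC of the averaged learning curve at every grid point.

    Simulations for all grid points run in one vectorized batch; grid point
    g, simulation i uses uniform column g*n_sims + i, so sweeps of two
    model variants with the same seed are paired run-for-run.
    """
    if variant not in OPAL_VARIANTS:
        raise ValueError(f"variant must be one of {OPAL_VARIANTS}")
    combos = grid.combos()
    P = len(combos)
    ac = np.repeat(combos["alpha_c"].to_numpy(), n_sims)
    aa = np.repeat(combos["alpha_a"].to_numpy(), n_sims)
    bb = np.repeat(combos["beta"].to_numpy(), n_sims)
    res = run_opal_batch(
        env.probs,
        n_trials,
        ac,
        aa,
        bb,
        hebbian=(variant != "no_hebb"),
        modulation=(variant != "opal_plus"),
        T=T,
        k=k,
        phi=phi,
        r_mag=env.r_mag,
        l_mag=env.l_mag,
        seed=seed,
    )
    curves = res.p_best.reshape(P, n_sims, n_trials).mean(axis=1)
    out = combos.copy()
    out.insert(0, "model", variant)
    for h in horizons:
        out[f"auc_{h}"] = curves[:, :h].sum(axis=1)
    return out


@dataclass
class ComparisonReport:
    """Paired grid comparison of two models.

    ``table`` has one row per grid point with both models' AUCs and their
    difference per horizon; ``tests`` maps horizon -> (t, p) from a
    two-sided one-sample t-test of the differences against zero.
    """

    model_a: str
    model_b: str
    table: pd.DataFrame
    tests: dict[int, tuple[float, float]]
    horizons: tuple[int, ...]
    n_sims: int

    def mean_diff(self, horizon: int) -> float:
        return float(self.table[f"diff_{horizon}"].mean())


def paired_grid_comparison(
    model_a: str,
    model_b: str,
    env: BanditEnv,
    grid: ParamGrid,
    horizons: tuple[int, ...] = (250,),
    n_sims: int = 100,
    n_trials: int | None = None,
    base_seed: int = 0,
    T: float = 10.0,
    k: float = 20.0,
    phi: float = 1.0,
) -> ComparisonReport:
    """Seed-paired AUC comparison of two OpAL-family variants over a grid."""
    n_trials = max(horizons) if n_trials is None else n_trials
    kwargs = dict(
        env=env, grid=grid, n_trials=n_trials, n_sims=n_sims,
        horizons=horizons, T=T, k=k, phi=phi,
    )
    a = sweep_opal(model_a, seed=base_seed, **kwargs)
    b = sweep_opal(model_b, seed=base_seed, **kwargs)
    table = a.drop(columns="model").rename(
        columns={f"auc_{h}": f"auc_a_{h}" for h in horizons}
    )
    tests: dict[int, tuple[float, float]] = {}
    for h in horizons:
        table[f"auc_b_{h}"] = b[f"auc_{h}"].to_numpy()
        diff = table[f"auc_a_{h}"] - table[f"auc_b_{h}"]
        table[f"diff_{h}"] = diff
        if np.allclose(diff, 0.0):
            tests[h] = (0.0, 1.0)
        else:
            t, p = stats.ttest_1samp(diff, 0.0)
            tests[h] = (float(t), float(p))
    return ComparisonReport(
        model_a=model_a, model_b=model_b, table=table,
        tests=tests, horizons=tuple(horizons), n_sims=n_sims,
    )


def percent_improvement(auc_a, auc_b) -> float:
    """Mean percent AUC improvement of model a over model b, normalized by
    model b, averaged over grid points."""
    auc_a = np.asarray(auc_a, dtype=float)
    auc_b = np.asarray(auc_b, dtype=float)
    if np.any(auc_b <= 0):
        raise ValueError("reference AUCs must be positive")
    return float(np.mean(100.0 * (auc_a - auc_b) / auc_b))


# ---------------------------------------------------------------------------
# mechanism diagnostics


def action_gap(values: np.ndarray, best: int = 0, invert: bool = False) -> np.ndarray:
    """Value of the best arm minus the best suboptimal arm (last axis).

    With ``invert`` (for cost-coding weights such as OpAL*'s N in lean
    environments) the gap is smallest-suboptimal minus best, positive when
    the optimal arm carries the *lowest* weight.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < 2:
        raise ValueError("need at least two arms")
    others = np.delete(values, best, axis=-1)
    if invert:
        return others.min(axis=-1) - values[..., best]
    return values[..., best] - others.max(axis=-1)


def ranking_proportion(value_traces: np.ndarray, best: int = 0, invert: bool = False) -> np.ndarray:
    """Per-trial fraction of simulations whose action gap is positive.

    ``value_traces`` has shape (n_sims, n_trials, n_actions).
    """
    gaps = action_gap(value_traces, best=best, invert=invert)
    return (gaps > 0).mean(axis=0)


def policy_fluctuation(p_best: np.ndarray) -> np.ndarray:
    """Within-simulation standard deviation of sign(p_best - p_other) for a
    two-arm run; higher values mean more policy flips.  Accepts (T,) or
    (R, T)."""
    p = np.asarray(p_best, dtype=float)
    signs = np.sign(2.0 * p - 1.0)
    return signs.std(axis=-1)


def make_replay(
    env: BanditEnv,
    n_trials: int,
    seed: int | np.random.SeedSequence = 0,
    policy: str = "uniform",
    alpha: float = 0.1,
    beta: float = 5.0,
) -> ReplaySequence:
    """Generate a fixed policy-and-reward sequence in ``env``.

    ``policy="uniform"`` samples every arm equally often (the cleanest way
    to expose learning dynamics under matched experience); ``policy="q"``
    freezes the realized experience of one softmax Q-learner instead.
    """
    if policy == "uniform":
        rng = np.random.default_rng(seed)
        actions = rng.integers(0, env.n_actions, size=n_trials)
        rewards = np.where(
            rng.uniform(size=n_trials) < env.probs[actions], env.r_mag, env.l_mag
        )
        return ReplaySequence(forced_actions=actions, forced_rewards=rewards)
    if policy == "q":
        from .baseline_agents import QAgent

        agent = QAgent(env.n_actions, alpha=alpha, beta=beta, r_mag=env.r_mag, l_mag=env.l_mag)
        result = run_episode(agent, env, n_trials, seed=seed)
        return ReplaySequence(forced_actions=result.choices, forced_rewards=result.rewards)
    raise ValueError(f"unknown replay policy {policy!r}")


def replay_run(agents: dict[str, object], replay: ReplaySequence) -> dict[str, dict]:
    """Drive every agent through the same forced actions and rewards.

    Returns, per agent, its internal traces plus the per-trial softmax
    policy it *would* have followed had it been free to choose.
    """
    out: dict[str, dict] = {}
    for name, agent in agents.items():
        policies = np.empty((len(replay), agent.n_actions))
        for t, (a, r) in enumerate(zip(replay.forced_actions, replay.forced_rewards)):
            policies[t] = agent.policy()
            agent.learn(int(a), float(r))
        out[name] = {"policy": policies, **agent.trace()}
    return out
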