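"""Synthetic task environments for opponent actor-critic simulations.

All experiments in this package run on purely synthetic inputs: stationary
k-armed Bernoulli bandits at several complexity levels (one optimal arm plus
``complexity - 1`` identical suboptimal arms), instructed gamble offers for
risky-choice paradigms, and fixed replay sequences that drive different
agents through identical experience.

Outcomes are encoded as magnitudes (``r_mag`` on success, ``l_mag`` on
failure; defaults 1/0 for bandits and +1/-1 for gambles) rather than
booleans, so the reward-range normalization used by the actors has explicit
bounds and a single code path serves both bandits and gambles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "BanditEnv",
    "GambleOffer",
    "ReplaySequence",
    "EnvSpec",
    "make_environment",
    "sample_outcome",
    "outcome_from_uniform",
    "full_information_outcomes",
    "make_gamble_state",
]

EnvKind = Literal["rich", "lean"]

#: Default (p_best, p_sub) pairs for the two canonical environment types.
DEFAULT_PROBS: dict[str, tuple[float, float]] = {
    "rich": (0.8, 0.7),
    "lean": (0.3, 0.2),
}


@dataclass(frozen=True)
class BanditEnv:
    """A stationary k-armed Bernoulli bandit.

    Arm ``a`` pays ``r_mag`` with probability ``probs[a]`` and ``l_mag``
    otherwise.  The optimal arm is always stored first.
    """

    probs: np.ndarray
    r_mag: float = 1.0
    l_mag: float = 0.0

    def __post_init__(self) -> None:
        probs = np.atleast_1d(np.asarray(self.probs, dtype=float))
        if probs.ndim != 1 or probs.size < 1:
            raise ValueError("probs must be a 1-D vector of probabilities")
        if np.any((probs < 0.0) | (probs > 1.0)):
            raise ValueError("reward probabilities must lie in [0, 1]")
        if not self.r_mag > self.l_mag:
            raise ValueError(
                "r_mag must exceed l_mag (the reward range normalizer "
                "r_mag - l_mag must be positive)"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def n_actions(self) -> int:
        return int(self.probs.size)

    @property
    def best_action(self) -> int:
        return int(np.argmax(self.probs))

    def expected_reward(self, action: int) -> float:
        """Expected outcome magnitude of always choosing ``action``."""
        p = self.probs[action]
        return float(p * self.r_mag + (1.0 - p) * self.l_mag)


def make_environment(
    kind: EnvKind = "rich",
    complexity: int = 2,
    p_best: float | None = None,
    p_sub: float | None = None,
    r_mag: float = 1.0,
    l_mag: float = 0.0,
) -> BanditEnv:
    """Build a rich or lean bandit with one optimal arm.

    ``complexity`` is the total number of arms: one arm at ``p_best`` and
    ``complexity - 1`` identical arms at ``p_sub``.  Defaults are the
    canonical rich (0.8 vs 0.7) and lean (0.3 vs 0.2) tasks.
    """
    if kind not in DEFAULT_PROBS:
        raise ValueError(f"kind must be 'rich' or 'lean', got {kind!r}")
    if complexity < 2:
        raise ValueError("complexity must be at least 2 (one optimal arm plus "
                         "at least one suboptimal arm)")
    default_best, default_sub = DEFAULT_PROBS[kind]
    p_best = default_best if p_best is None else float(p_best)
    p_sub = default_sub if p_sub is None else float(p_sub)
    if not 0.0 <= p_sub < p_best <= 1.0:
        raise ValueError(
            f"need 0 <= p_sub < p_best <= 1, got p_best={p_best}, p_sub={p_sub}"
        )
    probs = np.full(complexity, p_sub, dtype=float)
    probs[0] = p_best
    return BanditEnv(probs=probs, r_mag=r_mag, l_mag=l_mag)


def outcome_from_uniform(env: BanditEnv, action: int, u: float) -> float:
    """Deterministic Bernoulli outcome from a pre-drawn uniform.

    This is the primitive behind the paired-seed contract: agents compared
    on the same seed consume identical per-trial uniforms, so their reward
    sequences coincide whenever their choices do.
    """
    if not 0 <= action < env.n_actions:
        raise IndexError(f"action {action} out of range for {env.n_actions} arms")
    return env.r_mag if u < env.probs[action] else env.l_mag


def sample_outcome(env: BanditEnv, action: int, rng: np.random.Generator) -> float:
    """Draw the outcome magnitude of taking ``action``."""
    return outcome_from_uniform(env, action, rng.uniform())


def full_information_outcomes(env: BanditEnv, rng: np.random.Generator) -> np.ndarray:
    """Independent outcome for every arm on the same trial (counterfactual
    feedback)."""
    u = rng.uniform(size=env.n_actions)
    return np.where(u < env.probs, env.r_mag, env.l_mag)


@dataclass(frozen=True)
class GambleOffer:
    """An instructed gamble versus a sure thing.

    The sure thing is the reference point: outcomes are encoded relative to
    it, so accepting the sure thing maps to outcome 0, winning the gamble to
    ``win_mag`` (> 0) and losing to ``lose_mag`` (< 0).
    """

    p_win: float
    certain: float = 0.0
    win_mag: float = 1.0
    lose_mag: float = -1.0
    trial_type: str = "plain"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_win <= 1.0:
            raise ValueError("p_win must lie in [0, 1]")

    @property
    def relative_ev(self) -> float:
        """Expected value of the gamble relative to the sure thing."""
        return self.p_win * self.win_mag + (1.0 - self.p_win) * self.lose_mag


def make_gamble_state(kind: Literal["high", "low"], rng: np.random.Generator) -> GambleOffer:
    """Draw a gamble state with win probability uniform above (high) or
    below (low) 50%."""
    if kind == "high":
        p_win = 1.0 - rng.uniform(0.0, 0.5)   # (0.5, 1]
    elif kind == "low":
        p_win = rng.uniform(0.0, 0.5)         # [0, 0.5)
    else:
        raise ValueError(f"kind must be 'high' or 'low', got {kind!r}")
    return GambleOffer(p_win=p_win, trial_type=kind)


@dataclass(frozen=True)
class ReplaySequence:
    """A fixed policy-and-reward sequence, stored as data so every agent can
    be driven through identical experience."""

    forced_actions: np.ndarray
    forced_rewards: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.forced_actions, dtype=int)
        r = np.asarray(self.forced_rewards, dtype=float)
        if a.shape != r.shape or a.ndim != 1:
            raise ValueError("forced_actions and forced_rewards must be equal-length vectors")
        object.__setattr__(self, "forced_actions", a)
        object.__setattr__(self, "forced_rewards", r)

    def __len__(self) -> int:
        return int(self.forced_actions.size)


@dataclass
class EnvSpec:
    """Serializable environment specification (key/value config form)."""

    kind: str = "rich"
    complexity: int = 2
    p_best: float | None = None
    p_sub: float | None = None
    r_mag: float = 1.0
    l_mag: float = 0.0
    seed: int | None = None

    def make(self) -> BanditEnv:
        return make_environment(
            self.kind, self.complexity, self.p_best, self.p_sub, self.r_mag, self.l_mag
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "complexity": self.complexity,
            "p_best": self.p_best,
            "p_sub": self.p_sub,
            "r_mag": self.r_mag,
            "l_mag": self.l_mag,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvSpec":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown environment spec keys: {sorted(unknown)}")
        return cls(**d)
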