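"""Comparison agents: Q-learning, UCB, risk-sensitive RL, Moller-Bogacz.

All agents expose the same contract as the OpAL* agent — ``policy()``,
``choose_from_uniform(u)``, ``learn(action, reward)``, ``trace()`` — so the
experiment harness is agent-agnostic.  The Q-learner additionally supports
full counterfactual feedback via ``observe_all``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .opal_core import softmax, choose_from_uniform

__all__ = [
    "QAgent",
    "UCBAgent",
    "RSRLAgent",
    "MollerBogaczAgent",
    "q_update",
    "rsrl_update",
    "run_q_batch",
]


def _midpoint(r_mag: float, l_mag: float) -> float:
    return 0.5 * (r_mag + l_mag)


# ---------------------------------------------------------------------------
# Q-learning


class QAgent:
    """TD(0) Q-learner with softmax choice.

    Values initialize at the reward-range midpoint (a neutral prior).  In
    full-information mode every arm is updated each trial with its own
    counterfactual outcome.
    """

    def __init__(
        self,
        n_actions: int,
        alpha: float = 0.1,
        beta: float = 5.0,
        r_mag: float = 1.0,
        l_mag: float = 0.0,
        q0: float | None = None,
    ):
        self.n_actions = n_actions
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.Q = np.full(n_actions, _midpoint(r_mag, l_mag) if q0 is None else q0)
        self._trace: list[np.ndarray] = []

    def policy(self) -> np.ndarray:
        return softmax(self.beta * self.Q)

    def choose(self, rng: np.random.Generator) -> int:
        return choose_from_uniform(self.policy(), rng.uniform())

    def choose_from_uniform(self, u: float) -> int:
        return choose_from_uniform(self.policy(), u)

    def learn(self, action: int, reward: float) -> None:
        q_update(self, action, reward)
        self._trace.append(self.Q.copy())

    def observe_all(self, rewards: np.ndarray) -> None:
        """Full-information update: every arm learns from its own outcome."""
        self.Q += self.alpha * (np.asarray(rewards, float) - self.Q)
        self._trace.append(self.Q.copy())

    def trace(self) -> dict[str, np.ndarray]:
        return {"Q": np.stack(self._trace) if self._trace else np.empty((0, self.n_actions))}


def q_update(s: QAgent, action: int, reward: float) -> QAgent:
    """Q(a) += alpha * (R - Q(a)) for the chosen action only."""
    s.Q[action] += s.alpha * (reward - s.Q[action])
    return s


# ---------------------------------------------------------------------------
# Upper Confidence Bound


class UCBAgent:
    """UCB on sample means: At = argmax[Q(a) + c*sqrt(ln t / N(a))].

    The first ``n_actions`` trials select each action once in a random
    order (fixed at construction); thereafter the bonus-augmented greedy
    rule applies, with ties broken uniformly at random from the choice
    uniform.  The trial index t is 1-based.
    """

    def __init__(self, n_actions: int, c: float = 1.0, rng: np.random.Generator | int = 0):
        self.n_actions = n_actions
        self.c = float(c)
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self._init_order = rng.permutation(n_actions)
        self.counts = np.zeros(n_actions, dtype=int)
        self.sums = np.zeros(n_actions)
        self.t = 0  # trials completed

    @property
    def means(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, self.sums / np.maximum(self.counts, 1), 0.0)

    def _scores(self) -> np.ndarray:
        t = self.t + 1  # 1-based index of the upcoming trial
        if t <= self.n_actions:
            s = np.full(self.n_actions, -np.inf)
            s[self._init_order[t - 1]] = 0.0
            return s
        bonus = self.c * np.sqrt(np.log(t) / self.counts)
        return self.means + bonus

    def policy(self) -> np.ndarray:
        """Degenerate policy: uniform over the argmax set."""
        s = self._scores()
        best = s == s.max()
        return best / best.sum()

    def choose(self, rng: np.random.Generator) -> int:
        return self.choose_from_uniform(rng.uniform())

    def choose_from_uniform(self, u: float) -> int:
        return choose_from_uniform(self.policy(), u)

    def learn(self, action: int, reward: float) -> None:
        self.counts[action] += 1
        self.sums[action] += reward
        self.t += 1

    def trace(self) -> dict[str, np.ndarray]:
        return {"counts": self.counts.copy(), "means": self.means}


# ---------------------------------------------------------------------------
# risk-sensitive RL


class RSRLAgent(QAgent):
    """Q-learning with separate learning rates for positive and negative
    prediction errors; alpha_pos = alpha_neg reduces exactly to Q-learning."""

    def __init__(
        self,
        n_actions: int,
        alpha_pos: float = 0.3,
        alpha_neg: float = 0.1,
        beta: float = 1.5,
        r_mag: float = 1.0,
        l_mag: float = -1.0,
        q0: float | None = None,
    ):
        super().__init__(n_actions, alpha=alpha_pos, beta=beta, r_mag=r_mag, l_mag=l_mag, q0=q0)
        self.alpha_pos = float(alpha_pos)
        self.alpha_neg = float(alpha_neg)

    def learn(self, action: int, reward: float) -> None:
        rsrl_update(self, action, reward)
        self._trace.append(self.Q.copy())


def rsrl_update(s: RSRLAgent, action: int, reward: float) -> RSRLAgent:
    pe = reward - s.Q[action]
    rate = s.alpha_pos if pe >= 0 else s.alpha_neg
    s.Q[action] += rate * pe
    return s


# ---------------------------------------------------------------------------
# Moller-Bogacz opponent model


class MollerBogaczAgent:
    """Opponent G/N model where weights converge to expected payoffs/costs.

    The prediction error is taken against the model's own combined action
    value, delta = R - V(a) with V(a) = D*G - (1-D)*N and D = 0.5, and the
    actors update as

        dG = alpha * f_eps(delta)  - lam * G
        dN = alpha * f_eps(-delta) - lam * N

    with f_eps(x) = x for x > 0 and eps*x for x < 0, decay applied to the
    chosen action only.  Choice is a softmax over beta * V(a).

    At the fixed point V(a) tracks the expected reward (like a Q value),
    while G + N tracks the expected |prediction error|; with the default
    relation eps = 1 - lam/alpha the G/N pair converges to the expected
    payoff and cost magnitudes (e.g. 0.5/0.5 for a 50% +1/-1 gamble).
    """

    def __init__(
        self,
        n_actions: int,
        alpha: float = 0.1,
        epsilon: float = 0.9,
        lam: float = 0.01,
        beta: float = 50.0,
        D: float = 0.5,
    ):
        self.n_actions = n_actions
        self.alpha = float(alpha)
        self.epsilon = float(epsilon)
        self.lam = float(lam)
        self.beta = float(beta)
        self.D = float(D)
        self.G = np.zeros(n_actions)
        self.N = np.zeros(n_actions)
        self._trace: list[dict] = []

    def _f(self, x: float) -> float:
        return x if x > 0 else self.epsilon * x

    def values(self) -> np.ndarray:
        return self.D * self.G - (1.0 - self.D) * self.N

    def policy(self) -> np.ndarray:
        return softmax(self.beta * self.values())

    def choose(self, rng: np.random.Generator) -> int:
        return choose_from_uniform(self.policy(), rng.uniform())

    def choose_from_uniform(self, u: float) -> int:
        return choose_from_uniform(self.policy(), u)

    def learn(self, action: int, reward: float) -> float:
        delta = reward - self.values()[action]
        self.G[action] += self.alpha * self._f(delta) - self.lam * self.G[action]
        self.N[action] += self.alpha * self._f(-delta) - self.lam * self.N[action]
        self._trace.append({"G": self.G.copy(), "N": self.N.copy(), "V": self.values()})
        return delta

    def trace(self) -> dict[str, np.ndarray]:
        if not self._trace:
            return {k: np.empty((0, self.n_actions)) for k in ("G", "N", "V")}
        return {k: np.stack([rec[k] for rec in self._trace]) for k in self._trace[0]}


def mb_update(s: MollerBogaczAgent, action: int, reward: float) -> MollerBogaczAgent:
    """Convenience alias: one learn step of the Moller-Bogacz agent."""
    s.learn(action, reward)
    return s


def mb_values(s: MollerBogaczAgent) -> np.ndarray:
    return s.values()


# ---------------------------------------------------------------------------
# vectorized Q-learning batch (for convergence / action-gap analyses)


@dataclass
class QBatchResult:
    p_best: np.ndarray            # (R, T) policy prob of optimal arm, pre-choice
    Q: np.ndarray                 # (R, A) final values
    Q_trace: np.ndarray | None    # (R, T, A) post-update values, on request


def run_q_batch(
    probs: np.ndarray,
    n_trials: int,
    alpha,
    beta,
    *,
    full_info: bool = False,
    r_mag: float = 1.0,
    l_mag: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    record_traces: bool = False,
) -> QBatchResult:
    """Lock-step batch of softmax Q-learners.

    Follows the same per-trial uniform-block convention as the OpAL batch
    runner, so Q-learning runs can be seed-paired with OpAL runs.
    """
    probs = np.asarray(probs, dtype=float)
    A = probs.size
    alpha, beta = np.broadcast_arrays(np.asarray(alpha, float), np.asarray(beta, float))
    shape = alpha.shape
    alpha = alpha.reshape(-1)
    beta = beta.reshape(-1)
    R = alpha.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Q = np.full((R, A), 0.5 * (r_mag + l_mag))
    p_best = np.empty((R, n_trials), dtype=np.float32)
    Q_tr = np.empty((R, n_trials, A), dtype=np.float32) if record_traces else None
    rows = np.arange(R)
    best = int(np.argmax(probs))

    for t in range(n_trials):
        act = beta[:, None] * Q
        act = act - act.max(axis=1, keepdims=True)
        p = np.exp(act)
        p /= p.sum(axis=1, keepdims=True)
        p_best[:, t] = p[:, best]

        u = rng.uniform(size=(R, A + 1))
        outcomes = np.where(u[:, :A] < probs[None, :], r_mag, l_mag)
        if full_info:
            Q += alpha[:, None] * (outcomes - Q)
        else:
            a = np.minimum((u[:, A, None] >= np.cumsum(p, axis=1)).sum(axis=1), A - 1)
            reward = outcomes[rows, a]
            Q[rows, a] += alpha * (reward - Q[rows, a])
        if record_traces:
            Q_tr[:, t] = Q

    return QBatchResult(
        p_best=p_best.reshape(shape + (n_trials,)),
        Q=Q.reshape(shape + (A,)),
        Q_trace=None if Q_tr is None else Q_tr.reshape(shape + (n_trials, A)),
    )
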