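"""OpAL*: opponent actor-critic with dynamic dopaminergic modulation.

The model is a modified actor-critic of the basal ganglia.  A critic learns
expected action values V(a) and emits reward prediction errors (RPEs).  Two
opponent actors accumulate those RPEs with three-factor Hebbian updates:

    G(a) <- G(a) + alpha_G(t) * G(a) * f(+delta)      ("Go" / D1, benefits)
    N(a) <- N(a) + alpha_N(t) * N(a) * f(-delta)      ("NoGo" / D2, costs)

where f normalizes the RPE by the reward range.  The Hebbian factor (the
current weight multiplying the update) makes the G actor convex in reward
probability at the high end and the N actor convex at the low end, so each
actor specializes at discriminating options in its half of the probability
range.

A Bayesian *meta-critic* tracks the reward rate of the environment as a
whole — a Beta(eta, gamma) posterior over p(reward), updated every trial
regardless of which action was taken.  Once the posterior is confidently
above or below 0.5, the dopaminergic state

    rho = S * (E[X] - 0.5) * k,     S in {0, 1}

amplifies the actor best specialized for the environment at choice time via

    Act(a) = beta_g * G(a) - beta_n * N(a),
    beta_g = beta * max(0, 1 + rho),   beta_n = beta * max(0, 1 - rho),

and actions are drawn from a softmax over Act.  The meta-critic's posterior
variance also anneals the actor learning rates, stabilizing the weights as
uncertainty shrinks.

Two ablations are expressed as configuration flags: ``OpAL+`` fixes rho = 0
(no dopamine modulation) and ``No Hebb`` drops the Hebbian factor from the
actor updates (which renders the two actors redundant mirror images).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bandit_envs import BanditEnv

__all__ = [
    "CriticState",
    "MetaCriticState",
    "DopamineControl",
    "ActorState",
    "OpalConfig",
    "OpalAgent",
    "BatchResult",
    "critic_update",
    "meta_critic_update",
    "beta_moments",
    "compute_rho",
    "anneal_rate",
    "normalize_rpe",
    "actor_update",
    "act_values",
    "softmax",
    "choose",
    "choose_from_uniform",
    "gamble_accept_prob",
    "expanded_weight_update",
    "run_opal_batch",
]


# ---------------------------------------------------------------------------
# state containers


@dataclass
class CriticState:
    """Per-action expected-value estimates and the critic learning rate."""

    V: np.ndarray
    alpha_c: float
    last_delta: float = 0.0

    @classmethod
    def create(cls, n_actions: int, alpha_c: float, v0: float) -> "CriticState":
        return cls(V=np.full(n_actions, float(v0)), alpha_c=float(alpha_c))


@dataclass
class MetaCriticState:
    """Beta-distribution posterior over the environment-wide reward rate."""

    eta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.gamma <= 0:
            raise ValueError("beta hyperparameters must be strictly positive")

    @property
    def mean(self) -> float:
        return self.eta / (self.eta + self.gamma)

    @property
    def var(self) -> float:
        s = self.eta + self.gamma
        return self.eta * self.gamma / (s * s * (s + 1.0))

    @property
    def std(self) -> float:
        return math.sqrt(self.var)


@dataclass
class DopamineControl:
    """Dopaminergic state rho and the resulting actor gains.

    ``rho_baseline`` and ``rho_offset`` default to 0; they model tonic
    phenotype differences and choice-period manipulations (e.g. optogenetic
    D2 stimulation) in the rodent risky-choice simulation.
    """

    beta: float
    k: float = 20.0
    phi: float = 1.0
    rho: float = 0.0
    S: int = 0
    rho_baseline: float = 0.0
    rho_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("softmax gain beta must be positive")
        if self.k < 0 or self.phi < 0:
            raise ValueError("k and phi must be nonnegative")

    @property
    def beta_g(self) -> float:
        return self.beta * max(0.0, 1.0 + self.rho)

    @property
    def beta_n(self) -> float:
        return self.beta * max(0.0, 1.0 - self.rho)


@dataclass
class ActorState:
    """Nonnegative opponent weight vectors and actor hyperparameters."""

    G: np.ndarray
    N: np.ndarray
    alpha_g: float
    alpha_n: float
    T: float = 10.0
    hebbian: bool = True
    r_mag: float = 1.0
    l_mag: float = 0.0

    @classmethod
    def create(
        cls,
        n_actions: int,
        alpha_g: float,
        alpha_n: float,
        T: float = 10.0,
        hebbian: bool = True,
        r_mag: float = 1.0,
        l_mag: float = 0.0,
        g0: float = 1.0,
        n0: float = 1.0,
    ) -> "ActorState":
        return cls(
            G=np.full(n_actions, float(g0)),
            N=np.full(n_actions, float(n0)),
            alpha_g=float(alpha_g),
            alpha_n=float(alpha_n),
            T=float(T),
            hebbian=hebbian,
            r_mag=float(r_mag),
            l_mag=float(l_mag),
        )


@dataclass
class OpalConfig:
    """Full agent configuration.

    Variants: OpAL* = modulation and hebbian both on; OpAL+ = modulation
    off (rho = 0 throughout); No Hebb = modulation on, hebbian off.
    """

    n_actions: int
    alpha_c: float = 0.05
    alpha_g: float = 0.1
    alpha_n: float = 0.1
    beta: float = 5.0
    T: float = 10.0
    k: float = 20.0
    phi: float = 1.0
    modulation: bool = True
    hebbian: bool = True
    r_mag: float = 1.0
    l_mag: float = 0.0
    v0: float | None = None       # default: reward-range midpoint
    g0: float = 1.0
    n0: float = 1.0
    eta0: float = 1.0             # Beta(1, 1) uniform prior
    gamma0: float = 1.0
    rho_baseline: float = 0.0
    rho_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.r_mag > self.l_mag:
            raise ValueError("r_mag must exceed l_mag")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def variant(self) -> str:
        if self.modulation and self.hebbian:
            return "opal_star"
        if self.hebbian:
            return "opal_plus"
        return "no_hebb"

    @classmethod
    def for_variant(cls, variant: str, n_actions: int, **kwargs) -> "OpalConfig":
        flags = {
            "opal_star": dict(modulation=True, hebbian=True),
            "opal_plus": dict(modulation=False, hebbian=True),
            "no_hebb": dict(modulation=True, hebbian=False),
        }
        if variant not in flags:
            raise ValueError(f"unknown variant {variant!r}")
        return cls(n_actions=n_actions, **flags[variant], **kwargs)


# ---------------------------------------------------------------------------
# elementary operations


def critic_update(c: CriticState, action: int, reward: float) -> tuple[CriticState, float]:
    """Standard delta-rule update of the chosen action's value; returns the RPE."""
    delta = float(reward) - c.V[action]
    c.V[action] += c.alpha_c * delta
    c.last_delta = delta
    return c, delta


def meta_critic_update(m: MetaCriticState, reward_indicator: int) -> MetaCriticState:
    """Add one success/failure count to the beta posterior.

    Runs every trial regardless of which action was taken; the meta-critic
    is agnostic to action history.
    """
    if reward_indicator not in (0, 1):
        raise ValueError("reward_indicator must be 0 or 1")
    m.eta += reward_indicator
    m.gamma += 1 - reward_indicator
    return m


def beta_moments(eta, gamma):
    """Vectorized mean and variance of Beta(eta, gamma)."""
    eta = np.asarray(eta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    s = eta + gamma
    mean = eta / s
    var = eta * gamma / (s * s * (s + 1.0))
    return mean, var


def compute_rho(m: MetaCriticState, d: DopamineControl) -> DopamineControl:
    """Gate and set the dopaminergic state from the meta-critic posterior.

    The gate S opens only once the phi-scaled credible interval around the
    posterior mean excludes 0.5; rho then scales with the (signed) distance
    of the mean from 0.5.
    """
    mean, std = m.mean, m.std
    if mean - d.phi * std > 0.5 or mean + d.phi * std < 0.5:
        d.S = 1
    else:
        d.S = 0
    d.rho = d.rho_baseline + d.S * (mean - 0.5) * d.k + d.rho_offset
    return d


def anneal_rate(base_alpha: float, m: MetaCriticState, T: float) -> float:
    """Actor learning rate annealed by meta-critic uncertainty.

    alpha(t) = alpha / (1 + 1 / (T * std(X))).  As the posterior spread
    shrinks the effective rate goes to zero; large T delays annealing and
    T -> inf recovers the base rate.  The posterior standard deviation is
    the adopted uncertainty scale: it anneals gently enough that learning
    continues over hundreds of trials while still stabilizing the Hebbian
    weights against decay (see the methods note for this design choice).
    """
    if T <= 0:
        raise ValueError("annealing parameter T must be positive")
    std = m.std
    if std <= 0:
        return 0.0
    return base_alpha / (1.0 + 1.0 / (T * std))


def normalize_rpe(delta: float, r_mag: float, l_mag: float) -> float:
    """Scale the RPE by the range of available reward values."""
    if not r_mag > l_mag:
        raise ValueError("r_mag must exceed l_mag")
    return delta / (r_mag - l_mag)


def actor_update(a: ActorState, m: MetaCriticState, action: int, delta: float) -> ActorState:
    """Three-factor (or, with hebbian off, plain) actor update of the chosen action.

    Weights are floored at zero after each update (firing rates cannot go
    negative).
    """
    f = normalize_rpe(delta, a.r_mag, a.l_mag)
    ag = anneal_rate(a.alpha_g, m, a.T)
    an = anneal_rate(a.alpha_n, m, a.T)
    hg = a.G[action] if a.hebbian else 1.0
    hn = a.N[action] if a.hebbian else 1.0
    a.G[action] = max(0.0, a.G[action] + ag * hg * f)
    a.N[action] = max(0.0, a.N[action] + an * hn * (-f))
    return a


def act_values(a: ActorState, d: DopamineControl) -> np.ndarray:
    """Per-action decision variable Act(a) = beta_g*G(a) - beta_n*N(a)."""
    return d.beta_g * a.G - d.beta_n * a.N


def softmax(act: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized softmax (invariant to constant shifts)."""
    act = np.asarray(act, dtype=float)
    z = act - act.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def choose_from_uniform(p: np.ndarray, u: float) -> int:
    """Invert the policy's CDF at a pre-drawn uniform.

    Uses the same comparison as the vectorized batch runner so that a batch
    of size one is bit-identical to the object-level loop.
    """
    cum = np.cumsum(p)
    return min(int(np.sum(u >= cum)), p.size - 1)


def choose(act: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an action from the softmax over Act values."""
    return choose_from_uniform(softmax(act), rng.uniform())


def gamble_accept_prob(act_gamble: float) -> float:
    """Two-option softmax with the sure thing's Act fixed at 0."""
    return 1.0 / (1.0 + math.exp(-act_gamble))


def expanded_weight_update(
    delta_history: Sequence[float], base_alpha: float, t: int | None = None
) -> float:
    """Non-recursive form of the Hebbian G-weight change at trial ``t``.

    With initial weight 1 and constant learning rate, the recursive update
    G <- G + alpha*G*delta implies

        dG_t = alpha*delta_t * (1 + sum_i alpha*delta_i
                                  + sum_{i<j} alpha^2 delta_i delta_j + ...
                                  + prod_i alpha*delta_i),

    summing over all subsets of the prior RPEs delta_1..delta_{t-1}.  The
    explicit subset expansion is exponential in t, so the history is capped;
    this function exists as an independent oracle for the recursive path.
    """
    deltas = list(delta_history)
    if t is None:
        t = len(deltas)
    if not 1 <= t <= len(deltas):
        raise ValueError("t must index into delta_history")
    prior = [base_alpha * d for d in deltas[: t - 1]]
    if len(prior) > 20:
        raise ValueError("expanded form is exponential; history capped at 20")
    total = 0.0
    for r in range(len(prior) + 1):
        for combo in itertools.combinations(prior, r):
            total += math.prod(combo)
    return base_alpha * deltas[t - 1] * total


# ---------------------------------------------------------------------------
# the agent


class OpalAgent:
    """Object-level OpAL* agent implementing the common act/learn contract.

    Per-trial order of operations in :meth:`learn`: critic update ->
    meta-critic update -> dopaminergic state and annealed learning rates ->
    actor update.  The choice on the next trial therefore uses gains that
    reflect all outcomes observed so far.
    """

    def __init__(self, config: OpalConfig):
        self.config = config
        v0 = 0.5 * (config.r_mag + config.l_mag) if config.v0 is None else config.v0
        self.critic = CriticState.create(config.n_actions, config.alpha_c, v0)
        self.meta = MetaCriticState(eta=config.eta0, gamma=config.gamma0)
        self.dopamine = DopamineControl(
            beta=config.beta,
            k=config.k,
            phi=config.phi,
            rho_baseline=config.rho_baseline,
            rho_offset=config.rho_offset,
        )
        self.actors = ActorState.create(
            config.n_actions,
            config.alpha_g,
            config.alpha_n,
            T=config.T,
            hebbian=config.hebbian,
            r_mag=config.r_mag,
            l_mag=config.l_mag,
            g0=config.g0,
            n0=config.n0,
        )
        self._refresh_rho()
        self._trace: list[dict] = []

    @property
    def n_actions(self) -> int:
        return self.config.n_actions

    def _refresh_rho(self) -> None:
        if self.config.modulation:
            compute_rho(self.meta, self.dopamine)
        else:
            self.dopamine.S = 0
            self.dopamine.rho = (
                self.dopamine.rho_baseline + self.dopamine.rho_offset
            )

    def act_scores(self) -> np.ndarray:
        return act_values(self.actors, self.dopamine)

    def policy(self) -> np.ndarray:
        """Softmax choice probabilities from the current Act values."""
        return softmax(self.act_scores())

    def choose(self, rng: np.random.Generator) -> int:
        return choose_from_uniform(self.policy(), rng.uniform())

    def choose_from_uniform(self, u: float) -> int:
        return choose_from_uniform(self.policy(), u)

    def learn(self, action: int, reward: float) -> float:
        """Observe the outcome of ``action`` and update all components;
        returns the critic RPE."""
        _, delta = critic_update(self.critic, action, reward)
        meta_critic_update(self.meta, int(reward > self.config.l_mag))
        self._refresh_rho()
        actor_update(self.actors, self.meta, action, delta)
        self._trace.append(
            {
                "action": action,
                "reward": reward,
                "delta": delta,
                "rho": self.dopamine.rho,
                "V": self.critic.V.copy(),
                "G": self.actors.G.copy(),
                "N": self.actors.N.copy(),
            }
        )
        return delta

    def trace(self) -> dict[str, np.ndarray]:
        """Per-trial records as stacked arrays."""
        if not self._trace:
            return {k: np.empty(0) for k in ("action", "reward", "delta", "rho", "V", "G", "N")}
        return {
            k: np.stack([rec[k] for rec in self._trace])
            for k in self._trace[0]
        }


# ---------------------------------------------------------------------------
# vectorized batch runner


@dataclass
class BatchResult:
    """Output of a vectorized batch of simulations.

    ``p_best`` holds the policy's probability of the optimal arm before
    each choice, shape (n_runs, n_trials).  Weight/value traces are
    recorded only on request (shape (n_runs, n_trials, n_actions),
    post-update values).
    """

    p_best: np.ndarray
    G: np.ndarray
    N: np.ndarray
    V: np.ndarray
    rho: np.ndarray | None = None
    choices: np.ndarray | None = None
    rewards: np.ndarray | None = None
    G_trace: np.ndarray | None = None
    N_trace: np.ndarray | None = None
    V_trace: np.ndarray | None = None


def run_opal_batch(
    probs: np.ndarray,
    n_trials: int,
    alpha_c,
    alpha_a,
    beta,
    *,
    hebbian: bool = True,
    modulation: bool = True,
    T: float = 10.0,
    k: float = 20.0,
    phi: float = 1.0,
    r_mag: float = 1.0,
    l_mag: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    record_traces: bool = False,
    record_run: bool = False,
) -> BatchResult:
    """Run many independent OpAL-family simulations in lock-step.

    ``alpha_c``, ``alpha_a`` and ``beta`` broadcast against each other; one
    run is simulated per element of the broadcast shape.  All runs share the
    environment ``probs`` (optimal arm first).

    Randomness follows the paired-seed contract: each trial consumes one
    (n_runs, n_actions + 1) block of uniforms — a counterfactual outcome
    draw per arm plus a choice draw — so two calls with the same seed (e.g.
    OpAL* and its OpAL+ control) consume identical randomness, and a batch
    of size one reproduces the object-level agent exactly.
    """
    probs = np.asarray(probs, dtype=float)
    A = probs.size
    alpha_c, alpha_a, beta = np.broadcast_arrays(
        np.asarray(alpha_c, float), np.asarray(alpha_a, float), np.asarray(beta, float)
    )
    shape = alpha_c.shape
    alpha_c = alpha_c.reshape(-1).copy()
    alpha_a = alpha_a.reshape(-1).copy()
    beta = beta.reshape(-1).copy()
    R = alpha_c.size

    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    rng_range = r_mag - l_mag
    if rng_range <= 0:
        raise ValueError("r_mag must exceed l_mag")

    V = np.full((R, A), 0.5 * (r_mag + l_mag))
    G = np.ones((R, A))
    N = np.ones((R, A))
    eta = np.ones(R)
    gam = np.ones(R)

    p_best = np.empty((R, n_trials), dtype=np.float32)
    rho_tr = np.empty((R, n_trials), dtype=np.float32) if record_run else None
    choices = np.empty((R, n_trials), dtype=np.int16) if record_run else None
    rewards = np.empty((R, n_trials), dtype=np.float32) if record_run else None
    G_tr = np.empty((R, n_trials, A), dtype=np.float32) if record_traces else None
    N_tr = np.empty((R, n_trials, A), dtype=np.float32) if record_traces else None
    V_tr = np.empty((R, n_trials, A), dtype=np.float32) if record_traces else None

    rows = np.arange(R)
    best = int(np.argmax(probs))

    for t in range(n_trials):
        # dopaminergic state from the current posterior
        s = eta + gam
        mean = eta / s
        var = eta * gam / (s * s * (s + 1.0))
        if modulation:
            std = np.sqrt(var)
            S = (mean - phi * std > 0.5) | (mean + phi * std < 0.5)
            rho = S * (mean - 0.5) * k
        else:
            rho = np.zeros(R)
        bg = beta * np.maximum(0.0, 1.0 + rho)
        bn = beta * np.maximum(0.0, 1.0 - rho)

        act = bg[:, None] * G - bn[:, None] * N
        act -= act.max(axis=1, keepdims=True)
        p = np.exp(act)
        p /= p.sum(axis=1, keepdims=True)
        p_best[:, t] = p[:, best]

        u = rng.uniform(size=(R, A + 1))
        a = np.minimum((u[:, A, None] >= np.cumsum(p, axis=1)).sum(axis=1), A - 1)
        reward = np.where(u[rows, a] < probs[a], r_mag, l_mag)

        delta = reward - V[rows, a]
        V[rows, a] += alpha_c * delta

        succ = reward > l_mag
        eta += succ
        gam += ~succ

        # annealing uses the refreshed posterior spread
        s = eta + gam
        var = eta * gam / (s * s * (s + 1.0))
        aeff = alpha_a / (1.0 + 1.0 / (T * np.sqrt(var)))

        f = delta / rng_range
        hg = G[rows, a] if hebbian else 1.0
        hn = N[rows, a] if hebbian else 1.0
        G[rows, a] = np.maximum(0.0, G[rows, a] + aeff * hg * f)
        N[rows, a] = np.maximum(0.0, N[rows, a] + aeff * hn * (-f))

        if record_run:
            rho_tr[:, t] = rho
            choices[:, t] = a
            rewards[:, t] = reward
        if record_traces:
            G_tr[:, t] = G
            N_tr[:, t] = N
            V_tr[:, t] = V

    return BatchResult(
        p_best=p_best.reshape(shape + (n_trials,)),
        G=G.reshape(shape + (A,)),
        N=N.reshape(shape + (A,)),
        V=V.reshape(shape + (A,)),
        rho=None if rho_tr is None else rho_tr.reshape(shape + (n_trials,)),
        choices=None if choices is None else choices.reshape(shape + (n_trials,)),
        rewards=None if rewards is None else rewards.reshape(shape + (n_trials,)),
        G_trace=None if G_tr is None else G_tr.reshape(shape + (n_trials, A)),
        N_trace=None if N_tr is None else N_tr.reshape(shape + (n_trials, A)),
        V_trace=None if V_tr is None else V_tr.reshape(shape + (n_trials, A)),
    )
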