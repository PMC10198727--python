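"""Risky-choice and transfer simulations of empirical phenomena.

Four paradigms, all driven by the same opponent machinery:

* **Adaptive gambling** — repeated offers of the same gamble; dopamine
  modulation by the meta-critic's estimate of the gamble's reward rate lets
  the agent infer when gambling is advantageous.
* **Context-dependent transfer** — options learned in gain or loss contexts
  with partial or complete feedback; a per-context critic yields
  relative-value prediction errors that reproduce the counterintuitive
  preference for a frequent loss-avoider over an infrequent gain earner
  under complete information only.
* **Rodent risky choice** — certain option versus a 50/50 double-or-nothing
  gamble; tonic-dopamine phenotypes (risk-seeking / risk-averse), a
  choice-period D2-stimulation proxy (rho decreased by 1), and a
  risk-sensitive RL comparison that predicts the opposite stimulation
  effect in risk-averse agents.
* **Instructed human gambles** — offer-value-driven dopamine state for
  L-DOPA dose effects on gain-trial gambling (with per-subject dose
  correlation) and for environmental-richness effects on matched common
  trials.

In the instructed paradigms the G/N weights are set directly from the
offer, encoded relative to the sure thing: G is the potential relative
gain, N the magnitude of the potential relative loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .opal_core import beta_moments

__all__ = [
    "AdaptiveGambleResult",
    "PalminteriResult",
    "ZalocuskyResult",
    "RutledgeResult",
    "FrydmanResult",
    "simulate_adaptive_gamble",
    "simulate_palminteri",
    "simulate_zalocusky",
    "simulate_rutledge",
    "simulate_frydman",
]

_sigmoid = lambda x: 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# adaptive gamble acceptance


@dataclass
class AdaptiveGambleResult:
    kind: str
    accept_opal_star: np.ndarray   # (n_trials,) mean acceptance probability
    accept_opal_plus: np.ndarray

    def checks(self) -> dict[str, bool]:
        late = slice(-10, None)
        diff = float(
            self.accept_opal_star[late].mean() - self.accept_opal_plus[late].mean()
        )
        if self.kind == "high":
            return {"opal_star_gambles_more_late": diff > 0}
        return {"opal_star_gambles_less_late": diff < 0}


def simulate_adaptive_gamble(
    kind: str = "high",
    n_states: int = 1000,
    n_trials: int = 50,
    alpha_c: float = 0.05,
    alpha_a: float = 0.1,
    beta: float = 5.0,
    T: float = 10.0,
    k: float = 20.0,
    phi: float = 1.5,
    seed: int | np.random.SeedSequence = 0,
    p_win: float | np.ndarray | None = None,
) -> AdaptiveGambleResult:
    """Present the same gamble for ``n_trials`` trials in many states.

    Gamble outcomes are encoded relative to the sure thing (+1 win, -1
    loss, sure = 0).  Win probability is drawn uniformly above 0.5 (high
    states) or below 0.5 (low states) unless ``p_win`` is given.  The
    meta-critic tracks the gamble's reward rate; the critic and actors
    learn only from experienced gamble outcomes.  OpAL* (dopamine
    modulation on) and OpAL+ (rho = 0) consume identical random draws.
    """
    rng = np.random.default_rng(seed)
    if p_win is None:
        if kind == "high":
            pw = 1.0 - rng.uniform(0.0, 0.5, size=n_states)
        elif kind == "low":
            pw = rng.uniform(0.0, 0.5, size=n_states)
        else:
            raise ValueError("kind must be 'high' or 'low'")
    else:
        pw = np.broadcast_to(np.asarray(p_win, float), (n_states,)).copy()
    u = rng.uniform(size=(n_trials, n_states, 2))  # choice, outcome — shared draws

    curves = {}
    for modulation in (True, False):
        V = np.zeros(n_states)
        G = np.ones(n_states)
        N = np.ones(n_states)
        eta = np.ones(n_states)
        gam = np.ones(n_states)
        curve = np.empty(n_trials)
        for t in range(n_trials):
            mean, var = beta_moments(eta, gam)
            if modulation:
                std = np.sqrt(var)
                S = (mean - phi * std > 0.5) | (mean + phi * std < 0.5)
                rho = S * (mean - 0.5) * k
            else:
                rho = np.zeros(n_states)
            bg = beta * np.maximum(0.0, 1.0 + rho)
            bn = beta * np.maximum(0.0, 1.0 - rho)
            p_acc = _sigmoid(bg * G - bn * N)
            curve[t] = p_acc.mean()

            took = u[t, :, 0] < p_acc
            win = u[t, :, 1] < pw
            reward = np.where(win, 1.0, -1.0)
            delta = np.where(took, reward - V, 0.0)
            V += alpha_c * delta
            eta += took & win
            gam += took & ~win
            _, var = beta_moments(eta, gam)
            aeff = alpha_a / (1.0 + 1.0 / (T * np.sqrt(var)))
            f = delta / 2.0
            G = np.maximum(0.0, G + np.where(took, aeff * G * f, 0.0))
            N = np.maximum(0.0, N + np.where(took, aeff * N * (-f), 0.0))
        curves[modulation] = curve

    return AdaptiveGambleResult(
        kind=kind, accept_opal_star=curves[True], accept_opal_plus=curves[False]
    )


# ---------------------------------------------------------------------------
# context-dependent transfer preferences


STIMULI = ("G75c", "G25c", "L25c", "L75c", "G75p", "G25p", "L25p", "L75p")
#: (p of the non-zero outcome, outcome magnitude, complete information)
_STIM_SPEC = {
    "G75c": (0.75, 1.0, True),
    "G25c": (0.25, 1.0, True),
    "L25c": (0.25, -1.0, True),
    "L75c": (0.75, -1.0, True),
    "G75p": (0.75, 1.0, False),
    "G25p": (0.25, 1.0, False),
    "L25p": (0.25, -1.0, False),
    "L75p": (0.75, -1.0, False),
}
_CONTEXTS = (("G75c", "G25c"), ("L25c", "L75c"), ("G75p", "G25p"), ("L25p", "L75p"))


@dataclass
class PalminteriResult:
    preference: np.ndarray      # (8, 8) mean p(row preferred over column)
    stimuli: tuple[str, ...] = STIMULI

    def pref(self, a: str, b: str) -> float:
        return float(self.preference[self.stimuli.index(a), self.stimuli.index(b)])

    def checks(self) -> dict[str, bool]:
        return {
            "complete_info_loss_avoider_preferred": self.pref("L25c", "G25c") > 0.5,
            "partial_info_follows_expected_value": self.pref("G25p", "L25p") > 0.5,
            "gain_dominance_within_context": self.pref("G75c", "G25c") > 0.5
            and self.pref("G75p", "G25p") > 0.5,
            "loss_dominance_within_context": self.pref("L25c", "L75c") > 0.5
            and self.pref("L25p", "L75p") > 0.5,
        }


def simulate_palminteri(
    n_sims: int = 200,
    n_trials: int = 40,
    alpha_c_partial: float = 0.05,
    alpha_c_complete: float = 0.5,
    alpha_a: float = 0.1,
    beta: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
) -> PalminteriResult:
    """Four learning contexts (gain/loss x partial/complete feedback)
    followed by pairwise transfer choices among all eight stimuli.

    The critic is per-context, so prediction errors are relative to context
    value.  Complete feedback uses a fast critic (the context value is
    learned quickly from both outcomes) and updates the unchosen stimulus's
    actors with its own counterfactual RPE.  Transfer preferences are
    softmax in Act with balanced dopamine (rho = 0).
    """
    rng = np.random.default_rng(seed)
    n_stim = len(STIMULI)
    pref_acc = np.zeros((n_stim, n_stim))

    for _ in range(n_sims):
        G = np.ones(n_stim)
        N = np.ones(n_stim)
        for pair in _CONTEXTS:
            i, j = (STIMULI.index(s) for s in pair)
            complete = _STIM_SPEC[pair[0]][2]
            alpha_c = alpha_c_complete if complete else alpha_c_partial
            V = 0.0
            for _t in range(n_trials):
                act = beta * (G[[i, j]] - N[[i, j]])
                p_i = _sigmoid(act[0] - act[1])
                chosen, other = (i, j) if rng.uniform() < p_i else (j, i)
                outcomes = {}
                for s_idx in (i, j):
                    p_out, mag, _ = _STIM_SPEC[STIMULI[s_idx]]
                    outcomes[s_idx] = mag if rng.uniform() < p_out else 0.0
                updates = (chosen, other) if complete else (chosen,)
                for s_idx in updates:
                    f = outcomes[s_idx] - V  # stimulus RPE vs context value
                    G[s_idx] = max(0.0, G[s_idx] + alpha_a * G[s_idx] * f)
                    N[s_idx] = max(0.0, N[s_idx] + alpha_a * N[s_idx] * (-f))
                # context value learns from what was observed this trial
                target = 0.5 * (outcomes[i] + outcomes[j]) if complete else outcomes[chosen]
                V += alpha_c * (target - V)
        act = beta * (G - N)
        pref_acc += _sigmoid(act[:, None] - act[None, :])

    return PalminteriResult(preference=pref_acc / n_sims)


# ---------------------------------------------------------------------------
# rodent risky choice with D2 manipulation


@dataclass
class ZalocuskyPhenotype:
    p_gamble: float
    p_post_win: float
    p_post_loss: float
    d2_post_win: float
    d2_post_loss: float


@dataclass
class ZalocuskyResult:
    """Gamble rates, outcome-conditioned rates and the D2-activity proxy
    (beta_n * N at decision) for OpAL* and RSRL, with and without the
    choice-period D2-stimulation proxy."""

    opal: dict[str, dict[str, ZalocuskyPhenotype]]
    rsrl: dict[str, dict[str, float]]

    def checks(self) -> dict[str, bool]:
        base = self.opal["none"]
        stim = self.opal["d2_stim"]
        rs, ra = base["risk_seeking"], base["risk_averse"]
        out = {
            "post_loss_risk_reduction": rs.p_post_loss < rs.p_post_win
            and ra.p_post_loss < ra.p_post_win,
            "d2_proxy_larger_after_loss": rs.d2_post_loss > rs.d2_post_win
            and ra.d2_post_loss > ra.d2_post_win,
            "stim_reduces_gambling_both_phenotypes": (
                stim["risk_seeking"].p_gamble < rs.p_gamble
                and stim["risk_averse"].p_gamble < ra.p_gamble
            ),
            "stim_effect_stronger_when_risk_seeking": (
                rs.p_gamble - stim["risk_seeking"].p_gamble
                > ra.p_gamble - stim["risk_averse"].p_gamble
            ),
            "rsrl_dissociation": (
                self.rsrl["d2_stim"]["risk_seeking"] < self.rsrl["none"]["risk_seeking"]
                and self.rsrl["d2_stim"]["risk_averse"] > self.rsrl["none"]["risk_averse"]
            ),
        }
        return out


_PHENO_RHO = {"risk_seeking": 0.85, "risk_averse": -0.75}
_PHENO_RSRL = {"risk_seeking": (0.3, 0.1), "risk_averse": (0.1, 0.3)}


def _zalocusky_opal(
    rho_baseline: float,
    rho_offset: float,
    n_sims: int,
    n_trials: int,
    rng: np.random.Generator,
    beta: float = 1.5,
    alpha: float = 1.0,
    alpha_actor: float = 0.5,
    T: float = 20.0,
    k: float = 1.1,
    phi: float = 1.0,
) -> ZalocuskyPhenotype:
    V = np.zeros(n_sims)
    G = np.ones(n_sims)
    N = np.ones(n_sims)
    eta = np.ones(n_sims)
    gam = np.ones(n_sims)
    u = rng.uniform(size=(n_trials, n_sims, 2))

    p_all, p_pw, p_pl, d2_pw, d2_pl = [], [], [], [], []
    prev_outcome = np.full(n_sims, np.nan)  # +1 win, -1 loss, nan = sure/none
    for t in range(n_trials):
        mean, var = beta_moments(eta, gam)
        std = np.sqrt(var)
        S = (mean - phi * std > 0.5) | (mean + phi * std < 0.5)
        rho = rho_baseline + S * (mean - 0.5) * k + rho_offset
        bg = beta * np.maximum(0.0, 1.0 + rho)
        bn = beta * np.maximum(0.0, 1.0 - rho)
        p_acc = _sigmoid(bg * G - bn * N)
        d2 = bn * N

        p_all.append(p_acc.mean())
        after_win = prev_outcome == 1.0
        after_loss = prev_outcome == -1.0
        if after_win.any():
            p_pw.append(p_acc[after_win].mean())
            d2_pw.append(d2[after_win].mean())
        if after_loss.any():
            p_pl.append(p_acc[after_loss].mean())
            d2_pl.append(d2[after_loss].mean())

        took = u[t, :, 0] < p_acc
        win = u[t, :, 1] < 0.5
        reward = np.where(win, 1.0, -1.0)
        delta = np.where(took, reward - V, 0.0)
        V += alpha * delta
        eta += took & win
        gam += took & ~win
        _, var = beta_moments(eta, gam)
        aeff = alpha_actor / (1.0 + 1.0 / (T * np.sqrt(var)))
        f = delta / 2.0
        G = np.maximum(0.0, G + np.where(took, aeff * G * f, 0.0))
        N = np.maximum(0.0, N + np.where(took, aeff * N * (-f), 0.0))
        prev_outcome = np.where(took, reward, np.nan)

    return ZalocuskyPhenotype(
        p_gamble=float(np.mean(p_all)),
        p_post_win=float(np.mean(p_pw)),
        p_post_loss=float(np.mean(p_pl)),
        d2_post_win=float(np.mean(d2_pw)),
        d2_post_loss=float(np.mean(d2_pl)),
    )


def _zalocusky_rsrl(
    alpha_pos: float,
    alpha_neg: float,
    beta: float,
    n_sims: int,
    n_trials: int,
    rng: np.random.Generator,
) -> float:
    Q = np.zeros(n_sims)
    u = rng.uniform(size=(n_trials, n_sims, 2))
    p_all = []
    for t in range(n_trials):
        p_acc = _sigmoid(beta * Q)
        p_all.append(p_acc.mean())
        took = u[t, :, 0] < p_acc
        reward = np.where(u[t, :, 1] < 0.5, 1.0, -1.0)
        pe = np.where(took, reward - Q, 0.0)
        rate = np.where(pe >= 0, alpha_pos, alpha_neg)
        Q += rate * pe
    return float(np.mean(p_all))


def simulate_zalocusky(
    n_sims: int = 500,
    n_trials: int = 100,
    beta: float = 1.5,
    alpha: float = 1.0,
    alpha_actor: float = 0.5,
    T: float = 20.0,
    k: float = 1.1,
    phi: float = 1.0,
    stim_offset: float = -1.0,
    seed: int | np.random.SeedSequence = 0,
) -> ZalocuskyResult:
    """Certain option versus a 50/50 gamble for twice the payout (outcomes
    encoded +1/-1 relative to the sure thing), 100 trials.

    Risk phenotypes are tonic rho baselines (0.85 risk-seeking, -0.75
    risk-averse); D2 stimulation during choice subtracts 1.0 from rho.  The
    RSRL comparison learns with asymmetric rates and models stimulation as
    a collapse of the softmax gain (to 0.01), which pushes both phenotypes
    toward indifference — the opposite direction for risk-averse agents.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(2)
    opal: dict[str, dict[str, ZalocuskyPhenotype]] = {}
    rsrl: dict[str, dict[str, float]] = {}
    for mi, manipulation in enumerate(("none", "d2_stim")):
        offset = stim_offset if manipulation == "d2_stim" else 0.0
        opal[manipulation] = {}
        rsrl[manipulation] = {}
        for pi, (pheno, rho0) in enumerate(_PHENO_RHO.items()):
            rng = np.random.default_rng(children[0].spawn(4)[2 * mi + pi])
            opal[manipulation][pheno] = _zalocusky_opal(
                rho0, offset, n_sims, n_trials, rng,
                beta=beta, alpha=alpha, alpha_actor=alpha_actor, T=T, k=k, phi=phi,
            )
            ap, an = _PHENO_RSRL[pheno]
            rng2 = np.random.default_rng(children[1].spawn(4)[2 * mi + pi])
            rsrl[manipulation][pheno] = _zalocusky_rsrl(
                ap, an, 0.01 if manipulation == "d2_stim" else beta,
                n_sims, n_trials, rng2,
            )
    return ZalocuskyResult(opal=opal, rsrl=rsrl)


# ---------------------------------------------------------------------------
# L-DOPA instructed gambles


@dataclass
class RutledgeResult:
    """Per-trial-type gamble proportions on and off drug, per-pair
    gain-trial differences, and the dose correlation."""

    p_gamble_off: dict[str, float]
    p_gamble_on: dict[str, float]
    gain_diff: np.ndarray        # (n_pairs,) on - off gain-trial proportion
    doses: np.ndarray
    spearman_rho: float
    spearman_p: float

    def checks(self) -> dict[str, bool]:
        on_minus_off = {
            k: self.p_gamble_on[k] - self.p_gamble_off[k] for k in self.p_gamble_off
        }
        return {
            "gain_selective_ldopa_effect": on_minus_off["gain"] > on_minus_off["loss"]
            and on_minus_off["gain"] > on_minus_off["mixed"],
            "off_drug_ordering_gain_mixed_loss": self.p_gamble_off["gain"]
            > self.p_gamble_off["mixed"]
            > self.p_gamble_off["loss"],
            "dose_correlates_with_gain_effect": self.spearman_rho > 0,
        }


def simulate_rutledge(
    n_pairs: int = 300,
    n_per_type: int = 100,
    beta: float = 1.5,
    k: float = 1.0,
    dose_mean: float = 0.5,
    dose_sd: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
) -> RutledgeResult:
    """Instructed 50% gambles: gain, loss and mixed trials, on/off L-DOPA.

    The dopaminergic state tracks the value of the current offer,
    rho = k * (0.5*certain + 0.5*EV(gamble)); the drug amplifies it by
    (1 + d) on positive-value offers, with d drawn per subject pair from a
    zero-truncated normal.  G/N are set from the offer relative to the
    certain option.  Both members of a pair see the identical offer
    sequence; choice noise is independent between the two sessions.
    """
    rng = np.random.default_rng(seed)
    doses = np.maximum(0.0, rng.normal(dose_mean, dose_sd, size=n_pairs))

    p_off: dict[str, float] = {}
    p_on: dict[str, float] = {}
    gain_diff = np.zeros(n_pairs)
    for trial_type in ("gain", "loss", "mixed"):
        c = rng.uniform(0.2, 0.6, size=(n_pairs, n_per_type))
        ratio = rng.uniform(1.6, 2.4, size=(n_pairs, n_per_type))
        g = ratio * c
        if trial_type == "gain":
            win, lose = g - c, -c
            rho = k * (0.5 * c + 0.25 * g)
        elif trial_type == "loss":
            win, lose = c, -(g - c)
            rho = k * (-0.5 * c - 0.25 * g)
        else:
            gw = rng.uniform(0.3, 1.2, size=(n_pairs, n_per_type))
            gl = rng.uniform(0.3, 1.2, size=(n_pairs, n_per_type))
            win, lose = gw, -gl
            rho = k * 0.25 * (gw - gl)
        G = win
        N = -lose

        def accept_prob(rho_eff):
            bg = beta * np.maximum(0.0, 1.0 + rho_eff)
            bn = beta * np.maximum(0.0, 1.0 - rho_eff)
            return _sigmoid(bg * G - bn * N)

        # identical offer sequence within a pair; choice noise is drawn
        # independently for the two sessions (on- and off-drug are separate
        # visits in the within-subject design)
        rho_on = np.where(rho > 0, rho * (1.0 + doses[:, None]), rho)
        pa_off, pa_on = accept_prob(rho), accept_prob(rho_on)
        took_off = rng.uniform(size=(n_pairs, n_per_type)) < pa_off
        took_on = rng.uniform(size=(n_pairs, n_per_type)) < pa_on
        # reported proportions are the policy-level acceptance probabilities
        # (so equal doses give exactly equal on/off rates); the per-pair
        # dose correlation uses realized choices, which carry the session
        # sampling noise of the within-subject design
        p_off[trial_type] = float(pa_off.mean())
        p_on[trial_type] = float(pa_on.mean())
        if trial_type == "gain":
            gain_diff = took_on.mean(axis=1) - took_off.mean(axis=1)

    if np.ptp(doses) == 0 or np.ptp(gain_diff) == 0:
        rho_s, p_s = float("nan"), float("nan")
    else:
        sp = stats.spearmanr(doses, gain_diff)
        rho_s, p_s = float(sp.statistic), float(sp.pvalue)
    return RutledgeResult(
        p_gamble_off=p_off,
        p_gamble_on=p_on,
        gain_diff=gain_diff,
        doses=doses,
        spearman_rho=rho_s,
        spearman_p=p_s,
    )


# ---------------------------------------------------------------------------
# environmental richness and common-trial gambling


@dataclass
class FrydmanResult:
    p_gamble_common: dict[str, float]

    def checks(self) -> dict[str, bool]:
        return {
            "rich_block_gambles_more_on_common_trials": self.p_gamble_common["rich"]
            > self.p_gamble_common["lean"]
        }


def simulate_frydman(
    n_sims: int = 500,
    n_trials: int = 60,
    beta: float = 0.5,
    k: float = 0.09,
    magnitudes: np.ndarray | None = None,
    rich_weights: np.ndarray | None = None,
    lean_weights: np.ndarray | None = None,
    common_magnitude: float = 7.0,
    common_every: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> FrydmanResult:
    """Blocks of 50% gambles (magnitude X vs certain C = X/2) whose
    magnitude frequencies are skewed high (Rich) or low (Lean) over the
    same support, with identical common offers embedded in both blocks.

    rho tracks the learned mean offer value relative to a uniform-prior
    baseline over the magnitude grid; in the Rich block the learned mean
    exceeds the baseline, raising rho and hence gambling on the matched
    common trials.  The magnitude grids are a synthetic stand-in with
    linearly increasing (Rich) or decreasing (Lean) frequency weights.
    """
    rng = np.random.default_rng(seed)
    X = np.arange(1.0, 9.0) if magnitudes is None else np.asarray(magnitudes, float)
    w_rich = (np.arange(1, X.size + 1, dtype=float) if rich_weights is None
              else np.asarray(rich_weights, float))
    w_lean = (np.arange(X.size, 0, -1, dtype=float) if lean_weights is None
              else np.asarray(lean_weights, float))
    baseline = 0.5 * X.mean()  # offer value of a uniform prior over the grid

    common_idx = np.arange(common_every - 1, n_trials, common_every)
    out: dict[str, float] = {}
    for block, w in (("rich", w_rich), ("lean", w_lean)):
        w = w / w.sum()
        xs = rng.choice(X, size=(n_sims, n_trials), p=w)
        xs[:, common_idx] = common_magnitude
        offer_value = 0.5 * xs
        # running mean of offer values seen before each trial, baseline prior
        csum = np.cumsum(offer_value, axis=1) - offer_value
        counts = np.arange(n_trials, dtype=float)
        vbar = (baseline + csum) / (1.0 + counts)[None, :]
        rho = k * (vbar - baseline)
        # G = N = X/2 (relative win/loss magnitudes), so Act = beta * X * rho
        bg = np.maximum(0.0, 1.0 + rho)
        bn = np.maximum(0.0, 1.0 - rho)
        p_acc = _sigmoid(beta * 0.5 * xs * (bg - bn))
        out[block] = float(p_acc[:, common_idx].mean())

    return FrydmanResult(p_gamble_common=out)
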