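"""Core model operations: critic, meta-critic, dopamine gate, actors, choice."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import opalstar as op
from opalstar.opal_core import (
    ActorState,
    CriticState,
    DopamineControl,
    MetaCriticState,
    OpalAgent,
    OpalConfig,
    act_values,
    actor_update,
    anneal_rate,
    choose_from_uniform,
    compute_rho,
    critic_update,
    expanded_weight_update,
    gamble_accept_prob,
    meta_critic_update,
    normalize_rpe,
    run_opal_batch,
    softmax,
)
from opalstar.experiments import run_episode


class TestCritic:
    def test_delta_rule_substitution(self):
        c = CriticState(V=np.array([0.5, 0.2]), alpha_c=0.1)
        _, delta = critic_update(c, 0, 1.0)
        assert delta == pytest.approx(0.5)
        assert c.V[0] == pytest.approx(0.55)
        assert c.V[1] == 0.2  # unchosen value untouched

    def test_fixed_point(self):
        c = CriticState(V=np.array([0.3]), alpha_c=0.5)
        _, delta = critic_update(c, 0, 0.3)
        assert delta == 0.0 and c.V[0] == 0.3

    def test_monotone_contraction_to_reward(self):
        c = CriticState(V=np.array([0.0]), alpha_c=0.2)
        values = [critic_update(c, 0, 1.0) and c.V[0] for _ in range(60)]
        assert np.all(np.diff(values) > 0) and values[-1] == pytest.approx(1.0, abs=1e-5)


class TestMetaCritic:
    def test_posterior_counting(self):
        m = MetaCriticState(1.0, 1.0)
        meta_critic_update(m, 1)
        assert (m.eta, m.gamma) == (2.0, 1.0)
        assert m.mean == pytest.approx(2 / 3)

    def test_uniform_prior_moments(self):
        m = MetaCriticState(1.0, 1.0)
        assert m.var == pytest.approx(1 / 12)

    def test_count_conservation(self, rng):
        m = MetaCriticState(1.0, 1.0)
        n = 57
        for _ in range(n):
            meta_critic_update(m, int(rng.uniform() < 0.4))
        assert m.eta + m.gamma == 2.0 + n

    def test_rejects_non_binary_indicator(self):
        with pytest.raises(ValueError):
            meta_critic_update(MetaCriticState(), 0.5)

    @given(eta=st.floats(0.5, 200), gamma=st.floats(0.5, 200))
    def test_moments_match_scipy_beta(self, eta, gamma):
        m = MetaCriticState(eta, gamma)
        assert m.mean == pytest.approx(sps.beta.mean(eta, gamma), rel=1e-12)
        assert m.var == pytest.approx(sps.beta.var(eta, gamma), rel=1e-12)


class TestDopamineControl:
    def test_gate_closed_while_interval_straddles_half(self):
        # Beta(2,1): mean 0.667, std 0.236 -> 1-sd interval contains 0.5
        d = compute_rho(MetaCriticState(2.0, 1.0), DopamineControl(beta=1.0, k=20.0, phi=1.0))
        assert d.S == 0 and d.rho == 0.0
        assert d.beta_g == d.beta_n == 1.0

    def test_gate_open_confident_rich(self):
        # Beta(40,10): mean 0.8, std ~0.056 -> confidently above 0.5
        m = MetaCriticState(40.0, 10.0)
        assert m.std == pytest.approx(sps.beta.std(40, 10), rel=1e-12)
        d = compute_rho(m, DopamineControl(beta=1.0, k=20.0, phi=1.0))
        assert d.S == 1
        assert d.rho == pytest.approx(0.3 * 20)
        assert d.beta_n == 0.0  # clipped at zero
        assert d.beta_g == pytest.approx(7.0)

    def test_symmetric_posterior_gives_zero_rho(self):
        d = compute_rho(MetaCriticState(50.0, 50.0), DopamineControl(beta=2.0, k=20.0))
        assert d.rho == 0.0

    def test_invalid_gains(self):
        with pytest.raises(ValueError):
            DopamineControl(beta=0.0)
        with pytest.raises(ValueError):
            DopamineControl(beta=1.0, k=-1.0)


class TestAnnealing:
    def test_uniform_prior_value(self):
        # alpha/(1 + 1/(T*std)); Beta(1,1) std = sqrt(1/12)
        expected = 0.1 / (1.0 + 1.0 / (10.0 * math.sqrt(1 / 12)))
        assert anneal_rate(0.1, MetaCriticState(1.0, 1.0), 10.0) == pytest.approx(expected)

    def test_rate_vanishes_with_certainty(self):
        assert anneal_rate(0.1, MetaCriticState(1e8, 1e8), 10.0) < 1e-3

    def test_large_T_recovers_base_rate(self):
        assert anneal_rate(0.1, MetaCriticState(5.0, 5.0), 1e9) == pytest.approx(0.1, rel=1e-4)

    def test_monotone_in_uncertainty(self):
        rates = [anneal_rate(0.1, MetaCriticState(n, n), 10.0) for n in (1, 5, 50, 500)]
        assert np.all(np.diff(rates) < 0)

    def test_requires_positive_T(self):
        with pytest.raises(ValueError):
            anneal_rate(0.1, MetaCriticState(), 0.0)


class TestNormalizeRpe:
    @pytest.mark.parametrize(
        "delta, r_mag, l_mag, expected",
        [(1.0, 1.0, 0.0, 1.0), (1.0, 1.0, -1.0, 0.5), (-0.3, 1.0, -1.0, -0.15)],
    )
    def test_range_scaling(self, delta, r_mag, l_mag, expected):
        assert normalize_rpe(delta, r_mag, l_mag) == pytest.approx(expected)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            normalize_rpe(0.5, 0.0, 0.0)


def _actor(alpha=0.05, hebbian=True, n=1, T=1e12):
    # enormous T disables annealing so update magnitudes are exact
    return ActorState.create(n, alpha, alpha, T=T, hebbian=hebbian)


class TestActorUpdate:
    def test_opponent_substitution(self):
        a = _actor(alpha=0.05)
        actor_update(a, MetaCriticState(), 0, 0.5)  # f = 0.5 with unit range
        assert a.G[0] == pytest.approx(1.025)
        assert a.N[0] == pytest.approx(0.975)

    def test_hebbian_proportionality(self):
        a = _actor(alpha=0.05)
        a.G[:] = 2.0
        actor_update(a, MetaCriticState(), 0, 0.5)
        assert a.G[0] - 2.0 == pytest.approx(2 * 0.05 * 0.5 * 2 / 2)  # double the unit-weight change

    def test_zero_rpe_is_inert(self):
        a = _actor()
        G0, N0 = a.G.copy(), a.N.copy()
        actor_update(a, MetaCriticState(), 0, 0.0)
        assert np.array_equal(a.G, G0) and np.array_equal(a.N, N0)

    def test_weights_floored_at_zero(self):
        a = _actor(alpha=1.0, hebbian=False)
        for _ in range(5):
            actor_update(a, MetaCriticState(), 0, -1.0)
        assert a.G[0] == 0.0 and a.N[0] >= 0.0

    @given(
        deltas=st.lists(st.floats(-0.2, 0.2), min_size=1, max_size=12),
        alpha=st.floats(0.05, 0.5),
    )
    def test_no_hebb_actors_are_mirror_images(self, deltas, alpha):
        """Without the Hebbian factor, G and N changes are exact negatives
        (while the zero floor is not hit)."""
        a = ActorState.create(1, alpha, alpha, T=1e12, hebbian=False)
        for d in deltas:
            actor_update(a, MetaCriticState(), 0, d)
        assert a.G[0] - 1.0 == pytest.approx(-(a.N[0] - 1.0), abs=1e-12)


class TestChoice:
    def test_act_values_combination(self):
        a = _actor()
        a.G[:] = 1.2
        a.N[:] = 0.8
        d = DopamineControl(beta=1.0)
        assert act_values(a, d)[0] == pytest.approx(0.4)

    def test_positive_rho_silences_costs(self):
        a = _actor()
        d = DopamineControl(beta=1.0, rho=2.0)
        assert act_values(a, d)[0] == pytest.approx(3.0 * a.G[0])

    def test_negative_rho_amplifies_costs(self):
        a = _actor()
        a.G[:] = 1.0
        a.N[:] = 1.0
        d = DopamineControl(beta=2.0, rho=-0.5)
        assert act_values(a, d)[0] == pytest.approx(1.0 * 1.0 - 3.0 * 1.0)

    def test_softmax_symmetry_and_closed_form(self):
        assert softmax(np.zeros(2)).tolist() == [0.5, 0.5]
        p = softmax(np.array([np.log(2.0), 0.0]))
        assert p[0] == pytest.approx(2 / 3)

    def test_softmax_shift_invariance(self):
        act = np.array([0.3, -1.2, 2.0])
        assert np.allclose(softmax(act), softmax(act + 57.0))

    def test_choose_from_uniform_partitions(self):
        p = np.array([0.25, 0.75])
        assert choose_from_uniform(p, 0.1) == 0
        assert choose_from_uniform(p, 0.9) == 1
        assert choose_from_uniform(p, 0.999999) == 1

    @pytest.mark.parametrize(
        "act, expected", [(0.0, 0.5), (np.log(3.0), 0.75), (50.0, 1.0)]
    )
    def test_gamble_accept_prob_closed_forms(self, act, expected):
        assert gamble_accept_prob(act) == pytest.approx(expected, abs=1e-9)


class TestExpandedUpdate:
    def test_two_step_example(self):
        # recursive: G1 = 1 + 0.1*0.5 = 1.05; G2 = 1.05*(1.05) = 1.1025
        dG2 = expanded_weight_update([0.5, 0.5], 0.1, t=2)
        assert dG2 == pytest.approx(0.0525)

    def test_zero_rpes(self):
        assert expanded_weight_update([0.0, 0.0, 0.0], 0.3, t=3) == 0.0

    def test_matches_recursive_actor_on_random_histories(self, rng):
        """The subset-expansion of the weight change equals the recursive
        three-factor update to 1e-10 on 100 random RPE sequences."""
        for _ in range(100):
            n = int(rng.integers(1, 9))
            deltas = rng.uniform(-1, 1, size=n)
            alpha = float(rng.uniform(0.01, 0.5))
            G = 1.0
            for t in range(n):
                increment = alpha * G * deltas[t]
                expanded = expanded_weight_update(deltas, alpha, t=t + 1)
                assert abs(increment - expanded) < 1e-10
                G += increment

    def test_history_cap(self):
        with pytest.raises(ValueError):
            expanded_weight_update(list(range(25)), 0.1)


class TestAgentAndBatch:
    def test_variant_flags(self):
        assert OpalConfig.for_variant("opal_star", 2).variant == "opal_star"
        assert OpalConfig.for_variant("opal_plus", 2).modulation is False
        assert OpalConfig.for_variant("no_hebb", 2).hebbian is False
        with pytest.raises(ValueError):
            OpalConfig.for_variant("bogus", 2)

    def test_batch_of_one_reproduces_object_agent(self, rich2):
        agent = OpalAgent(OpalConfig.for_variant("opal_star", 2))
        result = run_episode(agent, rich2, 120, seed=77)
        batch = run_opal_batch(rich2.probs, 120, 0.05, 0.1, 5.0, seed=77)
        assert np.allclose(result.p_best, batch.p_best, atol=1e-6)
        assert np.allclose(agent.actors.G, batch.G, atol=1e-6)

    def test_modulation_gate_prefix_matches_balanced_model(self, lean2):
        """While the meta-critic's interval still straddles 0.5, OpAL* is
        trial-for-trial identical to OpAL+ on the same seed."""
        star = OpalAgent(OpalConfig.for_variant("opal_star", 2))
        plus = OpalAgent(OpalConfig.for_variant("opal_plus", 2))
        r_star = run_episode(star, lean2, 60, seed=5)
        r_plus = run_episode(plus, lean2, 60, seed=5)
        rho = star.trace()["rho"]
        first_open = int(np.argmax(rho != 0)) if np.any(rho != 0) else len(rho)
        assert first_open > 0
        assert np.array_equal(r_star.choices[:first_open], r_plus.choices[:first_open])
        assert np.allclose(r_star.p_best[:first_open], r_plus.p_best[:first_open])

    def test_k_zero_never_opens_modulation(self, lean2):
        star = run_episode(
            OpalAgent(OpalConfig.for_variant("opal_star", 2, k=0.0)), lean2, 150, seed=9
        )
        plus = run_episode(
            OpalAgent(OpalConfig.for_variant("opal_plus", 2)), lean2, 150, seed=9
        )
        assert np.array_equal(star.choices, plus.choices)
        assert np.allclose(star.p_best, plus.p_best)

    def test_weight_positivity_across_long_runs(self, lean2):
        res = run_opal_batch(
            lean2.probs, 1000,
            np.repeat([0.025, 0.05, 0.1], 40), 1.0, 10.0,
            seed=3, record_traces=True,
        )
        assert res.G_trace.min() >= 0.0 and res.N_trace.min() >= 0.0

    def test_balanced_no_hebb_reduces_to_single_actor(self, rich2):
        """rho=0 with hebbian off: Act = beta*(G-N) with mirror-image
        actors, so the policy equals a single actor driven by the same
        RPE stream with twice the gain."""
        agent = OpalAgent(
            OpalConfig(n_actions=2, beta=3.0, hebbian=False, modulation=False)
        )
        run_episode(agent, rich2, 100, seed=21)
        tr = agent.trace()
        assert np.allclose(tr["G"] - 1.0, -(tr["N"] - 1.0), atol=1e-10)
        single = 2 * 3.0 * (tr["G"][-1] - 1.0)
        assert np.allclose(agent.policy(), softmax(single))
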