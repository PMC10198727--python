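# opalstar

Simulator for **OpAL\***, an opponent actor-critic model of how the basal
ganglia and dopamine system solve reinforcement-learning and risky-choice
problems — together with its ablation controls, standard baseline agents,
and the bandit / instructed-gamble experiments built on them.

## The model

A critic learns action values from reward prediction errors (RPEs),

&nbsp;&nbsp;&nbsp;&nbsp;δ_t = R_t − V_t(a), &nbsp;&nbsp; V_{t+1}(a) = V_t(a) + α_c δ_t,

and two opponent actors accumulate those RPEs with a **three-factor Hebbian
rule** (the current weight multiplies its own update):

&nbsp;&nbsp;&nbsp;&nbsp;G_{t+1}(a) = G_t(a) + α(t) · G_t(a) · f(δ_t)
&nbsp;&nbsp;&nbsp;&nbsp;N_{t+1}(a) = N_t(a) + α(t) · N_t(a) · f(−δ_t)

where f normalizes δ by the reward range.  G ("Go", D1 pathway) grows
convex in reward probability at the high end and N ("NoGo", D2) at the low
end, so each actor *specializes* at discriminating options in its half of
the range.  A Bayesian **meta-critic** — a Beta(η, γ) posterior over the
environment-wide reward rate, updated every trial regardless of the action
taken — drives the dopaminergic state once it is confident the environment
is rich or lean:

&nbsp;&nbsp;&nbsp;&nbsp;ρ_t = S · (E[X] − ½) · k, &nbsp;&nbsp; S ∈ {0, 1},

which reweights the actors at choice through
Act(a) = β_g G(a) − β_n N(a) with β_g = β·max(0, 1+ρ),
β_n = β·max(0, 1−ρ), followed by a softmax.  High dopamine amplifies the
benefit-coding actor in rich environments; low dopamine amplifies the
cost-coding actor in lean ones — an efficient-coding strategy that sidesteps
the explore–exploit pathology value-based learners suffer under sparse
reward.  The meta-critic's posterior spread also anneals the actor learning
rates, stabilizing the Hebbian weights as uncertainty shrinks.

Two ablations are configuration flags: **OpAL+** (ρ ≡ 0, no dopamine
modulation) and **No Hebb** (the Hebbian factor removed, which makes the
two actors redundant mirror images of a single actor-critic).  Baselines
with the same act/learn interface: softmax **Q-learning** (optionally with
full counterfactual feedback), **UCB** on sample means, **risk-sensitive
RL** (separate learning rates for positive/negative RPEs), and the
**Möller–Bogacz** opponent model whose G/N weights converge to expected
payoffs and costs.

## Worked example

Seed-paired comparison of OpAL\* against its balanced control on the lean
two-arm bandit (30% vs 20% reward), sweeping the reduced parameter grid
with 50 simulations per grid point:

```bash
$ opalstar compare --models opal_star,opal_plus --env lean2 --sims 50 --seed 7
opal_star - opal_plus @ lean2, horizon 250: mean dAUC=7.71, t=7.79, p=3.18e-13
```

Every grid point runs both models from the same random seed; the mean
paired difference in learning-curve AUC (+7.7 trials' worth of probability
mass out of 250) and the one-sample t-test against zero say that dynamic
dopamine modulation reliably speeds learning in the sparse-reward task.

The same machinery adaptively rejects bad gambles.  With offers whose win
probability is drawn below 50%:

```bash
$ opalstar gamble --kind low --sims 500 --seed 7
{
  "kind": "low",
  "final_accept_opal_star": 0.091,
  "final_accept_opal_plus": 0.225,
  "checks": { "opal_star_gambles_less_late": true }
}
```

After 50 exposures the modulated model accepts the unfavorable gamble 9%
of the time versus 22% for the balanced control: once the meta-critic is
confident the gamble is lean, low dopamine amplifies the learned costs.

Library use mirrors the CLI:

```python
import opalstar as op

env = op.make_environment("lean", complexity=6)          # 0.3 vs 5 x 0.2
agent = op.OpalAgent(op.OpalConfig.for_variant("opal_star", env.n_actions))
result = op.run_episode(agent, env, n_trials=250, seed=0)
result.to_frame()         # trial, choice, reward, p_best, rho, V, G, N ...
```

Other subcommands: `sweep`, `curves`, `replay` (fixed-experience mechanism
runs), and the risky-choice simulations `palminteri`, `zalocusky`,
`rutledge`, `frydman` — each emits a JSON summary with named directional
checks.

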