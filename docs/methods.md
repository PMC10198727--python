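# Methods

This note documents the model equations as implemented, the defaults and
why they were chosen, what the synthetic tasks do and do not emulate, and
the numerical choices a maintainer would want to know.

## Model components and per-trial order

One trial of the opponent actor-critic proceeds:

1. **Choice.**  Act(a) = β_g G(a) − β_n N(a), with β_g = β·max(0, 1+ρ) and
   β_n = β·max(0, 1−ρ) (actor contributions are floored at zero — a
   pathway can be silenced but not inverted).  Actions are drawn from a
   numerically stabilized softmax over Act.  The probability assigned to
   the optimal arm is recorded *before* the draw; learning curves are
   policy probabilities, not realized choices, which is a lower-variance
   statistic with the same mean.
2. **Outcome.**  The environment returns `r_mag` with the arm's reward
   probability, else `l_mag` (defaults 1/0 for bandits, +1/−1 for gambles
   encoded relative to the sure option).
3. **Critic.**  δ = R − V(a); V(a) += α_c δ.  The critic is per-action and
   its learning rate is constant across trials.
4. **Meta-critic.**  η += [R was a success], γ += [failure], where success
   means R > `l_mag`.  The update happens every trial regardless of which
   action was taken — the meta-critic estimates the richness of the
   environment as a whole, not of any action.
5. **Dopaminergic state.**  With posterior mean m and sd s, the gate opens
   (S = 1) only when m − φs > ½ or m + φs < ½; then ρ = S·(m − ½)·k.  This
   conservative gate keeps ρ = 0 — and the model identical to its balanced
   control — until the agent has actually learned whether the world is
   rich or lean.
6. **Actors.**  G(a) += α(t)·G(a)·f(δ), N(a) += α(t)·N(a)·f(−δ), with
   f(δ) = δ/(r_mag − l_mag).  The `hebbian` flag replaces the G(a)/N(a)
   factors by 1 (the "No Hebb" ablation); the `modulation` flag pins
   ρ = 0 (the "OpAL+" ablation).  Weights are clipped at zero from below
   after each update.

Because ρ and α(t) are refreshed after the outcome, the next trial's
choice reflects all evidence so far.

## Annealing: form and rationale

The actor learning rate is annealed by meta-critic uncertainty:

    α(t) = α / (1 + 1 / (T · std(X))),   X ~ Beta(η, γ),  T = 10.

The annealing *scale* was a genuinely open design choice: the uncertainty
of a counting posterior can enter through its variance or its spread, and
the two differ enormously in how fast they bite (variance falls as 1/n,
spread as 1/√n).  Annealing through the variance freezes the actors within
a few dozen trials, after which learning curves are flat; annealing through
the spread lets learning continue over hundreds of trials while still
damping the multiplicative Hebbian updates enough to prevent the
well-known decay of G/N weights once the critic converges.  Only the
spread-based form jointly produces the three signatures the model family
is supposed to show: (i) learning curves that keep rising across a
250-trial horizon, (ii) a robust paired advantage of the modulated
Hebbian model over both of its ablations in rich and lean tasks of either
complexity, and (iii) the classic value-learner asymmetry (rich ≫ lean
performance ceiling) in the non-Hebbian control.  Removing annealing
entirely restores (iii) but breaks (ii): without it the Hebbian weights
decay stochastically late in learning and the modulated model loses its
edge.  Both stated limits hold in the adopted form: larger T delays
annealing (T → ∞ recovers the base rate) and the rate goes to zero as
uncertainty vanishes.

## Defaults (and their provenance)

| Parameter | Default | Meaning / rationale |
|---|---|---|
| α_c | 0.05 (grid {0.025, 0.05, 0.1}) | critic learning rate |
| α_G = α_N | 0.1 (grid 0.05–1 step 0.05) | actor base learning rate |
| β | 5 (grid 1–10 step 0.5) | softmax gain |
| T | 10 | annealing delay; fixed across all grid comparisons |
| k | 20 | modulation strength; fixed across models |
| φ | 1.0 | confidence required before modulation |
| G₀ = N₀ | 1 | multiplicative updates need a nonzero seed; symmetric start gives Act = 0 |
| V₀ | ½(r_mag + l_mag) | range midpoint — a neutral first RPE |
| η₀ = γ₀ | 1 | uniform Beta prior; keeps the gate conservative early |

Initial weights, critic initialization and the meta-critic prior are
package choices (no canonical values exist); everything in the grid rows
is the canonical sweep.  Q-learner grid: rate 0.05–1 step 0.05, gain
2–100 step 2; UCB exploration constant 0–2 step 0.01, with the first
`n_actions` trials selecting each arm once in random order and a 1-based
trial index inside the log bonus.

The Möller–Bogacz opponent baseline computes its prediction error against
its own combined value, δ = R − (D·G − (1−D)·N) with D = ½ — under that
reading (and only that one) its value converges to expected reward and the
G/N pair to expected payoff/cost magnitudes.  Its exact source parameters
are not published at this granularity; the defaults α = 0.1, ε = 0.9,
λ = 0.01, β = 50 satisfy the convergence relation the model requires
(λ ≪ α, ε ≈ 1, specifically ε = 1 − λ/α so the p = 0.5, ±1 gamble fixed
point is G = N = 0.5), with β at the middle of the 10–100 search range.

## Synthetic tasks

* **Bandits.**  Stationary Bernoulli arms, one optimal arm first:
  rich (0.8 vs 0.7) and lean (0.3 vs 0.2) at complexity 2–6.  Stationarity
  is a deliberate restriction — drifting contingencies and switch points
  are out of scope, so nothing here speaks to stability–flexibility
  tradeoffs in volatile environments.
* **Instructed gambles.**  Offers encoded relative to the sure thing
  (accepting it is outcome 0).  In instructed paradigms the actors are set
  directly from the offer — G = relative win magnitude, N = |relative
  loss| — rather than learned; the dopaminergic state is set from offer
  value without the confidence gate.  This is one consistent mapping of
  "explicitly set" weights; magnitudes themselves (certain ≈ U(0.2, 0.6),
  gamble/certain ratio ≈ U(1.6, 2.4)) are synthetic stand-ins chosen once
  to span a plausible offer range.
* **Learning-phase gambles** (repeated offer, 50 trials): the critic,
  actors and meta-critic update only on trials where the gamble is taken —
  experiential learning, no counterfactual feedback.
* **Context transfer.**  Four contexts (gain/loss × partial/complete
  feedback), 40 trials each; the critic is per-context so actor RPEs are
  context-relative.  Under complete feedback the context value learns fast
  (rate 0.5, target = mean of both observed outcomes) and the unchosen
  stimulus's actors update from its counterfactual RPE; under partial
  feedback a slow critic (0.05) leaves RPEs near-absolute.  Learning runs
  with ρ = 0 and no annealing: the transfer phenomenon depends only on
  relative-value RPEs plus Hebbian actors.
* **Rodent risky choice.**  100 trials of sure-vs-50/50-double gamble;
  phenotypes are tonic ρ baselines (+0.85 / −0.75); D2 stimulation
  subtracts 1.0 from ρ during choice.  Critic rate 1.0 with actor rate
  0.5 (annealed, T = 20): a critic at rate 1 makes δ the difference of
  consecutive outcomes, and driving the multiplicative actors at rate 1 as
  well makes the weights whipsaw and erases the phenotype-selective
  stimulation effect, so the actor rate is the moderate one.
* **Drug simulation.**  300 interleaved instructed trials (100 gain /
  loss / mixed); per-pair dose d ~ Normal(0.5, sd 0.5) truncated at zero,
  applied as ρ·(1+d) only when the offer value is positive.  Both members
  of a pair see identical offers; choice noise is independent between the
  on- and off-drug sessions (they model separate visits).  Reported
  per-type gamble rates are policy-level probabilities (so d = 0 gives
  exactly identical on/off rates); the dose correlation uses realized
  choices, whose session-level sampling noise is what keeps the
  correlation well below 1.
* **Richness blocks.**  50% gambles of magnitude X vs certain X/2, X drawn
  from an 8-point grid with linearly increasing (rich) or decreasing
  (lean) frequency weights — a synthetic stand-in with matched support;
  fixed common offers (X = 7) are embedded in both blocks.  ρ tracks the
  running mean offer value against a uniform-prior baseline.

What passing these simulations shows is that the *mechanism* produces the
right directional patterns under clean assumptions; it does not show that
the model fits any real data set, and none is fit here.

## Randomness and pairing

Every simulation consumes, per trial, one block of `n_actions + 1`
uniforms from a PCG64 stream — a counterfactual outcome draw per arm, then
the choice draw.  Model comparisons re-run the batch from the same seed,
so paired models experience identical randomness and identical reward
sequences wherever their choices agree; a batch of size one is
reproducible against the object-level agent loop to float32 precision.
Grid sweeps place grid point g, simulation i at uniform column
g·n_sims + i, which pairs sweeps run-for-run across model variants.

## Numerical choices

* Softmax is computed after subtracting the row maximum (shift-invariant).
* Sampling inverts the CDF with the same `u ≥ cumsum` comparison in the
  scalar and vectorized paths, with the index clipped to the last arm
  against floating-point shortfall in the cumulative sum.
* AUC is the plain trial-indexed sum of the averaged curve (horizon 250 ⇒
  maximum 250); no quadrature convention is needed at integer trials.
* The policy-fluctuation index is the within-run population standard
  deviation of sign(p_best − ½); sign(0) counts as 0.
* Actor weights are floored at 0 after every update.  For the non-Hebbian
  model this floor is the one place the two actors stop being exact mirror
  images; the mirror identity is only asserted away from the floor.
* t-tests on paired AUC differences are two-sided one-sample tests per
  horizon with no multiple-testing correction (none is part of the
  procedure being reproduced).
* The expanded (non-recursive) form of the Hebbian weight change is
  evaluated by explicit subset enumeration and is exponential in history
  length; it exists as a verification oracle and is capped at 20 trials.

## Problem sizes

Grid statistics in the acceptance script use the full 1,140-point
parameter grid with 250 simulations per grid point and a 250-trial
horizon; the test suite uses the 210-point reduced grid at 100
simulations.  These replicate counts were chosen so the whole suite and
script each run in minutes on one CPU while keeping the max-over-grid
statistic dominated by signal rather than selection noise (at 25
simulations per point, the maximum over 1,140 noisy AUC estimates is
inflated by tens of points; at 150–250 it is stable to a few points).

## Known limitations

* The annealing scale is a reconstruction (see above); its residual
  quantitative effect is that the non-Hebbian model's six-arm performance
  ceiling comes out ~15% high in lean and ~25% low in rich relative to the
  reported values, while every directional comparison reproduces.
* Stationary environments only; no drifting rewards, no contingency
  switches, no dynamic optimization of T.
* Instructed-gamble weight mappings and offer-magnitude distributions are
  principled stand-ins, not calibrated to any experiment's stimulus set.
* The D2-activity proxy is a decision-period scalar (β_n·N); no attempt is
  made to model photometry dynamics.
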