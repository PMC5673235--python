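# Methods

## The task

The environment is a small Markov decision process with six fractal-cued
states and two terminal outcomes. Each trial starts from one of four
first-stage states — two *passive* (no response required) and two *active*
(left/right button press within 1.5 s) — proceeds to one of two second-stage
passive states, and ends at a rewarded or unrewarded outcome. Trial events
follow a fixed grammar: intertrial fixation (4–8 s, discrete uniform in
80 ms steps, drawn without replacement within each 50-trial run), a 1 s
pre-trial cue signalling the upcoming trial type, the first-stage stimulus
(1.5 s), a 3.5 s interstimulus interval, the second-stage stimulus (1.5 s),
a second 3.5 s interval, and the outcome (1.5 s by default; the outcome
duration is configurable because it is not pinned down by the event
grammar). Responding on a passive trial or failing to respond on an active
trial aborts the trial with no outcome.

Transition probabilities are symmetric by construction: the two second-stage
states carry complementary reward probabilities, the two first-stage passive
states route to a given second-stage state with complementary probabilities,
and the action→successor mapping is inverted across the two active states.
One action per active state is therefore objectively better, except in the
degenerate all-0.5 configuration, which the accuracy scorer treats as a tie
and excludes. A 200-trial session is divided into blocks of 80, 60 and 60
trials; each block boundary reverses the transition probabilities at either
the first or the second stage (the stage of the initial reversal is a
counterbalancing flag; the second reversal takes the other stage).
Trials are scheduled in randomized quartets containing each of the four
initial states exactly once, and the four 50-trial scanning runs are not
aligned with block boundaries.

The concrete probability level is configurable with a default of 0.7/0.3
for every stochastic row — a standard level for probabilistic-reversal
designs; every downstream computation is probability-agnostic.
Reward is coded r = 1 internally; the 10-cent monetary magnitude is kept as
display metadata only, since all update equations use unitless reward.

## The model family

All learning models share the two-step episode *first-stage → second-stage →
outcome* and an augmented softmax policy. Four modules can operate alone or
in parallel:

**Critic.** Cached state values `V(s)`, all initialized to 0, taught by the
state-value prediction error (SVPE) `δV = r + V(s') − V(s)`. No discounting
(γ = 1): exactly one reward can occur per trial at a fixed delay. The
TD(λ) eligibility trace credits the n-th state back within the episode by
`α·λⁿ·δV`; traces never cross trial onsets.

**Actor.** Policy preferences `p(s,a)` for active states, updated by the
same SVPE (with the same eligibility), as in a classic actor/critic.

**Q-learner.** Action values `Q(s,a)` taught by the action-value prediction
error (AVPE) `δQ = r + max_a' Q(s',a') − Q(s,a)`. Action-less states carry a
formal pseudoaction `A0` whose value aliases the state value,
`Q(s,A0) ≡ V(s)`, so in hybrid (CQ/ACQ) models the second-stage bootstrap
term is `V(s2)` and the outcome-stage AVPE `r − V(s2)` reaches the
preceding real state–action pair through the eligibility trace. The *pure*
Q(0) model has no state values at all; it learns across the action-less gap
through a single update at outcome delivery, `δQ = r − Q(s1,a)`. This is
the only mechanism that lets a state-value-free learner learn in this task;
the alternative (no second-transition update at all) would make the model
unfittable as a learning model.

**Model-based planner.** A transition function `T(s,a,s')` initialized to
the uniform prior 1/2 over each pair's two feasible successors, updated from
state-prediction errors `δ* = 1 − T(s,a,s_obs)`: the observed entry moves up
by `α*·δ*` and the complementary entry shrinks by `1 − α*`, keeping rows
normalized exactly. Action values `Q*(s,a)` are recomputed for *all* pairs
on every trial by backward induction over the episode DAG with the known
reward function (R = 1 at the rewarded terminal).

**Policy.** Active-state choices follow a softmax over net weights
`W* = w*·Q* + (1 − w*)·W` with `W = w_Q·Q + (1 − w_Q)·p`, augmented by a
per-state perseveration bias (magnitude β₀, decaying geometrically per
visit with inverse rate λ_β) and a constant rightward bias β_R, all scaled
by the temperature τ. The perseveration bias is maintained incrementally
(`β ← λ_β·β`, then `+β₀` on the chosen action), which is algebraically
identical to the explicit sum over past visits and O(1) per choice.

The registry enumerates Q(0), AC(0), AC(1), AC(λ), CQ(0), CQ(1), CQ(λ),
ACQ(0), ACQ(1), ACQ(λ), MB, and the ten model-free variants paired with MB —
21 learning models — plus the 4-parameter hysteresis model (learning rates
fixed at zero; τ, β_R, β₀, λ_β free) and a null intercept model with the
single parameter P(A₁) (A₁ is the left action by convention). The 22
alternatives entering the factorial comparison are the learning models plus
hysteresis; the null model is a baseline outside the comparison. The
hysteresis model retains a scale redundancy between τ and the β
parameters; it is kept (not reparameterized) so that its free-parameter
count matches the comparison's accounting.

Error trials contribute no choice likelihood and no latent updates: the
trial aborts before any transition is shown. Actor preferences are neither
bounded nor renormalized; no normalization is specified for them and none is
applied.

## Fitting and comparison

Per-subject maximum likelihood: the negative sum of log choice
probabilities over valid active trials, minimized by Nelder–Mead restarted
from 20 random start points (uniform in an unconstrained reparameterization:
logit for unit-interval parameters, log for τ, identity for the βs), with
`xatol = 1e-6`, `fatol = 1e-8`. The winning point is polished by re-running
the simplex from the (clip-canonicalized) optimum until no further
improvement, which makes refitting from a returned optimum a no-op to
within 1e-6. All randomness is derived from an explicit seed.

Model comparison uses AICc = 2·NLL + 2k + 2k(k+1)/(n−k−1) with n = the
number of valid choices — the likelihood-bearing observations — and k from
the registry (ACQ(λ): 7, ACQ(λ)+MB: 9, hysteresis: 4, null: 1). AICc ties
break toward fewer parameters. The comparison table reports each model's
residual fit relative to the hysteresis benchmark with and without the
complexity penalty, the per-subject winner, and its model-free /
model-based / hybrid class.

Outcome sensitivity is `log(α(1+λ)/τ)`; α = 0 maps to −∞. Subjects are
classified Good if accuracy beats the 50% chance level by a one-tailed
exact binomial test at α = 0.05, otherwise Poor, and a Poor subject whose
lowest AICc belongs to the hysteresis model is a Nonperformer.

## Behavioral statistics

Accuracy is the proportion of valid choices matching the action with the
greater exact two-step probability of reward. The first completed encounter
with each active state is excluded as informationless; by default the
exclusion is applied per block (contingencies reset at reversals), and a
flag restricts it to session-initial encounters only. Error trials and
tie blocks are excluded, and all exclusion counts are reported.

The model-derived regressions use net action weights normalized per subject
by the maximum absolute right−left difference: a logistic regression of
right choices on the normalized weight difference; a logistic regression of
staying (repeating the previous action in the same state) on the
stay−switch weight difference, whose *intercept* is the weight-independent
perseveration tendency; and a linear regression of RT on the absolute
normalized weight difference after discarding contaminant RTs below 300 ms.
Choice curves bin the normalized weight difference with inner bins of width
0.2 and edge bins of width 0.3; empty bins are reported as missing.

## Synthetic cohorts

Closed-loop simulation: the policy samples each choice, the task samples
transitions and outcomes, latents update online; everything is
deterministic given a seed. Yoked replay regenerates only the choices while
copying the observed schedule; passive trials and error trials are copied
verbatim (passive outcomes still teach the simulated agent), and an active
trial's observed transition is kept whenever the re-sampled choice matches
the observed one, re-sampled from the task tables otherwise.

Cohort generation draws per-subject parameters from independent truncated
normals. The default means and SDs are the fitted Good-learner group values
(α 0.588 ± 0.237, λ 0.682 ± 0.323, w_Q 0.661 ± 0.315, τ 0.404 ± 0.262,
β₀ 0.093 ± 0.366, λ_β 0.621 ± 0.375, β_R 0.230 ± 0.425); a Poor-learner
set is also provided. Correlations between parameters are not modeled (only
marginal moments are available). The model-based learning rate mirrors the
model-free distribution and the model-based weight defaults to 0.5 ± 0.25,
as no group statistics exist for these. The default miss rate is 3%,
mimicking typical missed-trial counts (≈6 of 200); unit tests use 0.
Simulated RTs are drawn from a lognormal centered near 750 ms purely so the
RT-regression plumbing has input; no process model of RT is implied.

What the generator does *not* emulate: within-subject parameter drift,
session-level attention lapses beyond the constant miss rate, correlated
parameters, motor biases beyond β_R, and any RT–difficulty coupling (tests
that need one inject it explicitly). Passing recovery tests therefore
demonstrates internal consistency of simulation + fitting under the stated
generative conditions, not fidelity to any particular empirical cohort.

## fMRI design construction

The design matrix is built from four parametric regressors — SVPE, state
value V, AVPE, action value Q — plus unmodulated indicator regressors
(passive/active pre-trial cues, passive fractals, left/right active states,
rewarded/unrewarded outcomes, ISI/ITI fixation, error events). Value
boxcars persist through the interstimulus interval following the stimulus;
prediction-error boxcars span the stimulus immediately following the
predicting state; AVPE events exist only during and immediately after
active states, and the outcome-stage AVPE is the error that updates the
post-action state value while reaching the preceding action through the
eligibility trace, so SVPE and AVPE regressors are correlated but
dissociable. The ITI and pre-trial cues are coded as passive states with
their own V/SVPE modulators; this requires an *extended* forward pass that
chains ITI → cue → first stage into the critic's episode. The extension
adds states upstream of the first stage only, so first/second-stage
latents, choice probabilities, and hence behavioral fits are bit-identical
to the base pass (asserted by test).

Modulators are mean-centered per regressor before convolution (standard
parametric-modulator convention; positive and negative prediction errors
share one linear scale). Regressors are built on a 10 ms grid, convolved
with the canonical double-gamma HRF (peak 6 s, undershoot 16 s,
peak/undershoot ratio 6, via nilearn's SPM-style kernel), and sampled at
TR = 2.770 s. No orthogonalization is applied anywhere; the SVPE–AVPE
Pearson correlation is exposed as a diagnostic. Mean-centering is applied
per session, so the strict additivity (linearity) property of the
convolution holds with centering disabled, and the test suite checks it
that way. Nuisance regressors (motion, physiology, ICA components, AR(1))
are out of scope; only the constant column is appended.

## Numerical choices and degenerate inputs

- Softmax logits are max-shifted before exponentiation; choice
  probabilities are floored at 1e-300 inside the log.
- Transition rows are updated with the exact complementary-shrinkage rule,
  so row sums stay 1 to machine precision (asserted after every update).
- Unit-interval parameters are clipped to [1e-9, 1−1e-9] before the logit
  transform; τ's log transform is capped at exp(50).
- Ties in `better_action` (expected-value difference < 1e-12) return a
  sentinel and are excluded from accuracy.
- Zero scorable choices, degenerate (all-zero or constant) regression
  predictors, empty RT sets after the 300 ms cutoff, constant design
  columns, and cyclic transition graphs all raise `ValueError` rather than
  returning silently wrong numbers.

## Problem sizes used by the test suite

The suite exercises recovery at desk scale: chance calibration pools ~110
random-agent sessions (>10,000 scored choices); parameter recovery fits 20
simulated subjects (200 trials each, 20 restarts); model recovery fits all
22 alternatives to an 8-subject cohort with 4 restarts each; classifier
calibration simulates 1,000 random agents. These sizes were chosen to keep
the full suite in the tens of minutes on a single core while leaving the
statistical checks meaningfully powered; the known consequences of the
scale-down for the recovery checks are discussed above.

## Known limitations

- With ~100 choices per subject, α and τ trade off along a ridge (the
  sensitivity ratio α(1+λ)/τ is much better identified than either
  parameter alone), and w_Q is weakly identified because actor preferences
  and Q-values generate very similar policies in this task. Per-parameter
  rank-correlation recovery at cohort size 20 is therefore fragile even
  when the machinery is correct; the sensitivity composite and the
  raw-likelihood model-recovery check are the robust summaries.
- When generating parameters are drawn near a nested boundary (λ near 0 or
  1, w_Q near 0 or 1), AICc correctly prefers the boundary-restricted model
  for those subjects, so on small dispersed cohorts a restricted model can
  beat the full generator on *mean* AICc. This is expected behavior of a
  consistent criterion, not a recovery failure; discriminability at scale
  requires larger or interior-parameter cohorts.
- The null intercept model's P(A₁) refers to the left action by an
  arbitrary, documented convention.
- The outcome boxcar duration and the treatment of second-stage value
  modulators (state value V rather than the pseudoaction Q) are
  conventions; both are configurable or localized in one mapping table.
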