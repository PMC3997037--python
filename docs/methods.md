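# Methods

## Model

The agent learns two tabular quantities per state–action pair, both
zero-initialised.  The action value Q is updated by the TD error δ
(the dopamine correlate): `Q += eta_q * delta`, with
`delta = r − Q(s, a)` in single-decision tasks and
`delta = r + gamma * Q(s') − Q(s)` when reward is delayed (state
values; a terminal successor contributes 0).  The risk estimate h
tracks the second moment of δ: `h += eta_h * (delta² − h)`, an
exponential moving average of δ², hence a running TD-error variance.
Because the update is a convex combination of h and δ², h is provably
nonnegative; the containers enforce this.

Choice acts on the utility `U = Q − alpha * sign(Q) * sqrt(h)` through
a softmax with inverse temperature β.  The sign term makes the agent
risk-averse in gains and risk-seeking in losses; α ≥ 0 — the serotonin
correlate — scales the risk sensitivity, and α = 0 reduces the model
exactly to a classical softmax Q-learner (asserted trial-for-trial in
tests).  `sign(0) = 0`, so the risk term vanishes at the
zero-initialised value — the symmetric choice, avoiding an arbitrary
risk direction at neutral value.

Two structural switches support sensitivity analyses and are not part
of the model proper: `risk_transform="identity"` penalises raw h
instead of √h (the mean–variance rather than mean–standard-deviation
form), and `sign_dependent=False` drops the sign term (always
risk-averse).  √h is the default because the utility's risk part is a
standard-deviation-type quantity in the mean–risk utility literature
the model builds on, and because the identity form makes the fitted β
values dimensionally inconsistent across tasks whose rewards differ by
orders of magnitude.

Within a trial the order is: compute δ from the current tables,
compute ξ from the current h and that δ, then apply both updates.
Only the chosen (state, action) pair is updated.  Probability vectors
are normalised to 1 within 1e-12, with max-subtraction in the softmax
for overflow safety.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | risk weight (5HT correlate), dimensionless | task-specific | bee 1.5; saccade 1.985/1.658 (baseline/RTD); reversal 0.5/0.3 (balanced/depleted) |
| β | softmax inverse temperature, 1/(reward unit) | task-specific | bee 10, saccade 0.044, delayed 20, reversal 10 |
| γ | discount per 2.5 s step, in [0, 1) | 0.6 | only the delayed task uses it; swept over {0.5, 0.6, 0.7} |
| η_Q | value learning rate, (0, 1) | 0.1 | bee task fit uses 0.001 |
| η_h | risk learning rate, (0, 1) | 0.1 | bee task fit uses 0.051 |

## Tasks

**Bee foraging.**  A stateless two-armed bandit: blue yields 1 µl
deterministically, yellow 3 µl with probability 1/3 (equal means,
unequal variance); contingencies swap from trial 15 (1-indexed,
inclusive) through trial 40.  With the fitted slow value learning the
arms' Q stay near zero within a session; preference and the
post-reversal switch are driven by h.  Under sustained sampling Q of
both arms converges to the common mean 1 and h of the risky arm to the
TD-error variance — Var(r) = 2 at small η, inflated by the factor
2/(2−η_Q) at finite η because the tracked value itself fluctuates.

**Saccade task (tryptophan depletion).**  Six reward schedules
(states), each a safe juice time vs a 50/50 risky pair; the first four
are equal-expected-value (EEV), the last two unequal (UEV).  Learning
operates on the subjective reward r = juice − 193.2 ms, which places
the EEV schedules in a loss frame.  Each agent sees every state 200
times in shuffled order (the presentation count and ordering are this
package's choice; reported splits are then well-estimated), and choice
frequencies are measured over the whole run.  In this finite-training
regime the baseline α = 1.985 produces more safe choices than the
depleted α = 1.658 in all splits.  That trend is a transient-learning
effect: at the (Q, h) fixed point the loss-frame utility gives the
risky action a bonus α√h, so the asymptotic safe-choice rate
*decreases* in α — the package's dual-route test verifies the
simulation against exactly this closed form at convergence.  Users
probing very long training should expect the trend to invert.

**Delayed reward (patch removal).**  Two panels are occluded by black
patches (white: 18±9 patches hiding r = 1; yellow: 72±24 hiding
r = 4).  Each 2.5 s step the agent picks a panel by softmax over the
two panels' utilities; a trial-scheduled number of patches (integer-
uniform over the ± range, clamped ≥ 1; a rounded-Gaussian reading is
available) is removed from the chosen panel only, and the panel first
fully exposed is the trial's recorded choice and delivers its reward.
The eight-trial schedule uses removal-rate pairs (6±2, 8±2) ×4,
(6±2, 16±2) ×2, (14±2, 8±2) ×1, (14±2, 16±2) ×1.  State values are
keyed by exact patch count per panel colour, no function
approximation.  By default the softmax compares the panels'
*prospective resultant* states under the expected removal, with
imminent exposure valued at the panel's reward (`compare="current"`
compares the panels' current states; both give the same qualitative
trends).

Each agent performs the eight trials once, learning as it goes, and
choice is measured on those trials.  This early-learning protocol is
essential to the phenomenon: with extended training the value function
converges, TD surprises — and with them h — vanish along the white
panel's chain, and the small-early reward dominates for any α (the
large-late panel's discounted value only overtakes the white panel's
for γ ≳ 0.79).  In the early regime the white panel's imminent reward
generates the larger TD-error risk, so increasing α robustly and
monotonically shifts choice to the delayed reward (≈ 0.08 → 0.31 over
α ∈ [0, 2] at 2000 agents).  The discount factor has almost no
leverage at these horizons: the γ ∈ {0.5, 0.6, 0.7} curves coincide
within Monte-Carlo error at every training depth we examined, in both
comparison modes — a known limitation; the model expresses the
preference shift through α, not γ.

**Reversal learning.**  Two stimuli, one rewarding (+1) and one
punishing (−1); the agent predicts the outcome of the shown stimulus
(β = 10).  The design's complementarity is enforced exactly:
Q(s, a1) = −Q(s, a2) and Q(s1, a) = −Q(s2, a), leaving one free value,
which stays in [−1, 1] by induction; h is kept per (stimulus, action)
without coupling.  The chosen pair is updated, then the other three
entries are set from the rules.  Stages end when cumulative correct
responses reach a criterion drawn uniformly from {5..9}; blocks end
after 16 reversal stages or 120 trials; each agent runs two blocks per
condition (unexpected reward / unexpected punishment) in shuffled
order with fresh tables per block.  Erroneous trials repeat the same
stimulus.  Errors are tallied on non-reversal trials (the first trial
of a reversed stage is the reversal trial, the next the switch trial;
acquisition trials are included) and reported as sqrt(counts), per the
field's convention for count data.

The reinforcement signal is the stimulus's outcome value itself
(`outcome_coding="association"`): correctly predicting punishment is
still a −1 experience.  This is deliberately in tension with the
complementarity constraint — both correct responses share the single
free value but pull it in opposite directions — and that tension is
the mechanism of the headline result: the correct response to the
punishing stimulus accumulates large risk (its TD errors have
magnitude 1 + |Q|), so a higher α penalises it more and punishment-
prediction errors rise with α while reward-prediction errors move
less.  Removing the sign(Q) term makes the error pattern flat in α
(the asymmetry loses its α-dependence).  A side effect is a high
absolute error rate (blocks typically run to the 120-trial cap): the
model reproduces the experimental *trends*, not error magnitudes.
The alternative `outcome_coding="correctness"` (correct = +1,
error = −1) is consistent with the complementarity constraint and
learns the task cleanly, but it is exactly symmetric between trial
types and therefore shows no reward/punishment asymmetry; it serves
as a control.

## Harness and fitting

`bgrisk.harness` validates declarative configs (YAML/JSON; unknown
keys rejected with field-level messages), dispatches to the task
runners, and writes tidy CSVs (columns: experiment, condition,
statistic, mean, se, n, seed, alpha, beta, gamma, eta_q, eta_h; SE is
sample SD / √N, 0 for N = 1).  `bgrisk.fitting` provides a small
genetic algorithm (tournament selection, uniform crossover, Gaussian
mutation with σ = 10 % of each parameter's range, elitism, clipping to
bounds) for fitting parameters to behavioral statistics; its settings
are pragmatic defaults exposed in `SearchConfig`, not empirical
claims.  Noisy objectives benefit from common random numbers (same
seed inside the objective), as in `examples/fit_risk_weight.py`.

## Randomness and reproducibility

Scalar task runners give each agent its own generator derived from
(run seed, agent index), so a given agent's trajectory is independent
of the batch size.  The vectorised delayed-reward runner advances the
whole population in lockstep on one seeded stream; its reproducibility
contract is (seed, n_agents).  Every public entry point takes an
explicit seed.

## What the simulations do and do not show

All results here are synthetic: the tasks are generative models of the
published experimental designs (reward schedules, trial counts, block
structure), not datasets.  Agreement with the paradigms is directional
— choice-frequency and error-count *trends* under parameter changes —
and says nothing about fits to individual subjects, reaction times, or
neural signals.  Known limitations, found and verified in this
implementation: the saccade-task serotonin trend inverts at full
convergence (transient effect, above); the equal-expected-value
classical-RL baseline is not exactly 0.5 but ≈ 0.53 safe, the
hot-stove sampling bias of on-policy softmax learning (a downward
excursion of the risky value reduces its selection and hence its
correction rate; the bias grows with outcome variance); the discount
factor moves delayed-reward choice only negligibly; and reversal-task
error magnitudes are far above human rates.
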