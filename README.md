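# bgrisk — risk-sensitive reinforcement learning for basal-ganglia decision making

`bgrisk` implements a tabular reinforcement-learning model in which two
neuromodulatory signals shape choice: the temporal-difference (TD)
error δ, the classic dopamine correlate, drives learning of action
values *Q*, while a running estimate *h* of the TD-error variance
("risk") is weighted into the decision by a parameter α, the serotonin
(5HT) correlate.  Lowering α models tryptophan depletion, the standard
experimental manipulation of brain serotonin.  The package is aimed at
computational-neuroscience and neuroeconomics researchers who want a
tested, reproducible implementation of the model and of the four
behavioral paradigms it explains.

## The model

For each state–action pair, zero-initialised tables are updated after
every decision (learning rates η_Q, η_h ∈ (0, 1)):

    δ_t  = r_t − Q_t(s, a)                 (immediate-reward tasks)
    δ_t  = r_{t+1} + γ Q_t(s') − Q_t(s)    (delayed-reward tasks)
    Q_{t+1}(s, a) = Q_t(s, a) + η_Q δ_t
    ξ_t  = δ_t² − h_t(s, a)
    h_{t+1}(s, a) = h_t(s, a) + η_h ξ_t

so *h* converges to the variance of the TD error.  Choice acts on the
sign-dependent mean–risk utility

    U(s, a) = Q(s, a) − α · sign(Q(s, a)) · √h(s, a)

which is risk-averse for gains (Q > 0) and risk-seeking for losses
(Q < 0), the asymmetry of human risk preference.  Actions are drawn
from a softmax with inverse temperature β:

    P(a | s) = exp(β U(s, a)) / Σ_i exp(β U(s, i))

Four task simulators exercise the model:

| task | module | what varies | fitted parameters |
|---|---|---|---|
| bee foraging (two-armed bandit, reversal at trial 15) | `bgrisk.bee` | reward variance between equal-mean arms | η_Q = 0.001, η_h = 0.051, α = 1.5, β = 10 |
| saccade task under tryptophan depletion | `bgrisk.rtd` | α (5HT level); subjective reward r − 193.2 ms | α = 1.985 baseline / 1.658 RTD, β = 0.044 |
| delayed-reward patch removal | `bgrisk.delayed` | α × discount γ | β = 20, γ ∈ {0.5, 0.6, 0.7} |
| reward/punishment reversal learning | `bgrisk.reversal` | α; complementarity-locked values | α = 0.5 balanced / 0.3 depleted, β = 10 |

## A worked example

```python
from bgrisk import bee

res = bee.run_bee_experiment(bee.BEE_PARAMS, n_agents=1000, seed=1)
print(res.switch_latency())          # 3
print(res.q_final.mean(axis=0))      # [0.017 0.023]
print(res.h_final.mean(axis=0))      # [1.218 0.83 ]
```

One thousand simulated bees choose between blue flowers (1 µl of
nectar, always) and yellow flowers (3 µl one time in three).  Both
arms have mean reward 1 and the value learning rate is deliberately
tiny, so the learned values stay near zero — the preference for the
safe flower, and the switch of the population-modal choice only **3
trials** after the contingencies reverse, are carried entirely by the
risk estimates (final h ≈ 1.2 on the arm that is risky at session end
vs 0.8).

The other capabilities are shown in `examples/` (one short script
each): `bee_foraging.py`, `tryptophan_depletion.py`,
`delayed_reward_sweep.py`, `reversal_learning.py`, `fit_risk_weight.py`.
Representative output, 100 agents per condition:

```
baseline (alpha=1.985): P(safe) overall=0.336±0.013  EEV=0.309  UEV=0.392
RTD      (alpha=1.658): P(safe) overall=0.307±0.011  EEV=0.271  UEV=0.379
```

— depleting serotonin (lower α) shifts choice toward the risky target
in every split — and for the reversal task:

```
balanced  (alpha=0.5): sqrt errors  reward-prediction=16.49±0.29  punishment-prediction=8.90±0.26
depleted  (alpha=0.3): sqrt errors  reward-prediction=19.97±0.15  punishment-prediction=4.51±0.21
```

— depletion selectively reduces punishment-prediction errors.

A thin CLI mirrors the library (`bgrisk bee`, `bgrisk rtd`,
`bgrisk delayed`, `bgrisk reversal`, `bgrisk sweep`, `bgrisk fit`);
every subcommand takes `--seed` and writes a tidy CSV with `--out`.
Declarative YAML/JSON configs are supported via `--config` (schema:
`experiment`, optional `params` with `alpha/beta/gamma/eta_q/eta_h`,
`n_agents`, `seed`, `task` overrides; unknown keys are rejected).

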