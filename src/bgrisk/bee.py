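"""Bee-foraging two-armed bandit with a mid-session contingency reversal.

Bees choose between blue and yellow flowers that deliver the same mean
nectar volume but different variance: initially every blue flower gives
1 ul while one third of yellow flowers give 3 ul and the rest nothing.
From the reversal trial onward the contingencies are swapped.  Because
both arms share the same mean, a value-only learner is indifferent; the
risk-sensitive agent prefers the low-variance arm while expected value
is positive, reproducing the bees' risk aversion and their rapid switch
after the reversal.

The task has no state: each trial is one immediate-reward decision
between the two arms ("blue" = arm 0, "yellow" = arm 1).  Trials are
numbered from 1; the swap applies from ``reversal_trial`` inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .params import AgentParams

__all__ = [
    "BeeTaskSpec",
    "BEE_PARAMS",
    "bee_reward",
    "run_bee_experiment",
    "run_bee_stationary",
    "BeeResult",
]

ARMS = ("blue", "yellow")

#: Behavioral parameters fitted for this task (beta from the policy).
BEE_PARAMS = AgentParams(alpha=1.5, beta=10.0, eta_q=0.001, eta_h=0.051)


@dataclass(frozen=True)
class BeeTaskSpec:
    reward_safe: float = 1.0
    reward_risky_high: float = 3.0
    p_risky_high: float = 1.0 / 3.0
    reversal_trial: int = 15
    total_trials: int = 40

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_risky_high <= 1.0:
            raise ValueError("p_risky_high must be a probability")
        if self.reversal_trial < 1:
            raise ValueError("reversal_trial must be >= 1")
        # reversal_trial > total_trials is allowed: no reversal occurs
        # within the session (used for stationary convergence runs).


def bee_reward(
    arm: str, trial: int, rng: np.random.Generator, spec: BeeTaskSpec | None = None
) -> float:
    """Nectar reward for choosing ``arm`` on 1-indexed ``trial``.

    Before the reversal, blue is the safe arm (always ``reward_safe``)
    and yellow the risky one (``reward_risky_high`` with probability
    ``p_risky_high``, else 0); from ``reversal_trial`` onward the two
    contingencies are swapped.
    """
    spec = spec or BeeTaskSpec()
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if not 1 <= trial <= spec.total_trials:
        raise ValueError(f"trial {trial} outside session of {spec.total_trials}")
    reversed_ = trial >= spec.reversal_trial
    safe_arm = "yellow" if reversed_ else "blue"
    if arm == safe_arm:
        return spec.reward_safe
    return spec.reward_risky_high if rng.random() < spec.p_risky_high else 0.0


@dataclass
class BeeResult:
    """Population summary of a bee-foraging run."""

    frac_blue: np.ndarray  # shape (total_trials,) — fraction of agents on blue
    q_final: np.ndarray  # shape (n_agents, 2) — final Q per arm
    h_final: np.ndarray  # shape (n_agents, 2)
    choices: np.ndarray  # shape (n_agents, total_trials), 0 = blue, 1 = yellow
    spec: BeeTaskSpec
    n_agents: int

    def switch_latency(self) -> int:
        """Trials elapsed after the reversal until the population-modal
        choice is the newly safe (yellow) arm.

        Returns ``t* - reversal_trial`` where ``t*`` is the first trial
        at or after the reversal on which the majority of agents choose
        yellow.  Raises if the majority never switches.
        """
        rev = self.spec.reversal_trial
        for t in range(rev, self.spec.total_trials + 1):
            if self.frac_blue[t - 1] < 0.5:
                return t - rev
        raise RuntimeError("population never switched to the newly safe arm")


def run_bee_experiment(
    params: AgentParams = BEE_PARAMS,
    spec: BeeTaskSpec | None = None,
    n_agents: int = 1000,
    seed: int = 0,
) -> BeeResult:
    """Simulate ``n_agents`` independent bees over one session.

    Each agent keeps a per-arm Q and h (zero-initialised), updates only
    the chosen arm with the immediate-reward TD error, and chooses by
    softmax over the sign-dependent utilities.
    """
    spec = spec or BeeTaskSpec()
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    choices = np.empty((n_agents, spec.total_trials), dtype=np.int8)
    q_final = np.empty((n_agents, 2))
    h_final = np.empty((n_agents, 2))
    for i in range(n_agents):
        rng = core.agent_rng(seed, i)
        q = [0.0, 0.0]
        h = [0.0, 0.0]
        for t in range(1, spec.total_trials + 1):
            u = core.utilities_for(params, q, h)
            probs = core.softmax_probs(u, params.beta)
            a = core.sample_action(probs, rng)
            r = bee_reward(ARMS[a], t, rng, spec)
            delta = core.td_error_immediate(r, q[a])
            xi = core.risk_error(delta, h[a])
            q[a] = core.update_value(q[a], delta, params.eta_q)
            h[a] = core.update_risk(h[a], xi, params.eta_h)
            choices[i, t - 1] = a
        q_final[i] = q
        h_final[i] = h
    frac_blue = (choices == 0).mean(axis=0)
    return BeeResult(frac_blue, q_final, h_final, choices, spec, n_agents)


def run_bee_stationary(
    params: AgentParams,
    n_agents: int = 100,
    n_trials: int = 5000,
    seed: int = 0,
    spec: BeeTaskSpec | None = None,
) -> BeeResult:
    """Bee bandit without reversal, for convergence studies.

    Uses the same learning loop but holds the initial contingencies for
    all ``n_trials`` (the session is extended and the reversal pushed
    past its end).
    """
    base = spec or BeeTaskSpec()
    stationary = BeeTaskSpec(
        reward_safe=base.reward_safe,
        reward_risky_high=base.reward_risky_high,
        p_risky_high=base.p_risky_high,
        reversal_trial=n_trials + 1,
        total_trials=n_trials,
    )
    return run_bee_experiment(params, stationary, n_agents, seed)
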