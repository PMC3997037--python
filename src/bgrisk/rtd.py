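"""Tryptophan-depletion saccade task: safe vs risky juice targets.

Monkeys saccade to one of two targets: the safe target delivers a fixed
juice time, the risky target one of two juice times with probability
0.5 each.  Six reward schedules (states) are used; in the first four
the two targets share the same expected value (EEV), in the last two
they do not (UEV).  Rapid tryptophan depletion (RTD), which lowers
brain serotonin, is modeled by lowering the risk weight alpha
(fitted: 1.658 under RTD vs 1.985 at baseline, with softmax beta
0.044).

A fixed reward base of 193.2 ms is subtracted from every juice time so
that small rewards land in a loss frame: the agent learns on the
subjective reward r = r_juice - 193.2.  Each state keeps its own
(Q, h) per action and is updated with the immediate-reward TD error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .params import AgentParams

__all__ = [
    "RTDStateSpec",
    "SubjectiveRewardRule",
    "REWARD_BASE",
    "ALPHA_BASELINE",
    "ALPHA_RTD",
    "RTD_BETA",
    "subjective_reward",
    "make_rtd_schedule",
    "run_rtd_experiment",
    "converged_tables",
    "RTDResult",
]

REWARD_BASE = 193.2
ALPHA_BASELINE = 1.985
ALPHA_RTD = 1.658
RTD_BETA = 0.044

SAFE, RISKY = 0, 1


@dataclass(frozen=True)
class SubjectiveRewardRule:
    reward_base: float = REWARD_BASE

    def __post_init__(self) -> None:
        if self.reward_base <= 0:
            raise ValueError("reward_base must be > 0")


def subjective_reward(r_juice: float, rule: SubjectiveRewardRule | None = None) -> float:
    """Subjective reward r = r_juice - reward_base.

    Juice times below the base map to negative rewards (loss frame),
    above it to gains.
    """
    rule = rule or SubjectiveRewardRule()
    if r_juice < 0:
        raise ValueError("juice time must be >= 0")
    return r_juice - rule.reward_base


@dataclass(frozen=True)
class RTDStateSpec:
    """One reward schedule (state) of the saccade task."""

    state_id: int
    safe_ms: float
    risky_ms: tuple[float, float]  # each outcome with probability 0.5

    @property
    def ev_class(self) -> str:
        """'EEV' if the safe juice time equals the risky mean, else 'UEV'."""
        risky_mean = sum(self.risky_ms) / 2.0
        return "EEV" if abs(self.safe_ms - risky_mean) < 1e-9 else "UEV"


_SCHEDULE_ROWS = [
    (1, 150.0, (125.0, 175.0)),
    (2, 150.0, (100.0, 200.0)),
    (3, 150.0, (50.0, 250.0)),
    (4, 140.0, (40.0, 240.0)),
    (5, 200.0, (40.0, 240.0)),
    (6, 210.0, (40.0, 240.0)),
]


def make_rtd_schedule() -> list[RTDStateSpec]:
    """The six reward schedules of the task, EEV/UEV labelled by mean."""
    return [RTDStateSpec(i, safe, risky) for i, safe, risky in _SCHEDULE_ROWS]


@dataclass
class RTDResult:
    """Safe-choice frequencies, overall and split by expected-value class."""

    p_safe_overall: float
    p_safe_eev: float
    p_safe_uev: float
    se_overall: float
    se_eev: float
    se_uev: float
    per_agent_overall: np.ndarray
    q_final: np.ndarray  # (n_agents, n_states, 2)
    h_final: np.ndarray
    n_agents: int


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return m, se


def run_rtd_experiment(
    params: AgentParams,
    n_agents: int = 100,
    n_trials_per_state: int = 200,
    seed: int = 0,
    states: list[RTDStateSpec] | None = None,
    rule: SubjectiveRewardRule | None = None,
    measure_last: int | None = None,
) -> RTDResult:
    """Train agents on the saccade task and report safe-choice rates.

    Each agent sees every state ``n_trials_per_state`` times, in
    uniformly shuffled order within each round of presentations.  Safe
    and risky actions keep separate (Q, h) entries per state, updated
    on subjective rewards with the immediate-reward TD error; the
    policy is softmax over the sign-dependent utilities.

    ``measure_last`` restricts the reported frequencies to the final N
    presentations per state (learning still spans the whole run);
    otherwise the whole run is counted.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    states = states if states is not None else make_rtd_schedule()
    rule = rule or SubjectiveRewardRule()
    n_states = len(states)
    eev_mask = np.array([s.ev_class == "EEV" for s in states])

    safe_counts = np.zeros((n_agents, n_states))
    totals = np.zeros((n_agents, n_states))
    q_final = np.zeros((n_agents, n_states, 2))
    h_final = np.zeros((n_agents, n_states, 2))
    first_counted = (
        n_trials_per_state - measure_last if measure_last is not None else 0
    )

    for i in range(n_agents):
        rng = core.agent_rng(seed, i)
        q = np.zeros((n_states, 2))
        h = np.zeros((n_states, 2))
        for round_idx in range(n_trials_per_state):
            order = rng.permutation(n_states)
            for s_idx in order:
                spec = states[s_idx]
                u = core.utilities_for(params, q[s_idx], h[s_idx])
                probs = core.softmax_probs(u, params.beta)
                a = core.sample_action(probs, rng)
                if a == SAFE:
                    r_juice = spec.safe_ms
                else:
                    r_juice = spec.risky_ms[rng.random() < 0.5]
                r = subjective_reward(r_juice, rule)
                delta = core.td_error_immediate(r, q[s_idx, a])
                xi = core.risk_error(delta, h[s_idx, a])
                q[s_idx, a] = core.update_value(q[s_idx, a], delta, params.eta_q)
                h[s_idx, a] = core.update_risk(h[s_idx, a], xi, params.eta_h)
                if round_idx >= first_counted:
                    totals[i, s_idx] += 1
                    safe_counts[i, s_idx] += a == SAFE
        q_final[i] = q
        h_final[i] = h

    per_state = safe_counts / totals
    per_agent_overall = per_state.mean(axis=1)
    p_overall, se_overall = _mean_se(per_agent_overall)
    if eev_mask.any():
        p_eev, se_eev = _mean_se(per_state[:, eev_mask].mean(axis=1))
    else:
        p_eev, se_eev = float("nan"), float("nan")
    if (~eev_mask).any():
        p_uev, se_uev = _mean_se(per_state[:, ~eev_mask].mean(axis=1))
    else:
        p_uev, se_uev = float("nan"), float("nan")
    return RTDResult(
        p_overall, p_eev, p_uev, se_overall, se_eev, se_uev,
        per_agent_overall, q_final, h_final, n_agents,
    )


def converged_tables(
    spec: RTDStateSpec, rule: SubjectiveRewardRule | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form fixed points of (Q, h) for one state under sustained
    sampling of both actions.

    Q converges to the mean subjective reward of each action and h to
    the variance of its TD error at convergence (zero for the safe
    action, squared half-spread for the risky one).  Used as the
    independent oracle against which the simulation is checked.
    """
    rule = rule or SubjectiveRewardRule()
    lo, hi = spec.risky_ms
    q_safe = subjective_reward(spec.safe_ms, rule)
    q_risky = subjective_reward((lo + hi) / 2.0, rule)
    h_safe = 0.0
    h_risky = ((hi - lo) / 2.0) ** 2
    return np.array([q_safe, q_risky]), np.array([h_safe, h_risky])
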