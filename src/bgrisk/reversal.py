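"""Deterministic reward/punishment reversal learning.

Two stimuli are shown one at a time; the agent predicts whether the
highlighted stimulus currently leads to reward or punishment.  One
stimulus is rewarding (outcome value +1) and the other punishing (-1);
the mapping reverses repeatedly within a block.  Erroneous trials are
followed by the same stimulus.  Performance is scored on non-reversal
trials, split by outcome trial type (reward- vs punishment-prediction)
and by block condition (unexpected reward vs unexpected punishment).

The task's built-in complementarity leaves a single free action value:
Q(s, a1) = -Q(s, a2) for each stimulus and Q(s1, a) = -Q(s2, a) for
each action, so one learned entry determines all four.  Risk estimates
h are kept per (stimulus, action) without coupling.  Lowering the risk
weight alpha (0.5 balanced -> 0.3 tryptophan-depleted) selectively
reduces punishment-prediction errors, because the correct action on
punishment trials carries a large learned risk (its TD errors have
magnitude 1 + |Q|) that the sign-dependent utility penalises in
proportion to alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .params import AgentParams

__all__ = [
    "REVERSAL_PARAMS",
    "ALPHA_BALANCED",
    "ALPHA_DEPLETED",
    "StimulusActionMap",
    "ReversalBlockSpec",
    "StageState",
    "ErrorTally",
    "enforce_complementarity",
    "stage_controller",
    "run_reversal_trial",
    "run_reversal_block",
    "run_reversal_experiment",
]

ALPHA_BALANCED = 0.5
ALPHA_DEPLETED = 0.3
REVERSAL_PARAMS = AgentParams(alpha=ALPHA_BALANCED, beta=10.0)

PREDICT_REWARD, PREDICT_PUNISH = 0, 1
CONDITIONS = ("unexpected-reward", "unexpected-punishment")
TRIAL_TYPES = ("reward-prediction", "punishment-prediction")


@dataclass(frozen=True)
class ReversalBlockSpec:
    condition: str = "unexpected-reward"
    max_trials: int = 120
    max_reversal_stages: int = 16
    stage_criterion_range: tuple[int, int] = (5, 9)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        lo, hi = self.stage_criterion_range
        if not 1 <= lo <= hi:
            raise ValueError("bad stage criterion range")


def enforce_complementarity(q: np.ndarray, updated_key: tuple[int, int]) -> np.ndarray:
    """Propagate one learned entry to the other three.

    Given the 2x2 action-value array with entry ``updated_key`` freshly
    learned, sets the remaining entries from the two complementarity
    rules (anti-symmetric in both the action and the stimulus index).
    Idempotent.
    """
    s, a = updated_key
    v = q[s, a]
    out = q.copy()
    out[s, 1 - a] = -v
    out[1 - s, a] = -v
    out[1 - s, 1 - a] = v
    return out


class StimulusActionMap:
    """Complementarity-locked Q plus independent risk table h.

    ``rewarding_stimulus`` tracks the current true mapping: the index
    of the stimulus whose outcome is +1.
    """

    def __init__(self, rewarding_stimulus: int = 0) -> None:
        self.q = np.zeros((2, 2))
        self.h = np.zeros((2, 2))
        self.rewarding_stimulus = int(rewarding_stimulus)

    def outcome(self, stimulus: int) -> float:
        """Outcome value of a stimulus under the current mapping."""
        return 1.0 if stimulus == self.rewarding_stimulus else -1.0

    def correct_action(self, stimulus: int) -> int:
        return (
            PREDICT_REWARD
            if stimulus == self.rewarding_stimulus
            else PREDICT_PUNISH
        )

    def reverse(self) -> None:
        self.rewarding_stimulus = 1 - self.rewarding_stimulus

    def learn(
        self,
        stimulus: int,
        action: int,
        params: AgentParams,
        outcome_coding: str = "association",
    ) -> tuple[float, float]:
        """One learning step on the chosen (stimulus, action) pair.

        Returns (delta, xi).  The chosen entry is updated with the
        immediate-reward TD error, the other three Q entries follow by
        complementarity; h is updated for the chosen pair only.

        ``outcome_coding`` selects the reinforcement signal.  Under
        'association' (default) r is the stimulus's current outcome
        value (+1 rewarding, -1 punishing) regardless of the response:
        correctly predicting punishment is then itself punishing, in
        tension with the complementarity constraint (both correct
        responses share the one free value), and that tension — scaled
        by alpha through the risk term — is what produces the
        selective punishment-error effect.  Under 'correctness' a
        correct prediction earns r = +1 and an error r = -1, which is
        consistent with the complementarity constraint and learns the
        task cleanly but is symmetric between trial types, so no
        reward/punishment asymmetry can arise; kept for comparison.
        """
        if outcome_coding == "correctness":
            r = 1.0 if action == self.correct_action(stimulus) else -1.0
        elif outcome_coding == "association":
            r = self.outcome(stimulus)
        else:
            raise ValueError(f"unknown outcome_coding {outcome_coding!r}")
        delta = core.td_error_immediate(r, self.q[stimulus, action])
        xi = core.risk_error(delta, self.h[stimulus, action])
        self.q[stimulus, action] = core.update_value(
            self.q[stimulus, action], delta, params.eta_q
        )
        self.q = enforce_complementarity(self.q, (stimulus, action))
        self.h[stimulus, action] = core.update_risk(
            self.h[stimulus, action], xi, params.eta_h
        )
        return delta, xi


@dataclass
class StageState:
    """Progress through one block's stage/trial budget."""

    target: int
    correct_in_stage: int = 0
    reversals_done: int = 0
    trials_done: int = 0
    spec: ReversalBlockSpec = field(default_factory=ReversalBlockSpec)


def stage_controller(state: StageState, correct: bool, rng: np.random.Generator) -> str:
    """Advance the block controller after one trial.

    A stage ends when the cumulative correct responses reach its
    criterion (drawn uniformly from the 5..9 range per stage); the
    block ends after 16 completed reversal stages or 120 trials,
    whichever comes first.  Returns 'continue', 'reverse' or
    'end-block'; on 'reverse' the next stage's criterion is drawn and
    the stage counters reset.
    """
    state.trials_done += 1
    if correct:
        state.correct_in_stage += 1
    if state.trials_done >= state.spec.max_trials:
        return "end-block"
    if state.correct_in_stage >= state.target:
        if state.reversals_done >= state.spec.max_reversal_stages:
            return "end-block"
        state.reversals_done += 1
        state.correct_in_stage = 0
        lo, hi = state.spec.stage_criterion_range
        state.target = int(rng.integers(lo, hi + 1))
        return "reverse"
    return "continue"


def run_reversal_trial(
    mapping: StimulusActionMap,
    stimulus: int,
    params: AgentParams,
    rng: np.random.Generator,
    trial_index: int = 0,
    outcome_coding: str = "association",
) -> tuple[core.TrialRecord, bool]:
    """One prediction trial: softmax over the two responses' utilities,
    outcome +1/-1 from the stimulus's current association, then learning."""
    if stimulus not in (0, 1):
        raise ValueError("stimulus must be 0 or 1")
    u = core.utilities_for(params, mapping.q[stimulus], mapping.h[stimulus])
    probs = core.softmax_probs(u, params.beta)
    action = core.sample_action(probs, rng)
    correct = action == mapping.correct_action(stimulus)
    delta, xi = mapping.learn(stimulus, action, params, outcome_coding)
    rec = core.TrialRecord(
        trial=trial_index,
        state=stimulus,
        action=action,
        reward=mapping.outcome(stimulus),
        delta=delta,
        xi=xi,
        utilities=u,
        probs=probs,
    )
    return rec, correct


def run_reversal_block(
    spec: ReversalBlockSpec,
    params: AgentParams,
    rng: np.random.Generator,
    outcome_coding: str = "association",
) -> list[dict]:
    """Run one block; returns one dict per trial with labels.

    Trial classes: the first trial after a reversal is the 'reversal'
    trial, the one immediately after it the 'switch' trial, everything
    else (including the whole acquisition stage) 'non-reversal'.
    """
    mapping = StimulusActionMap(rewarding_stimulus=int(rng.integers(2)))
    lo, hi = spec.stage_criterion_range
    state = StageState(target=int(rng.integers(lo, hi + 1)), spec=spec)
    trials: list[dict] = []
    stimulus = int(rng.integers(2))
    trials_since_reversal: int | None = None  # None during acquisition
    while True:
        trial_type = TRIAL_TYPES[mapping.correct_action(stimulus)]
        if trials_since_reversal == 0:
            klass = "reversal"
        elif trials_since_reversal == 1:
            klass = "switch"
        else:
            klass = "non-reversal"
        rec, correct = run_reversal_trial(
            mapping, stimulus, params, rng, trial_index=state.trials_done,
            outcome_coding=outcome_coding,
        )
        trials.append(
            {
                "condition": spec.condition,
                "trial_type": trial_type,
                "class": klass,
                "stimulus": stimulus,
                "action": rec.action,
                "correct": correct,
                "stage": state.reversals_done,
            }
        )
        decision = stage_controller(state, correct, rng)
        if decision == "end-block":
            break
        if decision == "reverse":
            mapping.reverse()
            trials_since_reversal = 0
        elif trials_since_reversal is not None:
            trials_since_reversal += 1
        # erroneous trials repeat the same stimulus
        if correct:
            stimulus = int(rng.integers(2))
    return trials


@dataclass
class ErrorTally:
    """Square-root error counts on counted trials, per agent.

    ``by_type`` and ``by_condition`` hold raw per-agent error counts
    (columns ordered as TRIAL_TYPES / CONDITIONS); reported statistics
    follow the convention of presenting sqrt(counts).
    """

    by_type: np.ndarray  # (n_agents, 2) ints
    by_condition: np.ndarray  # (n_agents, 2) ints
    n_agents: int

    def sqrt_mean_se(self, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = np.sqrt(counts)
        se = (
            s.std(axis=0, ddof=1) / np.sqrt(self.n_agents)
            if self.n_agents > 1
            else np.zeros(counts.shape[1])
        )
        return s.mean(axis=0), se

    @property
    def type_stats(self):
        """(mean, se) of sqrt errors per outcome trial type."""
        return self.sqrt_mean_se(self.by_type)

    @property
    def condition_stats(self):
        """(mean, se) of sqrt errors per block condition."""
        return self.sqrt_mean_se(self.by_condition)


def run_reversal_experiment(
    alpha: float,
    n_agents: int = 100,
    seed: int = 0,
    params: AgentParams | None = None,
    counted_classes: tuple[str, ...] = ("non-reversal",),
    outcome_coding: str = "association",
) -> ErrorTally:
    """Run the full four-block session for a population of agents.

    Each agent performs two blocks per condition in a shuffled order,
    with fresh stimuli (fresh tables) per block; errors on counted
    trial classes are tallied by outcome trial type and by condition.
    Acquisition-stage trials are included.
    """
    base = params or REVERSAL_PARAMS
    p = base.with_(alpha=alpha)
    by_type = np.zeros((n_agents, 2), dtype=int)
    by_cond = np.zeros((n_agents, 2), dtype=int)
    for i in range(n_agents):
        rng = core.agent_rng(seed, i)
        blocks = [CONDITIONS[0]] * 2 + [CONDITIONS[1]] * 2
        order = rng.permutation(4)
        for b in order:
            spec = ReversalBlockSpec(condition=blocks[b])
            for t in run_reversal_block(spec, p, rng, outcome_coding):
                if t["class"] in counted_classes and not t["correct"]:
                    by_type[i, TRIAL_TYPES.index(t["trial_type"])] += 1
                    by_cond[i, CONDITIONS.index(t["condition"])] += 1
    return ErrorTally(by_type, by_cond, n_agents)
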