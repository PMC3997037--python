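"""Mathematical core of the risk-sensitive RL model.

The model learns, per (state, action) pair, an action value Q (expected
cumulative reward; its prediction error delta is the dopamine
correlate) and a risk estimate h (a running mean of delta^2, i.e. the
TD-error variance).  Action selection acts on a utility

    U = Q - alpha * sign(Q) * sqrt(h)

so that for positive expected value (gains) risk is penalised
(risk-aversion) and for negative expected value (losses) risk is
rewarded (risk-seeking), with alpha — the serotonin correlate —
scaling the effect.  A softmax policy with inverse temperature beta
turns utilities into choice probabilities.

All functions here are scalar and stateless; tasks compose them.  The
tabular containers default every unseen key to zero, matching the
zero initialisation of Q and h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .params import AgentParams

__all__ = [
    "ValueTable",
    "RiskTable",
    "TrialRecord",
    "td_error_immediate",
    "td_error_discounted",
    "update_value",
    "risk_error",
    "update_risk",
    "utility",
    "softmax_probs",
    "sample_action",
    "agent_rng",
]

PROB_TOL = 1e-12  # normalisation tolerance for probability vectors


def _check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# Tabular containers


class ValueTable:
    """Map (state, action) -> Q, defaulting to 0 for unseen keys."""

    def __init__(self) -> None:
        self._d: dict[Hashable, float] = {}

    def get(self, key: Hashable) -> float:
        return self._d.get(key, 0.0)

    def set(self, key: Hashable, value: float) -> None:
        self._d[key] = _check_finite("Q", value)

    def keys(self) -> Iterable[Hashable]:
        return self._d.keys()

    def items(self):
        return self._d.items()

    def __len__(self) -> int:
        return len(self._d)


class RiskTable(ValueTable):
    """Map (state, action) -> h.  Entries must stay nonnegative.

    The update rule h <- (1 - eta_h) h + eta_h delta^2 is a convex
    combination of two nonnegative quantities, so a negative entry can
    only arise from a contract violation upstream; ``set`` rejects it.
    """

    def set(self, key: Hashable, value: float) -> None:
        v = _check_finite("h", value)
        if v < 0:
            raise ValueError(f"risk estimate must be >= 0, got {v}")
        self._d[key] = v


@dataclass
class TrialRecord:
    """One decision event."""

    trial: int
    state: Hashable
    action: int
    reward: float
    delta: float
    xi: float
    utilities: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.utilities = np.asarray(self.utilities, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("choice probabilities must sum to 1")
        if not 0 <= self.action < len(self.utilities):
            raise ValueError("action index out of range")


# ---------------------------------------------------------------------------
# Prediction errors and updates


def td_error_immediate(reward: float, q: float) -> float:
    """TD error for single-decision (immediate reward) problems:
    delta = r - Q(s, a)."""
    return _check_finite("reward", reward) - _check_finite("q", q)


def td_error_discounted(
    reward: float, q_next: float, q_curr: float, gamma: float
) -> float:
    """Discounted TD error delta = r + gamma * Q(s') - Q(s).

    For a terminal successor the caller passes ``q_next = 0``.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    return (
        _check_finite("reward", reward)
        + gamma * _check_finite("q_next", q_next)
        - _check_finite("q_curr", q_curr)
    )


def update_value(q: float, delta: float, eta_q: float) -> float:
    """Incremental value update Q <- Q + eta_q * delta."""
    if not 0.0 < eta_q < 1.0:
        raise ValueError(f"eta_q must be in (0, 1), got {eta_q}")
    return q + eta_q * delta


def risk_error(delta: float, h: float) -> float:
    """Risk prediction error xi = delta^2 - h."""
    if h < 0:
        raise ValueError(f"risk estimate must be >= 0, got {h}")
    return delta * delta - h


def update_risk(h: float, xi: float, eta_h: float) -> float:
    """Incremental risk update h <- h + eta_h * xi.

    With ``xi`` produced by :func:`risk_error` from the same ``h`` this
    equals (1 - eta_h) h + eta_h delta^2, hence stays nonnegative.
    """
    if not 0.0 < eta_h < 1.0:
        raise ValueError(f"eta_h must be in (0, 1), got {eta_h}")
    h_new = h + eta_h * xi
    if h_new < 0:
        raise ValueError(
            "risk update produced a negative estimate; "
            "xi was not derived from this h"
        )
    return h_new


# ---------------------------------------------------------------------------
# Utility and policy


def utility(
    q: float,
    h: float,
    alpha: float,
    risk_transform: str = "sqrt",
    sign_dependent: bool = True,
) -> float:
    """Sign-dependent mean-risk utility.

    Default form: U = Q - alpha * sign(Q) * sqrt(h), with sign(0) = 0
    so that the risk term vanishes at neutral value.  ``risk_transform
    = 'identity'`` penalises raw h instead of its square root;
    ``sign_dependent = False`` drops the sign factor (always
    risk-averse), both for sensitivity analyses.
    """
    if h < 0:
        raise ValueError(f"risk estimate must be >= 0, got {h}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if risk_transform not in ("sqrt", "identity"):
        raise ValueError(f"unknown risk_transform {risk_transform!r}")
    risk = math.sqrt(h) if risk_transform == "sqrt" else h
    s = math.copysign(1.0, q) if q != 0 else 0.0
    if not sign_dependent:
        s = 1.0
    return q - alpha * s * risk


def utilities_for(
    params: AgentParams, qs: Sequence[float], hs: Sequence[float]
) -> np.ndarray:
    """Vector of utilities for one decision, given per-action Q and h."""
    return np.array(
        [
            utility(q, h, params.alpha, params.risk_transform, params.sign_dependent)
            for q, h in zip(qs, hs, strict=True)
        ]
    )


def softmax_probs(utilities: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities P_i = exp(beta u_i) / sum_j exp(beta u_j).

    Computed with max-subtraction so large beta*u cannot overflow.
    """
    u = np.asarray(utilities, dtype=float)
    if u.size == 0:
        raise ValueError("utility vector must be non-empty")
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    z = beta * u
    z -= z.max()
    e = np.exp(z)
    p = e / e.sum()
    assert abs(p.sum() - 1.0) <= PROB_TOL
    return p


def sample_action(probs: Sequence[float], rng: np.random.Generator) -> int:
    """Draw an action index from a probability vector."""
    p = np.asarray(probs, dtype=float)
    if p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("malformed probability vector")
    # inverse-CDF draw; one uniform per call keeps stream use predictable
    return int(np.searchsorted(np.cumsum(p), rng.random(), side="right").clip(0, p.size - 1))


def agent_rng(seed: int, agent_index: int) -> np.random.Generator:
    """Per-agent generator derived from a run-level seed.

    Each simulated agent gets an independent stream keyed by its index,
    so trajectories are reproducible regardless of how many agents run
    in the same batch.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(agent_index)]))
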