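"""Agent parameterisation.

The model has five free behavioral parameters:

``alpha``
    Risk weight (dimensionless, >= 0).  Trades expected value against
    risk in the utility; interpreted as the serotonin (5HT) correlate —
    tryptophan depletion is modeled by lowering ``alpha``.
``beta``
    Inverse temperature (>= 0) of the softmax policy.  ``beta -> 0``
    makes all actions equiprobable; large ``beta`` approaches greedy
    selection.
``gamma``
    Discount factor in [0, 1) for delayed-reward problems; immediate
    reward tasks use the undiscounted TD error and ignore it.
``eta_q``
    Learning rate of the action-value function Q, in (0, 1).
``eta_h``
    Learning rate of the risk (TD-error variance) function h, in (0, 1).

Two structural switches are carried alongside the numeric parameters:
``risk_transform`` chooses whether the utility penalises sqrt(h)
(mean-standard-deviation form, the default) or raw h, and
``sign_dependent`` toggles the sign(Q) factor that produces
risk-aversion for gains and risk-seeking for losses.  Both switches
exist for sensitivity analyses; defaults are the model proper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

RiskTransform = Literal["sqrt", "identity"]

#: Default learning rates shared by all tasks unless a task-specific
#: fit overrides them.
DEFAULT_ETA = 0.1


@dataclass(frozen=True)
class AgentParams:
    """Immutable record of one agent's free parameters.

    Raises ``ValueError`` on construction if any field is non-finite or
    outside its admissible range.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.0
    eta_q: float = DEFAULT_ETA
    eta_h: float = DEFAULT_ETA
    risk_transform: RiskTransform = "sqrt"
    sign_dependent: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "eta_q", "eta_h"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if not 0.0 < self.eta_q < 1.0:
            raise ValueError(f"eta_q must be in (0, 1), got {self.eta_q}")
        if not 0.0 < self.eta_h < 1.0:
            raise ValueError(f"eta_h must be in (0, 1), got {self.eta_h}")
        if self.risk_transform not in ("sqrt", "identity"):
            raise ValueError(
                f"risk_transform must be 'sqrt' or 'identity', got {self.risk_transform!r}"
            )

    def with_(self, **kwargs) -> "AgentParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)
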