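"""Meta-choice: is mental simulation worth its cost?

Before choosing at a decision state, the agent decides — separately for
each action — whether to improve that action's value estimate by mental
simulation. The benefit is scored by an approximate value of information:

    VoI(a) = C(a) / (|Q(a) - Q(other)| + eps)

High uncertainty about an action's value, or near-tied cached values, make
simulation worthwhile; a confidently large value gap makes it pointless.
The cost of simulating is a fixed threshold gamma: simulation runs only
when VoI strictly exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .maze import ACTIONS
from .values import AgentParams, ValueTable


def value_of_information(
    c_act: float, q_act: float, q_alt: float, epsilon: float
) -> float:
    """Approximate VoI of simulating one action against its alternative."""
    if c_act < 0:
        raise ValueError("uncertainty must be >= 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return c_act / (abs(q_act - q_alt) + epsilon)


@dataclass(frozen=True)
class MetaDecision:
    """Per-action VoI and simulate/rely-on-cache flags for one visit."""

    voi: dict[str, float]
    simulate: dict[str, bool]
    gamma: float


def decide_meta(values: ValueTable, state: str, params: AgentParams) -> MetaDecision:
    """Score both actions at `state` and flag each for simulation iff its
    VoI strictly exceeds gamma (ties go to the cheaper option: no
    simulation). Both VoIs use the pre-simulation cached values, and the
    two flags are independent — the agent may simulate only the more
    uncertain action.
    """
    if not values.is_decision(state):
        raise ValueError(f"{state} is not a decision state")
    a1, a2 = ACTIONS
    voi = {
        a1: value_of_information(
            values.c[(state, a1)], values.q[(state, a1)], values.q[(state, a2)],
            params.epsilon,
        ),
        a2: value_of_information(
            values.c[(state, a2)], values.q[(state, a2)], values.q[(state, a1)],
            params.epsilon,
        ),
    }
    simulate = {a: v > params.gamma for a, v in voi.items()}
    return MetaDecision(voi=voi, simulate=simulate, gamma=params.gamma)
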