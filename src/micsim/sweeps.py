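"""Forward sweeps: mental simulation as sequential sampling.

A sweep is one simulated rollout from the current decision state. The
first step is clamped to the action under evaluation; each later step
draws an action uniformly at random. Along the way the sweep accumulates
the learned mean rewards R̂ of the states it enters, discounted per step,
yielding one pseudo-observation O.

How much simulation happens is uncertainty-scaled:

* number of sweeps = round(lambda_coef * C), so a well-known action is
  simulated little or not at all;
* depth: when C > zeta the sweep runs to a leaf (a whole path); otherwise
  it is truncated after eta transitions and, if it stops at a decision
  state, bootstraps with a cached Q value there (a return, aggregating the
  remaining future, rather than a reward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .maze import MazeSpec
from .values import AgentParams, RewardModel, ValueTable


@dataclass(frozen=True)
class SweepMode:
    """Depth rule for one batch of sweeps: run to a leaf, or stop after
    `length` transitions."""

    full: bool
    length: int | None = None


def full_path() -> SweepMode:
    return SweepMode(full=True)


def truncated(length: int) -> SweepMode:
    if length < 1:
        raise ValueError("truncated sweep length must be >= 1")
    return SweepMode(full=False, length=length)


@dataclass(frozen=True)
class SweepResult:
    """One rollout: the states visited, its length in transitions, the
    pseudo-observation it produced, and whether it was cut short."""

    visited: tuple[str, ...]
    length: int
    pseudo_obs: float
    truncated: bool


def n_sweeps(c_act: float, lambda_coef: float) -> int:
    """round(lambda_coef * C), ties rounded half-up, floor 0."""
    if c_act < 0:
        raise ValueError("uncertainty must be >= 0")
    return max(0, int(math.floor(lambda_coef * c_act + 0.5)))


def sweep_depth_mode(c_act: float, zeta: float, eta: int) -> SweepMode:
    """Whole-path sweeps iff C strictly exceeds zeta, else truncated(eta)."""
    return full_path() if c_act > zeta else truncated(eta)


def run_sweep(
    maze: MazeSpec,
    reward_model: RewardModel,
    values: ValueTable,
    start: str,
    action: str,
    mode: SweepMode,
    delta: float,
    rng: np.random.Generator,
    bootstrap: str = "random",
) -> SweepResult:
    """One rollout from `start` with the first step clamped to `action`.

    O = sum_t delta^t * R̂(s_{t+1}) over the states entered, plus — if the
    sweep is truncated at a decision state — delta^length times a Q value
    retrieved there (`bootstrap`: a uniformly random action's Q, or the
    best action's). The start state's own R̂ is not counted.
    """
    if not maze.is_decision(start):
        raise ValueError(f"{start} is not a decision state")
    visited = [start]
    state = start
    o = 0.0
    t = 0
    next_action = action
    while True:
        state = maze.step(state, next_action)
        visited.append(state)
        o += delta**t * reward_model.r_hat[state]
        t += 1
        if maze.is_leaf(state):
            was_truncated = False
            break
        if not mode.full and t >= mode.length:
            if bootstrap == "best":
                q_boot = values.best_q(state)
            else:
                a_boot = maze.actions[rng.integers(len(maze.actions))]
                q_boot = values.q[(state, a_boot)]
            o += delta**t * q_boot
            was_truncated = True
            break
        next_action = maze.actions[rng.integers(len(maze.actions))]
    return SweepResult(
        visited=tuple(visited), length=t, pseudo_obs=float(o), truncated=was_truncated
    )


def simulate_action(
    maze: MazeSpec,
    reward_model: RewardModel,
    values: ValueTable,
    state: str,
    action: str,
    params: AgentParams,
    rng: np.random.Generator,
) -> list[SweepResult]:
    """Run the full batch of sweeps for one flagged action.

    The batch size is round(lambda_coef * C(state, action)) and every sweep
    uses the depth mode implied by the same uncertainty. Returns the sweep
    records in order; their ``pseudo_obs`` fields are the O values to fuse.
    """
    c_act = values.c[(state, action)]
    count = n_sweeps(c_act, params.lambda_coef)
    mode = sweep_depth_mode(c_act, params.zeta, params.eta)
    return [
        run_sweep(
            maze, reward_model, values, state, action, mode, params.delta, rng,
            bootstrap=params.truncation_bootstrap,
        )
        for _ in range(count)
    ]
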