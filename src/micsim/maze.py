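"""Double T-maze environment.

The maze is a deterministic discrete MDP shaped as a depth-2 binary tree:
three decision states (S1 at the stem, S2/S3 at the first junctions) and
four terminal arms (S4..S7). At each decision state the agent turns left or
right; transitions are deterministic and known to the agent. Rewards are
Gaussian per state, with means and variances that may change at scheduled
trial boundaries (non-stationary schedules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

LEFT = "left"
RIGHT = "right"
ACTIONS = (LEFT, RIGHT)

START = "S1"


class MazeError(ValueError):
    """Invalid state/action lookup — signals a caller bug, not bad data."""


@dataclass(frozen=True)
class MazeSpec:
    """A discrete state/action graph with deterministic transitions.

    Decision states carry exactly the two actions ``left``/``right``;
    leaves are terminal and have no transitions.
    """

    states: tuple[str, ...]
    decision_states: frozenset[str]
    leaf_states: frozenset[str]
    actions: tuple[str, ...]
    transitions: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        for s in self.decision_states:
            for a in self.actions:
                if (s, a) not in self.transitions:
                    raise MazeError(f"decision state {s} lacks action {a}")
        for (s, a), nxt in self.transitions.items():
            if s in self.leaf_states:
                raise MazeError(f"leaf state {s} must not have transitions")
            if nxt not in self.states:
                raise MazeError(f"transition ({s},{a}) -> unknown state {nxt}")

    def is_decision(self, state: str) -> bool:
        return state in self.decision_states

    def is_leaf(self, state: str) -> bool:
        return state in self.leaf_states

    def step(self, state: str, action: str) -> str:
        """Deterministic successor of (state, action)."""
        if state in self.leaf_states:
            raise MazeError(f"{state} is terminal; no actions are defined there")
        try:
            return self.transitions[(state, action)]
        except KeyError:
            raise MazeError(f"action {action!r} undefined at state {state}") from None


def build_double_t_maze() -> MazeSpec:
    """The canonical double T-maze.

    Layout: (S1,left)->S2, (S1,right)->S3, (S2,left)->S4, (S2,right)->S5,
    (S3,left)->S6, (S3,right)->S7. Two right turns reach S7 (top right),
    two left turns reach S4.
    """
    transitions = {
        ("S1", LEFT): "S2",
        ("S1", RIGHT): "S3",
        ("S2", LEFT): "S4",
        ("S2", RIGHT): "S5",
        ("S3", LEFT): "S6",
        ("S3", RIGHT): "S7",
    }
    return MazeSpec(
        states=tuple(f"S{i}" for i in range(1, 8)),
        decision_states=frozenset({"S1", "S2", "S3"}),
        leaf_states=frozenset({"S4", "S5", "S6", "S7"}),
        actions=ACTIONS,
        transitions=transitions,
    )


def step(maze: MazeSpec, state: str, action: str) -> str:
    return maze.step(state, action)


@dataclass(frozen=True)
class ChangeEvent:
    """A reward-contingency change: from `at_trial` (inclusive, 1-based)
    onward, `state` pays N(mean, variance)."""

    at_trial: int
    state: str
    mean: float
    variance: float


@dataclass
class RewardSchedule:
    """Per-state Gaussian reward parameters with scheduled changes.

    `base` maps state -> (mean, variance); states absent from `base` pay
    exactly 0 (mean 0, variance 0). Change events take effect at trial
    boundaries: the new parameters govern `at_trial` and all later trials.
    """

    base: dict[str, tuple[float, float]]
    change_events: list[ChangeEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, (_, var) in self.base.items():
            if var < 0:
                raise ValueError(f"negative variance for state {s}")
        for ev in self.change_events:
            if ev.variance < 0:
                raise ValueError(f"negative variance in change event for {ev.state}")
        self.change_events.sort(key=lambda ev: ev.at_trial)

    def active(self, state: str, trial: int) -> tuple[float, float]:
        """The (mean, variance) governing `state` at 1-based `trial`."""
        if trial < 1:
            raise ValueError("trials are 1-based")
        mean, var = self.base.get(state, (0.0, 0.0))
        for ev in self.change_events:
            if ev.at_trial <= trial and ev.state == state:
                mean, var = ev.mean, ev.variance
        return mean, var

    def sample(self, state: str, trial: int, rng: np.random.Generator) -> float:
        mean, var = self.active(state, trial)
        if var == 0.0:
            return mean  # degenerate Gaussian, exact
        return rng.normal(mean, np.sqrt(var))


def sample_reward(
    schedule: RewardSchedule, state: str, trial: int, rng: np.random.Generator
) -> float:
    return schedule.sample(state, trial, rng)


@dataclass
class PathOutcome:
    """One traversal S1 -> leaf with the rewards collected along it."""

    visited: tuple[str, ...]
    rewards: tuple[float, ...]
    total: float


def run_path(
    maze: MazeSpec,
    schedule: RewardSchedule,
    actions: Sequence[str],
    trial: int,
    rng: np.random.Generator,
) -> PathOutcome:
    """Walk `actions` from the start state, collecting a reward draw at
    every state entered (intermediate junction and leaf).

    The start state itself yields no reward: the agent begins the trial
    there and nothing is placed at the stem in any scenario.
    """
    visited = [START]
    rewards = [0.0]
    state = START
    for a in actions:
        state = maze.step(state, a)
        visited.append(state)
        rewards.append(schedule.sample(state, trial, rng))
    return PathOutcome(
        visited=tuple(visited), rewards=tuple(rewards), total=float(sum(rewards))
    )


def enumerate_paths(maze: MazeSpec, start: str = START) -> list[tuple[str, ...]]:
    """All decision-state-to-leaf state sequences from `start` (brute force)."""
    if maze.is_leaf(start):
        return [(start,)]
    out = []
    for a in maze.actions:
        nxt = maze.step(start, a)
        out.extend((start,) + tail for tail in enumerate_paths(maze, nxt))
    return out


def best_branch_value(
    maze: MazeSpec, schedule: RewardSchedule, first_action: str, trial: int = 1
) -> float:
    """Best cumulative MEAN reward attainable after taking `first_action`
    at the start state: max over completions of the summed active means of
    the states entered. Exact enumeration (the tree has <= 2 completions)."""
    root = maze.step(START, first_action)
    best = None
    for path in enumerate_paths(maze, root):
        total = sum(schedule.active(s, trial)[0] for s in path)
        best = total if best is None else max(best, total)
    return float(best)
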