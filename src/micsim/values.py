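"""Cached action values, the learned reward model, and the core update rules.

Three pieces of machinery live here:

* ``ValueTable`` — the habitual memory: a cached action value Q and an
  uncertainty C (the variance of the mean of the Q distribution) per
  (decision state, action) pair.
* ``RewardModel`` — the model-based state values: a learned mean reward
  R̂(s) per state, updated by a delta rule with learning rate α.
* The Bayesian fusion of pseudo-observations into a posterior action value
  (conjugate normal-mean update with unit observation variance), and the
  softmax choice rule with inverse temperature β.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .maze import ACTIONS, MazeSpec


@dataclass
class AgentParams:
    """All scalar parameters of the agent.

    alpha : float
        Learning rate of the model-based reward model (delta rule).
    beta : float
        Inverse temperature of the softmax choice rule.
    gamma : float
        Cost of mental simulation, implemented as a fixed threshold on the
        value of information; simulation runs only when VoI > gamma.
    delta : float
        Per-step discount factor applied inside forward sweeps.
    epsilon : float
        Guard added to |Q1 - Q2| in the VoI denominator.
    zeta : float
        Uncertainty threshold: above it sweeps run to a leaf, at or below
        it they are truncated.
    eta : int
        Length (in transitions) of a truncated sweep.
    lambda_coef : float
        Sweeps per unit of uncertainty (the number of sweeps is
        round(lambda_coef * C)).
    kappa : float
        Variance of the random walk on C in the particle filter.
    q0, c0 : float
        Initial cached value and uncertainty for every (state, action).
    r0 : float
        Initial learned mean reward for every state.
    n_particles : int
        Particle count of the value-learning filter.
    obs_variance : float
        Observation variance assumed by both the pseudo-observation fusion
        and the particle-filter likelihood (fixed at 1 in all scenarios).
    truncation_bootstrap : {"random", "best"}
        Which Q value a truncated sweep retrieves at its stop state.
    """

    alpha: float = 0.2
    beta: float = 0.4
    gamma: float = 0.5
    delta: float = 1.0
    epsilon: float = 1e-4
    zeta: float = 3.0
    eta: int = 1
    lambda_coef: float = 3.0
    kappa: float = 1.0
    q0: float = 1.0
    c0: float = 4.0
    r0: float = 1.0
    n_particles: int = 1000
    obs_variance: float = 1.0
    truncation_bootstrap: str = "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        for name in ("gamma", "epsilon", "zeta", "lambda_coef", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.c0 < 0 or self.obs_variance <= 0:
            raise ValueError("c0 must be >= 0 and obs_variance > 0")
        if self.truncation_bootstrap not in ("random", "best"):
            raise ValueError("truncation_bootstrap must be 'random' or 'best'")


@dataclass
class ValueTable:
    """Cached Q and uncertainty C per (decision state, action)."""

    q: dict[tuple[str, str], float]
    c: dict[tuple[str, str], float]

    @classmethod
    def initial(cls, maze: MazeSpec, q0: float = 1.0, c0: float = 4.0) -> "ValueTable":
        keys = [(s, a) for s in sorted(maze.decision_states) for a in maze.actions]
        return cls(q={k: q0 for k in keys}, c={k: c0 for k in keys})

    def __post_init__(self) -> None:
        if set(self.q) != set(self.c):
            raise ValueError("q and c must be defined on the same (state, action) keys")
        for k, v in self.c.items():
            if v < 0:
                raise ValueError(f"negative uncertainty at {k}")

    def is_decision(self, state: str) -> bool:
        return any(s == state for s, _ in self.q)

    def best_q(self, state: str) -> float:
        return max(v for (s, _), v in self.q.items() if s == state)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"state": s, "action": a, "q": self.q[(s, a)], "c": self.c[(s, a)]}
            for (s, a) in sorted(self.q)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ValueTable":
        q = {(r.state, r.action): float(r.q) for r in df.itertuples()}
        c = {(r.state, r.action): float(r.c) for r in df.itertuples()}
        return cls(q=q, c=c)


@dataclass
class RewardModel:
    """Learned mean reward R̂(s) per maze state."""

    r_hat: dict[str, float]

    @classmethod
    def initial(cls, maze: MazeSpec, r0: float = 1.0) -> "RewardModel":
        return cls(r_hat={s: r0 for s in maze.states})

    def update(self, state: str, r_observed: float, alpha: float) -> None:
        self.r_hat[state] = update_reward_model(self.r_hat[state], r_observed, alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"state": s, "r_hat": v} for s, v in sorted(self.r_hat.items())]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RewardModel":
        return cls(r_hat={r.state: float(r.r_hat) for r in df.itertuples()})


def softmax_p_act1(q1: float, q2: float, beta: float) -> float:
    """P(choose action 1) = exp(β q1) / (exp(β q1) + exp(β q2)).

    Computed with max-subtraction so large β·Q never overflows.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x1, x2 = beta * q1, beta * q2
    m = max(x1, x2)
    e1, e2 = np.exp(x1 - m), np.exp(x2 - m)
    return float(e1 / (e1 + e2))


def posterior_q(q_prior: float, c: float, pseudo_obs: Sequence[float]) -> float:
    """Fuse pseudo-observations into the cached value.

    With prior mean ``q_prior``, prior variance-of-the-mean ``c`` and N
    unit-variance pseudo-observations O_i, the posterior mean is

        (q_prior + c * sum(O_i)) / (1 + c * N)

    — the conjugate normal-mean update. With N = 0 the prior is returned
    unchanged. The result is transient: it feeds the current choice only
    and never overwrites the cache.
    """
    if c < 0:
        raise ValueError("uncertainty must be >= 0")
    obs = np.asarray(pseudo_obs, dtype=float)
    n = obs.size
    if n == 0:
        return float(q_prior)
    return float((q_prior + c * obs.sum()) / (1.0 + c * n))


def update_reward_model(r_hat: float, r_observed: float, alpha: float) -> float:
    """Delta rule: R̂ <- R̂ + α (R_observed - R̂)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return float(r_hat + alpha * (r_observed - r_hat))
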