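"""Particle-filter learning of cached values and their uncertainty.

After each executed action the agent observes o = collected reward plus,
if the new position is a decision state, the best cached Q there (a
one-step bootstrapped return; at a leaf the bootstrap is zero). A particle
filter then tracks the joint posterior over (C, Q) for the executed
(state, action) pair:

1. propose C_n ~ N(C_x, kappa) (clipped below at a tiny positive floor)
   and Q_n ~ N(Q_x, C_n), n = 1..N;
2. weight each particle by the Gaussian likelihood of o given Q_n with
   unit observation variance;
3. resample N particles multinomially by weight;
4. the new cached value and uncertainty are the post-resampling means of
   the Q and C coordinates.

The coupling of C into the spread of the Q proposals is what makes C an
uncertainty tracker: observations near the current value favour
low-spread particles and shrink C, while a surprising observation favours
high-C particles and re-inflates it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .values import AgentParams, ValueTable

C_FLOOR = 1e-6


@dataclass(frozen=True)
class LearningObservation:
    """The scalar observation driving one filter update."""

    o: float
    state: str | None = None
    action: str | None = None
    trial: int | None = None


@dataclass
class ParticleSet:
    """Particles over (C, Q) with normalized weights."""

    c: np.ndarray
    q: np.ndarray
    weights: np.ndarray


def make_observation(
    values: ValueTable, reward: float, next_state: str, **meta
) -> LearningObservation:
    """o = reward + max_a Q(next_state, a) at a decision state, else reward."""
    o = float(reward)
    if values.is_decision(next_state):
        o += values.best_q(next_state)
    return LearningObservation(o=o, **meta)


def propose(
    q_prior: float, c_prior: float, params: AgentParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: sample the (C_n, Q_n) prior vectors."""
    c_n = rng.normal(c_prior, np.sqrt(params.kappa), size=params.n_particles)
    c_n = np.clip(c_n, C_FLOOR, None)
    q_n = rng.normal(q_prior, np.sqrt(c_n))
    return c_n, q_n


def weight(q_n: np.ndarray, o: float, obs_variance: float) -> np.ndarray:
    """Step 2: normalized Gaussian likelihood weights P(o | Q_n).

    If every weight underflows to zero (an observation far outside the
    prior's support) fall back to uniform weights with a warning.
    """
    with np.errstate(invalid="ignore", over="ignore"):
        log_w = -0.5 * (o - q_n) ** 2 / obs_variance
        w = np.exp(log_w - log_w.max())
    total = w.sum()
    if not np.isfinite(total) or total == 0.0:
        warnings.warn(
            "degenerate particle weights: observation far outside the prior; "
            "falling back to uniform weights",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(q_n.shape, 1.0 / q_n.size)
    return w / total


def resample(ps: ParticleSet, rng: np.random.Generator) -> np.ndarray:
    """Step 3: multinomial resampling indices (inverse-CDF draw)."""
    cum = np.cumsum(ps.weights)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(ps.weights.size))


def particle_update(
    q_prior: float,
    c_prior: float,
    obs: LearningObservation,
    params: AgentParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One filter step; returns (q_post, c_post) as post-resampling means."""
    if c_prior < 0:
        raise ValueError("uncertainty must be >= 0")
    c_n, q_n = propose(q_prior, c_prior, params, rng)
    w = weight(q_n, obs.o, params.obs_variance)
    ps = ParticleSet(c=c_n, q=q_n, weights=w)
    idx = resample(ps, rng)
    return float(q_n[idx].mean()), float(c_n[idx].mean())
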