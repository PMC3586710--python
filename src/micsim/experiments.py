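"""The five T-maze scenarios and the per-trial agent loop.

Each trial is one episode: the agent starts at the maze stem, makes two
choices, collects rewards at the states it enters, and terminates in an
arm. At every decision state the cycle is meta-choice (simulate or rely
on cache, per action) -> mental simulation for the flagged actions ->
softmax choice over the values in effect -> execution -> learning (delta
rule on the reward model for the state entered; particle-filter update of
the executed action's cached value and uncertainty).

The five scenario factories cover a simple stable maze, a multi-reward
maze, a mid-session reward relocation, and high-variance versions of the
first two — the settings in which habitization, re-engagement of
simulation after contingency change, and persistence of simulation under
noise and near-tied values are observed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maze import ACTIONS, LEFT, RIGHT, START, ChangeEvent, MazeSpec, RewardSchedule, build_double_t_maze
from .meta import decide_meta
from .particle import make_observation, particle_update
from .sweeps import simulate_action
from .values import AgentParams, RewardModel, ValueTable, posterior_q, softmax_p_act1

SCENARIO_NAMES = ("sim1", "sim2", "sim3", "sim4", "sim5")


@dataclass
class ScenarioConfig:
    name: str
    maze: MazeSpec
    schedule: RewardSchedule
    n_trials: int = 100
    n_runs: int = 50
    params: AgentParams = field(default_factory=AgentParams)

    def describe(self) -> dict:
        """JSON-serializable echo of the resolved configuration."""
        return {
            "name": self.name,
            "n_trials": self.n_trials,
            "n_runs": self.n_runs,
            "rewards": {s: list(mv) for s, mv in sorted(self.schedule.base.items())},
            "change_events": [
                dataclasses.asdict(ev) for ev in self.schedule.change_events
            ],
            "params": dataclasses.asdict(self.params),
        }


def make_scenario(
    name: str,
    n_trials: int = 100,
    n_runs: int = 50,
    params: AgentParams | None = None,
) -> ScenarioConfig:
    """Scenario factories.

    sim1: reward N(5, 0.2) at S7 only (simple, stable, low variance).
    sim2: rewards at S2 (2), S4 (1), S7 (5), variance 0.2 (complex, stable).
    sim3: as sim1 for trials 1-50, then the reward moves to S4 (trial 51
          onward S4 pays N(5, 0.2) and S7 pays nothing).
    sim4: as sim1 with 5x variance (S7 ~ N(5, 1)).
    sim5: as sim2 with variance 1 at every rewarded state.
    """
    schedules = {
        "sim1": RewardSchedule({"S7": (5.0, 0.2)}),
        "sim2": RewardSchedule({"S2": (2.0, 0.2), "S4": (1.0, 0.2), "S7": (5.0, 0.2)}),
        "sim3": RewardSchedule(
            {"S7": (5.0, 0.2)},
            change_events=[
                ChangeEvent(at_trial=51, state="S4", mean=5.0, variance=0.2),
                ChangeEvent(at_trial=51, state="S7", mean=0.0, variance=0.0),
            ],
        ),
        "sim4": RewardSchedule({"S7": (5.0, 1.0)}),
        "sim5": RewardSchedule({"S2": (2.0, 1.0), "S4": (1.0, 1.0), "S7": (5.0, 1.0)}),
    }
    if name not in schedules:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    return ScenarioConfig(
        name=name,
        maze=build_double_t_maze(),
        schedule=schedules[name],
        n_trials=n_trials,
        n_runs=n_runs,
        params=params if params is not None else AgentParams(),
    )


@dataclass
class AgentState:
    """Everything the agent carries across trials."""

    values: ValueTable
    reward_model: RewardModel

    @classmethod
    def initial(cls, maze: MazeSpec, params: AgentParams) -> "AgentState":
        return cls(
            values=ValueTable.initial(maze, q0=params.q0, c0=params.c0),
            reward_model=RewardModel.initial(maze, r0=params.r0),
        )


def run_trial(
    agent: AgentState,
    scenario: ScenarioConfig,
    trial: int,
    rng: np.random.Generator,
    run: int = 0,
) -> list[dict]:
    """One episode; returns one record per decision-point visit.

    Each record holds the per-action VoI and simulate flags, sweep counts
    and mean lengths, the pseudo-observations, the softmax probability of
    going left as actually used for the choice, the chosen action, the
    sampled reward, the learning observation, and the executed action's
    cached (Q, C) before and after the particle-filter update.
    """
    maze, params, values = scenario.maze, scenario.params, agent.values
    records: list[dict] = []
    state = START
    while not maze.is_leaf(state):
        md = decide_meta(values, state, params)
        effective: dict[str, float] = {}
        sweep_obs: dict[str, list[float]] = {}
        sweep_lens: dict[str, list[int]] = {}
        for a in ACTIONS:
            if md.simulate[a]:
                results = simulate_action(
                    maze, agent.reward_model, values, state, a, params, rng
                )
                sweep_obs[a] = [r.pseudo_obs for r in results]
                sweep_lens[a] = [r.length for r in results]
                effective[a] = posterior_q(
                    values.q[(state, a)], values.c[(state, a)], sweep_obs[a]
                )
            else:
                sweep_obs[a], sweep_lens[a] = [], []
                effective[a] = values.q[(state, a)]
        p_left = softmax_p_act1(effective[LEFT], effective[RIGHT], params.beta)
        chosen = LEFT if rng.random() < p_left else RIGHT
        next_state = maze.step(state, chosen)
        reward = scenario.schedule.sample(next_state, trial, rng)
        agent.reward_model.update(next_state, reward, params.alpha)
        obs = make_observation(
            values, reward, next_state, state=state, action=chosen, trial=trial
        )
        q_pre = values.q[(state, chosen)]
        c_pre = values.c[(state, chosen)]
        q_post, c_post = particle_update(q_pre, c_pre, obs, params, rng)
        values.q[(state, chosen)] = q_post
        values.c[(state, chosen)] = c_post
        records.append(
            {
                "run": run,
                "trial": trial,
                "state": state,
                "voi_left": md.voi[LEFT],
                "voi_right": md.voi[RIGHT],
                "sim_left": md.simulate[LEFT],
                "sim_right": md.simulate[RIGHT],
                "n_sweeps_left": len(sweep_obs[LEFT]),
                "n_sweeps_right": len(sweep_obs[RIGHT]),
                "mean_len_left": float(np.mean(sweep_lens[LEFT])) if sweep_lens[LEFT] else np.nan,
                "mean_len_right": float(np.mean(sweep_lens[RIGHT])) if sweep_lens[RIGHT] else np.nan,
                "pseudo_obs_left": ";".join(f"{o:.6g}" for o in sweep_obs[LEFT]),
                "pseudo_obs_right": ";".join(f"{o:.6g}" for o in sweep_obs[RIGHT]),
                "p_left": p_left,
                "chosen": chosen,
                "reward": reward,
                "obs_o": obs.o,
                "q_pre": q_pre,
                "c_pre": c_pre,
                "q_post": q_post,
                "c_post": c_post,
            }
        )
        state = next_state
    return records


@dataclass
class ExperimentResult:
    """All decision-level logs plus figure-analogue per-trial series.

    ``decisions``: one row per decision-point visit across all runs.
    ``per_trial``: one row per (run, trial) with the panel quantities —
    the at-choice P(left) at S1/S2/S3 (NaN where the path did not visit
    S2/S3), the end-of-trial cached C and Q for going right at S1 and at
    S3, and the sweep count/mean length for going right at S1 (the series
    the figure panels track).
    ``series``: cross-run arithmetic means of ``per_trial`` by trial
    (NaN-skipping, so P(left) at S2/S3 averages over visiting runs).
    """

    config: ScenarioConfig
    decisions: pd.DataFrame
    per_trial: pd.DataFrame

    @property
    def series(self) -> pd.DataFrame:
        return self.per_trial.drop(columns="run").groupby("trial").mean()


def _per_trial_row(
    run: int, trial: int, records: list[dict], values: ValueTable
) -> dict:
    by_state = {r["state"]: r for r in records}
    s1 = by_state[START]
    row = {
        "run": run,
        "trial": trial,
        "p_left_s1": s1["p_left"],
        "p_left_s2": by_state["S2"]["p_left"] if "S2" in by_state else np.nan,
        "p_left_s3": by_state["S3"]["p_left"] if "S3" in by_state else np.nan,
        "sweeps_s1_right": s1["n_sweeps_right"],
        "sweep_len_s1_right": s1["mean_len_right"],
        "sweeps_s1_total": s1["n_sweeps_left"] + s1["n_sweeps_right"],
        "c_s1_right": values.c[(START, RIGHT)],
        "q_s1_right": values.q[(START, RIGHT)],
        "q_s3_right": values.q[("S3", RIGHT)],
    }
    return row


def run_experiment(
    scenario: ScenarioConfig, rng: np.random.Generator | int | None = None
) -> ExperimentResult:
    """Run ``scenario.n_runs`` independent agents for ``n_trials`` each.

    Per-run random streams are spawned from the master seed / generator,
    so results are bit-reproducible under a fixed seed and runs are
    mutually independent.
    """
    if isinstance(rng, np.random.Generator):
        children = rng.spawn(scenario.n_runs)
    else:
        seq = np.random.SeedSequence(rng if rng is not None else 0)
        children = [np.random.default_rng(s) for s in seq.spawn(scenario.n_runs)]
    decision_rows: list[dict] = []
    trial_rows: list[dict] = []
    for run, run_rng in enumerate(children):
        agent = AgentState.initial(scenario.maze, scenario.params)
        for trial in range(1, scenario.n_trials + 1):
            records = run_trial(agent, scenario, trial, run_rng, run=run)
            decision_rows.extend(records)
            trial_rows.append(_per_trial_row(run, trial, records, agent.values))
    return ExperimentResult(
        config=scenario,
        decisions=pd.DataFrame(decision_rows),
        per_trial=pd.DataFrame(trial_rows),
    )


def window_mean(result: ExperimentResult, column: str, lo: int, hi: int) -> float:
    """Cross-run mean of a per-trial series over trials lo..hi inclusive."""
    pt = result.per_trial
    sel = pt[(pt["trial"] >= lo) & (pt["trial"] <= hi)][column]
    return float(sel.mean())


def summarize(result: ExperimentResult) -> pd.DataFrame:
    """Windowed statistics of the figure-analogue series.

    One row per (window, series): the cross-run, cross-trial mean over the
    first/last 10- and 20-trial windows. Raises on an empty result.
    """
    if result.per_trial.empty:
        raise ValueError("nothing to summarize: empty experiment result")
    n = result.config.n_trials
    windows = {
        "first10": (1, min(10, n)),
        "first20": (1, min(20, n)),
        "last10": (max(1, n - 9), n),
        "last20": (max(1, n - 19), n),
    }
    cols = [c for c in result.per_trial.columns if c not in ("run", "trial")]
    rows = []
    for wname, (lo, hi) in windows.items():
        for col in cols:
            rows.append(
                {
                    "window": wname,
                    "trials": f"{lo}-{hi}",
                    "series": col,
                    "mean": window_mean(result, col, lo, hi),
                }
            )
    return pd.DataFrame(rows)
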