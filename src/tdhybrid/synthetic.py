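"""Closed-loop agent simulation and synthetic cohorts for recovery studies.

Agents of any model in the family play the task online: the policy samples
each choice, the task samples transitions and outcomes, and the latents
update trial by trial.  Yoked simulation replays an observed session's
stimulus schedule and contingencies while re-sampling only the choices, the
construction used for model-discriminability checks.  Cohort generation
draws per-subject parameters from independent truncated normals whose
defaults are the fitted Good-learner group means and SDs (learning rate
0.588+-0.237, eligibility 0.682+-0.323, action-value weight 0.661+-0.315,
temperature 0.404+-0.262, perseveration magnitude 0.093+-0.366 and inverse
decay 0.621+-0.375, rightward bias 0.230+-0.425).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io import records_to_frame, write_session
from .models import Agent, ModelSpec, ParamVector, UNIT_PARAMS, get_model
from .task import TaskSpec, build_task, run_trial, sample_schedule

__all__ = [
    "GOOD_LEARNER_PRIOR",
    "POOR_LEARNER_PRIOR",
    "CohortSpec",
    "simulate_agent",
    "simulate_random_agent",
    "simulate_yoked",
    "draw_params",
    "generate_cohort",
]

_A_NAME = {0: "L", 1: "R"}
_A_CODE = {"L": 0, "R": 1}
_S1_IDX = {"passive_1": 0, "passive_2": 1, "active_1": 2, "active_2": 3}
_S2_IDX = {"second_1": 0, "second_2": 1}

#: (mean, sd) generative distributions per parameter, Good-learner group.
GOOD_LEARNER_PRIOR: Mapping[str, tuple] = {
    "alpha": (0.588, 0.237),
    "lam": (0.682, 0.323),
    "w_q": (0.661, 0.315),
    "tau": (0.404, 0.262),
    "beta_0": (0.093, 0.366),
    "lam_beta": (0.621, 0.375),
    "beta_r": (0.230, 0.425),
    # not separately reported for the model-based module; mirror the
    # model-free learning rate and spread the weight over its range
    "alpha_star": (0.588, 0.237),
    "w_star": (0.5, 0.25),
    "p_a1": (0.5, 0.2),
}

#: Poor-learner group analogue (higher temperature, weaker perseveration).
POOR_LEARNER_PRIOR: Mapping[str, tuple] = {
    "alpha": (0.551, 0.308),
    "lam": (0.687, 0.431),
    "w_q": (0.626, 0.418),
    "tau": (1.390, 1.512),
    "beta_0": (-0.088, 0.521),
    "lam_beta": (0.751, 0.281),
    "beta_r": (0.128, 0.673),
    "alpha_star": (0.551, 0.308),
    "w_star": (0.5, 0.25),
    "p_a1": (0.5, 0.2),
}

_TAU_FLOOR = 0.02


def _sample_rt_ms(rng: np.random.Generator) -> float:
    """Plumbing-only RT draw (lognormal around ~750 ms, capped at the
    response window); no process model of RT is implied."""
    rt = rng.lognormal(mean=math.log(720.0), sigma=0.22)
    return float(min(rt, 1500.0))


def _truncnorm_draw(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def draw_params(
    model_spec: Union[str, ModelSpec],
    rng: np.random.Generator,
    distributions: Mapping[str, Union[float, tuple]] = GOOD_LEARNER_PRIOR,
) -> ParamVector:
    """Draw one subject's free parameters, truncated to the model bounds."""
    spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    values = {}
    for name in spec.free:
        d = distributions[name]
        if np.isscalar(d):
            values[name] = float(d)
        else:
            mean, sd = d
            if name in UNIT_PARAMS:
                values[name] = _truncnorm_draw(rng, mean, sd, 0.0, 1.0)
            elif name == "tau":
                values[name] = _truncnorm_draw(rng, mean, sd, _TAU_FLOOR, np.inf)
            else:
                values[name] = float(rng.normal(mean, sd))
    return spec.params(values)


def simulate_agent(
    model_spec: Union[str, ModelSpec],
    params: ParamVector,
    task_spec: TaskSpec,
    seed: int,
    miss_rate: float = 0.0,
) -> pd.DataFrame:
    """Closed-loop simulation of one session; deterministic given ``seed``.

    ``miss_rate`` injects technical errors: missed responses on active
    trials, inappropriate presses on passive trials.
    """
    spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    ss = np.random.SeedSequence(seed)
    sched_ss, play_ss = ss.spawn(2)
    schedule = sample_schedule(task_spec, sched_ss)
    rng = np.random.default_rng(play_ss)
    agent = Agent(spec, params)
    records = []
    for trial in schedule:
        active = trial.trial_type == "active"
        err = miss_rate > 0 and rng.random() < miss_rate
        if err:
            done = run_trial(task_spec, trial, "L" if not active else None, rng)
            records.append(done)
            continue
        if active:
            fi = _S1_IDX[trial.first_state]
            pi_l, _ = agent.policy(fi)
            a = 0 if rng.random() < pi_l else 1
            done = run_trial(task_spec, trial, _A_NAME[a], rng)
            done.rt_ms = _sample_rt_ms(rng)
            agent.register_choice(fi, a)
            agent.learn(1, fi, a, _S2_IDX[done.second_state], done.reward)
        else:
            done = run_trial(task_spec, trial, None, rng)
            agent.learn(0, _S1_IDX[trial.first_state], -1, _S2_IDX[done.second_state],
                        done.reward)
        records.append(done)
    return records_to_frame(records)


def simulate_random_agent(task_spec: TaskSpec, seed: int, miss_rate: float = 0.0) -> pd.DataFrame:
    """Outcome-insensitive agent choosing uniformly at random (hysteresis
    model with all biases zero)."""
    return simulate_agent(
        get_model("HYST"), ParamVector(tau=1.0), task_spec, seed, miss_rate=miss_rate
    )


def simulate_yoked(
    model_spec: Union[str, ModelSpec],
    params: ParamVector,
    observed_session: pd.DataFrame,
    task_spec: TaskSpec,
    seed: int,
) -> pd.DataFrame:
    """Replay an observed schedule while re-sampling only the choices.

    Passive trials and error trials are copied verbatim (and passive
    outcomes still teach the simulated agent).  On active trials the model
    samples a choice; if it matches the observed action the observed
    transition and outcome are kept (full yoking), otherwise they are
    re-sampled from the task's transition tables.
    """
    spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    rng = np.random.default_rng(seed)
    agent = Agent(spec, params)
    out = observed_session.copy().reset_index(drop=True)
    for i, row in out.iterrows():
        if row["error_flag"] != "none":
            continue
        fi = _S1_IDX[row["first_state"]]
        si_obs = _S2_IDX[row["second_state"]]
        r_obs = int(row["reward"])
        if row["trial_type"] == "passive":
            agent.learn(0, fi, -1, si_obs, r_obs)
            continue
        pi_l, _ = agent.policy(fi)
        a = 0 if rng.random() < pi_l else 1
        if _A_NAME[a] == row["action"]:
            si, r = si_obs, r_obs
        else:
            block = task_spec.blocks[int(row["block_index"])]
            row1 = block.row(row["first_state"], _A_NAME[a])
            second = "second_1" if rng.random() < row1["second_1"] else "second_2"
            r = int(rng.random() < block.row(second)["reward"])
            si = _S2_IDX[second]
            out.at[i, "second_state"] = second
            out.at[i, "reward"] = r
        out.at[i, "action"] = _A_NAME[a]
        agent.register_choice(fi, a)
        agent.learn(1, fi, a, si, r)
    return out


@dataclass
class CohortSpec:
    """Recipe for a simulated cohort with a ground-truth ledger."""

    n_subjects: int
    model: str = "ACQ(lambda)"
    distributions: Mapping[str, Union[float, tuple]] = field(
        default_factory=lambda: dict(GOOD_LEARNER_PRIOR)
    )
    task_config: Mapping = field(default_factory=dict)
    miss_rate: float = 0.03
    master_seed: int = 0


def generate_cohort(
    cohort_spec: CohortSpec, out_dir: Optional[Union[str, Path]] = None
) -> tuple[list, list]:
    """Simulate a cohort; returns (sessions, ledger).

    The ledger records each subject's generating model, drawn parameters and
    seed for recovery scoring.  With ``out_dir`` the sessions are written as
    TSV and the ledger as JSON.
    """
    spec = get_model(cohort_spec.model)
    task_spec = build_task(cohort_spec.task_config)
    ss = np.random.SeedSequence(cohort_spec.master_seed)
    children = ss.spawn(max(cohort_spec.n_subjects, 1))
    sessions, ledger = [], []
    for i in range(cohort_spec.n_subjects):
        child = children[i]
        rng = np.random.default_rng(child)
        pv = draw_params(spec, rng, cohort_spec.distributions)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        session = simulate_agent(spec, pv, task_spec, sim_seed,
                                 miss_rate=cohort_spec.miss_rate)
        sessions.append(session)
        ledger.append(
            {
                "subject": f"sub-{i:03d}",
                "model": spec.name,
                "params": pv.as_dict(),
                "seed": sim_seed,
            }
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for entry, session in zip(ledger, sessions):
            write_session(session, out / f"{entry['subject']}_session.tsv")
        with open(out / "ledger.json", "w") as fh:
            json.dump(ledger, fh, indent=2)
    return sessions, ledger
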