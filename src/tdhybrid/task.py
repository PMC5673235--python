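"""Two-stage Markov decision task with interleaved passive and active trials.

The task is a small MDP with four first-stage states (two passive, two
active), two second-stage passive states, and two terminal outcome states
(reward / no reward).  On passive trials the agent merely observes a chain
``first-stage -> second-stage -> outcome``; on active trials a left/right
button press at the first stage selects between the two second-stage states.
Transition probabilities are symmetric by construction: the reward
probabilities of the two second-stage states are complements, the two passive
first-stage states route to a given second-stage state with complementary
probabilities, and the action->successor mapping is inverted across the two
active states, so exactly one action per active state is objectively better.

A session is divided into three blocks (80, 60, 60 trials by default); block
boundaries are defined by reversals of transition probabilities at the first
or the second stage.  Trials come in randomized quartets containing each of
the four initial states once, and intertrial intervals are drawn without
replacement per 50-trial scanning run from a discrete 4-8 s grid in 80 ms
steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PASSIVE_FIRST_STATES",
    "ACTIVE_FIRST_STATES",
    "FIRST_STATES",
    "SECOND_STATES",
    "TERMINAL_STATES",
    "ACTIONS",
    "PSEUDOACTION",
    "TIE_SENTINEL",
    "TimingSpec",
    "BlockSpec",
    "TaskSpec",
    "TrialRecord",
    "build_task",
    "sample_schedule",
    "run_trial",
    "better_action",
]

PASSIVE_FIRST_STATES = ("passive_1", "passive_2")
ACTIVE_FIRST_STATES = ("active_1", "active_2")
FIRST_STATES = PASSIVE_FIRST_STATES + ACTIVE_FIRST_STATES
SECOND_STATES = ("second_1", "second_2")
TERMINAL_STATES = ("reward", "no_reward")
ACTIONS = ("L", "R")
#: Formal null action attached to action-less states.
PSEUDOACTION = "A0"
#: Returned by :func:`better_action` when both actions have equal expected value.
TIE_SENTINEL = "tie"

_EVENT_LABELS = ("iti", "cue", "first", "isi1", "second", "isi2", "outcome")


@dataclass(frozen=True)
class TimingSpec:
    """Trial event durations in seconds.

    The ITI grid is discrete uniform on [iti_min_s, iti_max_s] in steps of
    ``iti_increment_s`` (51 values with the defaults).
    """

    pretrial_cue_s: float = 1.0
    stimulus_s: float = 1.5
    isi_s: float = 3.5
    response_window_s: float = 1.5
    iti_min_s: float = 4.0
    iti_max_s: float = 8.0
    iti_increment_s: float = 0.080
    outcome_s: float = 1.5

    def iti_grid(self) -> np.ndarray:
        n = int(round((self.iti_max_s - self.iti_min_s) / self.iti_increment_s)) + 1
        return self.iti_min_s + self.iti_increment_s * np.arange(n)

    def trial_duration(self, iti_s: float) -> float:
        return (
            iti_s
            + self.pretrial_cue_s
            + self.stimulus_s
            + self.isi_s
            + self.stimulus_s
            + self.isi_s
            + self.outcome_s
        )


@dataclass(frozen=True)
class BlockSpec:
    """One block's transition tables.

    ``table`` maps ``(state, action)`` -- with ``action=None`` for action-less
    states -- to a probability distribution over the two feasible successors.
    """

    n_trials: int
    table: Mapping[tuple, Mapping[str, float]]
    reversal_stage: str = "none"  # relative to the previous block

    def row(self, state: str, action: Optional[str] = None) -> Mapping[str, float]:
        return self.table[(state, action)]

    def check(self, atol: float = 1e-12) -> None:
        for key, row in self.table.items():
            if len(row) != 2:
                raise ValueError(f"transition row {key} must have 2 successors")
            if abs(sum(row.values()) - 1.0) > atol:
                raise ValueError(f"transition row {key} does not sum to 1")


@dataclass(frozen=True)
class TaskSpec:
    """Full task definition: states, blockwise transition tables, timing."""

    blocks: Sequence[BlockSpec]
    timing: TimingSpec = field(default_factory=TimingSpec)
    reward_magnitude: float = 0.10  # dollars per reward event (display metadata)
    n_runs: int = 4

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def run_length(self) -> int:
        return self.n_trials // self.n_runs

    def block_index(self, trial_index: int) -> int:
        upper = 0
        for i, b in enumerate(self.blocks):
            upper += b.n_trials
            if trial_index < upper:
                return i
        raise IndexError(f"trial index {trial_index} beyond session length")


@dataclass
class TrialRecord:
    """One trial: schedule fields plus (once simulated) choice and outcome."""

    trial_index: int
    run_index: int
    block_index: int
    trial_type: str  # "passive" | "active"
    first_state: str
    iti_s: float
    action: Optional[str] = None
    second_state: Optional[str] = None
    reward: Optional[int] = None
    error_flag: str = "none"  # "none" | "missed" | "inappropriate"
    rt_ms: Optional[float] = None
    event_onsets: Mapping[str, float] = field(default_factory=dict)


def _pair_row(successors: Sequence[str], p_first: float) -> dict:
    return {successors[0]: p_first, successors[1]: 1.0 - p_first}


def _complement_row(row: Mapping[str, float]) -> dict:
    (s1, p1), (s2, p2) = row.items()
    return {s1: p2, s2: p1}


def _build_block1(p_first: float, p_second: float, swap_hands: bool) -> dict:
    """First block's tables under the symmetry constraints.

    With ``swap_hands=False``, L routes active_1 to second_1 with probability
    ``p_first``; the mapping is inverted within active_2.  ``swap_hands``
    exchanges the roles of L and R (hand counterbalancing).
    """
    a_hi, a_lo = ("L", "R") if not swap_hands else ("R", "L")
    table = {
        ("passive_1", None): _pair_row(SECOND_STATES, p_first),
        ("passive_2", None): _pair_row(SECOND_STATES, 1.0 - p_first),
        ("active_1", a_hi): _pair_row(SECOND_STATES, p_first),
        ("active_1", a_lo): _pair_row(SECOND_STATES, 1.0 - p_first),
        ("active_2", a_hi): _pair_row(SECOND_STATES, 1.0 - p_first),
        ("active_2", a_lo): _pair_row(SECOND_STATES, p_first),
        ("second_1", None): _pair_row(TERMINAL_STATES, p_second),
        ("second_2", None): _pair_row(TERMINAL_STATES, 1.0 - p_second),
    }
    return table


def _reverse_block(table: Mapping[tuple, Mapping[str, float]], stage: str) -> dict:
    """Reverse transition probabilities at the given stage ("first"/"second")."""
    if stage not in ("first", "second"):
        raise ValueError(f"unknown reversal stage {stage!r}")
    out = {}
    for (state, action), row in table.items():
        is_first = state in FIRST_STATES
        if (stage == "first" and is_first) or (stage == "second" and not is_first):
            out[(state, action)] = _complement_row(row)
        else:
            out[(state, action)] = dict(row)
    return out


def build_task(config: Optional[Mapping] = None) -> TaskSpec:
    """Construct a :class:`TaskSpec` from a configuration mapping.

    Config keys (all optional):

    - ``probabilities``: ``{"first": p, "second": q}`` or a single float used
      for both stages (default 0.7).  Complement probabilities are always
      derived, never configured independently.
    - ``block_lengths``: default ``[80, 60, 60]``.
    - ``counterbalance``: ``{"initial_reversal": "first"|"second",
      "swap_hands": bool}``.  The first within-session reversal occurs at the
      configured stage, the second reversal at the other stage.
    - ``timing``: overrides for :class:`TimingSpec` fields.
    - ``reward_magnitude``, ``n_runs``.
    """
    config = dict(config or {})
    probs = config.get("probabilities", 0.7)
    if isinstance(probs, Mapping):
        p_first = float(probs.get("first", 0.7))
        p_second = float(probs.get("second", 0.7))
    else:
        p_first = p_second = float(probs)
    for p in (p_first, p_second):
        if not 0.0 < p < 1.0:
            raise ValueError(f"transition probability {p} outside (0, 1)")

    block_lengths = list(config.get("block_lengths", [80, 60, 60]))
    if any(n <= 0 for n in block_lengths):
        raise ValueError("block lengths must be positive")
    cb = dict(config.get("counterbalance", {}))
    initial_reversal = cb.get("initial_reversal", "second")
    if initial_reversal not in ("first", "second"):
        raise ValueError(f"initial_reversal must be 'first' or 'second'")
    swap_hands = bool(cb.get("swap_hands", False))

    timing = TimingSpec(**dict(config.get("timing", {})))
    n_runs = int(config.get("n_runs", 4))
    n_trials = sum(block_lengths)
    if n_trials % 4 != 0:
        raise ValueError("session length must be divisible by 4 (quartets)")
    if n_trials % n_runs != 0:
        raise ValueError("session length must divide evenly into runs")

    other = {"first": "second", "second": "first"}[initial_reversal]
    stages = ["none", initial_reversal, other]
    tables = [_build_block1(p_first, p_second, swap_hands)]
    for stage in stages[1 : len(block_lengths)]:
        tables.append(_reverse_block(tables[-1], stage))

    blocks = []
    for n, table, stage in zip(block_lengths, tables, stages):
        block = BlockSpec(n_trials=n, table=table, reversal_stage=stage)
        block.check()
        blocks.append(block)
    return TaskSpec(
        blocks=tuple(blocks),
        timing=timing,
        reward_magnitude=float(config.get("reward_magnitude", 0.10)),
        n_runs=n_runs,
    )


def sample_schedule(spec: TaskSpec, seed: int) -> list[TrialRecord]:
    """Sample the stimulus/ITI schedule for one session (choices unfilled).

    Consecutive quartets each contain all four initial states exactly once in
    a seed-randomized order; ITIs are drawn without replacement within each
    run from the discrete grid; event onsets accumulate on a single session
    clock with runs back to back.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_trials = spec.n_trials
    if n_trials % 4 != 0:
        raise ValueError("session length must be divisible by 4")
    run_length = spec.run_length

    first_states: list[str] = []
    for _ in range(n_trials // 4):
        quartet = list(FIRST_STATES)
        rng.shuffle(quartet)
        first_states.extend(quartet)

    grid = spec.timing.iti_grid()
    itis = np.concatenate(
        [rng.choice(grid, size=run_length, replace=False) for _ in range(spec.n_runs)]
    )

    t = spec.timing
    records = []
    clock = 0.0
    for i, (state, iti) in enumerate(zip(first_states, itis)):
        onsets = {}
        onsets["iti"] = clock
        onsets["cue"] = onsets["iti"] + float(iti)
        onsets["first"] = onsets["cue"] + t.pretrial_cue_s
        onsets["isi1"] = onsets["first"] + t.stimulus_s
        onsets["second"] = onsets["isi1"] + t.isi_s
        onsets["isi2"] = onsets["second"] + t.stimulus_s
        onsets["outcome"] = onsets["isi2"] + t.isi_s
        clock = onsets["outcome"] + t.outcome_s
        records.append(
            TrialRecord(
                trial_index=i,
                run_index=i // run_length,
                block_index=spec.block_index(i),
                trial_type="passive" if state in PASSIVE_FIRST_STATES else "active",
                first_state=state,
                iti_s=float(iti),
                event_onsets=onsets,
            )
        )
    return records


def _sample_successor(rng: np.random.Generator, row: Mapping[str, float]) -> str:
    states = list(row)
    probs = [row[s] for s in states]
    return states[int(rng.choice(len(states), p=probs))]


def run_trial(
    spec: TaskSpec,
    trial: TrialRecord,
    action_or_none: Optional[str],
    rng: np.random.Generator,
) -> TrialRecord:
    """Resolve one trial given the agent's response (or lack thereof).

    Supplying an action on a passive trial marks the trial ``inappropriate``;
    omitting the action on an active trial marks it ``missed``.  Either error
    aborts the trial: no second-stage state and no outcome are shown.
    """
    block = spec.blocks[trial.block_index]
    active = trial.trial_type == "active"
    if active and action_or_none is None:
        return replace(trial, error_flag="missed", action=None, second_state=None, reward=None)
    if not active and action_or_none is not None:
        return replace(
            trial, error_flag="inappropriate", action=None, second_state=None, reward=None
        )
    if active and action_or_none not in ACTIONS:
        raise ValueError(f"unknown action {action_or_none!r}")

    row1 = block.row(trial.first_state, action_or_none if active else None)
    second = _sample_successor(rng, row1)
    outcome = _sample_successor(rng, block.row(second))
    return replace(
        trial,
        action=action_or_none if active else None,
        second_state=second,
        reward=int(outcome == "reward"),
        error_flag="none",
    )


def expected_reward(block: BlockSpec, state: str, action: str) -> float:
    """Exact two-step marginal P(reward | state, action)."""
    row1 = block.row(state, action)
    return sum(p * block.row(s2)["reward"] for s2, p in row1.items())


def better_action(spec: TaskSpec, block_index: int, active_state: str) -> str:
    """Action maximizing the exact probability of eventual reward.

    Returns :data:`TIE_SENTINEL` when both actions are exactly tied (such
    trials are excluded from accuracy scoring).
    """
    if active_state not in ACTIVE_FIRST_STATES:
        raise ValueError(f"{active_state!r} is not an active state")
    block = spec.blocks[block_index]
    ev = {a: expected_reward(block, active_state, a) for a in ACTIONS}
    if abs(ev["L"] - ev["R"]) < 1e-12:
        return TIE_SENTINEL
    return "L" if ev["L"] > ev["R"] else "R"
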