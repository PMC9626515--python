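"""Probabilistic reversal learning (PRL) task engine.

The task is a two-choice discrimination with serial reversals.  One of two
abstract stimuli is designated correct at any time; feedback is a win (+1)
for the correct stimulus and a loss (-1) for the incorrect one, except on a
small number of pre-planted *probabilistic errors* per stage, where a choice
of the correct stimulus is misleadingly punished.  Once a criterion number of
correct-stimulus choices has accumulated (misleadingly punished ones
included), the contingency reverses and a new discrimination stage begins.

The engine is split into a pre-generated plan (:class:`TaskSchedule`) and a
small state machine (:func:`feedback`) that adjudicates single trials, so
that simulated agents and likelihood code share exactly the same task logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "StagePlan",
    "TaskSchedule",
    "TaskState",
    "build_schedule",
    "feedback",
    "run_task",
]


class TaskConfigError(ValueError):
    """Raised for inconsistent task configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the PRL task.

    Defaults follow the standard design: three blocks of 11 discrimination
    stages (hence ten reversals per block), reversal criterion drawn from
    10-15 total correct responses, and 0-4 planted probabilistic errors per
    stage in a pseudorandomized (balanced, shuffled) sequence.
    """

    n_blocks: int = 3
    n_stages_per_block: int = 11
    criterion_min: int = 10
    criterion_max: int = 15
    prob_error_min: int = 0
    prob_error_max: int = 4
    max_trials_per_block: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion_min > self.criterion_max:
            raise TaskConfigError("criterion_min must be <= criterion_max")
        if self.prob_error_min > self.prob_error_max:
            raise TaskConfigError("prob_error_min must be <= prob_error_max")
        if self.n_stages_per_block < 1:
            raise TaskConfigError("need at least one stage per block")
        if self.n_blocks < 1:
            raise TaskConfigError("need at least one block")
        if self.criterion_min < 1:
            raise TaskConfigError("criterion_min must be >= 1")
        if self.prob_error_min < 0:
            raise TaskConfigError("prob_error_min must be >= 0")
        if self.max_trials_per_block < 1:
            raise TaskConfigError("max_trials_per_block must be >= 1")


@dataclass(frozen=True)
class StagePlan:
    """Plan for one discrimination stage.

    ``prob_error_positions`` indexes into the stage's sequence of
    correct-stimulus choices (0-based): the k-th qualifying correct response
    is misleadingly punished iff k is in the set.
    """

    stage_index: int
    correct_stimulus: int
    criterion_count: int
    prob_error_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.correct_stimulus not in (0, 1):
            raise TaskConfigError("correct_stimulus must be 0 or 1")
        if any(p < 0 or p >= self.criterion_count for p in self.prob_error_positions):
            raise TaskConfigError("prob_error_positions must lie in [0, criterion_count)")


@dataclass
class TaskState:
    """Mutable per-block task state while a simulated run is in progress."""

    block: int = 0
    stage: int = 0
    correct_responses_so_far: int = 0
    trial_in_block: int = 0
    finished: bool = False


@dataclass(frozen=True)
class TaskSchedule:
    """A fully pre-generated task plan: blocks of stage plans."""

    config: TaskConfig
    blocks: tuple[tuple[StagePlan, ...], ...]

    def to_json(self) -> str:
        doc = {
            "config": asdict(self.config),
            "blocks": [
                [
                    {
                        "stage_index": s.stage_index,
                        "correct_stimulus": s.correct_stimulus,
                        "criterion_count": s.criterion_count,
                        "prob_error_positions": sorted(s.prob_error_positions),
                    }
                    for s in block
                ]
                for block in self.blocks
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskSchedule":
        doc = json.loads(text)
        config = TaskConfig(**doc["config"])
        blocks = tuple(
            tuple(
                StagePlan(
                    stage_index=s["stage_index"],
                    correct_stimulus=s["correct_stimulus"],
                    criterion_count=s["criterion_count"],
                    prob_error_positions=frozenset(s["prob_error_positions"]),
                )
                for s in block
            )
            for block in doc["blocks"]
        )
        return cls(config=config, blocks=blocks)


def _balanced_error_counts(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Shuffled balanced sequence of per-stage probabilistic-error counts.

    The candidate counts [prob_error_min, prob_error_max] are tiled until they
    cover the block and shuffled, so every count appears as equally often as
    the stage count allows (a pseudorandomized balanced sequence).
    """
    candidates = np.arange(config.prob_error_min, config.prob_error_max + 1)
    reps = int(np.ceil(config.n_stages_per_block / len(candidates)))
    seq = np.tile(candidates, reps)[: config.n_stages_per_block]
    rng.shuffle(seq)
    return seq


def build_schedule(config: TaskConfig, rng: np.random.Generator | None = None) -> TaskSchedule:
    """Generate a :class:`TaskSchedule` from ``config``.

    Per stage, the criterion count is uniform on
    [criterion_min, criterion_max]; planted-error positions are drawn
    uniformly without replacement from [0, criterion_count).  The correct
    stimulus of the first stage of each block is random and alternates at
    every reversal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    blocks = []
    for _ in range(config.n_blocks):
        error_counts = _balanced_error_counts(config, rng)
        first_correct = int(rng.integers(0, 2))
        stages = []
        for s in range(config.n_stages_per_block):
            criterion = int(rng.integers(config.criterion_min, config.criterion_max + 1))
            n_err = int(min(error_counts[s], criterion))
            positions = frozenset(
                int(p) for p in rng.choice(criterion, size=n_err, replace=False)
            )
            stages.append(
                StagePlan(
                    stage_index=s,
                    correct_stimulus=(first_correct + s) % 2,
                    criterion_count=criterion,
                    prob_error_positions=positions,
                )
            )
        blocks.append(tuple(stages))
    return TaskSchedule(config=config, blocks=tuple(blocks))


def feedback(
    plan: StagePlan, state: TaskState, choice: int, *, n_stages_in_block: int
) -> int:
    """Adjudicate one trial: return the outcome (+1/-1) and advance ``state``.

    A correct-stimulus choice increments the criterion counter whether or not
    it is misleadingly punished; an incorrect choice is always punished.
    When the counter reaches the stage's criterion the stage index advances
    (a reversal) or, on the last stage, the block finishes.
    """
    if choice not in (0, 1):
        raise ValueError(f"choice must be 0 or 1, got {choice!r}")
    if state.finished:
        raise RuntimeError("block already finished")
    if choice == plan.correct_stimulus:
        outcome = -1 if state.correct_responses_so_far in plan.prob_error_positions else 1
        state.correct_responses_so_far += 1
        if state.correct_responses_so_far >= plan.criterion_count:
            state.correct_responses_so_far = 0
            if state.stage + 1 >= n_stages_in_block:
                state.finished = True
            else:
                state.stage += 1
    else:
        outcome = -1
    state.trial_in_block += 1
    return outcome


def run_task(
    agent,
    schedule: TaskSchedule,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run an agent through a schedule; return one row per trial.

    ``agent`` must provide ``reset()``, ``prob_stim1() -> float`` (probability
    of choosing stimulus 1 given its current values) and
    ``update(choice, outcome)``.  A block stops at stage completion or at the
    ``max_trials_per_block`` safety cap (the ``truncated`` column marks the
    latter).
    """
    cap = schedule.config.max_trials_per_block
    rows: list[dict] = []
    for b, block in enumerate(schedule.blocks):
        agent.reset()
        state = TaskState(block=b)
        block_rows: list[dict] = []
        while not state.finished and state.trial_in_block < cap:
            plan = block[state.stage]
            p1 = agent.prob_stim1()
            choice = int(rng.random() < p1)
            stage_before = state.stage
            outcome = feedback(plan, state, choice, n_stages_in_block=len(block))
            agent.update(choice, outcome)
            block_rows.append(
                {
                    "block": b,
                    "trial": state.trial_in_block - 1,
                    "stage": stage_before,
                    "choice": choice,
                    "outcome": outcome,
                    "correct": choice == plan.correct_stimulus,
                    "truncated": False,
                }
            )
        if not state.finished:
            for r in block_rows:
                r["truncated"] = True
        rows.extend(block_rows)
    df = pd.DataFrame(
        rows,
        columns=["block", "trial", "stage", "choice", "outcome", "correct", "truncated"],
    )
    return df.astype(
        {
            "block": np.int64,
            "trial": np.int64,
            "stage": np.int64,
            "choice": np.int64,
            "outcome": np.int64,
            "correct": bool,
            "truncated": bool,
        }
    )
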