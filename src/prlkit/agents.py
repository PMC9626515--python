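"""Reinforcement-learning agents for the PRL task.

Two models are implemented, each with a softmax choice rule over the two
stimulus values and outcome coding win = +1 / loss = -1:

* **RP (reward-punishment)** — a Rescorla-Wagner learner with separate
  learning rates for rewarded (``a_rew``) and punished (``a_pun``) trials.
  By default the unchosen stimulus receives a mirrored fictive update with
  the sign-flipped outcome at the same trial rate, the standard variant for
  two-option tasks with anticorrelated contingencies; set
  ``mirrored=False`` for chosen-only updating.

* **EWA (experience-weighted attraction)** — attractions are decayed payoff
  averages weighted by an experience count ``n`` that itself decays at rate
  ``rho``; the learning rate ``a`` controls payoff decay.  High ``rho``
  makes attractions sluggish, a candidate mechanism for perseveration.

Both models start every block with neutral values (q = 0, and n = 0 for
EWA): each block introduces new stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .task import TaskSchedule, run_task

__all__ = [
    "RPParams",
    "EWAParams",
    "ValueState",
    "softmax_prob",
    "rp_update",
    "ewa_update",
    "loglik_subject",
    "simulate_subject",
    "RLAgent",
    "MODEL_IDS",
    "PARAM_NAMES",
]

BETA_MAX_DEFAULT = 10.0
MODEL_IDS = ("rp", "ewa")
PARAM_NAMES = {"rp": ("a_rew", "a_pun", "beta"), "ewa": ("a", "rho", "beta")}


def _check_unit(name: str, x: float) -> None:
    if not np.isfinite(x) or not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {x!r}")


@dataclass(frozen=True)
class RPParams:
    """Reward-punishment model parameters."""

    a_rew: float
    a_pun: float
    beta: float
    beta_max: float = BETA_MAX_DEFAULT

    def __post_init__(self) -> None:
        _check_unit("a_rew", self.a_rew)
        _check_unit("a_pun", self.a_pun)
        if not np.isfinite(self.beta) or not (0.0 <= self.beta <= self.beta_max):
            raise ValueError(f"beta must lie in [0, {self.beta_max}], got {self.beta!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_rew, self.a_pun, self.beta])


@dataclass(frozen=True)
class EWAParams:
    """Experience-weighted attraction model parameters."""

    a: float
    rho: float
    beta: float
    beta_max: float = BETA_MAX_DEFAULT

    def __post_init__(self) -> None:
        _check_unit("a", self.a)
        _check_unit("rho", self.rho)
        if not np.isfinite(self.beta) or not (0.0 <= self.beta <= self.beta_max):
            raise ValueError(f"beta must lie in [0, {self.beta_max}], got {self.beta!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.rho, self.beta])


def _model_of(params) -> str:
    if isinstance(params, RPParams):
        return "rp"
    if isinstance(params, EWAParams):
        return "ewa"
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


@dataclass
class ValueState:
    """Stimulus values (and EWA experience weights) of one agent."""

    q: np.ndarray
    n: np.ndarray | None = None

    @classmethod
    def fresh(cls, model: str = "rp") -> "ValueState":
        return cls(q=np.zeros(2), n=np.zeros(2) if model == "ewa" else None)


def softmax_prob(state: ValueState, beta: float) -> float:
    """Probability of choosing stimulus 1: 1 / (1 + exp(-beta (q1 - q0)))."""
    if beta < 0 or not np.isfinite(beta):
        raise ValueError("beta must be finite and >= 0")
    q = np.asarray(state.q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite stimulus values")
    m = beta * (q[1] - q[0])
    with np.errstate(over="ignore"):
        return float(1.0 / (1.0 + np.exp(-m)))


def _check_outcome(outcome: int) -> None:
    if outcome not in (-1, 1):
        raise ValueError(f"outcome must be -1 or +1, got {outcome!r}")


def rp_update(
    state: ValueState, choice: int, outcome: int, params: RPParams, mirrored: bool = True
) -> ValueState:
    """One RP value update; returns a new state (input unchanged)."""
    _check_outcome(outcome)
    if choice not in (0, 1):
        raise ValueError("choice must be 0 or 1")
    q = np.asarray(state.q, dtype=float).copy()
    # the outcome's sign selects the learning rate for the whole trial:
    # rewarded trials learn at a_rew, punished trials at a_pun (for the
    # chosen and, when mirrored, the fictive unchosen update alike)
    rate = params.a_rew if outcome > 0 else params.a_pun
    q[choice] += rate * (outcome - q[choice])
    if mirrored:
        nc = 1 - choice
        q[nc] += rate * (-outcome - q[nc])
    return ValueState(q=q, n=None)


def ewa_update(state: ValueState, choice: int, outcome: int, params: EWAParams) -> ValueState:
    """One EWA attraction update; returns a new state (input unchanged)."""
    _check_outcome(outcome)
    if choice not in (0, 1):
        raise ValueError("choice must be 0 or 1")
    if state.n is None:
        raise ValueError("EWA state requires experience weights n")
    q = np.asarray(state.q, dtype=float).copy()
    n = np.asarray(state.n, dtype=float).copy()
    if np.any(n < 0):
        raise ValueError("experience weights must be >= 0")
    # the old attraction is weighted by the decayed experience rho * n, so
    # rho = 0 reduces to memoryless tracking of the last payoff
    n1 = params.rho * n[choice] + 1.0
    q[choice] = (q[choice] * (1.0 - params.a) * params.rho * n[choice] + outcome) / n1
    n[choice] = n1
    return ValueState(q=q, n=n)


def _trial_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (choices, outcomes, block-reset flags), validating ordering."""
    if "subject" in trials.columns and trials["subject"].nunique() > 1:
        raise ValueError("loglik_subject expects trials of a single subject")
    blocks = trials["block"].to_numpy()
    trial_idx = trials["trial"].to_numpy()
    for b in np.unique(blocks):
        t = trial_idx[blocks == b]
        if np.any(np.diff(t) <= 0):
            raise ValueError("trials must be strictly increasing within each block")
    if np.any(np.diff(blocks) < 0):
        raise ValueError("blocks must be in nondecreasing order")
    choices = trials["choice"].to_numpy(dtype=np.int64)
    outcomes = trials["outcome"].to_numpy(dtype=np.float64)
    if not np.all(np.isin(outcomes, (-1.0, 1.0))):
        raise ValueError("outcomes must be coded -1/+1")
    reset = np.zeros(len(trials), dtype=np.bool_)
    reset[0] = True
    reset[1:] = blocks[1:] != blocks[:-1]
    return choices, outcomes, reset


def loglik_subject(
    trials: pd.DataFrame,
    params: RPParams | EWAParams,
    model: str | None = None,
    mirrored: bool = True,
) -> tuple[float, np.ndarray]:
    """Log-likelihood of one subject's choices under a model.

    Values are reset at block boundaries.  Returns the total and the
    per-trial log-likelihoods (log softmax probability of each observed
    choice given the pre-trial values).
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    model = model or _model_of(params)
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    choices, outcomes, reset = _trial_arrays(trials)
    out = np.zeros(len(trials))
    if model == "rp":
        _kernels.rp_pointwise(
            choices, outcomes, reset, params.a_rew, params.a_pun, params.beta, mirrored, out
        )
    else:
        _kernels.ewa_pointwise(choices, outcomes, reset, params.a, params.rho, params.beta, out)
    return float(out.sum()), out


class RLAgent:
    """Task-facing wrapper around a parameterized RL model.

    Satisfies the agent protocol of :func:`prlkit.task.run_task`:
    ``reset`` / ``prob_stim1`` / ``update``.
    """

    def __init__(self, params: RPParams | EWAParams, mirrored: bool = True):
        self.params = params
        self.model = _model_of(params)
        self.mirrored = mirrored
        self.state = ValueState.fresh(self.model)

    def reset(self) -> None:
        self.state = ValueState.fresh(self.model)

    def prob_stim1(self) -> float:
        return softmax_prob(self.state, self.params.beta)

    def update(self, choice: int, outcome: int) -> None:
        if self.model == "rp":
            self.state = rp_update(self.state, choice, outcome, self.params, self.mirrored)
        else:
            self.state = ewa_update(self.state, choice, outcome, self.params)


def simulate_subject(
    params: RPParams | EWAParams,
    schedule: TaskSchedule,
    rng: np.random.Generator,
    model: str | None = None,
    mirrored: bool = True,
) -> pd.DataFrame:
    """Simulate one subject through a schedule; returns trial rows."""
    model = model or _model_of(params)
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    agent = RLAgent(params, mirrored=mirrored)
    return run_task(agent, schedule, rng)
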