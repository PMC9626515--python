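"""Synthetic two-group PRL cohorts with known ground-truth parameters.

Each subject's unconstrained parameters are drawn from the group-level
normal distribution, constrained by the inverse-probit transform, and the
subject is simulated through a freshly generated task schedule.  The
default group regimes encode the qualitative pattern reported for alcohol
use disorder patients versus healthy controls on this task: the AUDP-like
group learns faster from punishment, slightly slower from reward, and
chooses less consistently (lower inverse temperature).

Defaults (constrained-scale group means; raw-scale sd 0.3):

====================  =======  =========
parameter             HC-like  AUDP-like
====================  =======  =========
a_rew                 0.35     0.30
a_pun                 0.25     0.45
beta                  3.0      2.0
====================  =======  =========

Ground truth is always returned (and persisted) next to the choice data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .agents import BETA_MAX_DEFAULT, EWAParams, MODEL_IDS, PARAM_NAMES, RPParams, simulate_subject
from .data import GROUPS, validate_dataset, write_dataset
from .task import TaskConfig, TaskSchedule, build_schedule

__all__ = ["CohortSpec", "default_spec", "generate_cohort", "generate_study", "make_fixture"]


def _probit(p: float) -> float:
    return float(special.ndtri(p))


# unconstrained-scale group means matching the table in the module docstring
_DEFAULT_MEANS = {
    "HC": {"a_rew": _probit(0.35), "a_pun": _probit(0.25), "beta": _probit(0.30)},
    "AUDP": {"a_rew": _probit(0.30), "a_pun": _probit(0.45), "beta": _probit(0.20)},
}
_DEFAULT_SD = 0.3
_DEFAULT_N = {"AUDP": 28, "HC": 27}


@dataclass(frozen=True)
class CohortSpec:
    """Generating regime of one synthetic group."""

    group: str
    n_subjects: int
    model: str = "rp"
    mean_raw: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sd_raw: tuple[float, float, float] = (_DEFAULT_SD,) * 3
    task: TaskConfig = field(default_factory=TaskConfig)
    beta_max: float = BETA_MAX_DEFAULT
    mirrored: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.model not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}")
        if any(s <= 0 for s in self.sd_raw):
            raise ValueError("sd_raw entries must be > 0")

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        doc = json.loads(text)
        doc["task"] = TaskConfig(**doc["task"])
        doc["mean_raw"] = tuple(doc["mean_raw"])
        doc["sd_raw"] = tuple(doc["sd_raw"])
        return cls(**doc)


def default_spec(group: str, model: str = "rp", seed: int = 0,
                 n_subjects: int | None = None, task: TaskConfig | None = None) -> CohortSpec:
    """The default AUDP-like or HC-like generating regime."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    names = PARAM_NAMES["rp"]  # default means are stated for the RP model
    means = tuple(_DEFAULT_MEANS[group][p] for p in names)
    return CohortSpec(
        group=group,
        n_subjects=n_subjects if n_subjects is not None else _DEFAULT_N[group],
        model=model,
        mean_raw=means,
        sd_raw=(_DEFAULT_SD,) * 3,
        task=task or TaskConfig(),
        seed=seed,
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, TaskSchedule]]:
    """Generate one group: (choice data, ground truth, per-subject schedules).

    Subject parameters are drawn on the unconstrained scale from
    Normal(mean_raw, sd_raw), constrained via the inverse-probit transform,
    and each subject is simulated through a fresh task schedule.
    """
    rng = np.random.default_rng(spec.seed)
    names = PARAM_NAMES[spec.model]
    rows, truth_rows = [], []
    schedules: dict[str, TaskSchedule] = {}
    for i in range(spec.n_subjects):
        subject = f"{spec.group}{i:03d}"
        raw = np.array(spec.mean_raw) + np.array(spec.sd_raw) * rng.standard_normal(3)
        theta = special.ndtr(raw)
        theta[2] *= spec.beta_max
        theta = np.clip(theta, 1e-9, None)
        if spec.model == "rp":
            params = RPParams(a_rew=min(theta[0], 1 - 1e-9), a_pun=min(theta[1], 1 - 1e-9),
                              beta=min(theta[2], spec.beta_max), beta_max=spec.beta_max)
        else:
            params = EWAParams(a=min(theta[0], 1 - 1e-9), rho=min(theta[1], 1 - 1e-9),
                               beta=min(theta[2], spec.beta_max), beta_max=spec.beta_max)
        schedule = build_schedule(spec.task, rng)
        schedules[subject] = schedule
        sim = simulate_subject(params, schedule, rng,
                               model=spec.model, mirrored=spec.mirrored)
        sim = sim.drop(columns=["truncated"])
        sim.insert(0, "group", spec.group)
        sim.insert(0, "subject", subject)
        rows.append(sim)
        truth_rows.append({"subject": subject, "group": spec.group,
                           **{p: float(v) for p, v in zip(names, theta)}})
    data = validate_dataset(pd.concat(rows, ignore_index=True))
    truth = pd.DataFrame(truth_rows)
    return data, truth, schedules


def generate_study(
    seed: int = 0,
    model: str = "rp",
    n_audp: int | None = None,
    n_hc: int | None = None,
    task: TaskConfig | None = None,
):
    """Generate the full two-group study under the default regimes.

    Returns ``(data, truth, schedules)`` pooling both groups; the two
    groups use decorrelated seeds derived from ``seed``.
    """
    child = np.random.SeedSequence(seed).spawn(2)
    sa = default_spec("AUDP", model=model, seed=int(child[0].generate_state(1)[0] % (2**31)),
                      n_subjects=n_audp, task=task)
    sh = default_spec("HC", model=model, seed=int(child[1].generate_state(1)[0] % (2**31)),
                      n_subjects=n_hc, task=task)
    da, ta, scha = generate_cohort(sa)
    dh, th, schh = generate_cohort(sh)
    data = pd.concat([da, dh], ignore_index=True)
    truth = pd.concat([ta, th], ignore_index=True)
    return data, truth, {**scha, **schh}


def make_fixture(size: str = "tiny", seed: int = 0, out_dir: str | Path | None = None):
    """Bundled synthetic datasets for tests and acceptance runs.

    ``tiny``: 4 subjects (2 per group) x 1 block — sub-second, for unit
    tests.  ``standard``: the full 28 AUDP-like / 27 HC-like x 3 blocks
    study design.  When ``out_dir`` is given, writes ``choices.csv`` and
    ``ground_truth.csv`` there and returns the paths.
    """
    if size == "tiny":
        task = TaskConfig(n_blocks=1)
        data, truth, schedules = generate_study(seed=seed, n_audp=2, n_hc=2, task=task)
    elif size == "standard":
        data, truth, schedules = generate_study(seed=seed)
    else:
        raise ValueError("size must be 'tiny' or 'standard'")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(data, out / "choices.csv")
        truth.to_csv(out / "ground_truth.csv", index=False)
        for subj, sched in schedules.items():
            (out / f"schedule_{subj}.json").write_text(sched.to_json())
        return out / "choices.csv", out / "ground_truth.csv"
    return data, truth, schedules
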