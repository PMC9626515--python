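"""Behavioral statistics for PRL choice data.

Three families of analysis operate on a ChoiceDataset:

1. Per-subject counts: correct responses, perseverative errors after
   reversals (and the rate per qualifying reversal sequence), win-stay and
   lose-shift probabilities.
2. A mixed-effects logistic regression of stay/switch behavior on the
   previous trial's outcome (reward coded +0.5, loss -0.5), group
   (HC +0.5, AUDP -0.5) and their interaction, with a per-subject random
   intercept and Tukey-type post-hoc cell contrasts.
3. The same regression with cumulative negative feedback on a 0-3 scale in
   place of the single previous outcome.

Perseveration is contingency-based, not feedback-based: after a reversal,
the *reversal error* is the first choice of the previously correct stimulus
that is punished; the perseverative errors are the consecutive further
choices of that stimulus immediately following it.  A reversal enters the
rate denominator only if at least one such error occurred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import validate_dataset
from .mixedlm import RegressionResult, adjusted_contrasts, fit_mixed_logit

__all__ = [
    "BehaviorSummary",
    "count_correct",
    "perseveration",
    "stay_indicator",
    "stay_table",
    "winstay_loseshift",
    "summarize_subject",
    "summarize",
    "cumulative_negfb_code",
    "fit_stay_regression",
    "fit_cumulative_regression",
]


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-subject behavioral statistics."""

    subject: str
    n_trials: int
    n_correct: int
    n_persev_errors: int
    n_qualifying_sequences: int
    persev_error_rate: float  # NaN when no sequence qualifies
    p_winstay: float
    p_loseshift: float


def count_correct(trials: pd.DataFrame) -> int:
    """Number of choices of the designated correct stimulus.

    Correctness is contingency-based: a misleadingly punished choice of the
    correct stimulus still counts as correct.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    return int(trials["correct"].sum())


def _correct_stimulus(choice: np.ndarray, correct: np.ndarray) -> np.ndarray:
    """Designated correct stimulus per trial, recovered from the flags."""
    return np.where(correct, choice, 1 - choice)


def perseveration(trials: pd.DataFrame) -> tuple[int, int, float]:
    """Perseverative errors, qualifying reversal sequences, and their ratio.

    Returns ``(n_errors, n_qualifying, rate)`` with ``rate = NaN`` when no
    reversal qualifies.
    """
    n_errors = 0
    n_qualifying = 0
    for _, block in trials.groupby("block", sort=True):
        stage = block["stage"].to_numpy()
        choice = block["choice"].to_numpy()
        outcome = block["outcome"].to_numpy()
        corr_stim = _correct_stimulus(choice, block["correct"].to_numpy())
        n = len(block)
        # positions where a new stage begins (reversals)
        starts = [i for i in range(1, n) if stage[i] != stage[i - 1]]
        for p in starts:
            # previously correct stimulus: correct stimulus of the prior stage
            old = int(corr_stim[p - 1])
            # reversal error: first punished old-stimulus choice in this stage
            j = None
            i = p
            s = stage[p]
            while i < n and stage[i] == s:
                if choice[i] == old and outcome[i] == -1:
                    j = i
                    break
                i += 1
            if j is None:
                continue
            run = 0
            k = j + 1
            while k < n and choice[k] == old:
                run += 1
                k += 1
            n_errors += run
            if run >= 1:
                n_qualifying += 1
    rate = n_errors / n_qualifying if n_qualifying > 0 else float("nan")
    return n_errors, n_qualifying, rate


def stay_indicator(trials: pd.DataFrame) -> pd.Series:
    """Stay flag (choice repeats the previous trial's) per eligible trial.

    Defined from the second trial of each block; indexed by the original
    row labels of the eligible trials.  Pairs never span block boundaries.
    """
    out: list[pd.Series] = []
    for _, block in trials.groupby("block", sort=True):
        if len(block) < 2:
            raise ValueError("stay_indicator requires >= 2 trials per block")
        c = block["choice"].to_numpy()
        stay = pd.Series(c[1:] == c[:-1], index=block.index[1:])
        out.append(stay)
    return pd.concat(out)


def cumulative_negfb_code(trials: pd.DataFrame) -> pd.Series:
    """Cumulative-negative-feedback code (0-3) per eligible trial.

    0: the previous trial was rewarded.  1: a single loss on the previous
    trial (no earlier consecutive loss on a stayed choice).  2: losses on the
    previous two trials with a stay between them.  3: losses on the previous
    three trials with two consecutive stays; longer loss/stay runs are capped
    at 3.  Defined from the second trial of each block.
    """
    out: list[pd.Series] = []
    for _, block in trials.groupby("block", sort=True):
        if len(block) < 2:
            raise ValueError("cumulative_negfb_code requires >= 2 trials per block")
        c = block["choice"].to_numpy()
        o = block["outcome"].to_numpy()
        codes = np.zeros(len(block) - 1, dtype=np.int64)
        for t in range(1, len(block)):
            if o[t - 1] == 1:
                code = 0
            elif t - 2 < 0 or o[t - 2] == 1 or c[t - 1] != c[t - 2]:
                code = 1
            elif t - 3 < 0 or o[t - 3] == 1 or c[t - 2] != c[t - 3]:
                code = 2
            else:
                code = 3
            codes[t - 1] = code
        out.append(pd.Series(codes, index=block.index[1:]))
    return pd.concat(out)


def winstay_loseshift(trials: pd.DataFrame) -> tuple[float, float]:
    """(p_winstay, p_loseshift) over eligible trial pairs of one subject."""
    stay = stay_indicator(trials)
    prev_outcome = []
    for _, block in trials.groupby("block", sort=True):
        prev_outcome.append(pd.Series(block["outcome"].to_numpy()[:-1], index=block.index[1:]))
    prev = pd.concat(prev_outcome)
    wins = prev == 1
    losses = prev == -1
    p_ws = float(stay[wins].mean()) if wins.any() else float("nan")
    p_ls = float((~stay[losses]).mean()) if losses.any() else float("nan")
    return p_ws, p_ls


def summarize_subject(trials: pd.DataFrame, subject: str | None = None) -> BehaviorSummary:
    if subject is None:
        subject = str(trials["subject"].iloc[0]) if "subject" in trials.columns else ""
    n_err, n_qual, rate = perseveration(trials)
    p_ws, p_ls = winstay_loseshift(trials)
    return BehaviorSummary(
        subject=subject,
        n_trials=len(trials),
        n_correct=count_correct(trials),
        n_persev_errors=n_err,
        n_qualifying_sequences=n_qual,
        persev_error_rate=rate,
        p_winstay=p_ws,
        p_loseshift=p_ls,
    )


def summarize(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-subject :class:`BehaviorSummary` table for a full dataset."""
    dataset = validate_dataset(dataset)
    rows = []
    for subj, g in dataset.groupby("subject", sort=True):
        s = summarize_subject(g, subject=str(subj))
        rows.append({"group": g["group"].iloc[0], **s.__dict__})
    return pd.DataFrame(rows).set_index("subject")


def stay_table(dataset: pd.DataFrame) -> pd.DataFrame:
    """Long table of eligible trial pairs for the stay/switch regressions.

    Columns: subject, group, stay (0/1), prev_reward (+0.5 reward / -0.5
    loss), group_code (+0.5 HC / -0.5 AUDP), negfb_code (0-3).
    """
    dataset = validate_dataset(dataset)
    parts = []
    for subj, g in dataset.groupby("subject", sort=True):
        stay = stay_indicator(g)
        code = cumulative_negfb_code(g)
        prev = []
        for _, block in g.groupby("block", sort=True):
            prev.append(pd.Series(block["outcome"].to_numpy()[:-1], index=block.index[1:]))
        prev = pd.concat(prev)
        parts.append(
            pd.DataFrame(
                {
                    "subject": str(subj),
                    "group": g["group"].iloc[0],
                    "stay": stay.astype(int),
                    "prev_reward": np.where(prev == 1, 0.5, -0.5),
                    "group_code": 0.5 if g["group"].iloc[0] == "HC" else -0.5,
                    "negfb_code": code.astype(float),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


_CELLS = [("reward", 0.5), ("punish", -0.5)]
_GROUP_CELLS = [("HC", 0.5), ("AUDP", -0.5)]


def fit_stay_regression(dataset: pd.DataFrame, n_quad: int = 15) -> RegressionResult:
    """Mixed logistic regression of stay on previous outcome x group.

    Fixed effects: previous outcome (reward +0.5 / loss -0.5), group
    (HC +0.5 / AUDP -0.5), and their interaction; random intercept per
    subject.  Post-hoc: all pairwise contrasts of the four outcome-by-group
    cells with a max-|z| (Tukey-type) adjustment.
    """
    tab = stay_table(dataset)
    if tab.groupby("group")["subject"].nunique().min() < 2:
        raise ValueError("need >= 2 subjects per group")
    X = np.column_stack(
        [
            np.ones(len(tab)),
            tab["prev_reward"].to_numpy(),
            tab["group_code"].to_numpy(),
            tab["prev_reward"].to_numpy() * tab["group_code"].to_numpy(),
        ]
    )
    names = ["intercept", "prev_outcome", "group", "prev_outcome:group"]
    res = fit_mixed_logit(tab["stay"].to_numpy(), X, tab["subject"].to_numpy(), names, n_quad)
    cells = {
        f"{gname}:{oname}": np.array([1.0, o, g, o * g])
        for gname, g in _GROUP_CELLS
        for oname, o in _CELLS
    }
    labels, L = [], []
    keys = list(cells)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            labels.append(f"{keys[i]} - {keys[j]}")
            L.append(cells[keys[i]] - cells[keys[j]])
    res.contrasts = adjusted_contrasts(res, np.array(L), labels)
    return res


def fit_cumulative_regression(dataset: pd.DataFrame, n_quad: int = 15) -> RegressionResult:
    """Mixed logistic regression of stay on cumulative negative feedback x group.

    The cumulative code enters numerically (0-3); group is coded +0.5 (HC) /
    -0.5 (AUDP).  Post-hoc: the group contrast at each code level, max-|z|
    adjusted.
    """
    tab = stay_table(dataset)
    if tab.groupby("group")["subject"].nunique().min() < 2:
        raise ValueError("need >= 2 subjects per group")
    X = np.column_stack(
        [
            np.ones(len(tab)),
            tab["negfb_code"].to_numpy(),
            tab["group_code"].to_numpy(),
            tab["negfb_code"].to_numpy() * tab["group_code"].to_numpy(),
        ]
    )
    names = ["intercept", "negfb_code", "group", "negfb_code:group"]
    res = fit_mixed_logit(tab["stay"].to_numpy(), X, tab["subject"].to_numpy(), names, n_quad)
    labels, L = [], []
    for code in range(4):
        labels.append(f"HC - AUDP @ code {code}")
        L.append(np.array([0.0, 0.0, 1.0, float(code)]))
    res.contrasts = adjusted_contrasts(res, np.array(L), labels)
    return res
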