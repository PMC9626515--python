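"""Model evaluation: HDI group differences, LOOIC comparison, posterior
predictive checks, and parameter recovery.

Group comparison follows the separate-fits convention: each group has its
own posterior, so the difference distribution is formed by pairing
randomly permuted draws of the two independent posteriors (fixed pairing
seed) and summarized by the 95% highest density interval; a parameter
differs credibly between groups when that interval excludes zero.

Posterior predictive checks re-simulate the full task (simulated choices
feed back into the value recursion) for a thinned set of posterior draws,
yielding per-subject, per-trial simulated-choice probabilities and modal
choices; parameter recovery refits the model to the modal choices and
correlates subject-level posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import EWAParams, PARAM_NAMES, RPParams, simulate_subject
from .behavior import perseveration, summarize_subject
from .data import validate_dataset
from .inference import FitResult, MCMCConfig, fit_group
from .task import TaskSchedule

__all__ = [
    "HDIInterval",
    "RecoveryReport",
    "hdi",
    "group_difference",
    "compare_models",
    "posterior_predictive_choices",
    "parameter_recovery",
    "ppc_behavior",
]


@dataclass(frozen=True)
class HDIInterval:
    """Shortest interval containing ``mass`` of the posterior draws."""

    lower: float
    upper: float
    mass: float
    excludes_zero: bool


def hdi(samples: np.ndarray, mass: float = 0.95) -> HDIInterval:
    """Shortest contiguous interval over sorted samples holding ``mass``.

    Requires at least 100 samples.  With n samples the interval spans
    ceil(mass * n) consecutive order statistics.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 samples for an HDI, got {n}")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    lo, hi = float(x[i]), float(x[i + k - 1])
    return HDIInterval(lower=lo, upper=hi, mass=mass, excludes_zero=not (lo <= 0.0 <= hi))


def group_difference(
    fit_a: FitResult,
    fit_b: FitResult,
    parameter: str,
    mass: float = 0.95,
    pairing_seed: int = 0,
) -> HDIInterval:
    """HDI of the (a - b) difference of a constrained group-level mean.

    The two posteriors are independent, so equal-length difference draws are
    formed by pairing randomly permuted draws from each fit.  Each fit's
    permutation is derived from ``pairing_seed`` and the fit's own identity
    (data hash, model, group), which makes the difference antisymmetric in
    its arguments under the same seed.
    """
    da = fit_a.group_mean_draws(parameter)
    db = fit_b.group_mean_draws(parameter)
    n = min(len(da), len(db))
    ia = _fit_permutation(fit_a, pairing_seed, len(da))[:n]
    ib = _fit_permutation(fit_b, pairing_seed, len(db))[:n]
    return hdi(da[ia] - db[ib], mass=mass)


def _fit_permutation(fit: FitResult, pairing_seed: int, n: int) -> np.ndarray:
    import hashlib

    ident = f"{fit.data_hash}|{fit.model}|{fit.group}".encode()
    digest = int.from_bytes(hashlib.md5(ident).digest()[:4], "big")
    rng = np.random.default_rng(np.random.SeedSequence([pairing_seed, digest]))
    return rng.permutation(n)


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """LOOIC comparison table, ascending (best model first).

    All fits must be on identical data (checked by content hash); ties in
    LOOIC break by model name for determinism.
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash for f in fits if f.data_hash}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different datasets")
    rows = sorted(
        ({"model": f.model, "group": f.group, "looic": f.looic} for f in fits),
        key=lambda r: (r["looic"], r["model"]),
    )
    best = rows[0]["looic"]
    for r in rows:
        r["delta_looic"] = r["looic"] - best
    return pd.DataFrame(rows)


def posterior_predictive_choices(
    fit: FitResult,
    dataset: pd.DataFrame,
    schedules: dict[str, TaskSchedule] | TaskSchedule | None = None,
    n_draws: int = 500,
    seed: int = 0,
    method: str = "resimulate",
) -> pd.DataFrame:
    """Per-subject, per-trial simulated-choice probabilities and modal choices.

    ``method="resimulate"`` (default): for each thinned posterior draw the
    full task is re-simulated per subject — simulated choices feed back into
    the value recursion — and simulated rows are aligned to the empirical
    dataset by (subject, block, trial); ``p_choice1`` is the frequency of
    simulated stimulus-1 choices among draws reaching that trial.

    ``method="onestep"``: the predictive choice probability at each trial is
    computed conditional on the subject's *observed* history (values updated
    from the empirical choices and outcomes), averaged over the thinned
    draws.  This is the one-step-ahead predictive convention and requires no
    schedule.

    In both modes ``modal_choice`` is the most frequently simulated (or most
    probable) choice; ties break toward stimulus 0.
    """
    if method not in ("resimulate", "onestep"):
        raise ValueError("method must be 'resimulate' or 'onestep'")
    dataset = validate_dataset(dataset)
    subjects = fit.subjects
    if set(subjects) != set(dataset["subject"].unique()):
        raise ValueError("fit and dataset subjects do not match")
    names = PARAM_NAMES[fit.model]
    theta = np.stack(
        [fit.posterior[p].reshape(-1, len(subjects)) for p in names], axis=-1
    )  # (total_draws, n_subjects, 3)
    total = theta.shape[0]
    if total == 0:
        raise ValueError("fit contains no posterior draws")
    rng = np.random.default_rng(seed)
    take = (
        np.arange(total)
        if n_draws >= total
        else np.sort(rng.choice(total, size=n_draws, replace=False))
    )
    base = dataset.sort_values(["subject", "block", "trial"]).reset_index(drop=True)
    out = base[["subject", "group", "block", "trial", "choice", "outcome",
                "correct", "stage"]].copy()
    if method == "onestep":
        p1 = np.zeros(len(base))
        for si, subj in enumerate(subjects):
            mask = (base["subject"] == subj).to_numpy()
            rows = base[mask]
            p1[mask] = _onestep_probs(rows, theta[take, si, :], fit)
        out["p_choice1"] = p1
        out["n_sims"] = len(take)
        out["modal_choice"] = (out["p_choice1"] > 0.5).astype(np.int64)
        return out
    if schedules is None:
        raise ValueError("re-simulation requires task schedules")
    key_index = {
        (r.subject, r.block, r.trial): i
        for i, r in enumerate(base.itertuples(index=False))
    }
    count1 = np.zeros(len(base))
    present = np.zeros(len(base))
    beta_max = fit.config.beta_max
    for d in take:
        for si, subj in enumerate(subjects):
            sched = schedules[subj] if isinstance(schedules, dict) else schedules
            params = _params_from(theta[d, si], fit.model, beta_max)
            sim = simulate_subject(params, sched, rng,
                                   mirrored=fit.config.mirrored, model=fit.model)
            for b, t, c in zip(sim["block"].to_numpy(), sim["trial"].to_numpy(),
                               sim["choice"].to_numpy()):
                i = key_index.get((subj, b, t))
                if i is not None:
                    present[i] += 1
                    count1[i] += c
    with np.errstate(invalid="ignore", divide="ignore"):
        out["p_choice1"] = np.where(present > 0, count1 / np.maximum(present, 1), 0.5)
    out["n_sims"] = present.astype(int)
    out["modal_choice"] = (out["p_choice1"] > 0.5).astype(np.int64)
    return out


def _params_from(p: np.ndarray, model: str, beta_max: float):
    if model == "rp":
        return RPParams(a_rew=_clip01(p[0]), a_pun=_clip01(p[1]),
                        beta=_clip_beta(p[2], beta_max), beta_max=beta_max)
    return EWAParams(a=_clip01(p[0]), rho=_clip01(p[1]),
                     beta=_clip_beta(p[2], beta_max), beta_max=beta_max)


def _onestep_probs(rows: pd.DataFrame, thetas: np.ndarray, fit: FitResult) -> np.ndarray:
    """Mean one-step-ahead P(choice = 1) over posterior draws for one subject.

    Recovered from the per-trial log-likelihood of the observed choice:
    p1 = p_obs when the observed choice was 1, else 1 - p_obs.
    """
    from .agents import loglik_subject

    choices = rows["choice"].to_numpy()
    acc = np.zeros(len(rows))
    beta_max = fit.config.beta_max
    for p in thetas:
        params = _params_from(p, fit.model, beta_max)
        _, pw = loglik_subject(rows, params, model=fit.model,
                               mirrored=fit.config.mirrored)
        p_obs = np.exp(pw)
        acc += np.where(choices == 1, p_obs, 1.0 - p_obs)
    return acc / len(thetas)


def _clip01(x: float) -> float:
    return float(np.clip(x, 1e-9, 1 - 1e-9))


def _clip_beta(x: float, beta_max: float) -> float:
    return float(np.clip(x, 1e-9, beta_max))


@dataclass
class RecoveryReport:
    """True vs recovered subject-level posterior means per parameter."""

    parameters: list[str]
    true_means: pd.DataFrame  # posterior means of the original fit
    recovered_means: pd.DataFrame  # posterior means of the refit
    correlations: dict[str, float]
    ground_truth_correlations: dict[str, float] | None
    refit_converged: bool


def parameter_recovery(
    fit: FitResult,
    dataset: pd.DataFrame,
    schedules: dict[str, TaskSchedule] | TaskSchedule | None = None,
    mcmc_config: MCMCConfig | None = None,
    n_ppc_draws: int = 500,
    seed: int = 0,
    ground_truth: pd.DataFrame | None = None,
    method: str = "onestep",
) -> RecoveryReport:
    """Refit the model to modal simulated choices and correlate estimates.

    Simulated choices default to the one-step-ahead predictive mode: modal
    choices conditioned on each subject's observed history form a coherent
    behavioral sequence, which is what makes refitting meaningful (modal
    choices of independent full re-simulations decohere after the first
    reversal and carry no recoverable parameters).  The refit dataset pairs
    the modal choices with the observed outcome sequence — in these
    likelihoods outcomes are conditioning variables, not modeled — and
    recomputes the contingency-correct flags.

    "True" values are the subject-level posterior means of the original fit;
    when a synthetic ground-truth table (subject x parameter) is supplied,
    correlations against it are reported as well.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    ppc = posterior_predictive_choices(fit, dataset, schedules,
                                       n_draws=n_ppc_draws, seed=seed,
                                       method=method)
    refit_data = ppc.copy()
    corr_stim = np.where(ppc["correct"], ppc["choice"], 1 - ppc["choice"])
    refit_data["choice"] = ppc["modal_choice"]
    refit_data["correct"] = refit_data["choice"].to_numpy() == corr_stim
    refit_data = refit_data[["subject", "group", "block", "trial", "choice",
                             "outcome", "correct", "stage"]]
    config = mcmc_config or fit.config
    refit = fit_group(refit_data, fit.model, config)
    names = PARAM_NAMES[fit.model]
    true_means = fit.subject_posterior_means()
    rec_means = refit.subject_posterior_means()
    rec_means = rec_means.loc[true_means.index]
    corr = {
        p: float(np.corrcoef(true_means[p], rec_means[p])[0, 1]) for p in names
    }
    gt_corr = None
    if ground_truth is not None:
        gt = ground_truth.set_index("subject") if "subject" in ground_truth.columns else ground_truth
        gt = gt.loc[true_means.index]
        gt_corr = {
            p: float(np.corrcoef(gt[p], rec_means[p])[0, 1])
            for p in names if p in gt.columns
        }
    return RecoveryReport(
        parameters=list(names),
        true_means=true_means,
        recovered_means=rec_means,
        correlations=corr,
        ground_truth_correlations=gt_corr,
        refit_converged=refit.converged,
    )


def ppc_behavior(
    ppc: pd.DataFrame,
    mode: str = "weighted",
) -> pd.DataFrame:
    """Behavioral statistics computed from posterior predictive choices.

    ``mode="modal"`` feeds the modal simulated choices through the standard
    behavioral statistics.  ``mode="weighted"`` computes probability-weighted
    win-stay / lose-shift (stay probability of a trial pair is
    p*p' + (1-p)(1-p')); the perseveration run statistic has no per-trial
    expectation form, so weighted mode reports it from the modal choices.
    """
    if mode not in ("weighted", "modal"):
        raise ValueError("mode must be 'weighted' or 'modal'")
    required = {"p_choice1", "modal_choice"}
    if not required <= set(ppc.columns):
        raise ValueError("input must come from posterior_predictive_choices")
    rows = []
    for subj, g in ppc.groupby("subject", sort=True):
        g = g.sort_values(["block", "trial"])
        # designated correct stimulus per trial, from the empirical flags
        corr_stim = np.where(g["correct"], g["choice"], 1 - g["choice"])
        modal = g.copy()
        modal["choice"] = modal["modal_choice"].astype(np.int64)
        modal["correct"] = modal["choice"].to_numpy() == corr_stim
        n_err, n_qual, rate = perseveration(modal)
        if mode == "modal":
            s = summarize_subject(modal, subject=str(subj))
            p_ws, p_ls = s.p_winstay, s.p_loseshift
        else:
            p_ws, p_ls = _weighted_wsls(g)
        rows.append(
            {
                "subject": str(subj),
                "group": g["group"].iloc[0],
                "p_winstay": p_ws,
                "p_loseshift": p_ls,
                "n_persev_errors": n_err,
                "n_qualifying_sequences": n_qual,
                "persev_error_rate": rate,
            }
        )
    return pd.DataFrame(rows).set_index("subject")


def _weighted_wsls(g: pd.DataFrame) -> tuple[float, float]:
    stay_probs, prev_outcomes = [], []
    for _, block in g.groupby("block", sort=True):
        p = block["p_choice1"].to_numpy(dtype=float)
        o = block["outcome"].to_numpy()
        stay = p[1:] * p[:-1] + (1 - p[1:]) * (1 - p[:-1])
        stay_probs.append(stay)
        prev_outcomes.append(o[:-1])
    stay = np.concatenate(stay_probs)
    prev = np.concatenate(prev_outcomes)
    wins = prev == 1
    losses = prev == -1
    p_ws = float(stay[wins].mean()) if wins.any() else float("nan")
    p_ls = float(1 - stay[losses].mean()) if losses.any() else float("nan")
    return p_ws, p_ls
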