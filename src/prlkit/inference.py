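"""Hierarchical Bayesian estimation of RL parameters, one group at a time.

Model.  For each subject i and parameter k, an unconstrained value
``theta_raw[i, k]`` is drawn from a group-level normal with mean ``mu[k]``
and standard deviation ``sigma[k]``.  Priors are Normal(0, 1) on each
``mu[k]`` and half-Cauchy(0, 5) on each ``sigma[k]`` — weakly informative
hyperpriors suitable for small groups.  Constrained parameters are obtained
by the inverse-probit (standard normal CDF) transform: learning rates and
decays map to (0, 1); the inverse temperature is additionally scaled by an
upper limit ``beta_max`` (default 10).

Sampling uses the no-U-turn sampler over a non-centered parameterization
(``theta_raw = mu + sigma * z`` with ``z ~ N(0, 1)``), which removes the
funnel geometry that small groups otherwise induce, with analytic gradients
of the trial-level likelihoods.  Groups are always fitted separately; no
hyperparameters are shared across groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from . import _kernels
from .agents import BETA_MAX_DEFAULT, MODEL_IDS, PARAM_NAMES
from .data import validate_dataset
from .sampler import nuts_sample

__all__ = [
    "MCMCConfig",
    "RawParams",
    "FitResult",
    "constrain",
    "log_posterior",
    "fit_group",
    "rhat",
    "compute_looic",
]

_LOG_HALF_CAUCHY_NORM = float(np.log(2.0 / (np.pi * 5.0)))


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration. ``n_samples`` includes the warmup draws."""

    n_samples: int = 20_000
    n_warmup: int = 2_000
    n_chains: int = 4
    seed: int = 0
    target_accept: float = 0.8
    beta_max: float = BETA_MAX_DEFAULT
    mirrored: bool = True

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_samples:
            raise ValueError("n_samples must exceed n_warmup")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class RawParams:
    """Centered-parameterization group state: mu[k], sigma[k], theta_raw[i,k]."""

    mu: np.ndarray
    sigma: np.ndarray
    theta_raw: np.ndarray


def constrain(theta_raw, kind: str = "unit", beta_max: float = BETA_MAX_DEFAULT):
    """Inverse-probit transform to the parameter's native scale.

    ``kind="unit"`` maps to (0, 1) (learning rates, decays); ``kind="beta"``
    maps to (0, beta_max).
    """
    theta_raw = np.asarray(theta_raw, dtype=float)
    out = special.ndtr(theta_raw)
    if kind == "beta":
        out = out * beta_max
    elif kind != "unit":
        raise ValueError(f"unknown parameter kind {kind!r}")
    return out if out.ndim else float(out)


def _group_arrays(dataset: pd.DataFrame):
    """Concatenate a (single-group) dataset into kernel-ready arrays."""
    subjects = sorted(dataset["subject"].unique())
    choices, outcomes, resets, ptr = [], [], [], [0]
    for s in subjects:
        g = dataset[dataset["subject"] == s].sort_values(["block", "trial"])
        blocks = g["block"].to_numpy()
        choices.append(g["choice"].to_numpy(dtype=np.int64))
        outcomes.append(g["outcome"].to_numpy(dtype=np.float64))
        r = np.zeros(len(g), dtype=np.bool_)
        r[0] = True
        r[1:] = blocks[1:] != blocks[:-1]
        resets.append(r)
        ptr.append(ptr[-1] + len(g))
    return (
        subjects,
        np.concatenate(choices),
        np.concatenate(outcomes),
        np.concatenate(resets),
        np.asarray(ptr, dtype=np.int64),
    )


class HierarchicalModel:
    """Log posterior and gradient of one group's hierarchical model.

    Operates on the non-centered unconstrained vector
    ``x = [mu (3), log_sigma (3), z (n_subjects * 3)]``.
    """

    def __init__(self, dataset: pd.DataFrame, model: str,
                 beta_max: float = BETA_MAX_DEFAULT, mirrored: bool = True):
        if model not in MODEL_IDS:
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.model_id = _kernels.MODEL_RP if model == "rp" else _kernels.MODEL_EWA
        self.beta_max = beta_max
        self.mirrored = mirrored
        if len(dataset):
            (self.subjects, self.choices, self.outcomes,
             self.reset, self.subj_ptr) = _group_arrays(dataset)
        else:
            self.subjects = []
            self.choices = np.zeros(0, dtype=np.int64)
            self.outcomes = np.zeros(0)
            self.reset = np.zeros(0, dtype=np.bool_)
            self.subj_ptr = np.zeros(1, dtype=np.int64)
        self.n_subjects = len(self.subjects)
        self.dim = 6 + 3 * self.n_subjects

    def unpack(self, x: np.ndarray):
        mu = x[:3]
        log_sigma = x[3:6]
        z = x[6:].reshape(self.n_subjects, 3)
        return mu, log_sigma, z

    def constrain_subjects(self, theta_raw: np.ndarray) -> np.ndarray:
        theta = special.ndtr(theta_raw)
        theta = theta.copy()
        theta[..., 2] *= self.beta_max
        return theta

    def logp_grad(self, x: np.ndarray):
        """Log posterior and gradient (fully jitted fast path)."""
        logp, grad = _kernels.hier_logp_grad(
            np.asarray(x, dtype=float), self.choices, self.outcomes, self.reset,
            self.subj_ptr, self.model_id, self.mirrored, self.beta_max,
        )
        return float(logp), grad

    def logp_grad_reference(self, x: np.ndarray):
        """Pure numpy/scipy evaluation; kept as an independent cross-check."""
        mu, log_sigma, z = self.unpack(x)
        sigma = np.exp(log_sigma)
        grad = np.zeros_like(x)
        # hyperpriors
        logp = float(-0.5 * np.sum(mu**2))
        grad[:3] = -mu
        logp += float(np.sum(
            _LOG_HALF_CAUCHY_NORM - np.log1p((sigma / 5.0) ** 2) + log_sigma
        ))
        grad[3:6] = -2.0 * sigma**2 / (25.0 + sigma**2) + 1.0
        # standard-normal z
        logp += float(-0.5 * np.sum(z**2))
        gz = -z.copy()
        if self.n_subjects:
            raw = mu[None, :] + sigma[None, :] * z
            theta = self.constrain_subjects(raw)
            ll, g_theta = _kernels.group_loglik_grad(
                self.choices, self.outcomes, self.reset, self.subj_ptr,
                theta, self.model_id, self.mirrored,
            )
            logp += float(ll.sum())
            scale = np.array([1.0, 1.0, self.beta_max])
            g_raw = g_theta * _norm_pdf(raw) * scale[None, :]
            grad[:3] += g_raw.sum(axis=0)
            grad[3:6] += np.sum(g_raw * z, axis=0) * sigma
            gz += g_raw * sigma[None, :]
        grad[6:] = gz.ravel()
        return logp, grad


def _norm_pdf(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def log_posterior(dataset: pd.DataFrame, raw: RawParams, model: str,
                  beta_max: float = BETA_MAX_DEFAULT, mirrored: bool = True) -> float:
    """Centered-parameterization log posterior (up to additive constants).

    Sum of the hyperpriors, the Normal(mu, sigma) density of each subject's
    raw parameters, and each subject's choice log-likelihood at the
    constrained parameters.  Returns -inf for sigma <= 0.
    """
    mu = np.asarray(raw.mu, dtype=float)
    sigma = np.asarray(raw.sigma, dtype=float)
    theta_raw = np.asarray(raw.theta_raw, dtype=float).reshape(-1, 3)
    if np.any(sigma <= 0):
        return -np.inf
    logp = float(-0.5 * np.sum(mu**2) - 1.5 * np.log(2 * np.pi))
    logp += float(np.sum(_LOG_HALF_CAUCHY_NORM - np.log1p((sigma / 5.0) ** 2)))
    logp += float(np.sum(
        -0.5 * ((theta_raw - mu[None, :]) / sigma[None, :]) ** 2
        - np.log(sigma[None, :]) - 0.5 * np.log(2 * np.pi)
    ))
    if len(dataset):
        m = HierarchicalModel(dataset, model, beta_max=beta_max, mirrored=mirrored)
        if m.n_subjects != theta_raw.shape[0]:
            raise ValueError("theta_raw rows must match the number of subjects")
        theta = m.constrain_subjects(theta_raw)
        ll, _ = _kernels.group_loglik_grad(
            m.choices, m.outcomes, m.reset, m.subj_ptr, theta, m.model_id, m.mirrored
        )
        logp += float(ll.sum())
    return logp


def rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Constant chains return 1.0
    by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    n_chains, n_draws = chains.shape
    if n_draws < 10 or (n_chains < 2 and n_draws < 20):
        raise ValueError("need >= 2 chains (or one splittable chain) of >= 10 draws")
    half = n_draws // 2
    split = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    w = float(np.mean(split.var(axis=1, ddof=1)))
    b = n * float(np.var(chain_means, ddof=1))
    if w == 0.0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def compute_looic(pointwise_loglik: np.ndarray):
    """PSIS-smoothed leave-one-out estimate from per-draw unit log-likelihoods.

    ``pointwise_loglik`` has shape (n_chains, n_draws, n_units); units are
    subjects (each entry a subject's total trial log-likelihood at one
    posterior draw).  Returns ``(looic, elpd_per_unit, pareto_k)``.
    """
    import arviz as az

    pll = np.asarray(pointwise_loglik, dtype=float)
    if pll.ndim != 3:
        raise ValueError("expected (n_chains, n_draws, n_units)")
    if np.any(np.all(~np.isfinite(pll), axis=(0, 1))):
        raise ValueError("a unit has no finite log-likelihood values")
    # the log-likelihood draws double as the posterior group arviz needs for
    # its relative-efficiency (ESS) correction
    idata = az.from_dict(posterior={"subject_loglik": pll},
                         log_likelihood={"subject": pll})
    res = az.loo(idata, var_name="subject", pointwise=True)
    elpd_i = np.asarray(res.loo_i.values, dtype=float)
    pareto_k = np.asarray(res.pareto_k.values, dtype=float)
    looic = -2.0 * float(res.elpd_loo)
    return looic, elpd_i, pareto_k


@dataclass
class FitResult:
    """Posterior draws, diagnostics, and LOOIC for one group and model."""

    model: str
    group: str
    subjects: list[str]
    posterior: dict[str, np.ndarray]  # (chains, draws, ...) per key
    pointwise_loglik: np.ndarray  # (chains, draws, n_subjects)
    rhat: dict[str, np.ndarray]
    looic: float
    elpd_loo_i: np.ndarray
    pareto_k: np.ndarray
    diagnostics: dict
    config: MCMCConfig
    data_hash: str = ""

    @property
    def max_rhat(self) -> float:
        return float(max(np.max(v) for v in self.rhat.values()))

    @property
    def converged(self) -> bool:
        return self.max_rhat <= 1.1

    def group_mean_draws(self, parameter: str) -> np.ndarray:
        """Flattened posterior draws of a constrained group-level mean."""
        key = f"mu_{parameter}"
        if key not in self.posterior:
            raise KeyError(f"no group-level parameter {parameter!r}")
        return self.posterior[key].reshape(-1)

    def subject_posterior_means(self) -> pd.DataFrame:
        names = PARAM_NAMES[self.model]
        cols = {p: self.posterior[p].mean(axis=(0, 1)) for p in names}
        return pd.DataFrame(cols, index=pd.Index(self.subjects, name="subject"))

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = PARAM_NAMES[self.model]
        n_chains = self.posterior["mu_raw"].shape[0]
        cols: dict[str, np.ndarray] = {}
        for k in range(3):
            cols[f"mu_raw.{names[k]}"] = self.posterior["mu_raw"][..., k].reshape(-1)
            cols[f"sigma.{names[k]}"] = self.posterior["sigma"][..., k].reshape(-1)
            cols[f"mu_{names[k]}"] = self.posterior[f"mu_{names[k]}"].reshape(-1)
        for k, p in enumerate(names):
            arr = self.posterior[p]
            for i, s in enumerate(self.subjects):
                cols[f"{p}[{s}]"] = arr[..., i].reshape(-1)
        pd.DataFrame(cols).to_csv(out / "draws.csv", index=False)
        pll = self.pointwise_loglik.reshape(-1, len(self.subjects))
        pd.DataFrame(pll, columns=self.subjects).to_csv(out / "pointwise_loglik.csv", index=False)
        meta = {
            "model": self.model,
            "group": self.group,
            "subjects": self.subjects,
            "n_chains": n_chains,
            "rhat": {k: np.asarray(v).tolist() for k, v in self.rhat.items()},
            "looic": self.looic,
            "elpd_loo_i": self.elpd_loo_i.tolist(),
            "pareto_k": self.pareto_k.tolist(),
            "diagnostics": self.diagnostics,
            "config": asdict(self.config),
            "data_hash": self.data_hash,
        }
        (out / "fit.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "FitResult":
        out = Path(out_dir)
        meta = json.loads((out / "fit.json").read_text())
        draws = pd.read_csv(out / "draws.csv")
        names = PARAM_NAMES[meta["model"]]
        n_chains = meta["n_chains"]
        subjects = [str(s) for s in meta["subjects"]]

        def shape(col):
            return draws[col].to_numpy().reshape(n_chains, -1)

        posterior: dict[str, np.ndarray] = {}
        posterior["mu_raw"] = np.stack([shape(f"mu_raw.{n}") for n in names], axis=-1)
        posterior["sigma"] = np.stack([shape(f"sigma.{n}") for n in names], axis=-1)
        for n in names:
            posterior[f"mu_{n}"] = shape(f"mu_{n}")
            posterior[n] = np.stack([shape(f"{n}[{s}]") for s in subjects], axis=-1)
        pll = pd.read_csv(out / "pointwise_loglik.csv").to_numpy()
        pll = pll.reshape(n_chains, -1, len(subjects))
        return cls(
            model=meta["model"],
            group=meta["group"],
            subjects=subjects,
            posterior=posterior,
            pointwise_loglik=pll,
            rhat={k: np.asarray(v) for k, v in meta["rhat"].items()},
            looic=meta["looic"],
            elpd_loo_i=np.asarray(meta["elpd_loo_i"]),
            pareto_k=np.asarray(meta["pareto_k"]),
            diagnostics=meta["diagnostics"],
            config=MCMCConfig(**meta["config"]),
            data_hash=meta.get("data_hash", ""),
        )


def fit_group(dataset: pd.DataFrame, model: str,
              config: MCMCConfig = MCMCConfig()) -> FitResult:
    """Fit the hierarchical model to one group's choice data by NUTS MCMC.

    ``dataset`` must contain a single group with >= 2 subjects.  Chains are
    seeded independently from ``config.seed`` and run sequentially; R-hat is
    computed for every sampled and constrained parameter.  Any R-hat above
    1.1 sets ``diagnostics["warning"]`` (the result is still returned).
    """
    from .data import dataset_hash

    dataset = validate_dataset(dataset)
    groups = dataset["group"].unique()
    if len(groups) != 1:
        raise ValueError("fit_group expects a single-group dataset; split by group first")
    hmodel = HierarchicalModel(dataset, model, beta_max=config.beta_max,
                               mirrored=config.mirrored)
    if hmodel.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    n_keep = config.n_samples - config.n_warmup
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chain_draws, divergences, step_sizes, accept_rates = [], [], [], []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        x0 = 0.1 * rng.standard_normal(hmodel.dim)
        res = nuts_sample(hmodel.logp_grad, x0, n_keep, config.n_warmup, rng,
                          target_accept=config.target_accept)
        chain_draws.append(res.draws)
        divergences.append(res.n_divergent)
        step_sizes.append(res.step_size)
        accept_rates.append(res.accept_rate)
    draws = np.stack(chain_draws)  # (chains, n_keep, dim)

    names = PARAM_NAMES[model]
    mu_raw = draws[:, :, :3]
    sigma = np.exp(draws[:, :, 3:6])
    z = draws[:, :, 6:].reshape(config.n_chains, n_keep, hmodel.n_subjects, 3)
    theta_raw = mu_raw[:, :, None, :] + sigma[:, :, None, :] * z
    theta = special.ndtr(theta_raw)
    theta[..., 2] *= config.beta_max
    posterior: dict[str, np.ndarray] = {"mu_raw": mu_raw, "sigma": sigma, "z": z}
    group_mean = special.ndtr(mu_raw)
    group_mean[..., 2] = group_mean[..., 2] * config.beta_max
    for k, p in enumerate(names):
        posterior[f"mu_{p}"] = group_mean[..., k]
        posterior[p] = theta[..., k]

    rhat_map: dict[str, np.ndarray] = {}
    for k, p in enumerate(names):
        rhat_map[f"mu_raw.{p}"] = np.array(rhat(mu_raw[..., k]))
        rhat_map[f"sigma.{p}"] = np.array(rhat(sigma[..., k]))
        rhat_map[f"mu_{p}"] = np.array(rhat(group_mean[..., k]))
        rhat_map[p] = np.array(
            [rhat(theta[..., i, k]) for i in range(hmodel.n_subjects)]
        )
        rhat_map[f"z.{p}"] = np.array(
            [rhat(z[..., i, k]) for i in range(hmodel.n_subjects)]
        )

    pll = np.empty((config.n_chains, n_keep, hmodel.n_subjects))
    for c in range(config.n_chains):
        pll[c] = _kernels.group_pointwise_by_draw(
            hmodel.choices, hmodel.outcomes, hmodel.reset, hmodel.subj_ptr,
            np.ascontiguousarray(theta[c]), hmodel.model_id, config.mirrored,
        )
    looic, elpd_i, pareto_k = compute_looic(pll)

    max_rhat = float(max(np.max(v) for v in rhat_map.values()))
    diagnostics = {
        "n_divergent": [int(d) for d in divergences],
        "step_size": [float(s) for s in step_sizes],
        "accept_rate": [float(a) for a in accept_rates],
        "max_rhat": max_rhat,
        "warning": "non-convergence: R-hat > 1.1" if max_rhat > 1.1 else "",
    }
    return FitResult(
        model=model,
        group=str(groups[0]),
        subjects=[str(s) for s in hmodel.subjects],
        posterior=posterior,
        pointwise_loglik=pll,
        rhat=rhat_map,
        looic=looic,
        elpd_loo_i=elpd_i,
        pareto_k=pareto_k,
        diagnostics=diagnostics,
        config=config,
        data_hash=dataset_hash(dataset),
    )
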