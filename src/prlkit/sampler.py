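"""No-U-Turn sampler with dual-averaging step size and diagonal metric.

A self-contained gradient-based MCMC engine: slice-variable tree doubling
with the no-U-turn termination criterion, dual averaging of the step size
toward a target acceptance statistic during warmup, and a diagonal metric
(posterior-variance estimate) adapted in expanding windows, following the
standard warmup schedule of modern HMC implementations.

The target density is supplied as ``logp_grad(x) -> (logp, grad)`` on an
unconstrained parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsResult:
    """Post-warmup draws of one chain plus adaptation metadata."""

    draws: np.ndarray  # (n_kept, dim)
    logp: np.ndarray  # (n_kept,)
    n_divergent: int
    step_size: float
    metric: np.ndarray  # diagonal of the (co)variance estimate
    accept_rate: float


class _Tree:
    __slots__ = ("x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
                 "x_prop", "logp_prop", "n_valid", "stop", "divergent",
                 "alpha", "n_alpha")


def _leapfrog(logp_grad, x, p, g, eps, var):
    p1 = p + 0.5 * eps * g
    x1 = x + eps * var * p1
    logp1, g1 = logp_grad(x1)
    p1 = p1 + 0.5 * eps * g1
    return x1, p1, g1, logp1


def _kinetic(p, var):
    return 0.5 * float(np.dot(p * p, var))


def _build_tree(logp_grad, x, p, g, log_u, direction, depth, eps, var, joint0, rng):
    if depth == 0:
        x1, p1, g1, logp1 = _leapfrog(logp_grad, x, p, g, direction * eps, var)
        joint = logp1 - _kinetic(p1, var)
        t = _Tree()
        t.x_minus = t.x_plus = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = g1
        t.x_prop = x1
        t.logp_prop = logp1
        t.n_valid = int(log_u <= joint)
        t.divergent = bool(log_u - _DIVERGENCE_THRESHOLD > joint) or not np.isfinite(joint)
        t.stop = t.divergent
        t.alpha = min(1.0, float(np.exp(min(0.0, joint - joint0))))
        t.n_alpha = 1
        return t
    t = _build_tree(logp_grad, x, p, g, log_u, direction, depth - 1, eps, var, joint0, rng)
    if not t.stop:
        if direction == -1:
            t2 = _build_tree(logp_grad, t.x_minus, t.p_minus, t.g_minus, log_u,
                             direction, depth - 1, eps, var, joint0, rng)
            t.x_minus, t.p_minus, t.g_minus = t2.x_minus, t2.p_minus, t2.g_minus
        else:
            t2 = _build_tree(logp_grad, t.x_plus, t.p_plus, t.g_plus, log_u,
                             direction, depth - 1, eps, var, joint0, rng)
            t.x_plus, t.p_plus, t.g_plus = t2.x_plus, t2.p_plus, t2.g_plus
        total = t.n_valid + t2.n_valid
        if t2.n_valid > 0 and rng.random() < t2.n_valid / total:
            t.x_prop = t2.x_prop
            t.logp_prop = t2.logp_prop
        dx = t.x_plus - t.x_minus
        no_uturn = (np.dot(dx * var, t.p_minus) >= 0) and (np.dot(dx * var, t.p_plus) >= 0)
        t.stop = t.stop or t2.stop or not no_uturn
        t.divergent = t.divergent or t2.divergent
        t.n_valid = total
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
    return t


def _nuts_step(logp_grad, x, logp, g, eps, var, rng, max_depth):
    p0 = rng.standard_normal(len(x)) / np.sqrt(var)
    joint0 = logp - _kinetic(p0, var)
    log_u = joint0 + np.log(rng.random())
    x_minus = x_plus = x
    p_minus = p_plus = p0
    g_minus = g_plus = g
    x_prop, logp_prop = x, logp
    n_valid = 1
    divergent = False
    alpha_sum, n_alpha = 0.0, 0
    for depth in range(max_depth):
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            t = _build_tree(logp_grad, x_minus, p_minus, g_minus, log_u, direction,
                            depth, eps, var, joint0, rng)
            x_minus, p_minus, g_minus = t.x_minus, t.p_minus, t.g_minus
        else:
            t = _build_tree(logp_grad, x_plus, p_plus, g_plus, log_u, direction,
                            depth, eps, var, joint0, rng)
            x_plus, p_plus, g_plus = t.x_plus, t.p_plus, t.g_plus
        alpha_sum += t.alpha
        n_alpha += t.n_alpha
        if t.stop:
            divergent = divergent or t.divergent
            break
        if t.n_valid > 0 and rng.random() < min(1.0, t.n_valid / n_valid):
            x_prop, logp_prop = t.x_prop, t.logp_prop
        n_valid += t.n_valid
        dx = x_plus - x_minus
        if (np.dot(dx * var, p_minus) < 0) or (np.dot(dx * var, p_plus) < 0):
            break
    accept_stat = alpha_sum / max(n_alpha, 1)
    return x_prop, logp_prop, accept_stat, divergent


def _find_initial_step(logp_grad, x, logp, g, var, rng):
    eps = 1.0
    p0 = rng.standard_normal(len(x)) / np.sqrt(var)
    joint0 = logp - _kinetic(p0, var)
    _, p1, _, logp1 = _leapfrog(logp_grad, x, p0, g, eps, var)
    joint1 = logp1 - _kinetic(p1, var)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1 if (joint1 - joint0) > np.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, _, logp1 = _leapfrog(logp_grad, x, p0, g, eps, var)
        joint1 = logp1 - _kinetic(p1, var)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction == 1 and (joint1 - joint0) <= np.log(0.5):
            break
        if direction == -1 and (joint1 - joint0) > np.log(0.5):
            break
    return float(np.clip(eps, 1e-8, 1e2))


def _adaptation_windows(n_warmup: int) -> list[tuple[int, int]]:
    """Expanding metric-adaptation windows between the two step-size buffers."""
    init_buf = min(75, max(1, int(0.15 * n_warmup)))
    term_buf = min(50, max(1, int(0.10 * n_warmup)))
    windows = []
    start = init_buf
    size = 25
    end_of_middle = n_warmup - term_buf
    while start < end_of_middle:
        end = min(start + size, end_of_middle)
        # final window absorbs the remainder
        if end_of_middle - end < size * 2:
            end = end_of_middle
        windows.append((start, end))
        start = end
        size *= 2
    return windows


def nuts_sample(
    logp_grad,
    x0: np.ndarray,
    n_draws: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_depth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns the ``n_draws`` post-warmup draws."""
    x = np.asarray(x0, dtype=float).copy()
    logp, g = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    dim = len(x)
    var = np.ones(dim)  # diagonal metric = posterior variance estimate
    eps = _find_initial_step(logp_grad, x, logp, g, var, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    windows = _adaptation_windows(n_warmup)
    window_draws: list[np.ndarray] = []
    da_iter = 0

    kept = np.empty((n_draws, dim))
    kept_logp = np.empty(n_draws)
    n_div = 0
    accepts = []
    for it in range(n_warmup + n_draws):
        x, logp, accept_stat, divergent = _nuts_step(
            logp_grad, x, logp, g, eps, var, rng, max_depth
        )
        _, g = logp_grad(x)
        if it < n_warmup:
            da_iter += 1
            frac = 1.0 / (da_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            in_window = any(lo <= it < hi for lo, hi in windows)
            if in_window:
                window_draws.append(x.copy())
            for lo, hi in windows:
                if it == hi - 1 and window_draws:
                    draws_arr = np.asarray(window_draws)
                    n_w = len(draws_arr)
                    sample_var = draws_arr.var(axis=0)
                    # regularize toward unit scale as Stan does
                    var = (n_w / (n_w + 5.0)) * sample_var + (5.0 / (n_w + 5.0)) * 1e-3
                    var = np.clip(var, 1e-10, None)
                    window_draws = []
                    eps = _find_initial_step(logp_grad, x, logp, g, var, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            kept[it - n_warmup] = x
            kept_logp[it - n_warmup] = logp
            n_div += int(divergent)
            accepts.append(accept_stat)
    return NutsResult(
        draws=kept,
        logp=kept_logp,
        n_divergent=n_div,
        step_size=eps,
        metric=var,
        accept_rate=float(np.mean(accepts)) if accepts else float("nan"),
    )
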