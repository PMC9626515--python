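"""Numba kernels: RL likelihoods and their analytic gradients.

The value recursions of both models are sequential in trials, so the
log-likelihood and its gradient with respect to the (constrained) model
parameters are computed by forward accumulation through the recursion:
alongside each value q we carry dq/dparam, updated with the same recursion
differentiated term by term.  The softmax choice rule contributes

    d log p(c_t) / d q_s   = beta * ((s == c_t) - p_s)
    d log p(c_t) / d beta  = e_t * (q1 - q0),   e_t = (c_t == 1) - p1

Rate/sign switches (which learning rate applies) are treated as locally
constant, which is exact almost everywhere and standard for these models.

Outcome coding is +1 (win) / -1 (loss) throughout.
"""

import math

import numpy as np
from numba import njit

MODEL_RP = 0
MODEL_EWA = 1


@njit(cache=False)
def _log_p_chosen(q0, q1, beta, choice):
    """Stable log softmax probability of the observed binary choice."""
    m = beta * (q1 - q0)
    if choice == 1:
        if m > 0.0:
            return -np.log1p(np.exp(-m))
        return m - np.log1p(np.exp(m))
    else:
        if m > 0.0:
            return -m - np.log1p(np.exp(-m))
        return -np.log1p(np.exp(m))


@njit(cache=False)
def rp_pointwise(choices, outcomes, reset, a_rew, a_pun, beta, mirrored, out):
    """Per-trial log-likelihood under the reward-punishment model."""
    q0 = 0.0
    q1 = 0.0
    for t in range(choices.shape[0]):
        if reset[t]:
            q0 = 0.0
            q1 = 0.0
        c = choices[t]
        o = outcomes[t]
        out[t] = _log_p_chosen(q0, q1, beta, c)
        # learning rate selected by the outcome's sign; on a rewarded trial
        # the whole trial (chosen + fictive update) learns at a_rew, on a
        # punished trial at a_pun
        r = a_rew if o > 0.0 else a_pun
        if c == 1:
            q1 += r * (o - q1)
            if mirrored:
                q0 += r * (-o - q0)
        else:
            q0 += r * (o - q0)
            if mirrored:
                q1 += r * (-o - q1)


@njit(cache=False)
def ewa_pointwise(choices, outcomes, reset, a, rho, beta, out):
    """Per-trial log-likelihood under the experience-weighted attraction model."""
    q = np.zeros(2)
    n = np.zeros(2)
    for t in range(choices.shape[0]):
        if reset[t]:
            q[:] = 0.0
            n[:] = 0.0
        c = choices[t]
        o = outcomes[t]
        out[t] = _log_p_chosen(q[0], q[1], beta, c)
        n1 = rho * n[c] + 1.0
        q[c] = (q[c] * (1.0 - a) * rho * n[c] + o) / n1
        n[c] = n1


@njit(cache=False)
def rp_loglik_grad(choices, outcomes, reset, a_rew, a_pun, beta, mirrored):
    """Total log-likelihood and gradient wrt (a_rew, a_pun, beta)."""
    q = np.zeros(2)
    # dq[s, k]: derivative of q[s] wrt a_rew (k=0) and a_pun (k=1)
    dq = np.zeros((2, 2))
    ll = 0.0
    g = np.zeros(3)
    for t in range(choices.shape[0]):
        if reset[t]:
            q[:] = 0.0
            dq[:, :] = 0.0
        c = choices[t]
        o = outcomes[t]
        d = q[1] - q[0]
        ll += _log_p_chosen(q[0], q[1], beta, c)
        m = beta * d
        p1 = 1.0 / (1.0 + np.exp(-m))
        e = (1.0 if c == 1 else 0.0) - p1
        # chain rule through q0, q1
        g[0] += beta * e * (dq[1, 0] - dq[0, 0])
        g[1] += beta * e * (dq[1, 1] - dq[0, 1])
        g[2] += e * d
        # outcome-sign rate: rewarded trials learn at a_rew, punished at a_pun,
        # for both the chosen and the mirrored fictive update
        if o > 0.0:
            r = a_rew
            ridx = 0
        else:
            r = a_pun
            ridx = 1
        pe = o - q[c]
        for k in range(2):
            dq[c, k] = (1.0 - r) * dq[c, k] + (pe if k == ridx else 0.0)
        q[c] += r * pe
        if mirrored:
            nc = 1 - c
            pen = -o - q[nc]
            for k in range(2):
                dq[nc, k] = (1.0 - r) * dq[nc, k] + (pen if k == ridx else 0.0)
            q[nc] += r * pen
    return ll, g


@njit(cache=False)
def ewa_loglik_grad(choices, outcomes, reset, a, rho, beta):
    """Total log-likelihood and gradient wrt (a, rho, beta)."""
    q = np.zeros(2)
    n = np.zeros(2)
    dq = np.zeros((2, 2))  # wrt a (k=0) and rho (k=1)
    dn = np.zeros(2)  # wrt rho; n does not depend on a
    ll = 0.0
    g = np.zeros(3)
    for t in range(choices.shape[0]):
        if reset[t]:
            q[:] = 0.0
            n[:] = 0.0
            dq[:, :] = 0.0
            dn[:] = 0.0
        c = choices[t]
        o = outcomes[t]
        d = q[1] - q[0]
        ll += _log_p_chosen(q[0], q[1], beta, c)
        m = beta * d
        p1 = 1.0 / (1.0 + np.exp(-m))
        e = (1.0 if c == 1 else 0.0) - p1
        g[0] += beta * e * (dq[1, 0] - dq[0, 0])
        g[1] += beta * e * (dq[1, 1] - dq[0, 1])
        g[2] += e * d
        # old attraction weighted by the decayed experience rho * n[c]
        n1 = rho * n[c] + 1.0
        dn1 = n[c] + rho * dn[c]  # also d(rho * n[c]) / drho
        w = rho * n[c]
        num = q[c] * (1.0 - a) * w + o
        dnum_da = dq[c, 0] * (1.0 - a) * w - q[c] * w
        dnum_drho = dq[c, 1] * (1.0 - a) * w + q[c] * (1.0 - a) * dn1
        qnew = num / n1
        dq[c, 0] = dnum_da / n1
        dq[c, 1] = dnum_drho / n1 - num * dn1 / (n1 * n1)
        q[c] = qnew
        n[c] = n1
        dn[c] = dn1
    return ll, g


@njit(cache=False)
def group_loglik_grad(choices, outcomes, reset, subj_ptr, theta, model_id, mirrored):
    """Per-subject log-likelihoods and gradients wrt constrained parameters.

    ``theta`` is (n_subjects, 3): RP rows are (a_rew, a_pun, beta), EWA rows
    are (a, rho, beta).  Returns (ll[n], grad[n, 3]).
    """
    n = subj_ptr.shape[0] - 1
    ll = np.zeros(n)
    grad = np.zeros((n, 3))
    for i in range(n):
        lo = subj_ptr[i]
        hi = subj_ptr[i + 1]
        if model_id == MODEL_RP:
            l, g = rp_loglik_grad(
                choices[lo:hi], outcomes[lo:hi], reset[lo:hi],
                theta[i, 0], theta[i, 1], theta[i, 2], mirrored,
            )
        else:
            l, g = ewa_loglik_grad(
                choices[lo:hi], outcomes[lo:hi], reset[lo:hi],
                theta[i, 0], theta[i, 1], theta[i, 2],
            )
        ll[i] = l
        grad[i] = g
    return ll, grad


@njit(cache=False)
def group_pointwise_by_draw(choices, outcomes, reset, subj_ptr, thetas, model_id, mirrored):
    """Subject-level log-likelihood for many parameter draws.

    ``thetas`` is (n_draws, n_subjects, 3); returns (n_draws, n_subjects)
    with each entry the subject's summed trial log-likelihood at that draw.
    """
    n_draws = thetas.shape[0]
    n = subj_ptr.shape[0] - 1
    out = np.zeros((n_draws, n))
    scratch = np.zeros(choices.shape[0])
    for d in range(n_draws):
        for i in range(n):
            lo = subj_ptr[i]
            hi = subj_ptr[i + 1]
            buf = scratch[lo:hi]
            if model_id == MODEL_RP:
                rp_pointwise(
                    choices[lo:hi], outcomes[lo:hi], reset[lo:hi],
                    thetas[d, i, 0], thetas[d, i, 1], thetas[d, i, 2],
                    mirrored, buf,
                )
            else:
                ewa_pointwise(
                    choices[lo:hi], outcomes[lo:hi], reset[lo:hi],
                    thetas[d, i, 0], thetas[d, i, 1], thetas[d, i, 2], buf,
                )
            out[d, i] = buf.sum()
    return out


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
_LOG_HALF_CAUCHY_NORM = np.log(2.0 / (np.pi * 5.0))


@njit(cache=False)
def _ndtr(x):
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=False)
def hier_logp_grad(x, choices, outcomes, reset, subj_ptr, model_id, mirrored, beta_max):
    """Hierarchical log posterior and gradient on the non-centered vector.

    ``x = [mu (3), log_sigma (3), z (n_subjects * 3)]``; priors are
    Normal(0, 1) on mu, half-Cauchy(0, 5) on sigma (with the log-scale
    Jacobian), Normal(0, 1) on z; subject parameters are the inverse-probit
    transform of mu + sigma * z (beta additionally scaled by beta_max).
    """
    n = subj_ptr.shape[0] - 1
    mu = x[0:3]
    sigma = np.exp(x[3:6])
    logp = 0.0
    grad = np.zeros_like(x)
    for k in range(3):
        logp += -0.5 * mu[k] * mu[k]
        grad[k] = -mu[k]
        s = sigma[k]
        logp += _LOG_HALF_CAUCHY_NORM - np.log1p((s / 5.0) ** 2) + x[3 + k]
        grad[3 + k] = -2.0 * s * s / (25.0 + s * s) + 1.0
    theta = np.empty(3)
    for i in range(n):
        lo = subj_ptr[i]
        hi = subj_ptr[i + 1]
        base = 6 + 3 * i
        for k in range(3):
            z = x[base + k]
            logp += -0.5 * z * z
            grad[base + k] = -z
            raw = mu[k] + sigma[k] * z
            theta[k] = _ndtr(raw)
        theta[2] *= beta_max
        if model_id == MODEL_RP:
            ll, g = rp_loglik_grad(
                choices[lo:hi], outcomes[lo:hi], reset[lo:hi],
                theta[0], theta[1], theta[2], mirrored,
            )
        else:
            ll, g = ewa_loglik_grad(
                choices[lo:hi], outcomes[lo:hi], reset[lo:hi],
                theta[0], theta[1], theta[2],
            )
        logp += ll
        for k in range(3):
            z = x[base + k]
            raw = mu[k] + sigma[k] * z
            scale = beta_max if k == 2 else 1.0
            g_raw = g[k] * np.exp(-0.5 * raw * raw) * _INV_SQRT_2PI * scale
            grad[k] += g_raw
            grad[3 + k] += g_raw * sigma[k] * z
            grad[base + k] += g_raw * sigma[k]
    return logp, grad
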