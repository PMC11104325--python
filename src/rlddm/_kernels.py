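"""Compiled inner loops shared by simulation, likelihood and MCMC.

A single forward pass serves all nine models: structural flags select the
learning rule (none / single / dual learning rate) and whether boundary
separation and non-decision time follow power functions of the global
1-based trial index.  Parameters travel in a fixed 7-slot vector::

    0: a0      boundary separation offset
    1: a_exp   boundary power exponent (0 when fixed)
    2: t0      non-decision time offset, seconds
    3: t_exp   non-decision power exponent (0 when fixed)
    4: v       drift scaling v_coeff (or the constant drift of the no-learning
               null model)
    5: eta_p   learning rate for positive prediction errors, raw probit scale
    6: eta_m   learning rate for negative prediction errors, raw probit scale

Trial arrays use choice codes 1 = optimal, 0 = suboptimal, -1 = no response,
reward -1 on non-response trials, and a retained flag that marks trials
contributing likelihood terms (non-retained responded trials still drive
Q updates by default — the participant saw that feedback).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .wfpt import _logpdf_signed, _sample_signed_one

SQRT2 = math.sqrt(2.0)

# structural flag values
LEARN_NONE = 0
LEARN_SINGLE = 1
LEARN_DUAL = 2


@njit(cache=True)
def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / SQRT2))


@njit(cache=True)
def loglik_terms(
    theta,
    learn,
    a_pow,
    t_pow,
    pair,
    choice,
    reward,
    trial_no,
    signed_rt,
    retained,
    n_pairs,
    update_filtered,
    density_floor,
):
    """Per-trial log-likelihood aligned with the full trial sequence.

    Entries are NaN for trials without a likelihood term (excluded /
    no-response); retained trials get the signed-RT WFPT log density.
    """
    n = pair.shape[0]
    out = np.full(n, np.nan)
    q = np.full((n_pairs, 2), 0.5)
    for i in range(n):
        t = float(trial_no[i])
        p = pair[i]
        a_t = theta[0] * t ** theta[1] if a_pow == 1 else theta[0]
        tau_t = theta[2] * t ** theta[3] if t_pow == 1 else theta[2]
        if learn == LEARN_NONE:
            v = theta[4]
        else:
            v = theta[4] * (q[p, 0] - q[p, 1])
        if retained[i] == 1:
            lp = _logpdf_signed(signed_rt[i], a_t, tau_t, 0.5, v)
            if density_floor > 0.0:
                if lp == -np.inf:
                    lp = math.log(density_floor)
                else:
                    lp = math.log(math.exp(lp) + density_floor)
            out[i] = lp
        if learn != LEARN_NONE and choice[i] >= 0:
            if retained[i] == 1 or update_filtered == 1:
                col = 0 if choice[i] == 1 else 1
                delta = reward[i] - q[p, col]
                if delta > 0.0:
                    q[p, col] += _phi(theta[5]) * delta
                elif delta < 0.0:
                    if learn == LEARN_DUAL:
                        q[p, col] += _phi(theta[6]) * delta
                    else:
                        q[p, col] += _phi(theta[5]) * delta
    return out


@njit(cache=True)
def loglik_sum(
    theta,
    learn,
    a_pow,
    t_pow,
    pair,
    choice,
    reward,
    trial_no,
    signed_rt,
    retained,
    n_pairs,
    update_filtered,
    density_floor,
):
    """Summed log-likelihood over retained trials (allocation-free MCMC path)."""
    n = pair.shape[0]
    total = 0.0
    q = np.full((n_pairs, 2), 0.5)
    for i in range(n):
        t = float(trial_no[i])
        p = pair[i]
        a_t = theta[0] * t ** theta[1] if a_pow == 1 else theta[0]
        tau_t = theta[2] * t ** theta[3] if t_pow == 1 else theta[2]
        if learn == LEARN_NONE:
            v = theta[4]
        else:
            v = theta[4] * (q[p, 0] - q[p, 1])
        if retained[i] == 1:
            lp = _logpdf_signed(signed_rt[i], a_t, tau_t, 0.5, v)
            if density_floor > 0.0:
                if lp == -np.inf:
                    lp = math.log(density_floor)
                else:
                    lp = math.log(math.exp(lp) + density_floor)
            if lp == -np.inf:
                return -np.inf
            total += lp
        if learn != LEARN_NONE and choice[i] >= 0:
            if retained[i] == 1 or update_filtered == 1:
                col = 0 if choice[i] == 1 else 1
                delta = reward[i] - q[p, col]
                if delta > 0.0:
                    q[p, col] += _phi(theta[5]) * delta
                elif delta < 0.0:
                    if learn == LEARN_DUAL:
                        q[p, col] += _phi(theta[6]) * delta
                    else:
                        q[p, col] += _phi(theta[5]) * delta
    return total


@njit(cache=True)
def softmax_loglik_sum(beta, eta_p, eta_m, dual, pair, choice, reward, n_pairs):
    """Choice-only log-likelihood under softmax action selection.

    beta is the inverse temperature; learning rates are on the raw probit
    scale.  All responded trials contribute a Bernoulli term and update Q.
    """
    n = pair.shape[0]
    total = 0.0
    q = np.full((n_pairs, 2), 0.5)
    for i in range(n):
        p = pair[i]
        if choice[i] < 0:
            continue
        p_opt = 1.0 / (1.0 + math.exp(-beta * (q[p, 0] - q[p, 1])))
        pr = p_opt if choice[i] == 1 else 1.0 - p_opt
        if pr <= 1e-300:
            return -np.inf
        total += math.log(pr)
        col = 0 if choice[i] == 1 else 1
        delta = reward[i] - q[p, col]
        if delta > 0.0:
            q[p, col] += _phi(eta_p) * delta
        elif delta < 0.0:
            q[p, col] += _phi(eta_m if dual == 1 else eta_p) * delta
    return total


@njit(cache=True)
def softmax_loglik_terms(beta, eta_p, eta_m, dual, pair, choice, reward, n_pairs):
    """Per-trial choice log-likelihood under softmax; NaN on non-response trials."""
    n = pair.shape[0]
    out = np.full(n, np.nan)
    q = np.full((n_pairs, 2), 0.5)
    for i in range(n):
        p = pair[i]
        if choice[i] < 0:
            continue
        p_opt = 1.0 / (1.0 + math.exp(-beta * (q[p, 0] - q[p, 1])))
        pr = p_opt if choice[i] == 1 else 1.0 - p_opt
        out[i] = math.log(pr) if pr > 1e-300 else -np.inf
        col = 0 if choice[i] == 1 else 1
        delta = reward[i] - q[p, col]
        if delta > 0.0:
            q[p, col] += _phi(eta_p) * delta
        elif delta < 0.0:
            q[p, col] += _phi(eta_m if dual == 1 else eta_p) * delta
    return out


@njit(cache=True)
def simulate_trials(
    theta,
    learn,
    a_pow,
    t_pow,
    pair_order,
    rate_optimal,
    rate_suboptimal,
    deadline,
    n_pairs,
    seed,
):
    """Simulate one agent over a trial schedule.

    Returns (choice, rt, reward) arrays; decisions slower than the deadline
    become non-response trials (choice -1, NaN rt, reward -1) and trigger no
    Q update.
    """
    np.random.seed(seed)
    n = pair_order.shape[0]
    choice = np.full(n, -1, dtype=np.int64)
    rt = np.full(n, np.nan)
    reward = np.full(n, -1, dtype=np.int64)
    q = np.full((n_pairs, 2), 0.5)
    for i in range(n):
        t = float(i + 1)
        p = pair_order[i]
        a_t = theta[0] * t ** theta[1] if a_pow == 1 else theta[0]
        tau_t = theta[2] * t ** theta[3] if t_pow == 1 else theta[2]
        if learn == LEARN_NONE:
            v = theta[4]
        else:
            v = theta[4] * (q[p, 0] - q[p, 1])
        u1 = np.random.random()
        u2 = np.random.random()
        x = _sample_signed_one(a_t, tau_t, 0.5, v, u1, u2, deadline)
        if abs(x) > deadline:
            continue
        c = 1 if x > 0.0 else 0
        choice[i] = c
        rt[i] = abs(x)
        pr = rate_optimal if c == 1 else rate_suboptimal
        r = 1 if np.random.random() < pr else 0
        reward[i] = r
        if learn != LEARN_NONE:
            col = 0 if c == 1 else 1
            delta = r - q[p, col]
            if delta > 0.0:
                q[p, col] += _phi(theta[5]) * delta
            elif delta < 0.0:
                if learn == LEARN_DUAL:
                    q[p, col] += _phi(theta[6]) * delta
                else:
                    q[p, col] += _phi(theta[5]) * delta
    return choice, rt, reward
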