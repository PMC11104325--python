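"""Adaptive Metropolis-within-Gibbs kernel for the hierarchical model.

The hierarchy: each subject-level parameter is Normal(mu_p, sigma_p)
truncated to its admissible support; group means and SDs carry uniform
priors.  One sweep updates every active scalar subject parameter (random-walk
proposal against the subject's full likelihood plus its truncated-normal
prior term) and then each group mean and SD (against the truncated-normal
likelihood of the subject values, whose normalization constant depends on
mu and sigma and is therefore included).  Proposal scales adapt toward a
~44% acceptance rate during burn-in only, so the retained draws come from a
fixed transition kernel.

Two likelihood kinds share the kernel: the signed-RT Wiener first-passage
likelihood of the RL-DDMs (kind 0) and the choice-only softmax likelihood of
the baseline RL model (kind 1, with the inverse temperature living in the
drift slot of the 7-slot parameter vector).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._kernels import _phi, loglik_sum, softmax_loglik_sum

N_SLOTS = 7


@njit(cache=True)
def _subj_ll(
    theta_s,
    lik_kind,
    learn,
    a_pow,
    t_pow,
    pair,
    choice,
    reward,
    trial_no,
    srt,
    ret,
    n_pairs,
    update_filtered,
    density_floor,
):
    if lik_kind == 0:
        return loglik_sum(
            theta_s, learn, a_pow, t_pow, pair, choice, reward, trial_no, srt, ret,
            n_pairs, update_filtered, density_floor,
        )
    dual = 1 if learn == 2 else 0
    return softmax_loglik_sum(theta_s[4], theta_s[5], theta_s[6], dual, pair, choice, reward, n_pairs)


@njit(cache=True)
def _group_logp(theta_col, mu, sig, lo, hi):
    """Log density of subject values under TruncNormal(mu, sig, lo, hi)."""
    z = _phi((hi - mu) / sig) - _phi((lo - mu) / sig)
    if z <= 1e-300:
        return -np.inf
    total = 0.0
    n = theta_col.shape[0]
    for s in range(n):
        d = (theta_col[s] - mu) / sig
        total += -0.5 * d * d
    return total - n * (math.log(sig) + math.log(z))


@njit(cache=True)
def run_chain(
    seed,
    burn,
    keep,
    thin,
    theta0,
    mu0,
    sig0,
    active,
    tie_eta,
    learn,
    a_pow,
    t_pow,
    lik_kind,
    sub_lo,
    sub_hi,
    mu_lo,
    mu_hi,
    sig_lo,
    sig_hi,
    pair_all,
    choice_all,
    reward_all,
    trial_all,
    srt_all,
    ret_all,
    offsets,
    n_pairs,
    update_filtered,
    density_floor,
    anchor,
):
    np.random.seed(seed)
    S = theta0.shape[0]
    theta = theta0.copy()
    mu = mu0.copy()
    sig = sig0.copy()

    # current subject log-likelihoods
    cur_ll = np.empty(S)
    for s in range(S):
        a, b = offsets[s], offsets[s + 1]
        cur_ll[s] = _subj_ll(
            theta[s], lik_kind, learn, a_pow, t_pow,
            pair_all[a:b], choice_all[a:b], reward_all[a:b], trial_all[a:b],
            srt_all[a:b], ret_all[a:b], n_pairs, update_filtered, density_floor,
        )

    # proposal scales and adaptation counters
    sc_theta = np.full((S, N_SLOTS), 0.15)
    sc_mu = np.full(N_SLOTS, 0.15)
    sc_sig = np.full(N_SLOTS, 0.1)
    ac_theta = np.zeros((S, N_SLOTS))
    ac_mu = np.zeros(N_SLOTS)
    ac_sig = np.zeros(N_SLOTS)
    # joint (offset, exponent) moves for the two power-function pairs:
    # column 0 -> (slot 0, slot 1), column 1 -> (slot 2, slot 3)
    # columns: 0 -> (a0, a_exp), 1 -> (t0, t_exp), 2 -> (eta, v) ridge
    sc_joint = np.full((S, 3), 0.1)
    ac_joint = np.zeros((S, 3))
    log_anchor = math.log(anchor)
    window = 25

    # per-subject adaptive-covariance blocked proposals (all active params at
    # once, proposal covariance learned from the chain history during burn-in)
    active_idx = np.where(active == 1)[0]
    d_act = active_idx.shape[0]
    am_n = np.zeros(S)
    am_mean = np.zeros((S, d_act))
    am_m2 = np.zeros((S, d_act, d_act))
    am_L = np.zeros((S, d_act, d_act))
    for s in range(S):
        for j in range(d_act):
            am_L[s, j, j] = 0.05
    am_scale = np.full(S, 2.38 / math.sqrt(d_act))
    ac_block = np.zeros(S)

    total_iter = burn + keep * thin
    mu_draws = np.empty((keep, N_SLOTS))
    sig_draws = np.empty((keep, N_SLOTS))
    theta_draws = np.empty((keep, S, N_SLOTS))
    kept = 0

    for it in range(total_iter):
        # --- subject-level updates
        for s in range(S):
            a, b = offsets[s], offsets[s + 1]
            for p in range(N_SLOTS):
                if active[p] == 0:
                    continue
                old = theta[s, p]
                prop = old + sc_theta[s, p] * np.random.normal()
                if prop < sub_lo[p] or prop > sub_hi[p]:
                    continue
                theta[s, p] = prop
                if tie_eta == 1 and p == 5:
                    theta[s, 6] = prop
                new_ll = _subj_ll(
                    theta[s], lik_kind, learn, a_pow, t_pow,
                    pair_all[a:b], choice_all[a:b], reward_all[a:b], trial_all[a:b],
                    srt_all[a:b], ret_all[a:b], n_pairs, update_filtered, density_floor,
                )
                d_old = (old - mu[p]) / sig[p]
                d_new = (prop - mu[p]) / sig[p]
                log_acc = new_ll - cur_ll[s] - 0.5 * (d_new * d_new - d_old * d_old)
                if log_acc >= 0.0 or math.log(np.random.random()) < log_acc:
                    cur_ll[s] = new_ll
                    ac_theta[s, p] += 1.0
                else:
                    theta[s, p] = old
                    if tie_eta == 1 and p == 5:
                        theta[s, 6] = old

            # joint anchored moves along the (offset, exponent) ridge: shift
            # the exponent and rescale the offset so the trajectory value at
            # the anchor trial stays fixed; |Jacobian| = anchor**(-d)
            for j in range(2):
                off = 0 if j == 0 else 2
                exp_slot = off + 1
                if active[exp_slot] == 0:
                    continue
                old_off = theta[s, off]
                old_exp = theta[s, exp_slot]
                d = sc_joint[s, j] * np.random.normal()
                new_exp = old_exp + d
                new_off = old_off * math.exp(-d * log_anchor)
                if (new_exp < sub_lo[exp_slot] or new_exp > sub_hi[exp_slot]
                        or new_off < sub_lo[off] or new_off > sub_hi[off]):
                    continue
                theta[s, off] = new_off
                theta[s, exp_slot] = new_exp
                new_ll = _subj_ll(
                    theta[s], lik_kind, learn, a_pow, t_pow,
                    pair_all[a:b], choice_all[a:b], reward_all[a:b], trial_all[a:b],
                    srt_all[a:b], ret_all[a:b], n_pairs, update_filtered, density_floor,
                )
                dpri = 0.0
                d1o = (old_off - mu[off]) / sig[off]
                d1n = (new_off - mu[off]) / sig[off]
                d2o = (old_exp - mu[exp_slot]) / sig[exp_slot]
                d2n = (new_exp - mu[exp_slot]) / sig[exp_slot]
                dpri = -0.5 * (d1n * d1n - d1o * d1o + d2n * d2n - d2o * d2o)
                log_acc = new_ll - cur_ll[s] + dpri - d * log_anchor
                if log_acc >= 0.0 or math.log(np.random.random()) < log_acc:
                    cur_ll[s] = new_ll
                    ac_joint[s, j] += 1.0
                else:
                    theta[s, off] = old_off
                    theta[s, exp_slot] = old_exp

            # ridge move for learning models: shift the learning rate(s) and
            # rescale the drift coefficient by the inverse ratio of the
            # transformed rates (small learning rates produce small Q-value
            # differences that large drift scalings compensate, a near-flat
            # likelihood ridge); |Jacobian| = the rescaling factor
            if active[5] == 1 and active[4] == 1:
                d = sc_joint[s, 2] * np.random.normal()
                ep_old = theta[s, 5]
                em_old = theta[s, 6]
                v_old = theta[s, 4]
                ep_new = ep_old + d
                em_new = em_old + d
                mean_old = 0.5 * (ep_old + em_old)
                mean_new = 0.5 * (ep_new + em_new)
                c_ratio = _phi(mean_old) / _phi(mean_new)
                v_new = v_old * c_ratio
                ok = (sub_lo[5] <= ep_new <= sub_hi[5]
                      and sub_lo[4] <= v_new <= sub_hi[4]
                      and (active[6] == 0 or sub_lo[6] <= em_new <= sub_hi[6]))
                if ok:
                    theta[s, 5] = ep_new
                    theta[s, 6] = em_new
                    theta[s, 4] = v_new
                    new_ll = _subj_ll(
                        theta[s], lik_kind, learn, a_pow, t_pow,
                        pair_all[a:b], choice_all[a:b], reward_all[a:b], trial_all[a:b],
                        srt_all[a:b], ret_all[a:b], n_pairs, update_filtered, density_floor,
                    )
                    dpri = 0.0
                    dn = (ep_new - mu[5]) / sig[5]
                    do = (ep_old - mu[5]) / sig[5]
                    dpri += -0.5 * (dn * dn - do * do)
                    if active[6] == 1:
                        dn = (em_new - mu[6]) / sig[6]
                        do = (em_old - mu[6]) / sig[6]
                        dpri += -0.5 * (dn * dn - do * do)
                    dn = (v_new - mu[4]) / sig[4]
                    do = (v_old - mu[4]) / sig[4]
                    dpri += -0.5 * (dn * dn - do * do)
                    log_acc = new_ll - cur_ll[s] + dpri + math.log(c_ratio)
                    if log_acc >= 0.0 or math.log(np.random.random()) < log_acc:
                        cur_ll[s] = new_ll
                        ac_joint[s, 2] += 1.0
                    else:
                        theta[s, 5] = ep_old
                        theta[s, 6] = em_old
                        theta[s, 4] = v_old

            # blocked adaptive-covariance move over all active parameters
            x_old = np.empty(d_act)
            for j in range(d_act):
                x_old[j] = theta[s, active_idx[j]]
            z = np.empty(d_act)
            for j in range(d_act):
                z[j] = np.random.normal()
            x_new = x_old + am_scale[s] * (am_L[s] @ z)
            ok = True
            for j in range(d_act):
                p = active_idx[j]
                if x_new[j] < sub_lo[p] or x_new[j] > sub_hi[p]:
                    ok = False
            if ok:
                for j in range(d_act):
                    theta[s, active_idx[j]] = x_new[j]
                if tie_eta == 1 and active[5] == 1:
                    theta[s, 6] = theta[s, 5]
                new_ll = _subj_ll(
                    theta[s], lik_kind, learn, a_pow, t_pow,
                    pair_all[a:b], choice_all[a:b], reward_all[a:b], trial_all[a:b],
                    srt_all[a:b], ret_all[a:b], n_pairs, update_filtered, density_floor,
                )
                dpri = 0.0
                for j in range(d_act):
                    p = active_idx[j]
                    dn = (x_new[j] - mu[p]) / sig[p]
                    do = (x_old[j] - mu[p]) / sig[p]
                    dpri += -0.5 * (dn * dn - do * do)
                log_acc = new_ll - cur_ll[s] + dpri
                if log_acc >= 0.0 or math.log(np.random.random()) < log_acc:
                    cur_ll[s] = new_ll
                    ac_block[s] += 1.0
                else:
                    for j in range(d_act):
                        theta[s, active_idx[j]] = x_old[j]
                    if tie_eta == 1 and active[5] == 1:
                        theta[s, 6] = theta[s, 5]

            # accumulate running mean/covariance of the subject's state
            am_n[s] += 1.0
            xc = np.empty(d_act)
            for j in range(d_act):
                xc[j] = theta[s, active_idx[j]]
            delta1 = xc - am_mean[s]
            am_mean[s] += delta1 / am_n[s]
            delta2 = xc - am_mean[s]
            for j in range(d_act):
                for jj in range(d_act):
                    am_m2[s, j, jj] += delta1[j] * delta2[jj]

        # --- group-level updates
        for p in range(N_SLOTS):
            if active[p] == 0:
                continue
            col = theta[:, p].copy()
            # mean
            old_lp = _group_logp(col, mu[p], sig[p], sub_lo[p], sub_hi[p])
            prop = mu[p] + sc_mu[p] * np.random.normal()
            if mu_lo[p] <= prop <= mu_hi[p]:
                new_lp = _group_logp(col, prop, sig[p], sub_lo[p], sub_hi[p])
                log_acc = new_lp - old_lp
                if log_acc >= 0.0 or math.log(np.random.random()) < log_acc:
                    mu[p] = prop
                    old_lp = new_lp
                    ac_mu[p] += 1.0
            # SD
            prop = sig[p] + sc_sig[p] * np.random.normal()
            if sig_lo[p] <= prop <= sig_hi[p]:
                new_lp = _group_logp(col, mu[p], prop, sub_lo[p], sub_hi[p])
                log_acc = new_lp - old_lp
                if log_acc >= 0.0 or math.log(np.random.random()) < log_acc:
                    sig[p] = prop
                    ac_sig[p] += 1.0

        # --- adaptation (burn-in only)
        if it < burn and (it + 1) % window == 0:
            for s in range(S):
                for p in range(N_SLOTS):
                    if active[p] == 1:
                        rate = ac_theta[s, p] / window
                        sc_theta[s, p] *= math.exp(0.8 * (rate - 0.44))
                        sc_theta[s, p] = min(max(sc_theta[s, p], 1e-5), 50.0)
                        ac_theta[s, p] = 0.0
                for j in range(3):
                    rate = ac_joint[s, j] / window
                    sc_joint[s, j] *= math.exp(0.8 * (rate - 0.44))
                    sc_joint[s, j] = min(max(sc_joint[s, j], 1e-5), 50.0)
                    ac_joint[s, j] = 0.0
                rate = ac_block[s] / window
                am_scale[s] *= math.exp(0.8 * (rate - 0.23))
                am_scale[s] = min(max(am_scale[s], 1e-4), 20.0)
                ac_block[s] = 0.0
                if am_n[s] > 3.0 * d_act + 10.0:
                    cov = am_m2[s] / (am_n[s] - 1.0)
                    for j in range(d_act):
                        cov[j, j] += 1e-8 + 1e-6 * cov[j, j]
                    am_L[s] = np.linalg.cholesky(cov)
            for p in range(N_SLOTS):
                if active[p] == 1:
                    rate = ac_mu[p] / window
                    sc_mu[p] *= math.exp(0.8 * (rate - 0.44))
                    sc_mu[p] = min(max(sc_mu[p], 1e-5), 50.0)
                    ac_mu[p] = 0.0
                    rate = ac_sig[p] / window
                    sc_sig[p] *= math.exp(0.8 * (rate - 0.44))
                    sc_sig[p] = min(max(sc_sig[p], 1e-5), 50.0)
                    ac_sig[p] = 0.0

        # --- record
        if it >= burn and (it - burn) % thin == 0 and kept < keep:
            mu_draws[kept] = mu
            sig_draws[kept] = sig
            theta_draws[kept] = theta
            kept += 1

    return mu_draws, sig_draws, theta_draws
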