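"""Hierarchical Bayesian estimation, convergence diagnostics and model comparison.

Models are fit separately per group with group-level Gaussian distributions
for every parameter: subject values are Normal(mu, sigma) truncated to the
admissible supports, and group means/SDs carry uniform priors over
numerically plausible ranges (the default `PriorSpec`).  Sampling uses a
seeded adaptive Metropolis-within-Gibbs kernel; convergence is assessed with
the (split-chain) Gelman-Rubin R-hat, with 1 <= R-hat <= 1.01 treated as
acceptable.  Model comparison uses the estimated log pointwise predictive
density (elpd, via Pareto-smoothed importance-sampling LOO) with WAIC
reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _kernels, _mcmc
from .models import PARAM_SLOTS, SUBJECT_BOUNDS, ModelSpec, pack_subject

# ---------------------------------------------------------------------------
# priors and MCMC configuration

#: uniform prior bounds (mu_lo, mu_hi, sigma_lo, sigma_hi) for group-level
#: mean and SD of each parameter
DEFAULT_PRIOR_BOUNDS = {
    "a0": (0.01, 5.0, 0.0001, 2.0),
    "a_exp": (-3.0, 3.0, 0.0001, 2.0),
    "t0": (0.1, 2.0, 0.0001, 2.0),
    "t_exp": (-3.0, 3.0, 0.0001, 2.0),
    "v": (-100.0, 100.0, 0.0001, 10.0),
    "eta_p": (-3.0, 3.0, 0.0001, 4.0),
    "eta_m": (-3.0, 3.0, 0.0001, 4.0),
    # softmax baseline model only; not part of the RL-DDM prior table
    "beta": (0.0, 50.0, 0.0001, 10.0),
}


@dataclass
class PriorSpec:
    """Uniform prior bounds per parameter for group mean and SD."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_PRIOR_BOUNDS))

    def mu_bounds(self, name):
        b = self.bounds[name]
        return b[0], b[1]

    def sigma_bounds(self, name):
        b = self.bounds[name]
        return b[2], b[3]


@dataclass
class MCMCConfig:
    """Chain configuration; defaults follow the full estimation settings."""

    chains: int = 2
    burn: int = 50_000
    thin: int = 2
    keep: int = 10_000

    @classmethod
    def short(cls, chains: int = 2, burn: int = 2_000, keep: int = 1_000, thin: int = 2):
        """Scaled-down configuration for desk-scale runs and tests."""
        return cls(chains=chains, burn=burn, thin=thin, keep=keep)


# ---------------------------------------------------------------------------
# fit result container


@dataclass
class FitResult:
    """Posterior draws and diagnostics of one hierarchical fit.

    Draw arrays are indexed (chain, draw, ...); `param_names` orders the
    free-parameter axis, `subject_ids` the subject axis of `theta`.
    `pointwise` holds the log-likelihood of every retained trial under every
    retained draw, flattened over subjects in `subject_ids` order.
    """

    model: str
    param_names: list
    subject_ids: list
    mu: np.ndarray  # (chains, keep, P)
    sigma: np.ndarray  # (chains, keep, P)
    theta: np.ndarray  # (chains, keep, S, P)
    pointwise: np.ndarray  # (chains, keep, N)
    rhat: dict
    config: dict
    seed: int

    def mu_draws(self, name: str) -> np.ndarray:
        """Flattened group-mean draws for one parameter."""
        return self.mu[:, :, self.param_names.index(name)].ravel()

    def sigma_draws(self, name: str) -> np.ndarray:
        return self.sigma[:, :, self.param_names.index(name)].ravel()

    def subject_means(self) -> pd.DataFrame:
        """Posterior-mean subject-level parameters (the default point estimate)."""
        means = self.theta.mean(axis=(0, 1))
        return pd.DataFrame(means, columns=self.param_names).assign(participant_id=self.subject_ids)

    def subject_medians(self) -> pd.DataFrame:
        med = np.median(self.theta, axis=(0, 1))
        return pd.DataFrame(med, columns=self.param_names).assign(participant_id=self.subject_ids)

    @property
    def converged(self) -> bool:
        return all(1.0 <= r <= 1.01 for r in self.rhat.values())

    # -- persistence (CSV directory layout) --------------------------------
    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        C, K, P = self.mu.shape
        for c in range(C):
            for p, name in enumerate(self.param_names):
                rows.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(K),
                    "parameter": f"mu_{name}", "value": self.mu[c, :, p]}))
                rows.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(K),
                    "parameter": f"sigma_{name}", "value": self.sigma[c, :, p]}))
                for s, pid in enumerate(self.subject_ids):
                    rows.append(pd.DataFrame({
                        "chain": c, "iteration": np.arange(K),
                        "parameter": f"theta_{pid}_{name}", "value": self.theta[c, :, s, p]}))
        pd.concat(rows, ignore_index=True).to_csv(out / "draws.csv", index=False)
        pd.DataFrame(
            {"parameter": list(self.rhat), "rhat": list(self.rhat.values()),
             "converged": [1.0 <= r <= 1.01 for r in self.rhat.values()]}
        ).to_csv(out / "diagnostics.csv", index=False)
        np.savetxt(out / "pointwise_loglik.csv",
                   self.pointwise.reshape(-1, self.pointwise.shape[-1]), delimiter=",")
        meta = {"model": self.model, "param_names": self.param_names,
                "subject_ids": list(self.subject_ids), "config": self.config, "seed": self.seed}
        (out / "config.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# R-hat

def rhat(draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin diagnostic for one parameter.

    `draws` is (chains, iterations).  Bit-identical chains and zero-variance
    draws return exactly 1.0 (a duplicate chain carries no between-chain
    information), and the statistic is floored at 1.0.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 iterations")
    if all(np.array_equal(draws[0], draws[c]) for c in range(1, draws.shape[0])):
        return 1.0
    if np.var(draws) == 0.0:
        return 1.0
    n = draws.shape[1] // 2
    halves = np.concatenate([draws[:, :n], draws[:, n: 2 * n]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0
    B = n * halves.mean(axis=1).var(ddof=1)
    V = (n - 1) / n * W + B / n
    return max(1.0, float(np.sqrt(V / W)))


# ---------------------------------------------------------------------------
# fitting

_LIK_WFPT = 0
_LIK_SOFTMAX = 1

# slot index of every parameter name (softmax beta reuses the drift slot)
_SLOT_OF = {name: i for i, name in enumerate(PARAM_SLOTS)}
_SLOT_OF["beta"] = 4
_SOFTMAX_BOUNDS = {"beta": (0.0, 50.0), "eta_p": (-3.0, 3.0), "eta_m": (-3.0, 3.0)}


def _pack_group(data: pd.DataFrame):
    ids = list(dict.fromkeys(data["participant_id"]))
    packs, offsets = [], [0]
    for pid in ids:
        packs.append(pack_subject(data[data["participant_id"] == pid]))
        offsets.append(offsets[-1] + len(packs[-1]["pair"]))
    n_pairs = max(p["n_pairs"] for p in packs)
    cat = {k: np.concatenate([p[k] for p in packs]) for k in
           ("pair", "choice", "reward", "trial_no", "signed_rt", "retained")}
    return ids, cat, np.asarray(offsets, dtype=np.int64), n_pairs


def _initial_theta(param_names, data_by_subject, lik_kind, rng,
                   learn=0, a_pow=0, t_pow=0, n_pairs=2,
                   update_filtered=1, density_floor=0.0):
    """Data-informed starting values.

    The non-decision time starts below each subject's minimum |RT|; for the
    RL-DDMs a coarse per-subject grid search over (drift scaling, learning
    rate, threshold) places chains near the likelihood ridge — the drift
    coefficient trades off strongly with the learning rate (small Q-value
    differences are compensated by large scaling), and chains started far
    out on that ridge mix poorly within short burn-ins.
    """
    thetas = []
    for arrs in data_by_subject:
        p = {}
        srt = np.abs(arrs["signed_rt"][arrs["retained"] == 1])
        resp = arrs["choice"][arrs["choice"] >= 0]
        acc = resp.mean() if len(resp) else 0.5
        acc = min(max(acc, 0.05), 0.95)
        for name in param_names:
            if name == "a0":
                p[name] = 1.2
            elif name == "t0":
                p[name] = min(max(0.7 * float(srt.min()), 0.02), 1.9)
            elif name in ("a_exp", "t_exp"):
                p[name] = 0.0
            elif name == "v":
                p[name] = float(np.log(acc / (1 - acc)) / 1.2) if lik_kind == _LIK_WFPT else 2.0
            elif name == "beta":
                p[name] = 3.0
            else:  # learning rates
                p[name] = -0.5
        if lik_kind == _LIK_WFPT and "eta_p" in param_names:
            p.update(_grid_init(p, param_names, arrs, learn, a_pow, t_pow,
                                n_pairs, update_filtered, density_floor))
        for name in param_names:
            lo, hi = (_SOFTMAX_BOUNDS.get(name) or SUBJECT_BOUNDS[name])
            p[name] = float(np.clip(p[name] + 0.02 * rng.standard_normal(), lo + 1e-4, hi - 1e-4))
        thetas.append(p)
    return thetas


def _grid_init(p, param_names, arrs, learn, a_pow, t_pow, n_pairs,
               update_filtered, density_floor):
    """Coarse likelihood grid over (v, eta, a0) for one subject."""
    best, best_ll = {}, -np.inf
    theta7 = np.zeros(_mcmc.N_SLOTS)
    for a0 in (0.9, 1.4, 2.0):
        for v in (1.5, 3.0, 6.0):
            for eta in (-1.3, -0.7, -0.2):
                cand = dict(p, a0=a0, v=v, eta_p=eta)
                if "eta_m" in param_names:
                    cand["eta_m"] = eta
                for name in param_names:
                    theta7[_SLOT_OF[name]] = cand[name]
                if "eta_m" not in param_names:
                    theta7[6] = theta7[5]
                ll = _mcmc._subj_ll(
                    theta7, _LIK_WFPT, learn, a_pow, t_pow,
                    arrs["pair"], arrs["choice"], arrs["reward"], arrs["trial_no"],
                    arrs["signed_rt"], arrs["retained"], n_pairs,
                    update_filtered, density_floor,
                )
                if ll > best_ll:
                    best_ll = ll
                    best = {"a0": a0, "v": v, "eta_p": eta}
                    if "eta_m" in param_names:
                        best["eta_m"] = eta
    return best


def _run_fit(
    param_names,
    subject_bounds,
    learn,
    a_pow,
    t_pow,
    tie_eta,
    lik_kind,
    model_name,
    data,
    priors,
    mcmc,
    seed,
    update_filtered,
    density_floor,
):
    ids, cat, offsets, n_pairs = _pack_group(data)
    S = len(ids)
    if S < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()

    active = np.zeros(_mcmc.N_SLOTS, dtype=np.int64)
    sub_lo = np.zeros(_mcmc.N_SLOTS)
    sub_hi = np.ones(_mcmc.N_SLOTS)
    mu_lo = np.zeros(_mcmc.N_SLOTS)
    mu_hi = np.ones(_mcmc.N_SLOTS)
    sig_lo = np.full(_mcmc.N_SLOTS, 1e-4)
    sig_hi = np.ones(_mcmc.N_SLOTS)
    for name in param_names:
        slot = _SLOT_OF[name]
        active[slot] = 1
        sub_lo[slot], sub_hi[slot] = subject_bounds[name]
        mu_lo[slot], mu_hi[slot] = priors.mu_bounds(name)
        sig_lo[slot], sig_hi[slot] = priors.sigma_bounds(name)

    subj_arrays = [
        {k: cat[k][offsets[s]: offsets[s + 1]] for k in cat} for s in range(S)
    ]
    rng = np.random.default_rng(seed)

    mu_out = np.empty((mcmc.chains, mcmc.keep, len(param_names)))
    sig_out = np.empty((mcmc.chains, mcmc.keep, len(param_names)))
    theta_out = np.empty((mcmc.chains, mcmc.keep, S, len(param_names)))

    for c in range(mcmc.chains):
        init = _initial_theta(param_names, subj_arrays, lik_kind, rng,
                              learn=learn, a_pow=a_pow, t_pow=t_pow, n_pairs=n_pairs,
                              update_filtered=1 if update_filtered else 0,
                              density_floor=density_floor)
        theta0 = np.zeros((S, _mcmc.N_SLOTS))
        for s, p in enumerate(init):
            for name in param_names:
                theta0[s, _SLOT_OF[name]] = p[name]
            if tie_eta and "eta_p" in param_names:
                theta0[s, 6] = theta0[s, 5]
        # bounded retries: shrink t0 until every subject's log-likelihood is finite
        for attempt in range(12):
            ok = True
            for s in range(S):
                ll = _mcmc._subj_ll(
                    theta0[s], lik_kind, learn, a_pow, t_pow,
                    subj_arrays[s]["pair"], subj_arrays[s]["choice"], subj_arrays[s]["reward"],
                    subj_arrays[s]["trial_no"], subj_arrays[s]["signed_rt"], subj_arrays[s]["retained"],
                    n_pairs, 1 if update_filtered else 0, density_floor,
                )
                if not np.isfinite(ll):
                    ok = False
                    if active[2]:
                        theta0[s, 2] = max(0.5 * theta0[s, 2], SUBJECT_BOUNDS["t0"][0] + 1e-4)
            if ok:
                break
        else:
            raise RuntimeError("non-finite log-posterior at initialization after bounded retries")

        mu0 = np.zeros(_mcmc.N_SLOTS)
        sig0 = np.full(_mcmc.N_SLOTS, 0.3)
        for name in param_names:
            slot = _SLOT_OF[name]
            mu0[slot] = float(np.clip(theta0[:, slot].mean(), mu_lo[slot] + 1e-6, mu_hi[slot] - 1e-6))
            spread = max(theta0[:, slot].std(), 0.2)
            sig0[slot] = float(np.clip(spread, sig_lo[slot] + 1e-5, sig_hi[slot] - 1e-5))

        chain_seed = int(rng.integers(0, 2**31 - 1))
        mu_d, sig_d, theta_d = _mcmc.run_chain(
            chain_seed, mcmc.burn, mcmc.keep, mcmc.thin,
            theta0, mu0, sig0, active, 1 if tie_eta else 0,
            learn, a_pow, t_pow, lik_kind,
            sub_lo, sub_hi, mu_lo, mu_hi, sig_lo, sig_hi,
            cat["pair"], cat["choice"], cat["reward"], cat["trial_no"],
            cat["signed_rt"], cat["retained"], offsets, n_pairs,
            1 if update_filtered else 0, density_floor,
            float(np.exp(np.mean(np.log(cat["trial_no"])))),
        )
        slots = [_SLOT_OF[n] for n in param_names]
        mu_out[c] = mu_d[:, slots]
        sig_out[c] = sig_d[:, slots]
        theta_out[c] = theta_d[:, :, slots]

    # pointwise log-likelihood of retained (wfpt) / responded (softmax) trials
    pointwise = _pointwise_matrix(
        param_names, learn, a_pow, t_pow, tie_eta, lik_kind,
        subj_arrays, n_pairs, update_filtered, density_floor, theta_out,
    )

    diag = {}
    for p, name in enumerate(param_names):
        diag[f"mu_{name}"] = rhat(mu_out[:, :, p])
        diag[f"sigma_{name}"] = rhat(sig_out[:, :, p])
        for s, pid in enumerate(ids):
            diag[f"theta_{pid}_{name}"] = rhat(theta_out[:, :, s, p])

    return FitResult(
        model=model_name,
        param_names=list(param_names),
        subject_ids=ids,
        mu=mu_out,
        sigma=sig_out,
        theta=theta_out,
        pointwise=pointwise,
        rhat=diag,
        config={"chains": mcmc.chains, "burn": mcmc.burn, "thin": mcmc.thin, "keep": mcmc.keep,
                "update_filtered": update_filtered, "density_floor": density_floor},
        seed=int(seed),
    )


def _pointwise_matrix(param_names, learn, a_pow, t_pow, tie_eta, lik_kind,
                      subj_arrays, n_pairs, update_filtered, density_floor, theta_out):
    C, K, S, P = theta_out.shape
    slots = [_SLOT_OF[n] for n in param_names]
    masks = [
        (a["retained"] == 1) if lik_kind == _LIK_WFPT else (a["choice"] >= 0)
        for a in subj_arrays
    ]
    n_obs = int(sum(m.sum() for m in masks))
    out = np.empty((C, K, n_obs))
    theta7 = np.zeros(_mcmc.N_SLOTS)
    for c in range(C):
        for k in range(K):
            col = 0
            for s, arrs in enumerate(subj_arrays):
                theta7[:] = 0.0
                for name, slot in zip(param_names, slots):
                    theta7[slot] = theta_out[c, k, s, param_names.index(name)]
                if tie_eta and "eta_p" in param_names:
                    theta7[6] = theta7[5]
                if lik_kind == _LIK_WFPT:
                    terms = _kernels.loglik_terms(
                        theta7, learn, a_pow, t_pow,
                        arrs["pair"], arrs["choice"], arrs["reward"], arrs["trial_no"],
                        arrs["signed_rt"], arrs["retained"], n_pairs,
                        1 if update_filtered else 0, density_floor,
                    )
                else:
                    terms = _kernels.softmax_loglik_terms(
                        theta7[4], theta7[5], theta7[6], 1 if learn == 2 else 0,
                        arrs["pair"], arrs["choice"], arrs["reward"], n_pairs,
                    )
                vals = terms[masks[s]]
                out[c, k, col: col + len(vals)] = vals
                col += len(vals)
    return out


def fit_hierarchical(
    spec: ModelSpec,
    data: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    update_filtered: bool = True,
    density_floor: float = 0.0,
) -> FitResult:
    """Fit one RL-DDM to the preprocessed trials of one group.

    `data` must come out of :func:`rlddm.models.preprocess_rts`; groups are
    never pooled — call once per group.  Deterministic for a fixed seed and
    configuration.
    """
    return _run_fit(
        spec.free_params, SUBJECT_BOUNDS, spec.learn_code, spec.a_pow, spec.t_pow,
        spec.learning == "single", _LIK_WFPT, spec.name,
        data, priors, mcmc, seed, update_filtered, density_floor,
    )


def fit_softmax(
    data: pd.DataFrame,
    dual: bool = False,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the baseline softmax RL model (choices only) to one group."""
    names = ["beta", "eta_p"] + (["eta_m"] if dual else [])
    learn = _kernels.LEARN_DUAL if dual else _kernels.LEARN_SINGLE
    return _run_fit(
        names, _SOFTMAX_BOUNDS, learn, 0, 0, not dual, _LIK_SOFTMAX,
        "softmaxRL2" if dual else "softmaxRL1",
        data, priors, mcmc, seed, True, 0.0,
    )


# ---------------------------------------------------------------------------
# predictive density estimates


@dataclass
class ELPDResult:
    """PSIS-LOO and WAIC summaries computed from one pointwise log-lik matrix."""

    elpd_loo: float
    elpd_i: np.ndarray
    p_loo: float
    pareto_k: np.ndarray
    lppd: float
    lppd_i: np.ndarray
    elpd_waic: float
    waic_i: np.ndarray
    p_waic: float
    n_obs: int
    n_draws: int

    @property
    def waic(self) -> float:
        """WAIC on the deviance scale (-2 * elpd_waic)."""
        return -2.0 * self.elpd_waic


def compute_elpd(fit_or_matrix) -> ELPDResult:
    """elpd via PSIS-LOO plus WAIC from a pointwise log-likelihood matrix.

    Accepts a FitResult or an array shaped (draws, n_obs) or
    (chains, draws, n_obs).  With a single draw both penalties are zero and
    elpd equals the log pointwise density of that draw.
    """
    ll = fit_or_matrix.pointwise if isinstance(fit_or_matrix, FitResult) else np.asarray(fit_or_matrix, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2 or ll.size == 0:
        raise ValueError("need a non-empty (draws, n_obs) log-likelihood matrix")
    M, N = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(M)
    if M == 1:
        p_waic_i = np.zeros(N)
        elpd_i = lppd_i.copy()
        k = np.zeros(N)
    else:
        p_waic_i = ll.var(axis=0, ddof=1)
        import arviz as az

        lw, k = az.psislw(-ll.T)  # (N, M) smoothed log-weights
        elpd_i = logsumexp(ll.T + lw, axis=1)
        k = np.asarray(k, dtype=float)
    waic_i = lppd_i - p_waic_i
    return ELPDResult(
        elpd_loo=float(elpd_i.sum()),
        elpd_i=elpd_i,
        p_loo=float((lppd_i - elpd_i).sum()),
        pareto_k=np.asarray(k, dtype=float),
        lppd=float(lppd_i.sum()),
        lppd_i=lppd_i,
        elpd_waic=float(waic_i.sum()),
        waic_i=waic_i,
        p_waic=float(p_waic_i.sum()),
        n_obs=N,
        n_draws=M,
    )


def compare_models(fits: list) -> pd.DataFrame:
    """Model-comparison table ranked by -elpd (lower is better).

    The difference columns report each model's -elpd minus the best model's,
    with a 95% CI from the standard error of the pointwise elpd differences;
    the best model's CI is omitted (the difference is identically zero).
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.pointwise.shape[-1] for f in fits}
    if len(n_obs) != 1:
        raise ValueError("fits were computed on different trial sets")
    n = n_obs.pop()
    results = {f.model: compute_elpd(f) for f in fits}
    neg_elpd = {m: -r.elpd_loo for m, r in results.items()}
    best = min(neg_elpd, key=neg_elpd.get)
    rows = []
    for m, r in results.items():
        d_i = results[best].elpd_i - r.elpd_i
        diff = float(d_i.sum())
        if m == best:
            lo = hi = np.nan
            diff = 0.0
        else:
            se = float(np.sqrt(n * d_i.var(ddof=1)))
            lo, hi = diff - 1.96 * se, diff + 1.96 * se
        eta_lab = {"none": "-", "single": "1", "dual": "2"}.get(_learning_of(m), "?")
        rows.append({
            "model": m,
            "eta": eta_lab,
            "tau": _flag_of(m, "ndt"),
            "alpha": _flag_of(m, "threshold"),
            "neg_elpd": -r.elpd_loo,
            "neg_elpd_diff": diff,
            "ci_low": lo,
            "ci_high": hi,
            "waic": r.waic,
        })
    table = pd.DataFrame(rows).sort_values("neg_elpd", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _learning_of(name):
    from .models import get_model

    try:
        return get_model(name).learning
    except KeyError:
        return "?"


def _flag_of(name, which):
    from .models import get_model

    try:
        spec = get_model(name)
    except KeyError:
        return "-"
    return getattr(spec, which).capitalize()
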