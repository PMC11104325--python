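"""Posterior predictive checks, posterior group-difference summaries, and
model-agnostic behavioral measures.

Posterior predictive checks simulate full datasets from posterior draws on
each participant's observed trial schedule, then compare binned mean
accuracies and response times (bins of ten trials at the group level, five
equal bins per participant at the individual level) between observed and
simulated data, with 2.5/97.5 percentile bands taken across simulated
datasets' bin means.

Group differences are summarized draw-wise on the group-level means
(control minus gambling): posterior mean difference, 95% and 85% highest
density intervals, the posterior probability that the difference exceeds
zero, and a directed Bayes factor defined as the posterior mass ratio
P(diff > 0) / P(diff < 0) (the opposite direction is available via an
argument).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import _kernels
from .inference import FitResult
from .models import ModelSpec

__all__ = [
    "hdi",
    "posterior_predictive_bins",
    "individual_predictive_bins",
    "group_difference_summary",
    "model_agnostic_summary",
    "PPCSummary",
]


def hdi(samples, mass: float = 0.95):
    """Shortest contiguous interval containing `mass` of the samples.

    For flat densities the location of the interval is unstable by nature
    (many near-shortest windows); only its width is well determined.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class PPCSummary:
    """Binned observed vs. model-predicted accuracies and response times."""

    table: pd.DataFrame
    bin_width: int
    n_draws: int
    level: str  # 'group' or 'individual'


def _theta7_for(fit: FitResult, spec: ModelSpec, c: int, k: int, s: int) -> np.ndarray:
    from .inference import _SLOT_OF

    theta7 = np.zeros(7)
    for j, name in enumerate(fit.param_names):
        theta7[_SLOT_OF[name]] = fit.theta[c, k, s, j]
    if spec.learning == "single":
        theta7[6] = theta7[5]
    return theta7


def _subject_schedules(data: pd.DataFrame):
    scheds = {}
    for pid, sub in data.groupby("participant_id", sort=False):
        sub = sub.sort_values("trial")
        pairs = np.sort(sub["pair"].unique())
        pair_index = {p: i for i, p in enumerate(pairs)}
        scheds[pid] = (sub["pair"].map(pair_index).to_numpy(np.int64), len(pairs))
    return scheds


def _binned(trial_no, is_resp, is_opt, rts, edges):
    acc = np.full(len(edges) - 1, np.nan)
    rt = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        m = (trial_no > edges[b]) & (trial_no <= edges[b + 1]) & is_resp
        if m.any():
            acc[b] = is_opt[m].mean()
            rt[b] = rts[m].mean()
    return acc, rt


def posterior_predictive_bins(
    fit: FitResult,
    spec: ModelSpec,
    data: pd.DataFrame,
    bin_width: int = 10,
    n_draws: int = 1000,
    seed: int = 0,
    rate_optimal: float = 0.80,
    rate_suboptimal: float = 0.20,
    deadline: float = 3.0,
) -> PPCSummary:
    """Group-level posterior predictive check on trial bins.

    Each selected posterior draw simulates every participant on their
    observed pair order; bin means pool trials over participants, as in the
    observed data.  Bands are 2.5/97.5 percentiles across simulated
    datasets' bin means.
    """
    n_trials = int(data["trial"].max())
    if bin_width > n_trials:
        raise ValueError("bin width exceeds trial count")
    C, K = fit.theta.shape[:2]
    if n_draws > C * K:
        raise ValueError(f"n_draws={n_draws} exceeds available posterior draws ({C * K})")
    rng = np.random.default_rng(seed)
    picks = rng.choice(C * K, size=n_draws, replace=False)
    scheds = _subject_schedules(data)
    ids = [pid for pid in fit.subject_ids if pid in scheds]
    edges = np.arange(0, n_trials + 1, bin_width)

    obs = data.sort_values(["participant_id", "trial"])
    obs_resp = obs["choice"].isin(["optimal", "suboptimal"]).to_numpy()
    obs_acc, obs_rt = _binned(
        obs["trial"].to_numpy(), obs_resp, (obs["choice"] == "optimal").to_numpy(),
        obs["rt"].to_numpy(), edges,
    )

    nb = len(edges) - 1
    sim_acc = np.empty((n_draws, nb))
    sim_rt = np.empty((n_draws, nb))
    for d, flat in enumerate(picks):
        c, k = divmod(int(flat), K)
        tr_all, resp_all, opt_all, rt_all = [], [], [], []
        for s, pid in enumerate(ids):
            pair_order, n_pairs = scheds[pid]
            theta7 = _theta7_for(fit, spec, c, k, s)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            choice, rt, reward = _kernels.simulate_trials(
                theta7, spec.learn_code, spec.a_pow, spec.t_pow, pair_order,
                rate_optimal, rate_suboptimal, deadline, n_pairs, sub_seed,
            )
            tr_all.append(np.arange(1, len(pair_order) + 1))
            resp_all.append(choice >= 0)
            opt_all.append(choice == 1)
            rt_all.append(rt)
        acc, rt_b = _binned(
            np.concatenate(tr_all), np.concatenate(resp_all),
            np.concatenate(opt_all), np.concatenate(rt_all), edges,
        )
        sim_acc[d] = acc
        sim_rt[d] = rt_b

    table = pd.DataFrame({
        "bin": np.arange(1, nb + 1),
        "trial_lo": edges[:-1] + 1,
        "trial_hi": edges[1:],
        "obs_acc": obs_acc,
        "pred_acc_mean": np.nanmean(sim_acc, axis=0),
        "pred_acc_lo": np.nanpercentile(sim_acc, 2.5, axis=0),
        "pred_acc_hi": np.nanpercentile(sim_acc, 97.5, axis=0),
        "obs_rt": obs_rt,
        "pred_rt_mean": np.nanmean(sim_rt, axis=0),
        "pred_rt_lo": np.nanpercentile(sim_rt, 2.5, axis=0),
        "pred_rt_hi": np.nanpercentile(sim_rt, 97.5, axis=0),
    })
    return PPCSummary(table=table, bin_width=bin_width, n_draws=n_draws, level="group")


def individual_predictive_bins(
    fit: FitResult,
    spec: ModelSpec,
    data: pd.DataFrame,
    n_bins: int = 5,
    n_draws: int = 200,
    seed: int = 0,
    **schedule_kwargs,
) -> PPCSummary:
    """Per-participant predictive check on `n_bins` equal trial bins."""
    n_trials = int(data["trial"].max())
    bin_width = n_trials // n_bins
    frames = []
    for pid in fit.subject_ids:
        sub = data[data["participant_id"] == pid]
        sub_fit = _single_subject_view(fit, pid)
        summary = posterior_predictive_bins(
            sub_fit, spec, sub, bin_width=bin_width, n_draws=n_draws, seed=seed, **schedule_kwargs,
        )
        frames.append(summary.table.assign(participant_id=pid))
    return PPCSummary(pd.concat(frames, ignore_index=True), bin_width, n_draws, "individual")


def _single_subject_view(fit: FitResult, pid: str) -> FitResult:
    s = fit.subject_ids.index(pid)
    return FitResult(
        model=fit.model, param_names=fit.param_names, subject_ids=[pid],
        mu=fit.mu, sigma=fit.sigma, theta=fit.theta[:, :, s: s + 1, :],
        pointwise=fit.pointwise, rhat=fit.rhat, config=fit.config, seed=fit.seed,
    )


# ---------------------------------------------------------------------------
# posterior group differences


def _mass_ratio(x, direction: str) -> float:
    gt = np.mean(x > 0)
    lt = np.mean(x < 0)
    num, den = (gt, lt) if direction == "greater" else (lt, gt)
    if den == 0:
        return np.inf if num > 0 else np.nan
    return float(num / den)


def group_difference_summary(
    fit_control: FitResult,
    fit_gambling: FitResult,
    direction: str = "greater",
) -> pd.DataFrame:
    """Posterior group-difference table (control minus gambling) per parameter.

    Columns: posterior mean difference, 95% and 85% HDIs, P(diff > 0) in
    percent, the directed Bayes factor (mass ratio, default direction
    'greater': P(>0)/P(<0)), and within-group effect summaries vs. zero for
    each group.
    """
    if fit_control.model != fit_gambling.model or fit_control.param_names != fit_gambling.param_names:
        raise ValueError("fits use different model specifications")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    rows = []
    for name in fit_control.param_names:
        dc = fit_control.mu_draws(name)
        dg = fit_gambling.mu_draws(name)
        n = min(len(dc), len(dg))
        diff = dc[:n] - dg[:n]
        h95 = hdi(diff, 0.95)
        h85 = hdi(diff, 0.85)
        rows.append({
            "parameter": name,
            "m_diff": float(diff.mean()),
            "hdi95_lo": h95[0], "hdi95_hi": h95[1],
            "hdi85_lo": h85[0], "hdi85_hi": h85[1],
            "p_diff_gt0": 100.0 * float(np.mean(diff > 0)),
            "dbf": _mass_ratio(diff, direction),
            "p_effect_control": 100.0 * float(max(np.mean(dc > 0), np.mean(dc < 0))),
            "dbf_control": _mass_ratio(dc, direction),
            "p_effect_gambling": 100.0 * float(max(np.mean(dg > 0), np.mean(dg < 0))),
            "dbf_gambling": _mass_ratio(dg, direction),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-agnostic measures


def model_agnostic_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracy, median RT and total reward.

    Accuracy counts optimal choices among responded trials; the RT median is
    over responded trials; total reward counts rewarded trials.
    """
    rows = []
    for (pid, grp), sub in dataset.groupby(["participant_id", "group"], sort=False):
        resp = sub[sub["choice"].isin(["optimal", "suboptimal"])]
        if len(resp) == 0:
            raise ValueError(f"participant {pid!r} has no responded trials")
        rows.append({
            "participant_id": pid,
            "group": grp,
            "accuracy": float((resp["choice"] == "optimal").mean()),
            "median_rt": float(resp["rt"].median()),
            "total_reward": int((sub["reward"] == 1).sum()),
        })
    return pd.DataFrame(rows)


def plot_ppc(summary: PPCSummary, path, title: str = "") -> None:
    """Save a two-panel figure of binned observed vs. predicted RT/accuracy.

    Solid lines are predicted means, dashed lines the 2.5/97.5 percentile
    bands, black lines the observed bin means.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = summary.table
    fig, axes = plt.subplots(2, 1, figsize=(5, 6), sharex=True)
    for ax, kind, label in ((axes[0], "rt", "mean RT (s)"), (axes[1], "acc", "accuracy")):
        ax.plot(t["bin"], t[f"obs_{kind}"], "k-o", label="observed")
        ax.plot(t["bin"], t[f"pred_{kind}_mean"], "-", color="tab:blue", label="predicted")
        ax.plot(t["bin"], t[f"pred_{kind}_lo"], "--", color="tab:blue")
        ax.plot(t["bin"], t[f"pred_{kind}_hi"], "--", color="tab:blue")
        ax.set_ylabel(label)
    axes[1].set_xlabel(f"trial bin (width {summary.bin_width})")
    axes[0].legend(frameon=False)
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_posterior_panels(fit_control: FitResult, fit_gambling: FitResult, path) -> None:
    """Save per-parameter panels: group-mean posteriors and their difference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = fit_control.param_names
    fig, axes = plt.subplots(2, len(names), figsize=(2.6 * len(names), 5), squeeze=False)
    for j, name in enumerate(names):
        dc = fit_control.mu_draws(name)
        dg = fit_gambling.mu_draws(name)
        n = min(len(dc), len(dg))
        axes[0, j].hist(dc, bins=40, density=True, alpha=0.6, color="tab:blue")
        axes[0, j].hist(dg, bins=40, density=True, alpha=0.6, color="tab:red")
        axes[0, j].set_title(name)
        diff = dc[:n] - dg[:n]
        axes[1, j].hist(diff, bins=40, density=True, color="tab:gray")
        for mass, lw in ((0.95, 1.0), (0.85, 2.5)):
            lo, hi = hdi(diff, mass)
            axes[1, j].plot([lo, hi], [0, 0], "k-", linewidth=lw)
        axes[1, j].axvline(0.0, color="k", linestyle=":", linewidth=0.8)
    axes[0, 0].set_ylabel("group means")
    axes[1, 0].set_ylabel("difference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rank_sum(summary: pd.DataFrame, measure: str, groups=("control", "gambling")):
    """Ordinary two-sided rank-sum test on a model-agnostic measure.

    For orientation only — a plain frequentist statistic, not the Bayesian
    rank-sum analysis of the original behavioral workflow.
    """
    a = summary.loc[summary["group"] == groups[0], measure]
    b = summary.loc[summary["group"] == groups[1], measure]
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
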