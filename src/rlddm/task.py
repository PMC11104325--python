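"""Generative model of the probabilistic selection task and RL-DDM agents.

The task: 60 trials of a stationary two-pair reinforcement learning task
(30 trials per pair, randomized pair order).  Within each pair one stimulus
is reinforced on 80% of choices, the other on 20%, feedback is binary
(reward / no reward), and responses must arrive within a 3-second deadline.

Agents combine delta-rule Q-learning with a drift-diffusion decision stage:
on each trial the drift is ``v_coeff`` times the current Q-value difference
of the presented pair, boundary separation and non-decision time optionally
follow power functions of the trial index, and the sampled decision time
plus non-decision time must beat the deadline or the trial is recorded as a
non-response (with no feedback-driven value update).

Two-group presets encode the qualitative group differences this package is
built to study: relative to controls, the gambling preset has a lower
non-decision-time offset, a more negative threshold decay exponent and a
weaker value modulation of the drift rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .models import SUBJECT_BOUNDS, ModelSpec, params_to_theta


@dataclass(frozen=True)
class TaskSchedule:
    """Trial structure of one run of the task."""

    n_trials: int = 60
    n_pairs: int = 2
    rate_optimal: float = 0.80
    rate_suboptimal: float = 0.20
    deadline: float = 3.0
    trial_order: tuple = ()

    def __post_init__(self):
        if len(self.trial_order) != self.n_trials:
            raise ValueError("trial_order must have n_trials entries")
        counts = np.bincount(np.asarray(self.trial_order), minlength=self.n_pairs)
        if not np.all(counts == self.n_trials // self.n_pairs):
            raise ValueError("each pair must appear equally often")
        for r in (self.rate_optimal, self.rate_suboptimal):
            if not 0.0 < r < 1.0:
                raise ValueError("reinforcement rates must lie in (0, 1)")


def generate_task_schedule(
    n_trials: int = 60,
    n_pairs: int = 2,
    rate_optimal: float = 0.80,
    rate_suboptimal: float = 0.20,
    deadline: float = 3.0,
    seed: int | None = None,
) -> TaskSchedule:
    """Random pair order with exactly equal per-pair counts; seeded."""
    if n_trials % n_pairs != 0:
        raise ValueError(f"n_trials={n_trials} not divisible by n_pairs={n_pairs}")
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(n_pairs), n_trials // n_pairs)
    rng.shuffle(order)
    return TaskSchedule(
        n_trials=n_trials,
        n_pairs=n_pairs,
        rate_optimal=rate_optimal,
        rate_suboptimal=rate_suboptimal,
        deadline=deadline,
        trial_order=tuple(int(p) for p in order),
    )


@dataclass
class GroupParams:
    """Group-level mean and SD per free parameter of a model."""

    mu: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.mu) != set(self.sigma):
            raise ValueError("mu and sigma must cover the same parameters")
        for p, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma[{p}] must be positive")


# Invented presets, chosen once to mirror the directionality of the reported
# group effects (gambling: lower t0, more negative a_exp, lower v_coeff) at
# realistic accuracy/RT levels; all values inside the prior supports.
_PRESETS = {
    "control": GroupParams(
        mu={"a0": 1.40, "a_exp": -0.08, "t0": 0.50, "t_exp": -0.10, "v": 4.5, "eta_p": -0.9, "eta_m": -1.2},
        sigma={"a0": 0.25, "a_exp": 0.05, "t0": 0.07, "t_exp": 0.05, "v": 1.0, "eta_p": 0.5, "eta_m": 0.5},
    ),
    "gambling": GroupParams(
        mu={"a0": 1.55, "a_exp": -0.16, "t0": 0.37, "t_exp": -0.10, "v": 2.7, "eta_p": -1.0, "eta_m": -1.4},
        sigma={"a0": 0.25, "a_exp": 0.05, "t0": 0.07, "t_exp": 0.05, "v": 1.0, "eta_p": 0.5, "eta_m": 0.5},
    ),
}


def group_presets(label: str) -> GroupParams:
    """Generating group-level parameters for the 'control' or 'gambling' group."""
    if label not in _PRESETS:
        raise KeyError(f"unknown group label {label!r}; expected 'control' or 'gambling'")
    preset = _PRESETS[label]
    return GroupParams(mu=dict(preset.mu), sigma=dict(preset.sigma))


def restrict_group_params(params: GroupParams, spec: ModelSpec) -> GroupParams:
    """Project a full-parameter preset onto the free parameters of a model."""
    names = spec.free_params
    mu = {p: params.mu[p] for p in names if p in params.mu}
    sigma = {p: params.sigma[p] for p in names if p in params.sigma}
    missing = [p for p in names if p not in mu]
    if missing:
        raise ValueError(f"preset lacks parameters required by {spec.name}: {missing}")
    return GroupParams(mu=mu, sigma=sigma)


def draw_subject_params(group_params: GroupParams, spec: ModelSpec, rng) -> dict:
    """One subject's parameters from truncated group-level Gaussians."""
    params = {}
    for name in spec.free_params:
        mu = group_params.mu[name]
        sd = group_params.sigma[name]
        lo, hi = SUBJECT_BOUNDS[name]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        params[name] = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
    return params


def simulate_subject(
    subject_params: dict,
    spec: ModelSpec,
    schedule: TaskSchedule,
    seed: int,
    participant_id: str = "s01",
    group: str = "control",
) -> pd.DataFrame:
    """Simulate one participant; returns long-format trial records."""
    theta = params_to_theta(spec, subject_params)  # validates admissibility
    pair_order = np.asarray(schedule.trial_order, dtype=np.int64)
    choice, rt, reward = _kernels.simulate_trials(
        theta,
        spec.learn_code,
        spec.a_pow,
        spec.t_pow,
        pair_order,
        schedule.rate_optimal,
        schedule.rate_suboptimal,
        schedule.deadline,
        schedule.n_pairs,
        int(seed) % (2**31 - 1),
    )
    choice_lab = np.array(["suboptimal", "optimal"])
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "group": group,
            "trial": np.arange(1, schedule.n_trials + 1),
            "pair": pair_order,
            "choice": np.where(choice < 0, "none", choice_lab[np.clip(choice, 0, 1)]),
            "rt": rt,
            "reward": np.where(reward < 0, np.nan, reward.astype(float)),
        }
    )


def simulate_group(
    group_params: GroupParams,
    n_subjects: int,
    spec: ModelSpec,
    schedule: TaskSchedule,
    seed: int,
    group: str = "control",
    id_prefix: str | None = None,
):
    """Simulate a group; returns (dataset, generating subject parameters).

    Subject-level parameters are drawn from Gaussians truncated to the
    admissible supports; the generating values are returned alongside the
    data so recovery studies can compare against them.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else group[:4]
    datasets, truths = [], []
    for s in range(n_subjects):
        pid = f"{prefix}{s + 1:02d}"
        params = draw_subject_params(group_params, spec, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        datasets.append(simulate_subject(params, spec, schedule, sub_seed, participant_id=pid, group=group))
        truths.append({"participant_id": pid, **params})
    return pd.concat(datasets, ignore_index=True), pd.DataFrame(truths)
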