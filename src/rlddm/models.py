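"""The nine-model space, RT preprocessing and per-trial log-likelihoods.

The model space crosses three structural choices on top of a common
drift-diffusion decision rule whose trial-wise drift is linear in the
Q-value difference (``v_t = v_coeff * (Q_opt - Q_sub)``):

====== ========= ========== ===========
name   learning  ndt (tau)  threshold (alpha)
====== ========= ========== ===========
DDM0   none      fixed      fixed
RLDDM1 single    fixed      fixed
RLDDM2 single    fixed      power
RLDDM3 single    power      fixed
RLDDM4 single    power      power
RLDDM5 dual      fixed      fixed
RLDDM6 dual      fixed      power
RLDDM7 dual      power      fixed
RLDDM8 dual      power      power
====== ========= ========== ===========

The null model DDM0 replaces the value-linked drift with a free constant
drift ``v``.  "Power" means the parameter follows ``x_t = x0 * t**x_exp``
over the global 1-based trial index, capturing time-on-task effects that
accrue over the whole experiment (excluded trials advance the clock but
contribute no likelihood term).

Preprocessing mirrors the estimation pipeline: suboptimal-choice RTs are
sign-flipped, no-response trials are excluded, and per participant the
fastest ``floor(0.05 * n_responded)`` responded trials are dropped to protect
the non-decision time from leading-edge outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels

#: admissible subject-level parameter supports (truncation bounds)
SUBJECT_BOUNDS = {
    "a0": (0.01, 5.0),
    "a_exp": (-3.0, 3.0),
    "t0": (0.01, 2.0),
    "t_exp": (-3.0, 3.0),
    "v": (-100.0, 100.0),
    "eta_p": (-3.0, 3.0),
    "eta_m": (-3.0, 3.0),
}

#: canonical 7-slot parameter order used by the compiled kernels
PARAM_SLOTS = ["a0", "a_exp", "t0", "t_exp", "v", "eta_p", "eta_m"]

_LEARN_CODE = {"none": _kernels.LEARN_NONE, "single": _kernels.LEARN_SINGLE, "dual": _kernels.LEARN_DUAL}


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one model from the space."""

    name: str
    learning: str  # none | single | dual
    ndt: str  # fixed | power
    threshold: str  # fixed | power

    def __post_init__(self):
        if self.learning not in ("none", "single", "dual"):
            raise ValueError(f"unknown learning mode {self.learning!r}")
        if self.ndt not in ("fixed", "power") or self.threshold not in ("fixed", "power"):
            raise ValueError("ndt/threshold must be 'fixed' or 'power'")

    @property
    def learn_code(self) -> int:
        return _LEARN_CODE[self.learning]

    @property
    def a_pow(self) -> int:
        return 1 if self.threshold == "power" else 0

    @property
    def t_pow(self) -> int:
        return 1 if self.ndt == "power" else 0

    @property
    def free_params(self) -> list[str]:
        """Names of the free subject-level parameters under this spec."""
        names = ["a0"]
        if self.threshold == "power":
            names.append("a_exp")
        names.append("t0")
        if self.ndt == "power":
            names.append("t_exp")
        names.append("v")
        if self.learning in ("single", "dual"):
            names.append("eta_p")
        if self.learning == "dual":
            names.append("eta_m")
        return names


def enumerate_model_space() -> list[ModelSpec]:
    """The nine candidate models: the no-learning null plus RLDDM1-8."""
    space = [ModelSpec("DDM0", "none", "fixed", "fixed")]
    i = 1
    for learning in ("single", "dual"):
        for ndt, threshold in (("fixed", "fixed"), ("fixed", "power"), ("power", "fixed"), ("power", "power")):
            space.append(ModelSpec(f"RLDDM{i}", learning, ndt, threshold))
            i += 1
    return space


def get_model(name: str) -> ModelSpec:
    for spec in enumerate_model_space():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown model {name!r}")


def params_to_theta(spec: ModelSpec, params: dict) -> np.ndarray:
    """Expand a free-parameter dict to the 7-slot kernel vector, validating supports."""
    missing = [p for p in spec.free_params if p not in params]
    if missing:
        raise ValueError(f"missing parameters for {spec.name}: {missing}")
    theta = np.zeros(7)
    theta[0] = params["a0"]
    theta[1] = params.get("a_exp", 0.0) if spec.threshold == "power" else 0.0
    theta[2] = params["t0"]
    theta[3] = params.get("t_exp", 0.0) if spec.ndt == "power" else 0.0
    theta[4] = params["v"]
    if spec.learning in ("single", "dual"):
        theta[5] = params["eta_p"]
        theta[6] = params["eta_m"] if spec.learning == "dual" else params["eta_p"]
    for name, slot in zip(["a0", "a_exp", "t0", "t_exp", "v", "eta_p", "eta_m"], range(7)):
        if name in spec.free_params:
            lo, hi = SUBJECT_BOUNDS[name]
            if not (lo <= theta[slot] <= hi):
                raise ValueError(f"{name}={theta[slot]} outside admissible support ({lo}, {hi})")
    if theta[0] <= 0 or theta[2] < 0:
        raise ValueError("threshold offset must be positive and non-decision offset non-negative")
    return theta


# ---------------------------------------------------------------------------
# preprocessing

RAW_COLUMNS = ["participant_id", "group", "trial", "pair", "choice", "rt", "reward"]


def preprocess_rts(dataset: pd.DataFrame) -> pd.DataFrame:
    """Sign-code RTs and flag excluded trials, per participant.

    Adds ``signed_rt`` (negative for suboptimal choices, NaN for excluded
    trials) and ``excluded_reason`` ('', 'no_response' or 'fastest_5pct').
    The fastest-5% count is ``floor(0.05 * n_responded)`` with ties broken by
    stable trial order.  The function recomputes exclusively from the raw
    columns, so it is idempotent.
    """
    df = dataset.copy()
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    df["excluded_reason"] = ""
    df["signed_rt"] = np.nan
    out = []
    for pid, sub in df.groupby("participant_id", sort=False):
        sub = sub.sort_values("trial").copy()
        responded = sub["choice"].isin(["optimal", "suboptimal"])
        if not responded.any():
            raise ValueError(f"participant {pid!r} has no responded trials")
        sub.loc[~responded, "excluded_reason"] = "no_response"
        k = int(np.floor(0.05 * int(responded.sum())))
        if k > 0:
            resp = sub.loc[responded]
            # stable sort: equal RTs excluded in trial order
            fastest = resp.sort_values("rt", kind="stable").index[:k]
            sub.loc[fastest, "excluded_reason"] = "fastest_5pct"
        keep = sub["excluded_reason"] == ""
        sign = np.where(sub["choice"] == "optimal", 1.0, -1.0)
        sub.loc[keep, "signed_rt"] = sign[keep.to_numpy()] * sub.loc[keep, "rt"]
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def pack_subject(subject_df: pd.DataFrame) -> dict:
    """Convert one participant's preprocessed trials to kernel-ready arrays."""
    sub = subject_df.sort_values("trial")
    if "excluded_reason" not in sub.columns:
        raise ValueError("dataset must be preprocessed first (preprocess_rts)")
    choice_map = {"optimal": 1, "suboptimal": 0, "none": -1}
    pairs = np.sort(subject_df["pair"].unique())
    pair_index = {p: i for i, p in enumerate(pairs)}
    retained = (sub["excluded_reason"] == "").to_numpy().astype(np.int64)
    return {
        "pair": sub["pair"].map(pair_index).to_numpy(np.int64),
        "choice": sub["choice"].map(choice_map).to_numpy(np.int64),
        "reward": sub["reward"].fillna(-1).to_numpy(np.int64),
        "trial_no": sub["trial"].to_numpy(np.int64),
        "signed_rt": sub["signed_rt"].fillna(np.nan).to_numpy(float),
        "retained": retained,
        "n_pairs": len(pairs),
    }


def trialwise_loglik(
    spec: ModelSpec,
    params: dict,
    subject_df: pd.DataFrame,
    update_filtered: bool = True,
    density_floor: float = 0.0,
) -> np.ndarray:
    """Per-retained-trial log-likelihood for one participant under one model.

    The learning forward pass runs over the full chronological trial
    sequence (excluded responded trials still update Q-values when
    ``update_filtered`` is on), but only retained trials emit terms.
    """
    theta = params_to_theta(spec, params)
    arr = pack_subject(subject_df)
    terms = _kernels.loglik_terms(
        theta,
        spec.learn_code,
        spec.a_pow,
        spec.t_pow,
        arr["pair"],
        arr["choice"],
        arr["reward"],
        arr["trial_no"],
        arr["signed_rt"],
        arr["retained"],
        arr["n_pairs"],
        1 if update_filtered else 0,
        density_floor,
    )
    return terms[arr["retained"] == 1]
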