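"""Model space, RT preprocessing and trial-wise log-likelihoods."""

import numpy as np
import pandas as pd
import pytest

from rlddm import learning, models, wfpt
from conftest import make_subject_df


def test_model_space_enumeration():
    space = models.enumerate_model_space()
    assert len(space) == 9
    by_name = {m.name: m for m in space}
    m8 = by_name["RLDDM8"]
    assert (m8.learning, m8.ndt, m8.threshold) == ("dual", "power", "power")
    m1 = by_name["RLDDM1"]
    assert (m1.learning, m1.ndt, m1.threshold) == ("single", "fixed", "fixed")
    m6 = by_name["RLDDM6"]
    assert (m6.learning, m6.ndt, m6.threshold) == ("dual", "fixed", "power")
    assert by_name["DDM0"].learning == "none"
    assert by_name["DDM0"].free_params == ["a0", "t0", "v"]


def test_preprocess_excludes_fastest_five_percent(control_dataset):
    fd = models.preprocess_rts(control_dataset[0])
    for pid, sub in fd.groupby("participant_id"):
        responded = sub[sub["choice"] != "none"]
        k = int(np.floor(0.05 * len(responded)))
        fast = sub[sub["excluded_reason"] == "fastest_5pct"]
        assert len(fast) == k
        kept = sub[sub["excluded_reason"] == ""]
        # every excluded-fast trial is at most as slow as every retained one
        if k:
            assert fast["rt"].max() <= kept["rt"].min() + 1e-12


def test_preprocess_sign_flips_suboptimal_rts(control_dataset):
    fd = models.preprocess_rts(control_dataset[0])
    kept = fd[fd["excluded_reason"] == ""]
    sub = kept[kept["choice"] == "suboptimal"]
    opt = kept[kept["choice"] == "optimal"]
    assert np.all(sub["signed_rt"] < 0)
    assert np.all(opt["signed_rt"] > 0)
    assert np.allclose(np.abs(kept["signed_rt"]), kept["rt"])


def test_preprocess_tie_break_is_stable_by_trial_order():
    df = make_subject_df([0.5] * 60)
    k = int(np.floor(0.05 * 60))
    excluded = df[df["excluded_reason"] == "fastest_5pct"]
    assert len(excluded) == k
    assert excluded["trial"].tolist() == list(range(1, k + 1))


def test_preprocess_is_idempotent(control_dataset):
    once = models.preprocess_rts(control_dataset[0])
    twice = models.preprocess_rts(once)
    pd.testing.assert_frame_equal(
        once.reset_index(drop=True), twice[once.columns].reset_index(drop=True)
    )


def test_preprocess_rejects_participant_without_responses():
    df = pd.DataFrame({
        "participant_id": "p", "group": "control", "trial": [1, 2],
        "pair": 0, "choice": "none", "rt": np.nan, "reward": np.nan,
    })
    with pytest.raises(ValueError):
        models.preprocess_rts(df)


def test_ddm0_loglik_symmetric_at_zero_drift():
    df = make_subject_df([0.8, -0.8])
    spec = models.get_model("DDM0")
    ll = models.trialwise_loglik(spec, {"a0": 1.5, "t0": 0.3, "v": 0.0}, df)
    assert ll[0] == pytest.approx(ll[1], rel=1e-12)


def test_zero_value_coefficient_reduces_to_null_model():
    df = make_subject_df([0.8, -0.6, 1.1, 0.5, -0.9, 0.7])
    null = models.trialwise_loglik(models.get_model("DDM0"), {"a0": 1.4, "t0": 0.25, "v": 0.0}, df)
    rl = models.trialwise_loglik(
        models.get_model("RLDDM1"), {"a0": 1.4, "t0": 0.25, "v": 0.0, "eta_p": -0.5}, df
    )
    assert np.allclose(null, rl, rtol=1e-12)


def test_nested_models_collapse_exactly(control_filtered):
    """RLDDM8 equals RLDDM4 (eta+ = eta-), RLDDM6 (tau_exp = 0) and RLDDM1
    (both plus alpha_exp = 0) under the parameter restrictions."""
    sub = control_filtered[control_filtered["participant_id"] == control_filtered["participant_id"].iloc[0]]
    base = {"a0": 1.3, "a_exp": -0.12, "t0": 0.4, "t_exp": -0.07, "v": 3.5,
            "eta_p": -0.8, "eta_m": -0.8}
    m = models.get_model
    full = models.trialwise_loglik(m("RLDDM8"), base, sub)
    p4 = {k: v for k, v in base.items() if k != "eta_m"}
    assert np.allclose(full, models.trialwise_loglik(m("RLDDM4"), p4, sub), rtol=1e-12)
    p6 = dict(base, t_exp=0.0)
    full6 = models.trialwise_loglik(m("RLDDM8"), p6, sub)
    p6.pop("t_exp")
    assert np.allclose(full6, models.trialwise_loglik(m("RLDDM6"), p6, sub), rtol=1e-12)
    p1 = dict(base, t_exp=0.0, a_exp=0.0)
    full1 = models.trialwise_loglik(m("RLDDM8"), p1, sub)
    for k in ("t_exp", "a_exp", "eta_m"):
        p1.pop(k)
    assert np.allclose(full1, models.trialwise_loglik(m("RLDDM1"), p1, sub), rtol=1e-12)


def test_loglik_matches_independent_python_forward_pass(control_filtered):
    """Oracle: re-derive the likelihood with the pure-Python learning module
    and the public WFPT wrapper, including global trial indexing and Q
    updates on excluded responded trials."""
    pid = control_filtered["participant_id"].iloc[0]
    sub = control_filtered[control_filtered["participant_id"] == pid].sort_values("trial")
    params = {"a0": 1.5, "a_exp": -0.1, "t0": 0.35, "t_exp": -0.05, "v": 3.0,
              "eta_p": -0.7, "eta_m": -1.1}
    spec = models.get_model("RLDDM8")
    got = models.trialwise_loglik(spec, params, sub)

    rates = learning.LearningRates(params["eta_p"], params["eta_m"])
    state = learning.QState(n_pairs=2)
    expected = []
    for _, row in sub.iterrows():
        t = int(row["trial"])
        a_t = params["a0"] * t ** params["a_exp"]
        tau_t = params["t0"] * t ** params["t_exp"]
        v_t = params["v"] * state.q_diff(int(row["pair"]))
        if row["excluded_reason"] == "":
            expected.append(wfpt.wfpt_logpdf(row["signed_rt"], a_t, tau_t, v_t))
        if row["choice"] in ("optimal", "suboptimal"):
            learning.q_update(state, int(row["pair"]), row["choice"], int(row["reward"]), rates)
    assert np.allclose(got, np.array(expected), rtol=1e-10)


def test_single_trial_likelihood_is_a_proper_density():
    """Summing exp(loglik) over a dense (choice x rt) grid for one trial
    approximates 1."""
    spec = models.get_model("RLDDM8")
    params = {"a0": 1.3, "a_exp": -0.1, "t0": 0.3, "t_exp": -0.05, "v": 3.0,
              "eta_p": -0.5, "eta_m": -0.5}
    grid = np.linspace(0.3005, 25.0, 1500)
    df = make_subject_df([0.8])
    total = 0.0
    for sign in (1.0, -1.0):
        dens = []
        for x in (0.5 * (grid[:-1] + grid[1:])):
            df["choice"] = "optimal" if sign > 0 else "suboptimal"
            df["rt"] = x
            df["signed_rt"] = sign * x
            dens.append(np.exp(models.trialwise_loglik(spec, params, df)[0]))
        total += np.sum(np.array(dens) * np.diff(grid))
    assert total == pytest.approx(1.0, abs=5e-3)


def test_loglik_flags_rt_at_or_below_nondecision_time():
    df = make_subject_df([0.2])
    ll = models.trialwise_loglik(models.get_model("DDM0"), {"a0": 1.0, "t0": 0.5, "v": 1.0}, df)
    assert ll[0] == -np.inf


def test_params_outside_support_rejected(control_filtered):
    sub = control_filtered[control_filtered["participant_id"] == control_filtered["participant_id"].iloc[0]]
    with pytest.raises(ValueError):
        models.trialwise_loglik(models.get_model("DDM0"), {"a0": 7.0, "t0": 0.3, "v": 1.0}, sub)
    with pytest.raises(ValueError):
        models.trialwise_loglik(models.get_model("DDM0"), {"a0": 1.0, "t0": 0.3}, sub)
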