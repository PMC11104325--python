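"""HDI, posterior predictive checks, group differences and behavior summaries."""

import numpy as np
import pandas as pd
import pytest

from rlddm import diagnostics, task
from rlddm.diagnostics import group_difference_summary, hdi, model_agnostic_summary
from rlddm.inference import FitResult


def _fake_fit(mu_draws_by_param, theta=None, subject_ids=None, model="RLDDM8"):
    """FitResult stub with prescribed group-mean draws (1 chain)."""
    names = list(mu_draws_by_param)
    n = len(next(iter(mu_draws_by_param.values())))
    mu = np.stack([np.asarray(mu_draws_by_param[p], dtype=float) for p in names], axis=-1)[None]
    S = 1 if theta is None else theta.shape[2]
    theta_arr = np.zeros((1, n, S, len(names))) if theta is None else theta
    ids = subject_ids or [f"s{i}" for i in range(S)]
    return FitResult(model=model, param_names=names, subject_ids=ids,
                     mu=mu, sigma=np.full_like(mu, 0.1), theta=theta_arr,
                     pointwise=np.zeros((1, n, 1)), rhat={}, config={}, seed=0)


# ---------------------------------------------------------------------------
# HDI

def test_hdi_point_mass():
    lo, hi = hdi(np.full(50, 3.7))
    assert lo == hi == 3.7


def test_hdi_standard_normal_matches_quantiles():
    x = np.random.default_rng(0).normal(size=200_000)
    lo, hi = hdi(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hdi_uniform_width():
    x = np.random.default_rng(1).uniform(size=100_000)
    lo, hi = hdi(x, 0.5)
    assert (hi - lo) == pytest.approx(0.5, abs=0.02)


def test_hdi_never_wider_than_equal_tailed():
    rng = np.random.default_rng(2)
    for x in (rng.normal(size=5000), rng.gamma(2.0, size=5000), rng.uniform(size=5000)):
        lo, hi = hdi(x, 0.9)
        eq = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) <= (eq[1] - eq[0]) + 1e-12


def test_hdi_input_validation():
    with pytest.raises(ValueError):
        hdi([1.0], 0.95)
    with pytest.raises(ValueError):
        hdi([1.0, 2.0], 1.5)


# ---------------------------------------------------------------------------
# group differences

def test_identical_posteriors_give_null_summary():
    rng = np.random.default_rng(3)
    draws = {"v": rng.normal(3, 1, 4000)}
    a, b = _fake_fit(draws), _fake_fit(draws)
    out = group_difference_summary(a, b).iloc[0]
    assert out["m_diff"] == 0.0
    # posteriors of the same shape but independent noise: P ~ 50%, dBF ~ 1
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 4000)
    a = _fake_fit({"v": x})
    b = _fake_fit({"v": -x})  # diff = 2x, symmetric around 0
    out = group_difference_summary(a, b).iloc[0]
    assert out["p_diff_gt0"] == pytest.approx(50.0, abs=3.0)
    assert out["dbf"] == pytest.approx(1.0, abs=0.15)


def test_all_positive_differences_saturate():
    a = _fake_fit({"v": np.linspace(2, 3, 100)})
    b = _fake_fit({"v": np.linspace(0, 1, 100)})
    out = group_difference_summary(a, b).iloc[0]
    assert out["p_diff_gt0"] == 100.0
    assert np.isinf(out["dbf"])


def test_group_difference_antisymmetry():
    rng = np.random.default_rng(5)
    a = _fake_fit({"t0": rng.normal(0.5, 0.05, 3000)})
    b = _fake_fit({"t0": rng.normal(0.4, 0.05, 3000)})
    ab = group_difference_summary(a, b).iloc[0]
    ba = group_difference_summary(b, a).iloc[0]
    assert ab["m_diff"] == pytest.approx(-ba["m_diff"], rel=1e-12)
    assert ab["p_diff_gt0"] == pytest.approx(100.0 - ba["p_diff_gt0"], abs=1e-9)


def test_mass_ratio_consistency_with_probability():
    """A posterior probability of 96.39% for a positive difference implies a
    mass-ratio directed Bayes factor of .9639/.0361 ~ 26.7."""
    n = 10_000
    k = int(round(0.9639 * n))
    diff = np.concatenate([np.abs(np.random.default_rng(6).normal(size=k)) + 1e-9,
                           -np.abs(np.random.default_rng(7).normal(size=n - k)) - 1e-9])
    a = _fake_fit({"a_exp": diff})
    b = _fake_fit({"a_exp": np.zeros(n)})
    out = group_difference_summary(a, b).iloc[0]
    assert out["p_diff_gt0"] == pytest.approx(96.39, abs=1e-9)
    assert out["dbf"] == pytest.approx(0.9639 / 0.0361, rel=1e-3)


def test_direction_argument_flips_bayes_factor():
    rng = np.random.default_rng(8)
    a = _fake_fit({"v": rng.normal(1, 1, 2000)})
    b = _fake_fit({"v": rng.normal(0, 1, 2000)})
    g = group_difference_summary(a, b, direction="greater").iloc[0]["dbf"]
    l = group_difference_summary(a, b, direction="less").iloc[0]["dbf"]
    assert g == pytest.approx(1.0 / l, rel=1e-9)


def test_mismatched_specs_rejected():
    a = _fake_fit({"v": np.zeros(10) + 1})
    b = _fake_fit({"t0": np.zeros(10) + 1})
    with pytest.raises(ValueError):
        group_difference_summary(a, b)


# ---------------------------------------------------------------------------
# model-agnostic summaries

def test_model_agnostic_measures():
    df = pd.DataFrame({
        "participant_id": ["p1"] * 3 + ["p2"] * 3,
        "group": ["control"] * 3 + ["gambling"] * 3,
        "trial": [1, 2, 3] * 2,
        "pair": 0,
        "choice": ["optimal", "optimal", "optimal", "optimal", "suboptimal", "none"],
        "rt": [0.4, 0.6, 0.8, 0.5, 0.7, np.nan],
        "reward": [1, 0, 1, 1, 1, np.nan],
    })
    out = model_agnostic_summary(df).set_index("participant_id")
    assert out.loc["p1", "accuracy"] == 1.0
    assert out.loc["p1", "median_rt"] == pytest.approx(0.6)
    assert out.loc["p1", "total_reward"] == 2
    assert out.loc["p2", "accuracy"] == pytest.approx(0.5)


def test_model_agnostic_rejects_no_responses():
    df = pd.DataFrame({
        "participant_id": ["p1"], "group": ["control"], "trial": [1],
        "pair": [0], "choice": ["none"], "rt": [np.nan], "reward": [np.nan],
    })
    with pytest.raises(ValueError):
        model_agnostic_summary(df)


# ---------------------------------------------------------------------------
# posterior predictive checks

def test_ppc_point_mass_fit_recovers_generator_means(schedule60, rlddm8_spec):
    """A posterior concentrated on the generating parameters predicts bin
    means close to the generator's own Monte-Carlo means."""
    params = dict(task.group_presets("control").mu)
    data, _ = task.simulate_group(
        task.GroupParams(mu=params, sigma={k: 1e-9 for k in params}),
        8, rlddm8_spec, schedule60, seed=5)
    names = rlddm8_spec.free_params
    n_draws, S = 150, 8
    theta = np.tile(np.array([[params[p] for p in names]]), (1, n_draws, S, 1))
    fit = FitResult(model="RLDDM8", param_names=names,
                    subject_ids=list(dict.fromkeys(data["participant_id"])),
                    mu=theta[:, :, 0, :], sigma=np.full_like(theta[:, :, 0, :], 1e-6),
                    theta=theta, pointwise=np.zeros((1, n_draws, 1)), rhat={}, config={}, seed=0)
    summary = diagnostics.posterior_predictive_bins(fit, rlddm8_spec, data,
                                                    bin_width=10, n_draws=100, seed=2)
    t = summary.table
    # observed data come from the same generator: means should sit inside bands
    inside = ((t.pred_acc_lo <= t.obs_acc) & (t.obs_acc <= t.pred_acc_hi)).mean()
    assert inside >= 5 / 6 - 1e-9
    assert np.all(t.pred_acc_lo <= t.pred_acc_mean + 1e-12)
    assert np.all(t.pred_acc_mean <= t.pred_acc_hi + 1e-12)


def test_ppc_validates_bin_width_and_draws(schedule60, rlddm8_spec, control_dataset):
    data = control_dataset[0]
    names = rlddm8_spec.free_params
    theta = np.zeros((1, 10, 12, len(names)))
    fit = FitResult(model="RLDDM8", param_names=names,
                    subject_ids=list(dict.fromkeys(data["participant_id"])),
                    mu=theta[:, :, 0, :], sigma=theta[:, :, 0, :] + 0.1, theta=theta,
                    pointwise=np.zeros((1, 10, 1)), rhat={}, config={}, seed=0)
    with pytest.raises(ValueError):
        diagnostics.posterior_predictive_bins(fit, rlddm8_spec, data, bin_width=100, n_draws=5)
    with pytest.raises(ValueError):
        diagnostics.posterior_predictive_bins(fit, rlddm8_spec, data, bin_width=10, n_draws=1000)
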