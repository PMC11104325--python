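"""Wiener first-passage-time density, trajectories and samplers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from rlddm import wfpt


PARAM_GRID = [
    (0.8, 0.2, 0.0),
    (1.2, 0.3, 1.5),
    (1.2, 0.3, -1.5),
    (2.5, 0.5, 0.8),
    (0.5, 0.1, 3.0),
    (4.0, 1.0, 0.3),
]


@pytest.mark.parametrize("alpha,tau,v", PARAM_GRID)
def test_density_normalizes_over_both_boundaries(alpha, tau, v):
    up = quad(lambda t: wfpt.wfpt_pdf(t, alpha, tau, v), tau, tau + 200, limit=300)[0]
    lo = quad(lambda t: wfpt.wfpt_pdf(-t, alpha, tau, v), tau, tau + 200, limit=300)[0]
    assert up + lo == pytest.approx(1.0, abs=1e-4)
    # the upper-boundary mass matches the closed-form absorption probability
    assert up == pytest.approx(wfpt.prob_upper(alpha, v), abs=1e-6)


@pytest.mark.parametrize("alpha,tau,v", PARAM_GRID)
@pytest.mark.parametrize("z", [0.3, 0.5, 0.7])
def test_reflection_identity(alpha, tau, v, z):
    """Lower-boundary density equals the upper-boundary density of the
    mirrored process (v -> -v, z -> 1 - z)."""
    for t in (0.05, 0.2, 1.0, 3.0):
        lower = wfpt.wfpt_logpdf(-(tau + t), alpha, tau, v, z=z)
        mirrored = wfpt.wfpt_logpdf(tau + t, alpha, tau, -v, z=1.0 - z)
        assert lower == pytest.approx(mirrored, abs=1e-8)


@given(st.floats(0.05, 5.0))
@settings(deadline=None, max_examples=30)
def test_unbiased_zero_drift_density_is_symmetric(t):
    up = wfpt.wfpt_logpdf(0.2 + t, 1.5, 0.2, 0.0)
    lo = wfpt.wfpt_logpdf(-(0.2 + t), 1.5, 0.2, 0.0)
    assert up == pytest.approx(lo, rel=1e-12)


def test_logpdf_is_minus_inf_at_or_below_nondecision_time():
    assert wfpt.wfpt_logpdf(0.3, 1.0, 0.3, 1.0) == -np.inf
    assert wfpt.wfpt_logpdf(0.1, 1.0, 0.3, 1.0) == -np.inf
    assert np.isfinite(wfpt.wfpt_logpdf(0.31, 1.0, 0.3, 1.0))


def test_density_floor_keeps_logpdf_finite():
    lp = wfpt.wfpt_logpdf(0.1, 1.0, 0.3, 1.0, density_floor=1e-10)
    assert lp == pytest.approx(np.log(1e-10))


def test_inadmissible_parameters_rejected():
    with pytest.raises(ValueError):
        wfpt.wfpt_logpdf(1.0, -1.0, 0.3, 1.0)
    with pytest.raises(ValueError):
        wfpt.wfpt_logpdf(1.0, 1.0, 0.3, 1.0, z=1.5)
    with pytest.raises(ValueError):
        wfpt.sample_ddm(0.0, 0.3, 1.0)


def test_power_trajectory_values():
    assert wfpt.power_trajectory(1.7, -0.4, 1) == pytest.approx(1.7)
    assert wfpt.power_trajectory(1.7, 0.0, 37) == pytest.approx(1.7)
    assert wfpt.power_trajectory(2.0, -0.1, 60) == pytest.approx(2.0 * 60 ** -0.1)
    traj = wfpt.power_trajectory(1.0, -0.3, np.arange(1, 61))
    assert np.all(np.diff(traj) < 0)
    with pytest.raises(ValueError):
        wfpt.power_trajectory(1.0, 0.5, 0)


def test_drift_from_values_linear():
    assert wfpt.drift_from_values(2.0, 0.8, 0.2) == pytest.approx(1.2)
    assert wfpt.drift_from_values(5.0, 0.4, 0.4) == 0.0
    assert wfpt.drift_from_values(4.0, 0.8, 0.2) == 2 * wfpt.drift_from_values(2.0, 0.8, 0.2)


def test_sampler_boundary_probability_and_support():
    n = 20_000
    x = wfpt.sample_ddm(1.2, 0.3, 1.5, size=n, seed=1)
    assert np.all(np.abs(x) > 0.3)
    p = wfpt.prob_upper(1.2, 1.5)
    se = np.sqrt(p * (1 - p) / n)
    assert (x > 0).mean() == pytest.approx(p, abs=4 * se)
    # zero drift, unbiased start
    x0 = wfpt.sample_ddm(1.2, 0.3, 0.0, size=n, seed=2)
    assert (x0 > 0).mean() == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / n))


def test_sampler_is_reproducible():
    a = wfpt.sample_ddm(1.0, 0.2, 1.0, size=100, seed=9)
    b = wfpt.sample_ddm(1.0, 0.2, 1.0, size=100, seed=9)
    assert np.array_equal(a, b)


def test_sampler_matches_density_by_ks_distance():
    """Self-consistency: empirical CDF of the exact-style sampler against the
    numerically integrated density."""
    alpha, tau, v = 1.2, 0.3, 1.5
    n = 50_000
    x = np.sort(wfpt.sample_ddm(alpha, tau, v, size=n, seed=7))
    grid = np.linspace(tau + 1e-6, 30, 20001)
    pdf_up = wfpt.wfpt_pdf(grid, alpha, tau, v)
    pdf_lo = wfpt.wfpt_pdf(-grid, alpha, tau, v)
    from scipy.integrate import cumulative_trapezoid

    cdf_up = cumulative_trapezoid(pdf_up, grid, initial=0)
    cdf_lo = cumulative_trapezoid(pdf_lo, grid, initial=0)
    p_lo = cdf_lo[-1]
    F = np.empty(n)
    neg = x < 0
    F[neg] = p_lo - np.interp(-x[neg], grid, cdf_lo)
    F[~neg] = p_lo + np.interp(x[~neg], grid, cdf_up)
    emp = np.arange(1, n + 1) / n
    assert np.abs(F - emp).max() < 0.01


def test_euler_oracle_agrees_with_exact_sampler():
    n = 20_000
    e = wfpt.sample_ddm_euler(1.2, 0.3, 1.5, size=n, seed=3, dt=1e-3)
    x = wfpt.sample_ddm(1.2, 0.3, 1.5, size=n, seed=4)
    assert (e > 0).mean() == pytest.approx((x > 0).mean(), abs=0.02)
    assert np.abs(e).mean() == pytest.approx(np.abs(x).mean(), abs=0.03)
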