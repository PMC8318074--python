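"""Wiener first-passage numerics against quadrature, closed forms and the
path-simulation oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import kstest

from valenceddm import wfpt
from valenceddm.wfpt import DDMParams


def _integral(params, boundary, upper_limit=150.0):
    return quad(lambda t: wfpt.fpt_density(t, boundary, params),
                params.nondecision_t0, upper_limit, limit=300)[0]


@pytest.mark.parametrize("a", [1.0, 2.5, 4.0])
@pytest.mark.parametrize("v", [-1.0, 0.0, 1.0])
@pytest.mark.parametrize("z", [0.3, 0.5, 0.7])
def test_joint_normalization(a, v, z):
    """Defective densities over both boundaries integrate to 1."""
    p = DDMParams(a, 0.0, z, 0.0, v)
    total = _integral(p, "upper", 300.0) + _integral(p, "lower", 300.0)
    assert total == pytest.approx(1.0, abs=1e-4)


@pytest.mark.parametrize("a,v,z", [(1.0, 1.0, 0.5), (2.5, 0.5, 0.5),
                                   (2.0, -0.7, 0.3)])
def test_upper_mass_equals_choice_probability(a, v, z):
    p = DDMParams(a, 0.0, z, 0.0, v)
    assert _integral(p, "upper", 300.0) == pytest.approx(
        wfpt.choice_probability(p), abs=1e-4)


def test_density_zero_before_nondecision_time():
    p = DDMParams(2.5, 7.5, 0.5, 0.0, 0.5)
    assert wfpt.fpt_density(7.5, "upper", p) == 0.0
    assert wfpt.fpt_density(7.2, "lower", p) == 0.0


def test_zero_drift_symmetry():
    p = DDMParams(2.0, 0.0, 0.5, 0.0, 0.0)
    for t in (0.2, 0.8, 2.0, 5.0):
        assert wfpt.fpt_density(t, "upper", p) == \
            pytest.approx(wfpt.fpt_density(t, "lower", p), rel=1e-10)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(a=st.floats(0.5, 5.0), z=st.floats(0.1, 0.9),
       v=st.floats(-2.0, 2.0), t=st.floats(0.05, 8.0))
def test_reflection_symmetry_and_nonnegativity(a, z, v, t):
    """Swapping z -> 1-z, v -> -v swaps the boundary densities exactly;
    densities are nonnegative everywhere."""
    pa = DDMParams(a, 0.0, z, 0.0, v)
    pb = DDMParams(a, 0.0, 1.0 - z, 0.0, -v)
    fu = wfpt.fpt_density(t, "upper", pa)
    fl = wfpt.fpt_density(t, "lower", pb)
    assert fu >= 0.0
    assert fu == fl


def test_choice_probability_closed_form():
    # zero drift: probability equals the starting point
    assert wfpt.choice_probability(DDMParams(2.0, 0.0, 0.5)) == 0.5
    assert wfpt.choice_probability(DDMParams(2.0, 0.0, 0.9)) == 0.9
    # (1 - e^-1) / (1 - e^-2), evaluated independently
    expected = (1 - math.exp(-1.0)) / (1 - math.exp(-2.0))
    p = DDMParams(1.0, 0.0, 0.5, 0.0, 1.0)
    assert wfpt.choice_probability(p) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.731, abs=5e-4)
    # strong drift saturates
    assert wfpt.choice_probability(DDMParams(2.0, 0.0, 0.5, 0.0, 50.0)) == \
        pytest.approx(1.0, abs=1e-12)


def test_simulator_matches_choice_probability_with_sz():
    p = DDMParams(2.0, 0.0, 0.6, 0.3, 0.4)
    rng = np.random.default_rng(42)
    n = 20000
    b, t = wfpt.simulate_first_passage_batch(p, n, rng, dt=1e-3)
    prob = wfpt.choice_probability(p)
    se = math.sqrt(prob * (1 - prob) / n)
    assert abs(b.mean() - prob) < 3 * se
    assert (t > 0).all()


def test_simulator_zero_drift_absorption_equals_start():
    p = DDMParams(2.0, 0.0, 0.9, 0.0, 0.0)
    rng = np.random.default_rng(1)
    b, _ = wfpt.simulate_first_passage_batch(p, 20000, rng, dt=1e-3)
    assert abs(b.mean() - 0.9) < 3 * math.sqrt(0.9 * 0.1 / 20000)


def test_simulator_times_match_density_distribution():
    """Kolmogorov-Smirnov distance between simulated upper-boundary times
    and the model's conditional first-passage CDF stays below 0.01."""
    p = DDMParams(1.5, 0.0, 0.5, 0.0, 0.8)
    rng = np.random.default_rng(7)
    b, t = wfpt.simulate_first_passage_batch(p, 100_000, rng, dt=1e-4)
    tt = np.sort(t[b == 1])
    mass = wfpt.choice_probability(p)
    grid = np.linspace(1e-4, max(tt.max(), 10.0), 4000)
    dens = wfpt.fpt_density(grid, "upper", p)
    cdf_grid = np.cumsum(dens) * (grid[1] - grid[0]) / mass
    stat = kstest(tt, lambda x: np.interp(x, grid, cdf_grid)).statistic
    assert stat < 0.01


def test_single_passage_and_step_validation():
    p = DDMParams(2.0, 0.0, 0.5, 0.0, 0.5)
    rng = np.random.default_rng(3)
    fp = wfpt.simulate_first_passage(p, rng, dt=1e-3)
    assert fp.boundary in ("upper", "lower") and fp.decision_time > 0
    with pytest.raises(ValueError):
        wfpt.simulate_first_passage_batch(p, 10, rng, dt=0.0)


def test_trial_loglik_definition_and_floor():
    p = DDMParams(2.5, 7.5, 0.5, 0.0, 0.5)
    t = 8.3
    assert math.exp(wfpt.trial_loglik(t, "upper", p)) == \
        pytest.approx(wfpt.fpt_density(t, "upper", p), rel=1e-12)
    assert wfpt.trial_loglik(7.4, "upper", p) == -np.inf


def test_trial_loglik_sz_matches_monte_carlo_average():
    """The 11-node quadrature over the starting-point range agrees with a
    brute-force Monte-Carlo average over uniformly drawn starts."""
    p = DDMParams(2.5, 0.0, 0.5, 0.2, 0.5)
    t = 0.9
    rng = np.random.default_rng(0)
    zs = rng.uniform(0.4, 0.6, 10_000)
    mc = np.mean([wfpt.fpt_density(t, "upper", DDMParams(2.5, 0.0, z, 0.0, 0.5))
                  for z in zs])
    assert math.exp(wfpt.trial_loglik(t, "upper", p)) == \
        pytest.approx(mc, abs=1e-3)


def test_param_validation():
    with pytest.raises(ValueError):
        DDMParams(-1.0, 0.0, 0.5)
    with pytest.raises(ValueError):
        DDMParams(2.0, 0.0, 1.2)
    with pytest.raises(ValueError):
        DDMParams(2.0, 0.0, 0.1, 0.4)  # z - sz/2 <= 0
    with pytest.raises(ValueError):
        wfpt.fpt_density(np.nan, "upper", DDMParams(2.0, 0.0, 0.5))
    with pytest.raises(ValueError):
        wfpt.trial_loglik(1.0, "sideways", DDMParams(2.0, 0.0, 0.5))
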