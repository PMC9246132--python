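"""Exact stationary distributions against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolgrowth import (FeedbackParams, KappaThresholds, bistable_window,
                        count_modes, find_kappa0, marginalize, moments,
                        stationary_const_conc, stationary_joint_two,
                        stationary_single)
from poolgrowth.master_equation import StationaryDistribution

from conftest import birth_death_stationary, params, total_variation

AB_GRID = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (-1.0, 1.0), (-1.0, 0.0),
           (-0.2, 0.0), (-2.0, 1.0)]


@pytest.mark.parametrize("alpha,beta", AB_GRID)
@pytest.mark.parametrize("kappa", [0.0022, 0.1, 1.0])
def test_single_matches_generator_eigenvector(alpha, beta, kappa):
    """Closed form equals the stationary eigenvector of the explicit chain."""
    for N in (10, 30, 50):
        d = stationary_single(params(alpha, beta, kappa), N)
        pi = birth_death_stationary(alpha, beta, kappa, N)
        assert np.abs(d.probs - pi).max() < 1e-10


@settings(max_examples=40, deadline=None)
@given(alpha=st.floats(-2, 2), beta=st.floats(-1, 2),
       kappa=st.floats(1e-3, 10), N=st.integers(1, 60))
def test_detailed_balance_residuals(alpha, beta, kappa, N):
    """k- n^b P(n) = kappa k- (N-n+1) n^-a P(n-1) holds to 1e-10 relative."""
    d = stationary_single(params(alpha, beta, kappa), N)
    P = d.probs
    for n in range(1, N + 1):
        lhs = float(n) ** beta * P[n]
        rhs = kappa * (N - n + 1) * float(n) ** (-alpha) * P[n - 1]
        scale = max(lhs, rhs, 1e-300)
        assert abs(lhs - rhs) / scale < 1e-10


def test_single_tiny_pool_closed_form():
    # N=1: weights 1 and kappa*1!/(0!*(1!)^(a+b)) = kappa; kappa=1 -> 1/2, 1/2
    for ab in [(0.0, 0.0), (1.0, 0.0), (-1.0, 1.0)]:
        d = stationary_single(params(*ab, 1.0), 1)
        assert d.probs == pytest.approx([0.5, 0.5])


def test_single_canonical_mean_and_volume_convention():
    d = stationary_single(params(0.0, 0.0, 1.0), 50)
    assert abs(d.mean - 49.0) < 1.0        # deterministic n* = N - V/kappa
    assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)
    # V enters only through kappa/V
    d2 = stationary_single(params(0.0, 0.0, 2.0), 50, V=2.0)
    assert np.allclose(d.probs, d2.probs, atol=1e-14)


def test_joint_symmetry_and_normalization():
    p = params(0.0, 1.0, 1.0)
    j = stationary_joint_two(p, p, 50)
    assert j.probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.array_equal(j.probs, j.probs.T)
    m1, m2 = marginalize(j, 1), marginalize(j, 2)
    assert np.allclose(m1.probs, m2.probs)
    assert m1.cv < 1.0                     # robust control: narrow marginal


def test_joint_tiny_pool_hand_enumeration():
    """N=2, alpha+beta=1, kappa=1: six simplex states enumerated by hand."""
    p = params(0.0, 1.0, 1.0)
    j = stationary_joint_two(p, p, 2)
    # weights: (0,0)->1 (1,0),(0,1)->2 (1,1)->2 (2,0),(0,2)->1; total 9
    assert marginalize(j, 1).probs == pytest.approx([4 / 9, 4 / 9, 1 / 9])
    assert j.probs[1, 1] == pytest.approx(2 / 9)


def test_joint_mean_conservation():
    p1, p2 = params(0.0, 1.0, 1.0), params(0.0, 1.0, 0.5)
    j = stationary_joint_two(p1, p2, 50)
    n = np.arange(51, dtype=float)
    mean_av = float(((50 - n[:, None] - n[None, :]) * j.probs).sum())
    assert j.marginal_mean(1) + j.marginal_mean(2) + mean_av == \
        pytest.approx(50.0, abs=1e-9)


def test_limiting_pool_marginal_near_uniform():
    """alpha+beta=0 marginals are flat over [0, N - V/kappa]."""
    p = params(0.0, 0.0, 1.0)
    m = marginalize(stationary_joint_two(p, p, 50), 1)
    body = m.probs[:46]
    assert body.max() / body.min() < 1.01
    assert total_variation(m.probs, np.full(51, 1 / 51)) < 0.05


def test_const_conc_poisson_and_normalizability():
    p = params(0.0, 1.0, 3.0)
    d1, d2, ok = stationary_const_conc(p, p, rho=2.0)
    assert ok
    assert d1.mean == pytest.approx(6.0, abs=1e-9)     # Poisson(kappa rho)
    from scipy.stats import poisson
    ref = poisson.pmf(d1.support, 6.0)
    assert np.abs(d1.probs - ref).max() < 1e-12
    # degenerate line above the critical density: unbounded growth
    q = params(0.0, 0.0, 1.0)
    _, _, ok0 = stationary_const_conc(q, q, rho=2.0)
    assert not ok0
    _, _, ok_sub = stationary_const_conc(q, q, rho=0.5)
    assert ok_sub


def test_const_conc_truncation_error_message():
    p = params(0.0, 1.0, 3.0)
    with pytest.raises(ValueError, match="n_max"):
        stationary_const_conc(p, p, rho=2.0, n_max=4)


@pytest.mark.parametrize("probs,expected", [
    ([0.0, 0.0, 1.0, 0.0], (2.0, 0.0, 0.0)),           # point mass
    ([0.5, 0.0, 0.5], (1.0, 1.0, 1.0)),                # two-point {0, 2}
])
def test_moments_closed_cases(probs, expected):
    d = StationaryDistribution(support=np.arange(len(probs)),
                               probs=np.array(probs))
    mean, sd, cv = moments(d)
    assert (mean, sd, cv) == pytest.approx(expected)


def test_moments_mean_zero_cv_sentinel():
    d = StationaryDistribution(support=np.arange(3),
                               probs=np.array([1.0, 0.0, 0.0]))
    assert moments(d)[2] == math.inf


@pytest.mark.parametrize("probs,expected", [
    ([5.0, 3, 1, 0.5], 1),                 # monotone decreasing: mode at 0
    ([1.0, 3, 1, 0.2, 2, 1], 2),
    ([1.0, 2, 2, 2, 1], 1),                # plateau merges to one mode
    ([2.0, 2, 1, 2, 2], 2),                # endpoint plateaus both count
])
def test_count_modes(probs, expected):
    arr = np.array(probs) / np.sum(probs)
    d = StationaryDistribution(support=np.arange(arr.size), probs=arr)
    assert count_modes(d) == expected


def test_mode_structure_of_regimes():
    assert count_modes(stationary_single(params(-1, 0, 0.0022), 50)) == 2
    assert count_modes(stationary_single(params(0, 1, 1.0), 50)) == 1


def test_kappa0_defining_property_and_monotonicity():
    k0 = find_kappa0(0.0, 1.0, 50)
    cv_at = stationary_single(params(0, 1, k0), 50).cv
    assert abs(cv_at - 1.0) < 1e-6
    assert stationary_single(params(0, 1, k0 / 10), 50).cv > 1.0
    assert stationary_single(params(0, 1, k0 * 10), 50).cv < 1.0


def test_kappa0_no_crossing_raises():
    with pytest.raises(ValueError, match="CV"):
        find_kappa0(0.0, 1.0, 50, bracket=(10.0, 100.0))


def test_bistable_window_brackets_reference_point():
    th = bistable_window(-1.0, 0.0, 50)
    assert th.has_bistable_window
    assert th.kappa_star < 0.0022 < th.kappa_c
    assert th.kappa_star < th.kappa_c
    # bisection certificate at the lower edge
    eps = 1e-3 * th.kappa_star
    assert count_modes(stationary_single(
        params(-1, 0, th.kappa_star - eps), 50)) == 1
    assert count_modes(stationary_single(
        params(-1, 0, th.kappa_star + eps), 50)) == 2


def test_bistable_window_empty_for_nonnegative_feedback():
    th = bistable_window(0.0, 1.0, 50)
    assert not th.has_bistable_window
    assert math.isnan(th.kappa_star) and math.isnan(th.kappa_c)
    assert math.isfinite(th.kappa0)
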