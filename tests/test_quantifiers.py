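"""Renyi entropy/complexity against closed forms and brute-force oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import renyispace as rs


def renyi_divergence(p, m, q):
    """Oracle: order-q Renyi divergence R_q(P||M), natural log."""
    mask = p > 0
    return np.log((p[mask] ** q * m[mask] ** (1 - q)).sum()) / (q - 1)


def mixture_divergence_oracle(p, q):
    """Oracle: D_q = (1/2)[R_q(P||M) + R_q(Pe||M)], M the even mixture."""
    N = p.size
    pe = np.full(N, 1.0 / N)
    m = 0.5 * (p + pe)
    return 0.5 * (renyi_divergence(p, m, q) + renyi_divergence(pe, m, q))


def simplex_grid(N, steps):
    """All probability vectors on a grid over the N-simplex."""
    from itertools import product

    for ks in product(range(steps + 1), repeat=N - 1):
        if sum(ks) <= steps:
            p = np.array(list(ks) + [steps - sum(ks)], float) / steps
            yield p


@pytest.mark.parametrize("q", [0.5, 1.0, 2.0, 7.0])
def test_uniform_identities(q):
    """Uniform distribution: S_q = ln N, H_q = 1, D_q = 0, C_q = 0."""
    N = 24
    uni = np.full(N, 1.0 / N)
    assert rs.renyi_entropy(uni, q) == pytest.approx(math.log(N), abs=1e-12)
    assert rs.normalized_renyi_entropy(uni, q) == pytest.approx(1.0, abs=1e-12)
    assert abs(rs.jensen_renyi_divergence(uni, q)) < 1e-12
    assert abs(rs.renyi_complexity(uni, q)) < 1e-12


@pytest.mark.parametrize("q", [0.5, 1.0, 2.0, 7.0])
def test_delta_identities(q):
    """Delta distribution: H_q = 0, C_q = 0, and D_q attains D_q*."""
    N = 6
    delta = np.zeros(N)
    delta[0] = 1.0
    assert rs.normalized_renyi_entropy(delta, q) == pytest.approx(0.0, abs=1e-12)
    assert rs.renyi_complexity(delta, q) == pytest.approx(0.0, abs=1e-12)
    assert rs.jensen_renyi_divergence(delta, q) == pytest.approx(
        rs.max_divergence(N, q), abs=1e-12
    )


def test_entropy_rejects_nonpositive_q():
    p = np.array([0.5, 0.5])
    for fn in (rs.renyi_entropy, rs.jensen_renyi_divergence, rs.renyi_complexity):
        with pytest.raises(ValueError):
            fn(p, 0.0)
        with pytest.raises(ValueError):
            fn(p, -1.0)
    with pytest.raises(ValueError):
        rs.max_divergence(1, 2.0)


def test_min_entropy_limit():
    """S_q converges to -ln(max p) as q grows."""
    p = np.array([0.4, 0.4, 0.2, 0.0, 0.0, 0.0])
    assert rs.renyi_entropy(p, 50.0) == pytest.approx(-math.log(0.4), rel=0.02)


def test_max_entropy_limit_counts_support():
    """S_q -> ln(support size) as q -> 0."""
    p = np.array([0.7, 0.2, 0.1, 0.0])
    assert rs.renyi_entropy(p, 1e-6) == pytest.approx(math.log(3), rel=1e-4)


def test_shannon_case_hand_computed():
    """H_1 of the {0.4, 0.4, 0.2} pattern distribution over N = 3! states."""
    p = np.array([0.4, 0.4, 0.2, 0.0, 0.0, 0.0])
    expected = (-2 * 0.4 * math.log(0.4) - 0.2 * math.log(0.2)) / math.log(6)
    assert rs.normalized_renyi_entropy(p, 1.0) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("N", [6, 24])
@pytest.mark.parametrize("q", [0.5, 2.0, 4.0])
def test_divergence_matches_mixture_oracle(N, q, rng):
    """D_q equals (1/2)[R_q(P||M) + R_q(Pe||M)] on random simplex points."""
    for _ in range(200):
        p = rng.dirichlet(np.ones(N))
        assert rs.jensen_renyi_divergence(p, q) == pytest.approx(
            mixture_divergence_oracle(p, q), abs=1e-10
        )


def test_max_divergence_by_simplex_grid_search():
    """The closed-form D_q* dominates a dense grid over the N=3 simplex."""
    for q in (0.5, 2.0, 4.0):
        best = max(rs.jensen_renyi_divergence(p, q) for p in simplex_grid(3, 60))
        star = rs.max_divergence(3, q)
        assert best <= star + 1e-9
        assert best == pytest.approx(star, abs=1e-4)


def test_max_divergence_n2_grid():
    """N=2: a 1-D sweep over {(p, 1-p)} reproduces D_q*."""
    q = 2.0
    ps = np.linspace(0, 1, 20_001)
    best = max(rs.jensen_renyi_divergence(np.array([p, 1 - p]), q) for p in (0.0, 1.0))
    sweep = max(
        rs.jensen_renyi_divergence(np.array([p, 1 - p]), q) for p in ps[::100]
    )
    star = rs.max_divergence(2, q)
    assert star > 0
    assert best == pytest.approx(star, abs=1e-12)
    assert sweep <= star + 1e-12


def test_max_divergence_continuous_at_q_one():
    """D_q* at q = 1 +/- 1e-4 brackets the Jensen-Shannon maximum; the
    symmetric mean cancels the first-order term in q and agrees to 1e-6."""
    N = 6
    js = rs.max_divergence(N, 1.0)
    above = rs.max_divergence(N, 1 + 1e-4)
    below = rs.max_divergence(N, 1 - 1e-4)
    assert below < js < above  # D_q* increases with q
    assert above == pytest.approx(js, abs=2e-5)
    assert below == pytest.approx(js, abs=2e-5)
    assert 0.5 * (above + below) == pytest.approx(js, abs=1e-6)


def test_divergence_never_exceeds_maximum(rng):
    """D_q <= D_q* over many random simplex points at N in {3, 6, 24}."""
    for N in (3, 6, 24):
        for q in (0.5, 1.0, 2.0, 7.0):
            star = rs.max_divergence(N, q)
            for _ in range(500):
                p = rng.dirichlet(np.ones(N))
                assert rs.jensen_renyi_divergence(p, q) <= star + 1e-9


def test_mpr_trivial_cases():
    N = 6
    uni = np.full(N, 1.0 / N)
    delta = np.zeros(N)
    delta[0] = 1.0
    u = rs.mpr_complexity(uni)
    assert u.H == pytest.approx(1.0, abs=1e-12)
    assert u.C == pytest.approx(0.0, abs=1e-12)
    d = rs.mpr_complexity(delta)
    assert d.H == pytest.approx(0.0, abs=1e-12)
    assert d.Q_J == pytest.approx(1.0, abs=1e-12)
    assert d.C == pytest.approx(0.0, abs=1e-12)


def test_mpr_is_q_to_one_limit(rng):
    """C_MPR agrees with C_q evaluated just off q = 1 (base-invariant)."""
    for _ in range(50):
        p = rng.dirichlet(np.ones(6))
        cm = rs.mpr_complexity(p).C
        assert rs.renyi_complexity(p, 1 + 1e-3) == pytest.approx(cm, abs=1e-4)
        assert rs.renyi_complexity(p, 1 - 1e-3) == pytest.approx(cm, abs=1e-4)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_entropy_weakly_decreasing_in_q(seed):
    """S_q is non-increasing along the q grid for random distributions."""
    p = np.random.default_rng(seed).dirichlet(np.ones(6))
    curve = rs.ec_curve(p)
    assert np.all(np.diff(curve.S) <= 1e-10)
    assert np.all(curve.H >= -1e-12) and np.all(curve.H <= 1 + 1e-12)
    assert np.all(curve.C >= -1e-12)


def test_curve_grid_and_uniform():
    uni = np.full(6, 1.0 / 6)
    curve = rs.ec_curve(uni)
    assert len(curve) == 691
    assert curve.q_grid[0] == pytest.approx(0.1)
    assert curve.q_grid[-1] == pytest.approx(7.0)
    np.testing.assert_allclose(curve.H, 1.0, atol=1e-12)
    np.testing.assert_allclose(curve.C, 0.0, atol=1e-12)


def test_curve_matches_pointwise_evaluation(rng):
    """Vectorized curve equals scalar evaluation, including the q = 1 point."""
    p = rng.dirichlet(np.ones(24))
    grid = np.array([0.5, 0.9, 1.0, 1.1, 3.0])
    curve = rs.ec_curve(p, grid)
    for i, q in enumerate(grid):
        pt = rs.renyi_point(p, q)
        assert curve.H[i] == pytest.approx(pt.H_q, abs=1e-12)
        assert curve.C[i] == pytest.approx(pt.C_q, abs=1e-12)


def test_curve_rejects_bad_grids(rng):
    p = rng.dirichlet(np.ones(6))
    with pytest.raises(ValueError):
        rs.ec_curve(p, [])
    with pytest.raises(ValueError):
        rs.ec_curve(p, [1.0, 0.5])
    with pytest.raises(ValueError):
        rs.ec_curve(p, [-1.0, 0.5])


def test_curve_from_ordinal_distribution_carries_metadata(rng):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = rs.ordinal_distribution(rng.normal(size=2000), 3, 2)
    curve = rs.ec_curve(dist, [0.5, 1.0, 2.0], label="test")
    assert curve.D == 3 and curve.tau == 2 and curve.label == "test"
    c2 = rs.ECCurve.from_json(curve.to_json())
    np.testing.assert_allclose(c2.C, curve.C)
    assert c2.label == "test"
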