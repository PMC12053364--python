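"""Solver correctness: closed-form limits, oracle equivalence, scaling laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_hydraulics, random_tree
from rhizoflow import params as p
from rhizoflow.architecture import RootSystem, simulate_growth
from rhizoflow.hydraulics import (HydraulicInputError, HydraulicParams,
                                  PiecewiseLinearFunction, compute_krs,
                                  krs_trajectory, network_oracle, property_at,
                                  segment_conductance, sensitivity_sweep)

TWO_PI = 2.0 * math.pi


# --- piecewise-linear property functions -----------------------------------

def test_property_interpolation_and_clamping():
    f = PiecewiseLinearFunction.from_knots([(0, 1e-7), (10, 2e-7)])
    assert property_at(f, 5) == pytest.approx(1.5e-7)
    assert property_at(f, 50) == pytest.approx(2e-7)   # clamped beyond last
    assert property_at(f, 0) == pytest.approx(1e-7)
    single = PiecewiseLinearFunction.from_knots([(3, 7e-8)])
    for age in (0, 3, 100):
        assert property_at(single, age) == pytest.approx(7e-8)
    with pytest.raises(HydraulicInputError):
        property_at(f, -1)


@given(st.floats(0, 60))
@settings(max_examples=50, deadline=None)
def test_property_values_stay_within_knot_range(age):
    f = PiecewiseLinearFunction.from_knots([(0, 1e-8), (7, 9e-8), (40, 3e-8)])
    v = f(age)
    assert 1e-8 - 1e-20 <= v <= 9e-8 + 1e-20


def test_bad_knots_rejected():
    with pytest.raises(HydraulicInputError):
        PiecewiseLinearFunction.from_knots([(0, 1e-7), (0, 2e-7)])
    with pytest.raises(HydraulicInputError):
        PiecewiseLinearFunction.from_knots([(0, -1e-7)])
    with pytest.raises(HydraulicInputError):
        PiecewiseLinearFunction.from_knots([])


# --- single-segment conductance --------------------------------------------

def test_segment_conductance_degenerate_cases():
    assert segment_conductance(0.1, 3e-4, 0.0, 1e-12, 0.0) == 0.0
    # zero-length segment is transparent
    assert segment_conductance(0.0, 3e-4, 1e-7, 1e-12, 2.5e-11) == 2.5e-11
    # kr = 0: pure axial series combination
    Kd = 1e-11
    expected = 1.0 / (0.1 / 1e-12 + 1.0 / Kd)
    assert segment_conductance(0.1, 3e-4, 0.0, 1e-12, Kd) == pytest.approx(expected)
    with pytest.raises(HydraulicInputError):
        segment_conductance(-0.1, 3e-4, 1e-7, 1e-12)
    with pytest.raises(HydraulicInputError):
        segment_conductance(0.1, 0.0, 1e-7, 1e-12)


def test_single_segment_against_network_oracle():
    """Transmission-line closed form vs a 2000-node resistor chain."""
    l, r, kr, kx = 0.1, 3e-4, 1e-7, 1e-12
    K = segment_conductance(l, r, kr, kx, 0.0)
    tau = math.sqrt(TWO_PI * r * kr / kx)
    assert tau == pytest.approx(13.73, rel=0.01)
    sys1 = RootSystem(np.array([-1]), np.array([0]), np.array([0]),
                      np.array([l]), np.array([r]), np.array([0.0]), 1.0)
    const = HydraulicParams(
        {t: PiecewiseLinearFunction.from_knots([(0, kr)])
         for t in ("seminal", "crown", "lateral")},
        {t: PiecewiseLinearFunction.from_knots([(0, kx)])
         for t in ("seminal", "crown", "lateral")},
    )
    ref = network_oracle(sys1, const, nodes_per_segment=2000)
    assert K == pytest.approx(ref, rel=1e-5)
    assert K == pytest.approx(1.21e-11, rel=0.01)


def test_long_root_saturates_at_kappa():
    r, kr, kx = 3e-4, 1e-7, 1e-12
    kappa = math.sqrt(TWO_PI * r * kr * kx)
    tau = math.sqrt(TWO_PI * r * kr / kx)
    for Kd in (0.0, 1e-11, 1e-9):
        K = segment_conductance(30.0 / tau, r, kr, kx, Kd)
        assert K == pytest.approx(kappa, rel=1e-8)


def test_short_segment_adds_radial_surface():
    r, kr, kx = 3e-4, 1e-7, 1e-12
    tau = math.sqrt(TWO_PI * r * kr / kx)
    l = 1e-5 / tau  # tau*l = 1e-5
    Kd = 1e-15      # far below kappa
    K = segment_conductance(l, r, kr, kx, Kd)
    assert K == pytest.approx(Kd + TWO_PI * r * l * kr, rel=1e-6)


@given(st.floats(0.1, 10.0), st.floats(0.005, 0.5))
@settings(max_examples=50, deadline=None)
def test_joint_scaling_of_kr_kx_scales_kappa(c, l):
    """Dimensional consistency: kr,kx -> c*kr,c*kx multiplies the closed-tip
    conductance by exactly c (tau is unchanged, kappa scales by c)."""
    r, kr, kx = 2e-4, 5e-8, 2e-12
    K1 = segment_conductance(l, r, kr, kx, 0.0)
    K2 = segment_conductance(l, r, c * kr, c * kx, 0.0)
    assert K2 == pytest.approx(c * K1, rel=1e-10)


# --- whole-tree folding -----------------------------------------------------

def _const_hydraulics(kr, kx):
    return HydraulicParams(
        {t: PiecewiseLinearFunction.from_knots([(0, kr)])
         for t in ("seminal", "crown", "lateral")},
        {t: PiecewiseLinearFunction.from_knots([(0, kx)])
         for t in ("seminal", "crown", "lateral")},
    )


def test_unbranched_chain_equals_manual_fold():
    n = 5
    lengths = np.full(n, 0.02)
    radii = np.full(n, 2e-4)
    sys_chain = RootSystem(np.arange(-1, n - 1), np.zeros(n, int),
                           np.zeros(n, int), lengths, radii,
                           np.arange(n, dtype=float), 10.0)
    hyd = _const_hydraulics(1e-7, 1e-12)
    K = 0.0
    for i in range(n - 1, -1, -1):
        K = segment_conductance(0.02, 2e-4, 1e-7, 1e-12, K)
    res = compute_krs(sys_chain, hyd, t=10.0)
    assert res.krs == pytest.approx(K, rel=1e-12)


def test_parallel_roots_add_exactly():
    n = 4
    single = RootSystem(np.arange(-1, n - 1), np.zeros(n, int),
                        np.zeros(n, int), np.full(n, 0.03), np.full(n, 2e-4),
                        np.zeros(n), 5.0)
    both = RootSystem(
        np.array([-1, 0, 1, 2, -1, 4, 5, 6]),
        np.array([0, 0, 0, 0, 1, 1, 1, 1]),
        np.zeros(8, int), np.full(8, 0.03), np.full(8, 2e-4),
        np.zeros(8), 5.0)
    hyd = _const_hydraulics(1e-7, 1e-12)
    k1 = compute_krs(single, hyd, t=5.0).krs
    k2 = compute_krs(both, hyd, t=5.0).krs
    assert k2 == pytest.approx(2 * k1, rel=1e-12)


def test_empty_system_zero_conductance():
    res = compute_krs(RootSystem.empty(), _const_hydraulics(1e-7, 1e-12))
    assert res.krs == 0.0 and res.krs_area == 0.0 and res.krs_length == 0.0


def test_segments_created_after_t_are_excluded():
    n = 3
    sys3 = RootSystem(np.arange(-1, n - 1), np.zeros(n, int), np.zeros(n, int),
                      np.full(n, 0.02), np.full(n, 2e-4),
                      np.array([0.0, 1.0, 2.0]), 2.0)
    hyd = _const_hydraulics(1e-7, 1e-12)
    k_2seg = compute_krs(sys3, hyd, t=1.0)
    manual = segment_conductance(0.02, 2e-4, 1e-7, 1e-12,
                                 segment_conductance(0.02, 2e-4, 1e-7, 1e-12, 0.0))
    assert k_2seg.krs == pytest.approx(manual, rel=1e-12)
    assert k_2seg.total_length == pytest.approx(0.04)


def test_random_tree_matches_network_oracle(rng):
    sys30 = random_tree(rng, 30)
    hyd = random_hydraulics(rng)
    analytic = compute_krs(sys30, hyd, t=40.0).krs
    ref = network_oracle(sys30, hyd, t=40.0, nodes_per_segment=1000)
    assert analytic == pytest.approx(ref, rel=1e-6)


def test_oracle_converges_with_discretisation(rng):
    sys10 = random_tree(rng, 10)
    hyd = random_hydraulics(rng)
    analytic = compute_krs(sys10, hyd, t=40.0).krs
    errs = [abs(network_oracle(sys10, hyd, t=40.0, nodes_per_segment=n) - analytic)
            / analytic for n in (10, 100, 1000)]
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-6


def test_oracle_radial_limit_with_huge_kx():
    l, r, kr = 0.05, 2e-4, 1e-7
    sys1 = RootSystem(np.array([-1]), np.array([0]), np.array([0]),
                      np.array([l]), np.array([r]), np.array([0.0]), 1.0)
    K = network_oracle(sys1, _const_hydraulics(kr, 1e-3), nodes_per_segment=200)
    assert K == pytest.approx(TWO_PI * r * l * kr, rel=1e-6)


def test_oracle_zero_kr_closed_tips_gives_zero():
    sys2 = RootSystem(np.array([-1, 0]), np.zeros(2, int), np.zeros(2, int),
                      np.full(2, 0.02), np.full(2, 2e-4), np.zeros(2), 1.0)
    K = network_oracle(sys2, _const_hydraulics(0.0, 1e-12), nodes_per_segment=50)
    assert K == pytest.approx(0.0, abs=1e-20)


# --- trajectories and sensitivity ------------------------------------------

def test_constant_properties_give_monotone_krs_series():
    cp = p.cultivar_params("Tommi")
    traj = simulate_growth(cp, t_end=25.0, dt=0.5, seed=11)
    df = krs_trajectory(traj, _const_hydraulics(1e-7, 2e-12))
    k = df["krs"].to_numpy()
    assert (np.diff(k) >= -1e-18).all()
    assert k[-1] > 0


def test_empty_trajectory_gives_empty_series():
    cp = p.cultivar_params("Tommi")
    traj = simulate_growth(cp, t_end=0.0, dt=0.5, seed=0)
    df = krs_trajectory(traj, _const_hydraulics(1e-7, 2e-12))
    assert len(df) == 1 and df["krs"].iloc[0] == 0.0


def test_sensitivity_identity_and_monotonicity(rng):
    sys30 = random_tree(rng, 30)
    hyd = random_hydraulics(rng)
    base = compute_krs(sys30, hyd, t=40.0).krs
    df = sensitivity_sweep(sys30, hyd, [0.5, 1.0, 2.0], target="kr", t=40.0)
    k = df["krs"].to_numpy()
    assert k[1] == pytest.approx(base, rel=1e-12)
    assert k[0] < k[1] < k[2]
    with pytest.raises(HydraulicInputError):
        sensitivity_sweep(sys30, hyd, [-1.0], t=40.0)


def test_sensitivity_radial_limited_linearity(rng):
    """With kx effectively unlimited, Krs is linear in kr."""
    sys20 = random_tree(rng, 20)
    hyd = random_hydraulics(rng).scaled(kx_factor=1e8)
    k1 = compute_krs(sys20, hyd, t=40.0).krs
    k2 = sensitivity_sweep(sys20, hyd, [2.0], target="kr", t=40.0)["krs"].iloc[0]
    assert k2 == pytest.approx(2 * k1, rel=1e-6)
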