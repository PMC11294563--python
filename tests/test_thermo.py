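"""Equilibrium model: mass action, activities, solver, landscape."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from dimercoop.thermo import (
    DEFAULT_CTOT_SWEEP, ModelParams, compartment_fractions,
    cooperativity_landscape, dimer_partition, equilibrium_sweep,
    invert_activity, reduced_activity, solve_equilibrium,
)

KD_MEM = 10 ** -2.43


# ---------------------------------------------------------------- oracles

def dimer_partition_bisect(c, kd_dim):
    """Independent mass-action oracle: solve 2 c1^2/K + c1 = c by bisection."""
    if c == 0:
        return 0.0, 0.0
    c1 = brentq(lambda x: 2 * x * x / kd_dim + x - c, 0.0, c, xtol=1e-30,
                rtol=1e-15)
    return c1, c - c1


def solve_equilibrium_bisect(params, n=2):
    """Independent equilibrium oracle: nested bracketed root-finding on
    log10(c_c), inverting activities by brentq (no closed forms)."""
    def act(c):
        if c == 0:
            return 0.0
        D = 1 + 4 * c / params.kd_dim + np.sqrt(1 + 8 * c / params.kd_dim)
        return c / np.sqrt(D)

    def inv(a_target):
        if a_target == 0:
            return 0.0
        hi = max(4 * a_target, 8 * a_target ** 2 / params.kd_dim)
        while act(hi) < a_target:
            hi *= 2
        return brentq(lambda c: act(c) - a_target, 0.0, hi, rtol=1e-14)

    def residual(log_cc):
        cc = 10.0 ** log_cc
        a = act(cc)
        tot = cc + params.a * params.psi * inv(a / params.kd_mem)
        if n == 3:
            tot += params.a * params.phi * inv(a / params.kd_int)
        return tot - params.c_tot

    lo, hi = np.log10(params.c_tot) - 12, np.log10(params.c_tot)
    return 10.0 ** brentq(residual, lo, hi, rtol=1e-14)


# ---------------------------------------------------------- dimer partition

@pytest.mark.parametrize("c, kd, expect", [
    (358e-9, 358e-9, (179e-9, 179e-9)),   # c = K forces an even split
    (0.0, 358e-9, (0.0, 0.0)),
    (1e-15, 358e-9, (1e-15, 0.0)),        # dilute limit: all monomer
])
def test_dimer_partition_examples(c, kd, expect):
    c1, c2 = dimer_partition(c, kd)
    assert c1 == pytest.approx(expect[0], rel=1e-9, abs=1e-22)
    assert c2 == pytest.approx(expect[1], rel=1e-9, abs=1e-22)


def test_dimer_partition_matches_bisection_oracle():
    # 0.75 mg/ml of the 9.23 kDa construct is ~81.2 uM; at kd = 358 nM the
    # dimer mass fraction should be ~0.95
    c, kd = 81.2e-6, 358e-9
    c1, c2 = dimer_partition(c, kd)
    o1, o2 = dimer_partition_bisect(c, kd)
    assert c1 == pytest.approx(o1, rel=1e-9)
    assert c2 / c == pytest.approx(0.95, abs=0.01)


@given(st.floats(1e-12, 1e-2), st.floats(1e-9, 1e-3))
@settings(max_examples=200, deadline=None)
def test_dimer_partition_mass_action_invariants(c, kd):
    c1, c2 = dimer_partition(c, kd)
    assert c1 >= 0 and c2 >= 0
    assert c1 + c2 == pytest.approx(c, rel=1e-12)
    if c2 > 1e-30:
        assert c1 ** 2 / (c2 / 2) == pytest.approx(kd, rel=1e-9)


def test_dimer_partition_rejects_negative():
    with pytest.raises(ValueError):
        dimer_partition(-1e-9, 358e-9)
    with pytest.raises(ValueError):
        dimer_partition(1e-9, -358e-9)


# ---------------------------------------------------------- reduced activity

def test_reduced_activity_values_and_limits():
    # direct evaluation at the membrane concentration of polarized zygotes
    assert reduced_activity(47.6e-6, 358e-9) == pytest.approx(2.0e-6, rel=0.01)
    assert reduced_activity(0.0, 358e-9) == 0.0
    # monomer limit: proportional to c (constant sqrt(2) factor, which
    # cancels between compartments)
    c = 10e-9
    assert reduced_activity(c, 1.0) == pytest.approx(c / np.sqrt(2), rel=1e-6)
    # strong-dimer asymptote ~ sqrt(c * kd) / 2
    c, kd = 1e-2, 1e-9
    assert reduced_activity(c, kd) == pytest.approx(np.sqrt(c * kd) / 2, rel=1e-3)


def test_reduced_activity_strictly_increasing_and_invertible():
    kd = 425e-9
    c = np.geomspace(1e-12, 1e-3, 200)
    a = reduced_activity(c, kd)
    assert np.all(np.diff(a) > 0)
    np.testing.assert_allclose(invert_activity(a, kd), c, rtol=1e-12)


# ------------------------------------------------------------- equilibrium

def test_equilibrium_monomer_limit_closed_form():
    # dimerization off: c_c (1 + a psi / kd_mem) = c_tot, c_m = c_c/kd_mem
    p = ModelParams(kd_dim=1.0, kd_mem=KD_MEM, c_tot=27e-9)
    st_ = solve_equilibrium(p)
    cc_expect = 27e-9 / (1 + p.a * p.psi / p.kd_mem)
    assert st_.c_c == pytest.approx(cc_expect, rel=1e-4)
    assert st_.c_m == pytest.approx(st_.c_c / p.kd_mem, rel=1e-4)
    assert st_.c_c == pytest.approx(21.9e-9, rel=0.01)
    assert st_.c_m == pytest.approx(5.9e-6, rel=0.02)


def test_equilibrium_no_membrane_preference():
    p = ModelParams(kd_dim=425e-9, kd_mem=1.0, c_tot=27e-9)
    st_ = solve_equilibrium(p)
    assert st_.c_m == pytest.approx(st_.c_c, rel=1e-9)
    assert st_.c_c == pytest.approx(27e-9, rel=1e-3)  # a*psi << 1


def test_equilibrium_wt_regime_order_of_magnitude():
    # at the fitted constants, ~10 nM cytoplasm maps to tens of uM membrane
    p = ModelParams(kd_dim=425e-9, kd_mem=KD_MEM, c_tot=40e-9)
    st_ = solve_equilibrium(p)
    assert 1e-9 < st_.c_c < 20e-9
    assert 10e-6 < st_.c_m < 100e-6


def test_equilibrium_zero_total_protein():
    p = ModelParams(kd_dim=425e-9, kd_mem=KD_MEM, c_tot=0.0)
    st_ = solve_equilibrium(p)
    assert st_.c_c == st_.c_m == 0.0


def test_equilibrium_matches_bisection_oracle():
    p = ModelParams(kd_dim=425e-9, kd_mem=KD_MEM, c_tot=27e-9)
    assert solve_equilibrium(p).c_c == pytest.approx(
        solve_equilibrium_bisect(p), rel=1e-8)
    p3 = p.with_(kd_int=5 * KD_MEM, phi=0.087e6, psi=0.087e6)
    assert solve_equilibrium(p3, 3).c_c == pytest.approx(
        solve_equilibrium_bisect(p3, 3), rel=1e-8)


def test_conservation_residual_single_sign_change():
    # on a log grid of candidate c_c the conservation residual changes
    # sign exactly once (monotone activities -> unique root)
    p = ModelParams(kd_dim=425e-9, kd_mem=KD_MEM, c_tot=27e-9)
    cc = np.geomspace(27e-9 * 1e-12, 27e-9, 400)
    a = reduced_activity(cc, p.kd_dim)
    resid = cc + p.a * p.psi * invert_activity(a / p.kd_mem, p.kd_dim) - p.c_tot
    assert int((np.sign(resid[1:]) != np.sign(resid[:-1])).sum()) == 1


def test_equilibrium_invariants_random_draws():
    """Conservation, mass action and activity equality on 1000 random
    parameter draws (2- and 3-compartment)."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        three = rng.random() < 0.5
        kd_int = 10 ** rng.uniform(-4, 0) if three else None
        p = ModelParams(
            kd_dim=10 ** rng.uniform(-9, -2),
            kd_mem=10 ** rng.uniform(-5, 0),
            c_tot=10 ** rng.uniform(-10, -7),
            psi=10 ** rng.uniform(4.5, 6.5),
            kd_int=kd_int,
            phi=10 ** rng.uniform(4.5, 6.5) if three else None)
        st_ = solve_equilibrium(p, 3 if three else 2)
        total = st_.c_c + p.a * p.psi * st_.c_m
        if three:
            total += p.a * p.phi * st_.c_n
        assert total == pytest.approx(p.c_tot, rel=1e-9)
        for tot, c1, c2 in [(st_.c_c, st_.c_c_monomer, st_.c_c_dimer),
                            (st_.c_m, st_.c_m_monomer, st_.c_m_dimer)]:
            assert c1 + c2 == pytest.approx(tot, rel=1e-9)
            if c2 > 1e-30:
                assert c1 ** 2 / (c2 / 2) == pytest.approx(p.kd_dim, rel=1e-9)
        lhs = reduced_activity(st_.c_c, p.kd_dim)
        assert lhs == pytest.approx(
            p.kd_mem * reduced_activity(st_.c_m, p.kd_dim), rel=1e-9)
        if three:
            assert lhs == pytest.approx(
                p.kd_int * reduced_activity(st_.c_n, p.kd_dim), rel=1e-9)


# ---------------------------------------------------------------- landscape

def test_landscape_limits_and_shape(wt_params):
    # all-dimer limit must sit far below even the membrane-depleted
    # cytoplasmic concentrations, hence 1e-18 M
    kd_dim = np.geomspace(1e-18, 1e0, 30)
    kd_mem = np.geomspace(1e-4, 1e0, 9)
    alpha = cooperativity_landscape(kd_dim, kd_mem, wt_params)
    # no-dimer and all-dimer rows are linear binders
    np.testing.assert_allclose(alpha[-1, :], 1.0, atol=1e-3)
    np.testing.assert_allclose(alpha[0, :], 1.0, atol=1e-2)
    assert np.all(alpha >= 1.0 - 1e-9)
    assert np.all(alpha <= 2.0 + 1e-6)
    # unimodal in kd_dim at fixed kd_mem: rises then falls
    for j in range(kd_mem.size):
        col = alpha[:, j]
        peak = int(np.argmax(col))
        assert np.all(np.diff(col[:peak + 1]) >= -1e-9)
        assert np.all(np.diff(col[peak:]) <= 1e-9)
    # strong membrane binding at intermediate dimer strength: alpha > 1.5
    assert alpha[:, 0].max() > 1.5
    # peak location moves with kd_mem
    peaks = kd_dim[np.argmax(alpha, axis=0)]
    assert peaks[0] != peaks[-2]


def test_landscape_rejects_nonpositive_grid(wt_params):
    with pytest.raises(ValueError):
        cooperativity_landscape([-1e-9], [0.1], wt_params)


# ----------------------------------------------------- compartment fractions

def _three_params(kd_dim, kd_int_over_mem=5.0, c_tot=27e-9):
    return ModelParams(kd_dim=kd_dim, kd_mem=KD_MEM,
                       kd_int=kd_int_over_mem * KD_MEM, c_tot=c_tot,
                       psi=0.087e6, phi=0.087e6)


def test_fractions_sum_and_symmetric_compartments():
    p = ModelParams(kd_dim=425e-9, kd_mem=KD_MEM, kd_int=KD_MEM,
                    c_tot=27e-9, psi=0.087e6, phi=0.087e6)
    st_ = solve_equilibrium(p, 3)
    f_cyt, f_pm, f_im, ratio = compartment_fractions(st_, p)
    assert f_cyt + f_pm + f_im == pytest.approx(1.0, rel=1e-12)
    assert ratio == pytest.approx(1.0, rel=1e-9)


def test_pm_preference_grows_with_dimer_strength():
    ratios = []
    for kd in [1e-5, 1e-6, 1e-7, 1e-8]:  # decreasing kd_dim = stronger
        p = _three_params(kd)
        ratios.append(compartment_fractions(solve_equilibrium(p, 3), p)[3])
    assert np.all(np.diff(ratios) >= -1e-9)


def test_monomer_limit_ratio_equals_kd_ratio():
    p = _three_params(kd_dim=1.0, c_tot=1e-12)
    f_cyt, f_pm, f_im, ratio = compartment_fractions(solve_equilibrium(p, 3), p)
    assert ratio == pytest.approx(5.0, rel=1e-4)
    assert f_pm / f_im == pytest.approx(5.0, rel=1e-4)


def test_fractions_require_three_compartments(wt_params):
    with pytest.raises(ValueError):
        compartment_fractions(solve_equilibrium(wt_params, 2), wt_params)
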