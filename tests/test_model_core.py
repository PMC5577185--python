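"""Unit and property tests for the closed-form rupture model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from dfsbind import (
    BOLTZMANN,
    BindingEnergy,
    BondModelParams,
    bell_unbinding_rate,
    binding_free_energy,
    coverage_from_energy,
    energy_from_coverage,
    exp_integral_e1,
    mean_rupture_force,
    reduced_loading,
)
from dfsbind.model_core import (
    exp1_scaled,
    rupture_force_pdf,
    rupture_force_quantile,
    rupture_force_survival,
)

from conftest import random_params


class TestBondModelParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BondModelParams(f_eq=-1e-12, x_t=0.3e-9, k_u=1.0)
        with pytest.raises(ValueError):
            BondModelParams(f_eq=0.0, x_t=0.0, k_u=1.0)
        with pytest.raises(ValueError):
            BondModelParams(f_eq=0.0, x_t=0.3e-9, k_u=0.0)
        with pytest.raises(ValueError):
            BondModelParams(f_eq=0.0, x_t=0.3e-9, k_u=1.0, n_bonds=0)
        with pytest.raises(ValueError):
            BondModelParams(f_eq=0.0, x_t=0.3e-9, k_u=1.0, n_bonds=1.5)

    def test_f_beta_recomputed(self, params_a):
        # k_B T / x_t with the exact SI Boltzmann constant
        assert params_a.f_beta == pytest.approx(
            1.380649e-23 * 298.0 / 0.30e-9, rel=1e-12
        )
        assert params_a.f_beta > 0


class TestBellRate:
    def test_zero_force_gives_k_u(self, params_a):
        assert bell_unbinding_rate(params_a, 0.0) == params_a.k_u

    def test_thermal_force_gives_e_fold(self, params_a):
        rate = bell_unbinding_rate(params_a, params_a.f_beta)
        assert rate == pytest.approx(params_a.k_u * math.e, rel=1e-12)

    def test_at_equilibrium_force(self, params_a):
        # independent evaluation of the exponential at f_eq = 50 pN
        expected = math.exp(50e-12 * 0.30e-9 / (BOLTZMANN * 298.0))
        assert bell_unbinding_rate(params_a, 50e-12) == pytest.approx(expected)
        assert bell_unbinding_rate(params_a, 50e-12) == pytest.approx(38.31, rel=1e-3)

    def test_rejects_bad_force(self, params_a):
        with pytest.raises(ValueError):
            bell_unbinding_rate(params_a, float("nan"))
        with pytest.raises(ValueError):
            bell_unbinding_rate(params_a, -1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_strictly_increasing_in_force(self, seed):
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        f = np.sort(rng.uniform(0, 500e-12, size=5))
        rates = bell_unbinding_rate(p, f)
        assert np.all(np.diff(rates) >= 0)


class TestReducedLoading:
    def test_reference_value(self, params_a):
        assert reduced_loading(params_a, 1.0e-9) == pytest.approx(1.903, rel=1e-3)

    def test_zero_f_eq_reduces_to_bare_rate(self):
        p = BondModelParams(f_eq=0.0, x_t=0.3e-9, k_u=2.0, temperature=298.0)
        r = 1e-9
        assert reduced_loading(p, r) == pytest.approx(r / (p.k_u * p.f_beta))

    def test_linear_in_rate(self, params_a):
        assert reduced_loading(params_a, 2e-9) == pytest.approx(
            2 * reduced_loading(params_a, 1e-9)
        )

    def test_rejects_nonpositive_rate(self, params_a):
        with pytest.raises(ValueError):
            reduced_loading(params_a, 0.0)


class TestExpIntegral:
    def test_against_quadrature(self):
        # oracle: adaptive quadrature of the defining integral
        for z in (0.1, 0.52549, 1.0, 3.0):
            oracle = quad(lambda s: math.exp(-s) / s, z, np.inf)[0]
            assert exp_integral_e1(z) == pytest.approx(oracle, rel=1e-8)
        assert exp_integral_e1(1.0) == pytest.approx(0.21938, rel=1e-4)
        assert exp_integral_e1(0.52549) == pytest.approx(0.5300, rel=1e-3)

    def test_asymptotic_limit(self):
        z = 100.0
        assert exp1_scaled(z) == pytest.approx(1 / z, rel=1e-2)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            exp_integral_e1(0.0)
        with pytest.raises(ValueError):
            exp_integral_e1(-1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=-3, max_value=8))
    def test_scaled_sandwich(self, log10z):
        z = 10.0**log10z
        val = exp1_scaled(z)
        assert 1 / (z + 1) < val < 1 / z

    def test_scaled_continuous_across_series_switchover(self):
        z = np.array([699.0, 699.999, 700.001, 701.0])
        vals = exp1_scaled(z)
        assert np.all(np.diff(vals) < 0)
        assert np.allclose(vals * z, 1 - 1 / z, rtol=1e-5)


class TestMeanRuptureForce:
    def test_equilibrium_limit(self, params_a):
        # R < 0.01: the mean sits within 0.01 f_beta of f_eq (plateau)
        r = 0.009 * bell_unbinding_rate(params_a, params_a.f_eq) * params_a.f_beta
        assert reduced_loading(params_a, r) < 0.01
        excess = mean_rupture_force(params_a, r) - params_a.f_eq
        assert 0 < excess < 0.01 * params_a.f_beta

    def test_reference_value_against_density_oracle(self, params_a):
        # oracle: first moment of the rupture-force density by quadrature
        p, r = params_a, 1.0e-9
        R = reduced_loading(p, r)

        def dens(f):
            k = p.k_u * math.exp(f / p.f_beta)
            surv = math.exp(-(math.exp((f - p.f_eq) / p.f_beta) - 1) / R)
            return k / r * surv

        oracle = quad(lambda f: f * dens(f), p.f_eq, p.f_eq + 40 * p.f_beta,
                      limit=200)[0]
        closed = mean_rupture_force(p, r)
        assert closed == pytest.approx(oracle, rel=1e-3)
        assert closed == pytest.approx(62.3e-12, rel=2e-3)

    def test_single_bond_formula_special_case(self, params_a):
        # N = 1 reduces the general expression to f_eq + f_beta e^(1/R) E1(1/R)
        r = 3e-10
        R = reduced_loading(params_a, r)
        direct = params_a.f_eq + params_a.f_beta * exp1_scaled(1 / R)
        assert mean_rupture_force(params_a, r) == pytest.approx(direct, rel=1e-12)

    def test_monotone_in_rate_and_above_f_eq(self, params_a):
        rates = np.geomspace(1e-13, 1e-5, 40)
        means = mean_rupture_force(params_a, rates)
        assert np.all(np.diff(means) >= 0)
        assert np.all(means > params_a.f_eq)

    def test_no_overflow_deep_in_equilibrium(self, params_a):
        # a = 1/R huge: naive exp(a) would overflow
        val = mean_rupture_force(params_a, 1e-15)
        assert np.isfinite(val)
        assert val == pytest.approx(params_a.f_eq, rel=1e-3)

    def test_multibond_exceeds_single_bond(self, params_a):
        p4 = params_a.replace(n_bonds=4)
        assert mean_rupture_force(p4, 1e-9) > mean_rupture_force(params_a, 1e-9)


class TestRuptureDistribution:
    def test_quantile_inverts_survival(self, params_a):
        r = 1e-9
        for q in (0.1, 0.5, 0.9):
            fq = rupture_force_quantile(params_a, r, q)
            assert rupture_force_survival(params_a, r, fq) == pytest.approx(1 - q)
        assert rupture_force_quantile(params_a, r, 0.5) == pytest.approx(
            61.5e-12, rel=1e-3
        )

    def test_pdf_normalised(self, params_a):
        r = 1e-9
        total = quad(
            lambda f: rupture_force_pdf(params_a, r, f),
            params_a.f_eq,
            params_a.f_eq + 40 * params_a.f_beta,
            limit=200,
        )[0]
        assert total == pytest.approx(1.0, rel=1e-6)


class TestBindingFreeEnergy:
    def test_exact_identity_at_unit_argument(self):
        # f_eq x_t = k_B T  =>  dG_b = 2 k_B T exactly under this convention
        T = 298.15
        x_t = 0.3e-9
        f_eq = BOLTZMANN * T / x_t
        dg = binding_free_energy(f_eq, x_t, T)
        assert dg.delta_g_kt == pytest.approx(2.0, abs=1e-12)

    def test_reference_value(self):
        # ln(3.646) + 3.646 + 1 in k_B T units
        dg = binding_free_energy(50e-12, 0.30e-9, 298.0)
        u = 50e-12 * 0.30e-9 / (BOLTZMANN * 298.0)
        assert dg.delta_g_kt == pytest.approx(math.log(u) + u + 1, rel=1e-12)
        assert dg.delta_g_kt == pytest.approx(5.94, abs=5e-3)

    def test_joules_and_kt_consistent(self):
        dg = binding_free_energy(80e-12, 0.5e-9, 300.0)
        assert dg.delta_g == pytest.approx(dg.delta_g_kt * BOLTZMANN * 300.0)

    def test_unit_invariance(self):
        # pN x nm inputs converted to SI give identical energies
        dg_si = binding_free_energy(72e-12, 0.41e-9)
        dg_conv = binding_free_energy(72.0 * 1e-12, 0.41 * 1e-9)
        assert dg_si.delta_g == dg_conv.delta_g

    def test_monotone_in_both_arguments(self):
        base = binding_free_energy(50e-12, 0.3e-9).delta_g
        assert binding_free_energy(60e-12, 0.3e-9).delta_g > base
        assert binding_free_energy(50e-12, 0.4e-9).delta_g > base

    def test_below_detection_raises(self):
        with pytest.raises(ValueError, match="detection"):
            binding_free_energy(0.0, 0.3e-9)


class TestCoverage:
    def test_half_coverage_at_zero_energy(self):
        assert coverage_from_energy(BindingEnergy(0.0), 1.0) == pytest.approx(0.5)

    def test_ninety_percent_coverage_identity(self):
        # theta = 0.9 at unit activity  <=>  dG_b = k_B T ln 9
        dg = energy_from_coverage(0.9, 1.0)
        assert dg.delta_g_kt == pytest.approx(math.log(9.0), rel=1e-12)
        assert dg.delta_g_kt == pytest.approx(2.197, abs=1e-3)
        assert coverage_from_energy(dg, 1.0) == pytest.approx(0.9)

    def test_limits(self):
        kt = BOLTZMANN * 298.15
        assert coverage_from_energy(BindingEnergy(-100 * kt)) < 1e-20
        assert coverage_from_energy(BindingEnergy(100 * kt)) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=-10, max_value=10),
        st.floats(min_value=-10, max_value=10),
    )
    def test_monotone_in_energy(self, g1, g2):
        kt = BOLTZMANN * 298.15
        t1 = coverage_from_energy(BindingEnergy(g1 * kt))
        t2 = coverage_from_energy(BindingEnergy(g2 * kt))
        if g1 <= g2:
            assert t1 <= t2
        else:
            assert t1 >= t2
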