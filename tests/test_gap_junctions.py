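"""Delay-chain kinetics, the Erlang closed form, and the permeability/flux
algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from campnet.gap_junctions import (
    CouplingParams,
    DelayChainParams,
    GJPoolState,
    camp_flux,
    delay_chain_derivatives,
    delay_chain_response,
    effective_permeability,
)


def integrate_chain(p, y0, t_eval, pka_of_t):
    """Numerically integrate the chain ODEs (independent of the closed form)."""

    def rhs(t, y):
        pool = GJPoolState(gj_na=y[0], gj_d=y[1:-1], gj_ca=y[-1])
        d = delay_chain_derivatives(pool, pka_of_t(t), p)
        return np.concatenate(([d.gj_na], d.gj_d, [d.gj_ca]))

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), y0, t_eval=t_eval,
                    method="LSODA", rtol=1e-9, atol=1e-12)
    assert sol.success
    return sol.y


class TestDelayChainDerivatives:
    def test_no_driving_is_stationary(self):
        p = DelayChainParams(gamma_gj=0.0)
        pool = GJPoolState(gj_na=1.0, gj_d=np.zeros(p.n_steps), gj_ca=0.5)
        d = delay_chain_derivatives(pool, 0.0, p)
        assert d.gj_na == 0.0 and d.gj_ca == 0.0
        assert np.all(d.gj_d == 0.0)

    @given(
        na=st.floats(0, 10), ca=st.floats(0, 10),
        pka=st.floats(0, 1),
        d=st.lists(st.floats(0, 10), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_closed_chain_derivatives_sum_to_zero(self, na, ca, pka, d):
        p = DelayChainParams()
        pool = GJPoolState(gj_na=na, gj_d=np.array(d), gj_ca=ca)
        dd = delay_chain_derivatives(pool, pka, p)
        assert abs(dd.gj_na + dd.gj_d.sum() + dd.gj_ca) < 1e-12

    def test_flow_direction_from_inactive_pool(self):
        p = DelayChainParams()
        pool = GJPoolState(gj_na=1.0, gj_d=np.zeros(p.n_steps), gj_ca=0.0)
        d = delay_chain_derivatives(pool, 1.0, p)
        assert d.gj_na < 0 and d.gj_d[0] > 0
        assert np.all(d.gj_d[1:] == 0.0) and d.gj_ca == 0.0

    def test_length_mismatch_is_structural_error(self):
        p = DelayChainParams(n_steps=4)
        pool = GJPoolState(gj_na=1.0, gj_d=np.zeros(3), gj_ca=0.0)
        with pytest.raises(ValueError, match="n_steps"):
            delay_chain_derivatives(pool, 0.5, p)


class TestClosedForm:
    def test_single_step_matches_exponential(self):
        p = DelayChainParams(tau_gj=15.0, n_steps=1, gamma_gj=0.0)
        t = np.linspace(0, 60, 121)
        expected = 1.0 - np.exp(-t / 15.0)
        assert np.allclose(delay_chain_response(p, 1.0, t), expected, atol=1e-12)
        assert delay_chain_response(p, 1.0, 15.0) == pytest.approx(
            1 - np.exp(-1), abs=1e-12
        )

    def test_zero_time_and_negative_time(self):
        for n in (1, 3, 10):
            p = DelayChainParams(n_steps=n, gamma_gj=0.0)
            assert delay_chain_response(p, 1.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            delay_chain_response(DelayChainParams(gamma_gj=0.0), 1.0, -1.0)

    def test_large_n_is_switch_like(self):
        # transit-time sd is tau / sqrt(N): the response sharpens toward a
        # step at tau as N grows
        p = DelayChainParams(tau_gj=15.0, n_steps=2500, gamma_gj=0.0)
        assert delay_chain_response(p, 1.0, 14.5) < 0.05
        assert delay_chain_response(p, 1.0, 15.5) > 0.95
        widths = []
        for n in (4, 40, 400):
            pn = DelayChainParams(tau_gj=15.0, n_steps=n, gamma_gj=0.0)
            widths.append(
                delay_chain_response(pn, 1.0, 15.5)
                - delay_chain_response(pn, 1.0, 14.5)
            )
        assert widths[0] < widths[1] < widths[2]

    @pytest.mark.parametrize("n_steps", [1, 4, 7, 50])
    def test_integrated_chain_matches_closed_form(self, n_steps):
        tau = 15.0
        p = DelayChainParams(tau_gj=tau, n_steps=n_steps, gamma_gj=0.0)
        t = np.linspace(0, 4 * tau, 241)
        y0 = np.zeros(n_steps + 2)
        y0[1] = 1.0  # all mass starts in the first delay step
        y = integrate_chain(p, y0, t, lambda _t: 0.0)
        assert np.max(np.abs(y[-1] - delay_chain_response(p, 1.0, t))) < 1e-4

    def test_activation_time_dispersion_decreases_with_n(self):
        # Erlang(N, N/tau) variance is tau^2 / N: strictly decreasing in N
        tau = 15.0
        t = np.linspace(0, 25 * tau, 20001)
        spreads = []
        for n in (1, 2, 4, 10):
            p = DelayChainParams(tau_gj=tau, n_steps=n, gamma_gj=0.0)
            cdf = delay_chain_response(p, 1.0, t)
            pdf = np.gradient(cdf, t)
            mean = np.trapezoid(t * pdf, t)
            var = np.trapezoid((t - mean) ** 2 * pdf, t)
            spreads.append(var)
            assert var == pytest.approx(tau**2 / n, rel=0.02)
        assert all(a > b for a, b in zip(spreads, spreads[1:]))

    def test_mass_conserved_under_time_varying_drive(self):
        p = DelayChainParams(tau_gj=10.0, n_steps=5, gamma_gj=0.2, k_act=0.7)
        t = np.linspace(0, 100, 201)
        y0 = np.zeros(p.n_steps + 2)
        y0[0] = 1.0
        y = integrate_chain(p, y0, t, lambda tt: 0.5 * (1 + np.sin(0.3 * tt)))
        total = y.sum(axis=0)
        assert np.max(np.abs(total - 1.0)) < 1e-9


class TestPermeabilityAndFlux:
    def test_basal_term_only(self):
        cp = CouplingParams()
        assert effective_permeability(0, 0, 5, 5, cp) == pytest.approx(cp.k_gj)

    def test_no_interface_means_zero(self):
        cp = CouplingParams()
        assert effective_permeability(3.0, 2.0, 5, 4, cp, omega_ij=0) == 0.0

    @given(
        ca_i=st.floats(0, 5), ca_j=st.floats(0, 5),
        p_i=st.integers(1, 8), p_j=st.integers(1, 8),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_under_cell_swap(self, ca_i, ca_j, p_i, p_j):
        cp = CouplingParams()
        a = effective_permeability(ca_i, ca_j, p_i, p_j, cp)
        b = effective_permeability(ca_j, ca_i, p_j, p_i, cp)
        assert a == pytest.approx(b, rel=1e-12)
        assert a >= 0

    def test_degree_zero_is_an_error(self):
        with pytest.raises(ValueError):
            effective_permeability(1.0, 1.0, 0, 5, CouplingParams())

    def test_flux_examples(self):
        assert camp_flux(1.0, 1.0, 0.7) == 0.0
        assert camp_flux(1.0, 2.0, 1.0) == pytest.approx(1.0)

    @given(ci=st.floats(0, 10), cj=st.floats(0, 10), rho=st.floats(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_flux_antisymmetry(self, ci, cj, rho):
        assert camp_flux(ci, cj, rho) == pytest.approx(
            -camp_flux(cj, ci, rho), abs=1e-12
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DelayChainParams(tau_gj=0.0)
        with pytest.raises(ValueError):
            DelayChainParams(n_steps=0)
        with pytest.raises(ValueError):
            camp_flux(1.0, 2.0, -0.1)
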