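"""Spectra, feedback control, and Lyapunov global-stability machinery."""

import numpy as np
import pytest
import sympy as sp
from types import SimpleNamespace

from ffmtumor.model import (EquilibriumKind, StateVector, equilibria,
                            jacobian, reproduction_number)
from ffmtumor.solver import FractionalOrders, SolverConfig, Trajectory, \
    simulate_classical
from ffmtumor.stability import (ControlGains, controlled_spectrum,
                                dfe_spectrum_closed_form,
                                global_stability_scan, lyapunov_terms,
                                spectrum_at)

from conftest import random_params

INFERRED_GAINS = ControlGains(1.0, 0.5038, 3.0, 4.0027, 5.0027, 6.0)


def _dfe(p):
    return [e for e in equilibria(p)
            if e.kind is EquilibriumKind.disease_free][0]


class TestDfeSpectrum:
    def test_reference_closed_forms(self, paper_params):
        rep = dfe_spectrum_closed_form(paper_params)
        got = sorted(rep.eigenvalues.real)
        expected = sorted([-0.04, -3e-4, -0.0486, -3e-4, -0.2400002,
                           -0.0199800])
        np.testing.assert_allclose(got, expected, rtol=1e-4)
        assert rep.verdict == "stable"

    def test_matches_numeric_eigensolver(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            p = random_params(rng)
            cf = dfe_spectrum_closed_form(p).eigenvalues
            num = spectrum_at(_dfe(p), p).eigenvalues
            scale = 1.0 + np.max(np.abs(cf))
            np.testing.assert_allclose(np.sort(cf.real), np.sort(num.real),
                                       atol=1e-10 * scale)

    def test_verdict_iff_r0_below_one_and_slow_tumor(self):
        rng = np.random.default_rng(29)
        for _ in range(60):
            p = random_params(rng)
            rep = dfe_spectrum_closed_form(p)
            should_be_stable = (reproduction_number(p) < 1
                                and p.alpha < p.gamma)
            assert (rep.verdict == "stable") == should_be_stable

    def test_equal_growth_and_kill_rates_are_marginal(self):
        p = SimpleNamespace(alpha=0.1, beta=1e-9, gamma=0.1, phi=1e-7,
                            rho=1e-8, kappa=0.02, mu=480.0, omega=0.24,
                            lam=2e-7, d=3e-4, psi=3e-4, a=0.04)
        rep = dfe_spectrum_closed_form(p)
        assert rep.verdict == "marginal"


class TestControlledSpectrum:
    def test_reference_gains_reproduce_printed_spectrum(self, paper_params):
        # gains inferred by inverting the triangular diagonal closed forms
        rep = controlled_spectrum(_dfe(paper_params), paper_params,
                                  INFERRED_GAINS)
        got = np.round(np.sort(rep.eigenvalues.real), 4)
        np.testing.assert_array_equal(
            got, [-6.04, -5.003, -4.003, -3.24, -1.0486, -0.5238])
        assert rep.verdict == "stable"

    def test_zero_gains_reduce_to_uncontrolled(self, paper_params):
        rep0 = controlled_spectrum(_dfe(paper_params), paper_params,
                                   ControlGains())
        cf = dfe_spectrum_closed_form(paper_params)
        np.testing.assert_allclose(np.sort(rep0.eigenvalues.real),
                                   np.sort(cf.eigenvalues.real), atol=1e-12)

    def test_diagonal_shift_closed_forms_at_dfe(self, paper_params):
        p = paper_params
        g = INFERRED_GAINS
        rep = controlled_spectrum(_dfe(p), p, g)
        expected = sorted([p.alpha - p.gamma - g.w1,
                           p.mu * p.rho / (p.lam + p.omega) - p.kappa - g.w2,
                           -p.lam - p.omega - g.w3, -p.d - g.w4,
                           -p.psi - g.w5, -p.a - g.w6])
        np.testing.assert_allclose(np.sort(rep.eigenvalues.real), expected,
                                   rtol=1e-12)

    def test_gains_never_destabilize_dfe(self, paper_params):
        rng = np.random.default_rng(31)
        base = dfe_spectrum_closed_form(paper_params).max_real
        for _ in range(50):
            g = ControlGains(*rng.uniform(0, 10, size=6))
            rep = controlled_spectrum(_dfe(paper_params), paper_params, g)
            assert rep.max_real <= base + 1e-12

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            ControlGains(w3=-0.1)


@pytest.fixture()
def interior(endemic_params):
    return [e for e in equilibria(endemic_params)
            if e.kind is EquilibriumKind.endemic_interior][0]


class TestLyapunov:
    def test_zero_at_equilibrium(self, endemic_params, interior):
        rec = lyapunov_terms(interior.state, interior, endemic_params)
        assert rec.L == pytest.approx(0.0, abs=1e-12)
        assert rec.Sigma - rec.Omega == pytest.approx(0.0, abs=1e-9)
        assert rec.dL_sign == 0 or abs(rec.Sigma - rec.Omega) < 1e-9

    def test_positive_for_perturbations(self, endemic_params, interior):
        rng = np.random.default_rng(41)
        base = interior.state.as_array()
        for _ in range(100):
            x = base * np.exp(rng.normal(0, 0.3, size=6))
            rec = lyapunov_terms(x, interior, endemic_params)
            assert rec.L > 0

    def test_aggregates_match_symbolic_transcription(self, endemic_params,
                                                     interior):
        # independent second implementation: symbolic term-by-term sums
        T, C, D, I2, I12, Z = sp.symbols("T C D I2 I12 Z", positive=True)
        Ts, Cs, Ds, I2s, I12s, Zs = sp.symbols(
            "Ts Cs Ds I2s I12s Zs", positive=True)
        al, be, ga, ph, ro, ka, mu, om, la, d, ps, a = sp.symbols(
            "al be ga ph ro ka mu om la d ps a", positive=True)
        Sigma_sym = (al * (T - Ts) ** 2 / T + ph * Cs * (T - Ts) ** 2 / T
                     + ph * T * (C - Cs) ** 2 / C + ro * D * (C - Cs) ** 2 / C
                     + mu + ro * Cs * (D - Ds) ** 2 / D
                     + la * D + la * Ds * I2s / I2
                     + d * I2 + d * I2s * I12s / I12
                     + ps * I12 - ps * I12s + ps * I12s * Zs / Z)
        Omega_sym = (al * be * (T - Ts) ** 3 / T + ga * (T - Ts) ** 2 / T
                     + ph * C * (T - Ts) ** 2 / T
                     + ph * Ts * (C - Cs) ** 2 / C
                     + ro * Ds * (C - Cs) ** 2 / C + ka * (C - Cs) ** 2 / C
                     + mu * Ds / D + ro * C * (D - Ds) ** 2 / D
                     + om * (D - Ds) ** 2 / D + la * (D - Ds) ** 2 / D
                     + la * D * I2s / I2 + la * Ds
                     + d * (I2 - I2s) ** 2 / I2 + d * I2s + d * I2 * I12s / I12
                     + ps * (I12 - I12s) ** 2 / I12 + ps * I12 * Zs / Z
                     + a * (Z - Zs) ** 2 / Z)
        p = endemic_params
        xv = interior.state.as_array() * np.array([1.3, 0.8, 1.1, 0.9, 1.2, 1.05])
        subs = dict(zip((T, C, D, I2, I12, Z), xv))
        subs.update(zip((Ts, Cs, Ds, I2s, I12s, Zs),
                        interior.state.as_array()))
        subs.update(zip((al, be, ga, ph, ro, ka, mu, om, la, d, ps, a),
                        [p.alpha, p.beta, p.gamma, p.phi, p.rho, p.kappa,
                         p.mu, p.omega, p.lam, p.d, p.psi, p.a]))
        rec = lyapunov_terms(xv, interior, p)
        assert rec.Sigma == pytest.approx(float(Sigma_sym.subs(subs)),
                                          rel=1e-12)
        assert rec.Omega == pytest.approx(float(Omega_sym.subs(subs)),
                                          rel=1e-12)

    def test_nonpositive_state_is_domain_error(self, endemic_params, interior):
        x = interior.state.as_array().copy()
        x[1] = 0.0
        with pytest.raises(ValueError):
            lyapunov_terms(x, interior, endemic_params)


class TestGlobalStabilityScan:
    def test_constant_trajectory_at_equilibrium(self, endemic_params):
        eq = [e for e in equilibria(endemic_params)
              if e.kind is EquilibriumKind.endemic_interior][0]
        traj = Trajectory(times=np.arange(10.0),
                          states=np.tile(eq.state.as_array(), (10, 1)),
                          orders=FractionalOrders(1, 1))
        rep = global_stability_scan(traj, eq, endemic_params,
                                    keep_records=True)
        assert rep.n_skipped == 0
        assert all(abs(r.Sigma - r.Omega) < 1e-9 for r in rep.records)
        assert all(r.L == rep.records[0].L for r in rep.records)

    def test_lyapunov_decreases_toward_interior_point(self, endemic_params):
        # persistent-immune regime: trajectory started near the interior
        # point relaxes to it and L is non-increasing wherever Sigma < Omega
        eq = [e for e in equilibria(endemic_params)
              if e.kind is EquilibriumKind.endemic_interior][0]
        x0 = StateVector.from_array(
            eq.state.as_array() * np.array([1.2, 0.9, 1.1, 1.05, 0.95, 1.1]))
        traj = simulate_classical(endemic_params, x0,
                                  SolverConfig(dt=0.1, t_end=200.0))
        rep = global_stability_scan(traj, eq, endemic_params)
        assert rep.fraction_L_nonincreasing_where_sigma_lt_omega >= 0.95

    def test_scan_is_deterministic(self, endemic_params):
        eq = [e for e in equilibria(endemic_params)
              if e.kind is EquilibriumKind.endemic_interior][0]
        x0 = StateVector.from_array(eq.state.as_array() * 1.1)
        traj = simulate_classical(endemic_params, x0,
                                  SolverConfig(dt=0.5, t_end=20.0))
        a = global_stability_scan(traj, eq, endemic_params)
        b = global_stability_scan(traj, eq, endemic_params)
        assert a.as_dict() == b.as_dict()

    def test_nonpositive_steps_are_skipped_and_counted(self, endemic_params):
        eq = [e for e in equilibria(endemic_params)
              if e.kind is EquilibriumKind.endemic_interior][0]
        states = np.tile(eq.state.as_array(), (4, 1))
        states[2, 0] = -1.0
        traj = Trajectory(times=np.arange(4.0), states=states,
                          orders=FractionalOrders(1, 1))
        rep = global_stability_scan(traj, eq, endemic_params)
        assert rep.n_skipped == 1


class TestSpectrumAt:
    def test_interior_point_spectrum_is_finite(self, endemic_params):
        eq = [e for e in equilibria(endemic_params)
              if e.kind is EquilibriumKind.endemic_interior][0]
        rep = spectrum_at(eq, endemic_params)
        assert np.all(np.isfinite(rep.eigenvalues))
        assert len(rep.eigenvalues) == 6

    def test_triangular_jacobian_eigenvalues_are_diagonal(self):
        p = SimpleNamespace(alpha=0.5, beta=0.01, gamma=0.1, phi=0.0,
                            rho=0.0, kappa=0.1, mu=1.0, omega=0.1, lam=0.1,
                            d=0.1, psi=0.1, a=0.1)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        J = jacobian(x, p)
        eigs = np.sort(np.linalg.eigvals(J).real)
        np.testing.assert_allclose(eigs, np.sort(np.diag(J)), atol=1e-12)
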