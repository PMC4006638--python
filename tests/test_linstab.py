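import numpy as np
import pytest

from patternlab import linstab as ls
from patternlab.models.brusselator import BrusselatorParams
from patternlab.models.cortical import CorticalParams
from patternlab.reference import GAMMA_I_PROBE


def brusselator_eigs_closed_form(p, q):
    """Quadratic-formula eigenvalues of the 2x2 dispersion matrix (oracle)."""
    a11 = p.B - 1.0 - p.D_X * q * q
    a12 = p.A**2
    a21 = -p.B
    a22 = -p.A**2 - p.D_Y * q * q
    tr, det = a11 + a22, a11 * a22 - a12 * a21
    disc = np.emath.sqrt(tr * tr - 4.0 * det)
    return (tr + disc) / 2.0, (tr - disc) / 2.0


class TestSteadyStates:
    def test_brusselator_closed_form(self):
        p = BrusselatorParams(A=2.0, B=4.8)
        (ss,) = ls.steady_states("brusselator", p)
        assert ss.values == {"X": 2.0, "Y": 2.4}
        assert ss.residual == 0.0

    def test_cortical_roots_in_range_with_tiny_residual(self):
        params = CorticalParams()
        states = ls.steady_states("cortical", params)
        assert len(states) >= 1
        for ss in states:
            assert -90.0 < ss.values["V_e"] < -40.0
            assert ss.residual <= 1e-10
        # deduplicated
        ve = sorted(s.values["V_e"] for s in states)
        assert all(b - a > 1e-6 for a, b in zip(ve, ve[1:]))

    def test_multistable_branch_selection(self):
        params = CorticalParams(rest_offset_psi=False, s_drive=1.0)
        states = ls.steady_states("cortical", params)
        assert len(states) == 3  # low / mid / high firing branches
        low = ls.select_branch(states, branch="low")
        high = ls.select_branch(states, branch="high")
        assert low.values["V_e"] < high.values["V_e"]
        nearest = ls.select_branch(states)  # default: nearest -64 mV
        assert nearest.values["V_e"] == min(
            (s.values["V_e"] for s in states), key=lambda v: abs(v + 64.0))


class TestJacobian:
    def test_brusselator_reaction_jacobian_at_q0(self):
        p = BrusselatorParams(A=2.0, B=4.8)
        (ss,) = ls.steady_states("brusselator", p)
        J = ls.jacobian_at_q("brusselator", p, ss, 0.0)
        np.testing.assert_allclose(J, [[3.8, 4.0], [-4.8, -4.0]], atol=1e-12)

    def test_cortical_jacobian_matches_finite_difference(self):
        # q = 0 Jacobian vs finite differences of the space-free RHS
        from patternlab.grid import GridSpec
        from patternlab.models.cortical import CorticalState, make_cortical_rhs

        params = CorticalParams()
        ss = ls.select_branch(ls.steady_states("cortical", params))
        grid = GridSpec(1, (3,), 1.0)
        rhs = make_cortical_rhs(params, grid)

        def space_free(vec14):
            st = CorticalState(grid)
            for i in range(14):
                st.data[i] = vec14[i]
            return rhs(0.0, st.flatten()).reshape(14, 3)[:, 0]

        x0 = np.array([ss.values["phi_eb"], ss.values["phi_eb"], 0, 0,
                       ss.values["Phi_eb"], ss.values["Phi_eb"],
                       ss.values["Phi_ib"], ss.values["Phi_ib"],
                       0, 0, 0, 0, ss.values["V_e"], ss.values["V_i"]])
        J_fd = np.empty((14, 14))
        for j in range(14):
            # step large enough that the gamma^2-amplified rounding floor
            # of the dendrite rows stays far below the secant change
            h = 1e-6 * (abs(x0[j]) + 1e3)
            dx = np.zeros(14)
            dx[j] = h
            J_fd[:, j] = (space_free(x0 + dx) - space_free(x0 - dx)) / (2 * h)
        J = ls.jacobian_at_q("cortical", params, ss, 0.0)
        np.testing.assert_allclose(J, J_fd, rtol=1e-6, atol=1e-3)

    def test_large_q_damps_diffusive_modes(self):
        # wave and voltage rows are crushed by -q^2; the local dendrite
        # filters carry no diffusion, so the spectrum's ceiling at large q
        # is their -gamma_i eigenvalue
        params = CorticalParams(D2=1.0)
        ss = ls.select_branch(ls.steady_states("cortical", params))
        a_small = np.linalg.eigvals(
            ls.jacobian_at_q("cortical", params, ss, 1.0)).real.max()
        a_big = np.linalg.eigvals(
            ls.jacobian_at_q("cortical", params, ss, 200.0)).real.max()
        assert a_big < a_small
        assert a_big == pytest.approx(-params.gamma_i, rel=1e-6)


class TestDispersion:
    def test_matches_closed_form_everywhere(self, brusselator_turing_params):
        p = brusselator_turing_params
        (ss,) = ls.steady_states("brusselator", p)
        q = np.linspace(0.0, 2.0, 200)
        curve = ls.dispersion("brusselator", p, ss, q)
        for k, qv in enumerate(q):
            lam = brusselator_eigs_closed_form(p, qv)
            dom = max(lam, key=lambda z: (z.real, abs(z.imag)))
            assert curve.alpha[k] == pytest.approx(
                dom.real, rel=1e-9, abs=1e-9)
            assert curve.omega[k] == pytest.approx(
                abs(dom.imag), rel=1e-9, abs=1e-9)

    def test_no_diffusion_flat_dispersion(self):
        p = BrusselatorParams(A=2.0, B=4.8, D_X=0.0, D_Y=0.0)
        (ss,) = ls.steady_states("brusselator", p)
        curve = ls.dispersion("brusselator", p, ss, np.linspace(0, 3, 50))
        assert np.ptp(curve.alpha) < 1e-12
        assert np.ptp(curve.omega) < 1e-12


class TestClassification:
    def test_oscillatory_regime_is_hopf(self, brusselator_hopf_params):
        p = brusselator_hopf_params
        (ss,) = ls.steady_states("brusselator", p)
        curve = ls.dispersion("brusselator", p, ss, np.linspace(0, 3, 256))
        assert ls.classify(curve).label == "Hopf"

    def test_stationary_regime_is_turing(self, brusselator_turing_params):
        p = brusselator_turing_params
        (ss,) = ls.steady_states("brusselator", p)
        curve = ls.dispersion("brusselator", p, ss, np.linspace(0, 3, 256))
        lab = ls.classify(curve)
        assert lab.label == "Turing"
        assert lab.q_critical > 0
        assert lab.frequency_hz == 0.0

    def test_label_invariant_under_grid_refinement(
            self, brusselator_turing_params):
        p = brusselator_turing_params
        (ss,) = ls.steady_states("brusselator", p)
        labels = set()
        for n in (200, 400, 800):
            curve = ls.dispersion("brusselator", p, ss,
                                  np.linspace(0, 3, n))
            labels.add(ls.classify(curve).label)
        assert labels == {"Turing"}

    def test_cortical_mixed_regime_is_turing_hopf(self, reference_setup):
        params, ss = reference_setup
        params = params.with_(gamma_i=GAMMA_I_PROBE, D2=1.0)
        curve = ls.dispersion("cortical", params, ss,
                              np.linspace(0.0, 6.0, 256))
        lab = ls.classify(curve)
        assert lab.label == "Turing-Hopf"
        assert lab.q_critical > 0
        assert lab.frequency_hz > 0

    def test_below_both_onsets_is_stable(self, reference_record):
        params = reference_record.params(
            gamma_i=70.0, D2=0.5 * reference_record.D2_turing)
        ss = min(ls.steady_states("cortical", params),
                 key=lambda s: abs(s.values["V_e"] - reference_record.branch_Ve))
        curve = ls.dispersion("cortical", params, ss,
                              np.linspace(0.0, 6.0, 256))
        assert ls.classify(curve).label == "stable"


class TestCriticalValue:
    def test_brusselator_hopf_threshold_closed_form(self):
        p = BrusselatorParams(A=2.0, B=2.0, D_X=2.0, D_Y=10.0)
        bc = ls.critical_value("brusselator", p, "B", "hopf_q0",
                               bracket=(1.5, 12.0), tol=1e-8)
        assert bc == pytest.approx(1.0 + 4.0, abs=1e-6)

    def test_brusselator_turing_threshold_closed_form(self):
        p = BrusselatorParams(A=2.0, B=2.0, D_X=2.0, D_Y=10.0)
        bc = ls.critical_value("brusselator", p, "B", "turing_qne0",
                               bracket=(1.0, 8.0), tol=1e-8)
        assert bc == pytest.approx(ls.brusselator_turing_threshold(p),
                                   abs=1e-5)

    def test_random_draws_match_closed_forms(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = rng.uniform(1.0, 4.0)
            dx = rng.uniform(1.0, 8.0)
            dy = dx * rng.uniform(2.0, 6.0)
            p = BrusselatorParams(A=A, B=2.0, D_X=dx, D_Y=dy)
            b_h = 1.0 + A * A
            b_t = ls.brusselator_turing_threshold(p)
            num_h = ls.critical_value("brusselator", p, "B", "hopf_q0",
                                      (0.3 * b_h, 2.5 * b_h), tol=1e-8)
            num_t = ls.critical_value("brusselator", p, "B", "turing_qne0",
                                      (0.3 * b_t, 2.5 * b_t), tol=1e-8)
            assert num_h == pytest.approx(b_h, rel=1e-6)
            assert num_t == pytest.approx(b_t, rel=1e-5)

    def test_no_sign_change_reports_endpoints(self):
        p = BrusselatorParams(A=2.0, B=2.0, D_X=2.0, D_Y=10.0)
        with pytest.raises(ValueError, match="g\\("):
            ls.critical_value("brusselator", p, "B", "hopf_q0",
                              bracket=(1.1, 2.0))

    def test_cortical_turing_onset_in_D2(self, reference_record,
                                         reference_setup):
        params, ss = reference_setup
        params = params.with_(gamma_i=GAMMA_I_PROBE)
        d2c = ls.critical_value(
            "cortical", params, "D2", "turing_qne0", bracket=(0.05, 3.0),
            tol=1e-5, near_Ve=reference_record.branch_Ve)
        assert d2c == pytest.approx(reference_record.D2_turing, abs=1e-3)
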