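import numpy as np
import pytest
from scipy.integrate import solve_ivp

from patternlab.grid import GridSpec, laplacian
from patternlab.integrators import integrate_fixed
from patternlab.models.brusselator import (
    BrusselatorParams,
    brusselator_rhs,
    brusselator_steady_state,
    make_brusselator_rhs,
)
from patternlab.models.cortical import (
    CORTICAL_COMPONENTS,
    CorticalParams,
    CorticalState,
    alpha_response,
    cortical_noise_spec,
    firing_rate,
    firing_rate_deriv,
    make_cortical_rhs,
    psi_weight,
    subcortical_drive,
)
from patternlab.models.vanderpol import VanDerPolParams, vdp_rhs


class TestVanDerPol:
    def test_direct_substitution(self):
        assert vdp_rhs((2.0, 0.0), VanDerPolParams(mu=1.0)) == (0.0, -2.0)
        assert vdp_rhs((0.0, 0.0), VanDerPolParams(mu=1.0)) == (0.0, 0.0)

    def test_limit_cycle_amplitude(self):
        # independent oracle: SciPy adaptive integration of the plain ODE
        sol = solve_ivp(
            lambda t, y: [y[1], (1 - y[0] ** 2) * y[1] - y[0]],
            (0.0, 60.0), [2.0, 0.0], rtol=1e-10, atol=1e-12,
            dense_output=True,
        )
        t = np.linspace(30.0, 60.0, 20000)
        amp = np.max(np.abs(sol.sol(t)[0]))
        assert amp == pytest.approx(2.0086, abs=2e-3)


class TestBrusselator:
    def test_steady_state_zeroes_rhs(self, grid1d):
        p = BrusselatorParams(A=2.0, B=4.8, D_X=2.0, D_Y=10.0)
        assert brusselator_steady_state(p) == (2.0, 2.4)
        X = np.full(grid1d.shape, 2.0)
        Y = np.full(grid1d.shape, 2.4)
        dX, dY = brusselator_rhs(X, Y, p, grid1d)
        np.testing.assert_allclose(dX, 0.0, atol=1e-12)
        np.testing.assert_allclose(dY, 0.0, atol=1e-12)

    def test_uniform_fields_feel_no_diffusion(self, grid1d):
        p0 = BrusselatorParams(A=2.0, B=4.8, D_X=0.0, D_Y=0.0)
        p1 = BrusselatorParams(A=2.0, B=4.8, D_X=50.0, D_Y=80.0)
        X = np.full(grid1d.shape, 1.3)
        Y = np.full(grid1d.shape, 0.7)
        for a, b in zip(brusselator_rhs(X, Y, p0, grid1d),
                        brusselator_rhs(X, Y, p1, grid1d)):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_subthreshold_perturbations_decay(self, grid1d, rng):
        # B below both the Hopf (1 + A^2 = 5) and Turing thresholds
        p = BrusselatorParams(A=2.0, B=3.0, D_X=2.0, D_Y=10.0)
        rhs = make_brusselator_rhs(p, grid1d)
        X0, Y0 = brusselator_steady_state(p)
        flat = np.concatenate([np.full(60, X0), np.full(60, Y0)])
        flat += 0.05 * rng.standard_normal(flat.shape)
        traj = integrate_fixed(rhs, flat, (0.0, 20.0), 0.005, "rk4",
                               save_every=800)
        dev0 = np.max(np.abs(traj.states[0] - np.concatenate(
            [np.full(60, X0), np.full(60, Y0)])))
        dev1 = np.max(np.abs(traj.states[-1] - np.concatenate(
            [np.full(60, X0), np.full(60, Y0)])))
        assert dev1 < 0.05 * dev0

    def test_turing_regime_freezes_spatially(self, grid1d,
                                             brusselator_turing_params, rng):
        p = brusselator_turing_params
        rhs = make_brusselator_rhs(p, grid1d)
        X0, Y0 = brusselator_steady_state(p)
        flat = np.concatenate([np.full(60, X0), np.full(60, Y0)])
        flat += 0.01 * rng.standard_normal(flat.shape)
        traj = integrate_fixed(rhs, flat, (0.0, 30.0), 0.005, "rk4",
                               save_every=200)
        late = traj.states[-6:, :60]
        spatial_var = np.var(late[-1])
        temporal_var = np.mean(np.var(late, axis=0))
        assert spatial_var > 0.1            # a structure has formed
        assert temporal_var < 0.01 * spatial_var  # and it is frozen


class TestFiringRate:
    def test_half_maximum_at_threshold(self):
        p = CorticalParams()
        assert firing_rate(-58.5, "e", p) == pytest.approx(15.0, abs=1e-12)

    def test_sigmoid_limits_and_monotonicity(self):
        p = CorticalParams()
        assert firing_rate(-1e3, "e", p) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(1e3, "e", p) == pytest.approx(30.0, abs=1e-12)
        V = np.linspace(-90, -30, 200)
        assert np.all(np.diff(firing_rate(V, "i", p)) > 0)

    def test_one_sigma_above_threshold(self):
        # independent arithmetic: Q = 30 / (1 + exp(-pi/sqrt(3)))
        p = CorticalParams()
        expected = 30.0 / (1.0 + np.exp(-np.pi / np.sqrt(3.0)))
        assert firing_rate(-55.5, "e", p) == pytest.approx(expected, rel=1e-12)

    def test_analytic_derivative_matches_finite_difference(self):
        p = CorticalParams()
        V = np.array([-70.0, -58.5, -50.0])
        fd = (firing_rate(V + 1e-6, "e", p) - firing_rate(V - 1e-6, "e", p)) / 2e-6
        np.testing.assert_allclose(firing_rate_deriv(V, "e", p), fd, rtol=1e-8)


class TestAlphaResponse:
    @pytest.mark.parametrize("gamma,peak", [(58.6, 0.017), (25.0, 0.04)])
    def test_peak_time_is_inverse_gamma(self, gamma, peak):
        t = np.linspace(0.0, 0.2, 200001)
        H = alpha_response(t, gamma)
        t_peak = t[np.argmax(H)]
        assert round(t_peak, 3) == pytest.approx(round(1.0 / gamma, 3))
        # reported to two significant figures
        assert float(f"{t_peak:.2g}") == peak

    def test_value_at_origin_and_peak(self):
        gamma = 40.0
        assert alpha_response(0.0, gamma) == 0.0
        assert alpha_response(1.0 / gamma, gamma) == pytest.approx(
            gamma / np.e, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            alpha_response(-0.1, 25.0)


class TestPsiWeight:
    def test_unity_at_rest_zero_at_reversal(self):
        p = CorticalParams()
        assert psi_weight(p.psi_rest("e"), "e", "e", p) == pytest.approx(1.0)
        assert psi_weight(p.Vrev_i, "i", "e", p) == pytest.approx(0.0)

    def test_inhibitory_weight_falls_toward_reversal(self):
        p = CorticalParams()
        V = np.linspace(-60.0, -69.0, 10)  # falling toward V_i^rev = -70
        psi = psi_weight(V, "i", "i", p)
        assert np.all(np.diff(psi) < 0)

    def test_degenerate_denominator_rejected_at_load(self):
        with pytest.raises(ValueError, match="degenerate"):
            CorticalParams(Vrev_i=-64.0, dVrest_i=0.0)


class TestSubcorticalDrive:
    def test_dc_level(self):
        p = CorticalParams(noise_amp=0.0)
        grid = GridSpec(2, (4, 4), 1.0)
        out = subcortical_drive(0.0, p, grid)
        np.testing.assert_array_equal(out, np.full((4, 4), 300.0))

    def test_kick_is_off_after_first_step(self, rng):
        p = CorticalParams(noise_amp=1.0, noise_mode="kick")
        grid = GridSpec(1, (8,), 1.0)
        kicked = subcortical_drive(0.0, p, grid, rng=rng, step=1)
        assert np.std(kicked) > 0
        quiet = subcortical_drive(0.1, p, grid, rng=rng, step=2)
        np.testing.assert_array_equal(quiet, np.full(8, 300.0))

    def test_negative_scale_factor_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            CorticalParams(s_drive=-0.5)


class TestCorticalRHS:
    def test_steady_state_zeroes_rhs(self, reference_setup):
        params, ss = reference_setup
        grid = GridSpec(2, (6, 6), 0.5)
        state = CorticalState.homogeneous(grid, params, ss.values["V_e"],
                                          ss.values["V_i"])
        rhs = make_cortical_rhs(params, grid)
        deriv = np.abs(rhs(0.0, state.flatten()))
        scale = np.abs(state.flatten()) + 1.0
        assert np.max(deriv / scale) < 1e-9

    def test_uniform_state_reduces_to_space_free(self):
        params = CorticalParams()
        grid = GridSpec(1, (12,), 0.5)
        state = CorticalState.homogeneous(grid, params, -60.0, -62.0)
        nodiff = make_cortical_rhs(
            params.with_(D2=0.0, D1=0.0), grid)(0.0, state.flatten())
        withdiff = make_cortical_rhs(params, grid)(0.0, state.flatten())
        np.testing.assert_allclose(withdiff, nodiff, atol=1e-12)

    def test_translation_equivariance(self, rng):
        params = CorticalParams()
        grid = GridSpec(2, (8, 8), 0.5)
        flat = CorticalState.homogeneous(grid, params, -60.0, -62.0).flatten()
        flat = flat * (1.0 + 0.01 * rng.standard_normal(flat.shape))
        rhs = make_cortical_rhs(params, grid)
        rolled = flat.reshape(14, 8, 8)
        rolled = np.roll(rolled, (2, -3), axis=(1, 2)).ravel()
        a = rhs(0.0, rolled).reshape(14, 8, 8)
        b = np.roll(rhs(0.0, flat).reshape(14, 8, 8), (2, -3), axis=(1, 2))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_wave_subsystem_relaxes_to_source(self):
        # with Q_e held by clamping voltages, phi_eb -> Q_e at long times
        params = CorticalParams()
        grid = GridSpec(1, (8,), 1.0)
        state = CorticalState.homogeneous(grid, params, -60.0, -62.0)
        qe = state["phi_ee"][0]
        state["phi_ee"] = 0.0  # displace the wave field
        rhs = make_cortical_rhs(params, grid)

        layout = state.layout

        def frozen_rhs(t, flat):
            d = rhs(t, flat).copy()
            for name in CORTICAL_COMPONENTS[4:]:  # clamp all but the waves
                d[layout.slice_of(name)] = 0.0
            return d

        traj = integrate_fixed(frozen_rhs, state.flatten(), (0.0, 0.1),
                               1e-5, "rk4", save_every=10**6)
        final = CorticalState.from_flat(traj.states[-1], grid)
        np.testing.assert_allclose(final["phi_ee"], qe, rtol=1e-6)

    def test_stable_point_decays_back(self, reference_record):
        # below the Turing onset and above the Hopf crossing the perturbed
        # homogeneous state relaxes (matching the LSA prediction)
        from patternlab.linstab import steady_states

        params = reference_record.params(
            gamma_i=70.0, D2=0.5 * reference_record.D2_turing)
        ss = min(steady_states("cortical", params),
                 key=lambda s: abs(s.values["V_e"] - reference_record.branch_Ve))
        grid = GridSpec(2, (12, 12), 1.0 / 3.0)
        state = CorticalState.homogeneous(grid, params, ss.values["V_e"],
                                          ss.values["V_i"])
        base = state.flatten()
        rng = np.random.default_rng(3)
        layout = state.layout
        pert = base.copy()
        for name in ("V_e", "V_i"):
            sl = layout.slice_of(name)
            pert[sl] += 0.5 * rng.standard_normal(grid.nnodes)
        rhs = make_cortical_rhs(params, grid)
        traj = integrate_fixed(rhs, pert, (0.0, 5.0), 4e-4, "rk4",
                               save_every=2500)
        sl = layout.slice_of("V_e")
        dev = [np.max(np.abs(s[sl] - base[sl])) for s in traj.states]
        assert dev[-1] < 0.05 * dev[0]

    def test_noise_spec_targets_excitatory_dendrites(self):
        params = CorticalParams(noise_amp=0.5, noise_mode="continuous")
        grid = GridSpec(1, (6,), 1.0)
        spec = cortical_noise_spec(params, grid)
        layout = CorticalState(grid).layout
        mask = np.zeros(layout.size, dtype=bool)
        mask[layout.slice_of("Psi_ee")] = True
        mask[layout.slice_of("Psi_ei")] = True
        assert np.all(spec.scale[mask] > 0)
        assert np.all(spec.scale[~mask] == 0)

    def test_state_flatten_roundtrip(self, rng):
        grid = GridSpec(2, (5, 7), 1.0)
        data = rng.standard_normal((14, 5, 7))
        st = CorticalState(grid, data)
        back = CorticalState.from_flat(st.flatten(), grid)
        np.testing.assert_array_equal(back.data, data)
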