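"""Linear stability analysis: steady states, dispersion curves, instability
classification and critical-parameter bisection.

The homogeneous steady state of a model is linearised in Fourier space by the
substitution lap -> -q^2 (continuous convention; the discrete circulant
eigenvalue -(2-2cos(qh))/h^2 is available for reconciling coarse-grid
simulations).  The dominant eigenvalue sigma_q = alpha(q) + i omega(q) of the
resulting wavenumber-dependent Jacobian decides stability: alpha > 0 grows,
omega/2pi is the oscillation frequency.  Four instability classes follow from
the sign pattern: Turing (stationary, finite q), Hopf (oscillatory, q = 0),
mixed Turing-Hopf, and wave (oscillatory at finite q).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, fsolve

from .grid import laplacian_symbol
from .models.brusselator import (
    BrusselatorParams,
    brusselator_steady_state,
    reaction_jacobian,
)
from .models.cortical import (
    CORTICAL_COMPONENTS,
    CorticalParams,
    firing_rate,
    firing_rate_deriv,
    psi_weight,
    psi_weight_deriv,
)

#: classification thresholds (the theory supplies none)
TOL_OMEGA = 1e-6   # rad/s
TOL_ALPHA = 1e-8   # s^-1

#: tolerance for treating a mode as stationary when taking the Turing maximum
_STATIONARY_OMEGA = 1e-2  # rad/s


@dataclass
class SteadyState:
    """A homogeneous fixed point of the space-free dynamics."""

    model: str
    values: dict
    residual: float

    def vector(self) -> np.ndarray:
        if self.model == "brusselator":
            return np.array([self.values["X"], self.values["Y"]])
        return np.array([self.values["V_e"], self.values["V_i"]])


@dataclass
class DispersionCurve:
    """Dominant eigenvalue vs wavenumber, plus the stationary-mode envelope."""

    q: np.ndarray          # rad/cm
    alpha: np.ndarray      # s^-1, real part of dominant eigenvalue
    omega: np.ndarray      # rad/s, |imaginary part| of dominant eigenvalue
    alpha_stat: np.ndarray  # max real part over (near-)stationary modes
    steady_state: SteadyState | None = None


@dataclass
class InstabilityLabel:
    label: str             # stable | Turing | Hopf | Turing-Hopf | wave
    q_critical: float      # rad/cm
    frequency_hz: float    # omega(q*)/2pi


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def _cortical_reduced_residual(params: CorticalParams, V: np.ndarray) -> np.ndarray:
    """Residual of the two coupled soma fixed-point equations in (V_e, V_i)."""
    Ve, Vi = V
    qe = firing_rate(Ve, "e", params)
    qi = firing_rate(Vi, "i", params)
    Phi_eb = (params.N_alpha_eb + params.N_beta_eb) * qe + params.drive_dc
    Phi_ib = params.N_beta_ib * qi
    r_e = (params.soma_rest("e") - Ve
           + params.rho_e * psi_weight(Ve, "e", "e", params) * Phi_eb
           + params.rho_i * psi_weight(Ve, "i", "e", params) * Phi_ib)
    r_i = (params.soma_rest("i") - Vi
           + params.rho_e * psi_weight(Vi, "e", "i", params) * Phi_eb
           + params.rho_i * psi_weight(Vi, "i", "i", params) * Phi_ib)
    return np.array([r_e, r_i])


def _cortical_state_values(params: CorticalParams, Ve: float, Vi: float) -> dict:
    qe = float(firing_rate(Ve, "e", params))
    qi = float(firing_rate(Vi, "i", params))
    return {
        "V_e": Ve,
        "V_i": Vi,
        "Q_e": qe,
        "Q_i": qi,
        "phi_eb": qe,
        "Phi_eb": params.N_alpha_eb * qe + params.N_beta_eb * qe + params.drive_dc,
        "Phi_ib": params.N_beta_ib * qi,
    }


def _cortical_residual_norm(params: CorticalParams, Ve: float, Vi: float) -> float:
    """Scaled residual of the full space-free 14-component RHS."""
    from .grid import GridSpec
    from .models.cortical import CorticalState, make_cortical_rhs

    grid = GridSpec(ndim=1, npoints=(3,), spacing=1.0)
    state = CorticalState.homogeneous(grid, params, Ve, Vi)
    rhs = make_cortical_rhs(params, grid)
    deriv = np.abs(rhs(0.0, state.flatten()))
    scale = np.abs(state.flatten()) + 1.0
    return float(np.max(deriv / scale))


def steady_states(model: str, params, guess_grid=None) -> list[SteadyState]:
    """All distinct homogeneous steady states, deduplicated at 1e-6.

    The Brusselator fixed point is closed-form, (X*, Y*) = (A, B/A).  The
    cortical fixed points are found by a multi-start Newton solve of the two
    reduced soma equations over a lattice of voltage guesses (default
    V in [-90, -40] mV); the model family is multistable, so every converged
    branch is returned, sorted by ascending V_e.
    """
    if model == "brusselator":
        X, Y = brusselator_steady_state(params)
        return [SteadyState("brusselator", {"X": X, "Y": Y}, 0.0)]
    if model != "cortical":
        raise ValueError(f"unknown model {model!r}")

    if guess_grid is None:
        guess_grid = np.linspace(-90.0, -40.0, 8)

    def _newton_polish(V: np.ndarray) -> np.ndarray:
        # drive the reduced residual to machine precision
        for _ in range(6):
            r = _cortical_reduced_residual(params, V)
            if np.max(np.abs(r)) < 1e-13:
                break
            eps = 1e-7
            J = np.empty((2, 2))
            for j in range(2):
                dV = np.zeros(2)
                dV[j] = eps
                J[:, j] = (_cortical_reduced_residual(params, V + dV)
                           - _cortical_reduced_residual(params, V - dV)) / (2 * eps)
            V = V - np.linalg.solve(J, r)
        return V

    roots: list[np.ndarray] = []
    for g0 in guess_grid:
        for g1 in guess_grid:
            sol, _info, ier, _msg = fsolve(
                lambda V: _cortical_reduced_residual(params, V),
                [g0, g1], full_output=True, xtol=1e-13,
            )
            if ier != 1:
                continue
            sol = _newton_polish(sol)
            if np.max(np.abs(_cortical_reduced_residual(params, sol))) > 1e-11:
                continue
            if not any(np.max(np.abs(sol - r)) < 1e-6 for r in roots):
                roots.append(sol)
    if not roots:
        raise RuntimeError(
            "no cortical steady state converged; widen the guess grid"
        )
    roots.sort(key=lambda r: r[0])
    out = []
    for r in roots:
        res = _cortical_residual_norm(params, r[0], r[1])
        out.append(
            SteadyState("cortical", _cortical_state_values(params, r[0], r[1]), res)
        )
    return out


def select_branch(states: list[SteadyState], near_Ve: float | None = None,
                  branch: str | None = None) -> SteadyState:
    """Pick one steady-state branch: nearest to a voltage, or by position.

    ``branch`` may be "low", "high" or "mid" (by V_e); default is the root
    nearest V_e = -64 mV.
    """
    if branch is not None:
        order = sorted(states, key=lambda s: s.values.get("V_e", 0.0))
        return {"low": order[0], "high": order[-1],
                "mid": order[len(order) // 2]}[branch]
    target = -64.0 if near_Ve is None else near_Ve
    return min(states, key=lambda s: abs(s.values.get("V_e", 0.0) - target))


# ---------------------------------------------------------------------------
# Fourier-space Jacobians
# ---------------------------------------------------------------------------

def _lap_eig(q: float, spacing: float | None) -> float:
    """Fourier symbol of the Laplacian: -q^2, or the discrete circulant
    eigenvalue when a grid spacing is supplied."""
    if spacing is None:
        return -q * q
    return float(laplacian_symbol(np.asarray(q), spacing))


def jacobian_at_q(model: str, params, ss: SteadyState, q: float,
                  spacing: float | None = None) -> np.ndarray:
    """Jacobian of the linearised dynamics at wavenumber q (rad/cm).

    Brusselator: 2x2 reaction Jacobian minus diag(D_X, D_Y) q^2.  Cortical:
    14x14 over the state layout, with v^2 lap -> v^2 L(q) in the wave rows
    and D_bb lap / tau_b in the voltage rows, and analytic sigmoid / psi
    derivatives.
    """
    L = _lap_eig(q, spacing)
    if model == "brusselator":
        J = reaction_jacobian(params).astype(float)
        J[0, 0] += params.D_X * L
        J[1, 1] += params.D_Y * L
        return J
    if model != "cortical":
        raise ValueError(f"unknown model {model!r}")

    p: CorticalParams = params
    Ve, Vi = ss.values["V_e"], ss.values["V_i"]
    Phi_eb, Phi_ib = ss.values["Phi_eb"], ss.values["Phi_ib"]
    dQe = float(firing_rate_deriv(Ve, "e", p))
    dQi = float(firing_rate_deriv(Vi, "i", p))
    idx = {name: k for k, name in enumerate(CORTICAL_COMPONENTS)}
    vL = p.v_axon * p.Lambda_eb
    ge, gi = p.gamma_e, p.gamma_i
    J = np.zeros((14, 14))
    for phi, chi in (("phi_ee", "chi_ee"), ("phi_ei", "chi_ei")):
        J[idx[phi], idx[chi]] = 1.0
        J[idx[chi], idx[phi]] = p.v_axon**2 * L - vL**2
        J[idx[chi], idx[chi]] = -2.0 * vL
        J[idx[chi], idx["V_e"]] = vL**2 * dQe
    for Phi, Psi in (("Phi_ee", "Psi_ee"), ("Phi_ei", "Psi_ei"),
                     ("Phi_ie", "Psi_ie"), ("Phi_ii", "Psi_ii")):
        J[idx[Phi], idx[Psi]] = 1.0
    for Phi, Psi, phi in (("Phi_ee", "Psi_ee", "phi_ee"),
                          ("Phi_ei", "Psi_ei", "phi_ei")):
        J[idx[Psi], idx[Psi]] = -2.0 * ge
        J[idx[Psi], idx[Phi]] = -ge * ge
        J[idx[Psi], idx[phi]] = ge * ge * p.N_alpha_eb
        J[idx[Psi], idx["V_e"]] = ge * ge * p.N_beta_eb * dQe
    for Phi, Psi in (("Phi_ie", "Psi_ie"), ("Phi_ii", "Psi_ii")):
        J[idx[Psi], idx[Psi]] = -2.0 * gi
        J[idx[Psi], idx[Phi]] = -gi * gi
        J[idx[Psi], idx["V_i"]] = gi * gi * p.N_beta_ib * dQi
    for b, (Phi_e, Phi_i, D, tau, Phi_eb_val, Phi_ib_val, V) in {
        "e": ("Phi_ee", "Phi_ie", p.D1_eff, p.tau_e, Phi_eb, Phi_ib, Ve),
        "i": ("Phi_ei", "Phi_ii", p.D2, p.tau_i, Phi_eb, Phi_ib, Vi),
    }.items():
        row = idx[f"V_{b}"]
        J[row, idx[Phi_e]] = p.rho_e * float(psi_weight(V, "e", b, p)) / tau
        J[row, idx[Phi_i]] = p.rho_i * float(psi_weight(V, "i", b, p)) / tau
        diff = D * L if p.diffusion_in_tau else D * L * tau
        J[row, row] = (
            -1.0
            + p.rho_e * Phi_eb_val * psi_weight_deriv("e", b, p)
            + p.rho_i * Phi_ib_val * psi_weight_deriv("i", b, p)
            + diff
        ) / tau
    return J


# ---------------------------------------------------------------------------
# dispersion and classification
# ---------------------------------------------------------------------------

def _dominant(eigvals: np.ndarray) -> complex:
    """Maximal real part; ties broken toward larger |omega|."""
    order = np.lexsort((-np.abs(eigvals.imag), -eigvals.real))
    return eigvals[order[0]]


def dispersion(model: str, params, ss: SteadyState, q_grid,
               spacing: float | None = None) -> DispersionCurve:
    """Dominant eigenvalue sigma_q = alpha + i omega over a wavenumber grid.

    ``alpha_stat`` records at each q the largest real part among
    (near-)stationary eigenvalues (|omega| below a small threshold), which is
    the quantity bisected for Turing onsets; -inf when no stationary mode
    exists at that q.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    alpha = np.empty_like(q_grid)
    omega = np.empty_like(q_grid)
    alpha_stat = np.full_like(q_grid, -np.inf)
    for k, q in enumerate(q_grid):
        try:
            ev = np.linalg.eigvals(jacobian_at_q(model, params, ss, q, spacing))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            J = jacobian_at_q(model, params, ss, q, spacing)
            raise RuntimeError(
                f"eigenvalue solve failed at q={q} "
                f"(condition ~{np.linalg.cond(J):.2e})"
            ) from exc
        dom = _dominant(ev)
        alpha[k] = dom.real
        omega[k] = abs(dom.imag)
        stat = ev[np.abs(ev.imag) < _STATIONARY_OMEGA]
        if stat.size:
            alpha_stat[k] = stat.real.max()
    return DispersionCurve(q=q_grid, alpha=alpha, omega=omega,
                           alpha_stat=alpha_stat, steady_state=ss)


def classify(curve: DispersionCurve, tol_omega: float = TOL_OMEGA,
             tol_alpha: float = TOL_ALPHA) -> InstabilityLabel:
    """Label the dispersion curve with its instability class.

    Hopf: excitation at q = 0 with nonzero frequency and no excited
    stationary finite-q mode.  Turing: excited stationary mode at finite q
    with a stable q = 0.  Both together: Turing-Hopf.  Wave: the oscillatory
    growth rate peaks at finite q above its q = 0 value.
    """
    if curve.q[0] != 0.0:
        raise ValueError("q_grid must include q = 0")
    a0, w0 = curve.alpha[0], curve.omega[0]
    hopf = (a0 > -tol_alpha) and (w0 > tol_omega)

    finite = curve.q > 0
    a_stat = curve.alpha_stat[finite]
    turing = a_stat.size > 0 and np.nanmax(a_stat) > -tol_alpha
    q_turing = 0.0
    if turing:
        qf = curve.q[finite]
        q_turing = float(qf[np.nanargmax(a_stat)])

    osc = finite & (curve.omega > tol_omega)
    wave = bool(
        np.any(osc)
        and curve.alpha[osc].max() > max(-tol_alpha, a0 + tol_alpha)
    )

    if turing and hopf:
        return InstabilityLabel("Turing-Hopf", q_turing, w0 / (2 * np.pi))
    if turing and a0 <= tol_alpha:
        return InstabilityLabel("Turing", q_turing, 0.0)
    if hopf:
        return InstabilityLabel("Hopf", 0.0, w0 / (2 * np.pi))
    if wave:
        qw = curve.q[osc][np.argmax(curve.alpha[osc])]
        ww = curve.omega[osc][np.argmax(curve.alpha[osc])]
        return InstabilityLabel("wave", float(qw), float(ww / (2 * np.pi)))
    return InstabilityLabel("stable", 0.0, 0.0)


# ---------------------------------------------------------------------------
# critical-parameter bisection
# ---------------------------------------------------------------------------

def _default_q_grid(model: str, params) -> np.ndarray:
    if model == "brusselator":
        qc2 = params.A / np.sqrt(max(params.D_X * params.D_Y, 1e-30))
        q_max = 4.0 * np.sqrt(qc2)
        return np.linspace(1e-3, q_max, 200)
    return np.linspace(0.02, 8.0, 160)


def growth_rate(model: str, params, mode: str, q_grid=None,
                ss: SteadyState | None = None, branch=None,
                near_Ve: float | None = None, refine_q: bool = True) -> float:
    """Monitored growth rate g: alpha(0) for 'hopf_q0', or the maximum over
    stationary finite-q modes for 'turing_qne0'."""
    if ss is None:
        ss = select_branch(steady_states(model, params), near_Ve=near_Ve,
                           branch=branch)
    if mode == "hopf_q0":
        ev = np.linalg.eigvals(jacobian_at_q(model, params, ss, 0.0))
        return float(_dominant(ev).real)
    if mode != "turing_qne0":
        raise ValueError("mode must be 'hopf_q0' or 'turing_qne0'")
    if q_grid is None:
        q_grid = _default_q_grid(model, params)

    def a_stat(q: float) -> float:
        ev = np.linalg.eigvals(jacobian_at_q(model, params, ss, q))
        stat = ev[np.abs(ev.imag) < _STATIONARY_OMEGA]
        return float(stat.real.max()) if stat.size else -np.inf

    vals = np.array([a_stat(q) for q in q_grid])
    k = int(np.argmax(vals))
    best = vals[k]
    if not np.isfinite(best):
        return float(best)
    # bounded refinement of the maximising wavenumber (the grid maximum
    # underestimates the continuous one by O(dq^2))
    if refine_q and 0 < k < len(q_grid) - 1:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda q: -a_stat(q),
            bracket=None,
            bounds=(q_grid[k - 1], q_grid[k + 1]),
            method="bounded",
            options={"xatol": 1e-6 * max(1.0, q_grid[-1])},
        )
        best = max(best, -res.fun)
    return float(best)


def critical_value(model: str, params, param_name: str, mode: str,
                   bracket: tuple[float, float], tol: float = 1e-5,
                   q_grid=None, branch: str | None = None,
                   near_Ve: float | None = None) -> float:
    """Bisection of the monitored growth rate over one parameter.

    At every trial value the steady state is re-solved (continuation by
    branch selection) before the dispersion evaluation.  Raises if the growth
    rate does not change sign across the bracket, reporting both endpoint
    values.
    """
    def g(p_val: float) -> float:
        trial = replace(params, **{param_name: p_val})
        return growth_rate(model, trial, mode, q_grid=q_grid, branch=branch,
                           near_Ve=near_Ve)

    lo, hi = bracket
    g_lo, g_hi = g(lo), g(hi)
    if np.sign(g_lo) == np.sign(g_hi):
        raise ValueError(
            f"no sign change of growth rate over {param_name} in "
            f"[{lo}, {hi}]: g({lo}) = {g_lo:.6g}, g({hi}) = {g_hi:.6g}"
        )
    return float(brentq(g, lo, hi, xtol=tol))


def brusselator_hopf_threshold(params: BrusselatorParams) -> float:
    """Closed-form Hopf threshold B_c = 1 + A^2 (trace condition at q = 0)."""
    return 1.0 + params.A**2


def brusselator_turing_threshold(params: BrusselatorParams) -> float:
    """Closed-form Turing threshold B_c = (1 + A sqrt(D_X/D_Y))^2."""
    return (1.0 + params.A * np.sqrt(params.D_X / params.D_Y)) ** 2
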