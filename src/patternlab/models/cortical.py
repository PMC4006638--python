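"""Mean-field cortical model with chemical synapses and gap-junction diffusion.

The cortex is a 2-D continuum of interacting excitatory (e) and inhibitory
(i) neural populations.  Long-range excitatory spike flux propagates by a
damped wave equation; dendrites filter incoming flux with a critically damped
alpha-function response; soma voltages relax toward rest, driven by
reversal-potential-weighted synaptic flux and by voltage diffusion through
gap junctions (strength D1 between e<->e pairs, D2 between i<->i pairs).
Strong D2 drives a Turing instability; slowing the inhibitory dendritic rate
constant gamma_i adds a low-frequency Hopf oscillation.

State components (14 fields sharing one grid):

====== ==========================================================
phi_ee, phi_ei    long-range e->b axonal fluxes (s^-1)
chi_ee, chi_ei    their time derivatives
Phi_ab (4)        post-synaptic dendritic fluxes, ab in {ee,ei,ie,ii}
Psi_ab (4)        their time derivatives
V_e, V_i          population-mean soma voltages (mV)
====== ==========================================================

First-order dynamics (b in {e, i}):

  d(phi_eb)/dt = chi_eb
  d(chi_eb)/dt = v^2 lap(phi_eb) - 2 v Lambda chi_eb - (v Lambda)^2 phi_eb
                 + (v Lambda)^2 Q_e
  d(Phi_ab)/dt = Psi_ab
  d(Psi_eb)/dt = -2 gamma_e Psi_eb - gamma_e^2 Phi_eb
                 + gamma_e^2 (N_alpha phi_eb + N_beta_eb Q_e + phi_sc)
  d(Psi_ib)/dt = -2 gamma_i Psi_ib - gamma_i^2 Phi_ib + gamma_i^2 N_beta_ib Q_i
  d(V_b)/dt    = [V_b_rest_eff - V_b + rho_e psi_eb Phi_eb
                 + rho_i psi_ib Phi_ib + D_bb lap(V_b)] / tau_b

Q_a(V) is the sigmoid firing-rate map and psi_ab the linear
reversal-potential weight (1 at rest, 0 at the presynaptic reversal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ..grid import GridSpec, laplacian
from .layout import StateLayout

C_SQRT3 = math.pi / math.sqrt(3.0)
C_THIRD = math.pi / 3.0

CORTICAL_COMPONENTS = (
    "phi_ee", "phi_ei", "chi_ee", "chi_ei",
    "Phi_ee", "Phi_ei", "Phi_ie", "Phi_ii",
    "Psi_ee", "Psi_ei", "Psi_ie", "Psi_ii",
    "V_e", "V_i",
)


@dataclass(frozen=True)
class CorticalParams:
    """Complete parameter record.

    Defaults are the canonical published set: Lambda = 4 cm^-1, v = 140 cm/s,
    Qmax = 30/60 s^-1, theta = -58.5 mV, sigma = 3/5 mV, N_alpha = 2000,
    N_beta = 800/600, gamma_e = 170 s^-1, gamma_i = 50 s^-1,
    <phi_sc> = 300 s^-1, tau = 0.04 s, V_rev = 0/-70 mV, V_rest = -64 mV,
    dV_rest = 1.5/0 mV, rho_e = 1.00e-3, rho_i = -1.05e-3 mV s,
    D2 in [0, 2] cm^2 with D1 = D2/100 unless overridden.

    Documented switches (the literature leaves them open):

    * ``C_sigmoid`` -- sigmoid slope constant, pi/sqrt(3) by default with
      pi/3 as the alternative reading.
    * ``rest_offset_soma`` / ``rest_offset_psi`` -- whether the resting-level
      offset dV_rest enters the soma relaxation target and/or the psi-weight
      normalisation denominator.
    * ``diffusion_in_tau`` -- whether the gap-junction term is divided by
      tau_b (it is, by default, since it sits inside tau dV/dt = ...).
    * ``noise_scaling`` -- fluctuations scale with sqrt(s <phi_sc>)
      ("sqrt", default) or linearly with s <phi_sc> ("linear").
    """

    Lambda_eb: float = 4.0        # cm^-1
    v_axon: float = 140.0         # cm/s
    Qmax_e: float = 30.0          # s^-1
    Qmax_i: float = 60.0
    theta_e: float = -58.5        # mV
    theta_i: float = -58.5
    sigma_e: float = 3.0          # mV
    sigma_i: float = 5.0
    C_sigmoid: float = C_SQRT3
    N_alpha_eb: float = 2000.0
    N_beta_eb: float = 800.0
    N_beta_ib: float = 600.0
    gamma_e: float = 170.0        # s^-1
    gamma_i: float = 50.0
    phi_sc_mean: float = 300.0    # s^-1
    s_drive: float = 1.0
    tau_e: float = 0.04           # s
    tau_i: float = 0.04
    Vrev_e: float = 0.0           # mV
    Vrev_i: float = -70.0
    Vrest_e: float = -64.0
    Vrest_i: float = -64.0
    dVrest_e: float = 1.5
    dVrest_i: float = 0.0
    rho_e: float = 1.00e-3        # mV s
    rho_i: float = -1.05e-3
    D2: float = 1.0               # cm^2
    D1: float | None = None       # cm^2; None -> D2/100
    noise_amp: float = 0.0
    noise_mode: str = "off"       # off | kick | continuous
    rest_offset_soma: bool = True
    rest_offset_psi: bool = True
    diffusion_in_tau: bool = True
    noise_scaling: str = "sqrt"   # sqrt | linear

    def __post_init__(self) -> None:
        if self.rho_e <= 0 or self.rho_i >= 0:
            raise ValueError("rho_e must be positive and rho_i negative")
        if self.s_drive < 0:
            raise ValueError("subcortical scale-factor s must be non-negative")
        if self.noise_mode not in ("off", "kick", "continuous"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.noise_scaling not in ("sqrt", "linear"):
            raise ValueError(f"unknown noise_scaling {self.noise_scaling!r}")
        for pre in "ei":
            for post in "ei":
                if abs(self.rev(pre) - self.psi_rest(post)) < 1e-9:
                    raise ValueError(
                        f"degenerate psi weight: V_{pre}^rev equals the "
                        f"{post}-population normalisation rest level"
                    )

    # -- derived values -----------------------------------------------------
    @property
    def D1_eff(self) -> float:
        return self.D2 / 100.0 if self.D1 is None else self.D1

    def rev(self, pre: str) -> float:
        return self.Vrev_e if pre == "e" else self.Vrev_i

    def soma_rest(self, pop: str) -> float:
        """Effective soma resting level (rest + offset when enabled)."""
        if pop == "e":
            return self.Vrest_e + (self.dVrest_e if self.rest_offset_soma else 0.0)
        return self.Vrest_i + (self.dVrest_i if self.rest_offset_soma else 0.0)

    def psi_rest(self, pop: str) -> float:
        """Rest level normalising the psi weight for postsynaptic pop."""
        if pop == "e":
            return self.Vrest_e + (self.dVrest_e if self.rest_offset_psi else 0.0)
        return self.Vrest_i + (self.dVrest_i if self.rest_offset_psi else 0.0)

    @property
    def drive_dc(self) -> float:
        """Tonic subcortical flux level s * <phi_sc> (s^-1)."""
        return self.s_drive * self.phi_sc_mean

    @property
    def noise_scale_flux(self) -> float:
        """Physical scale of subcortical flux fluctuations (before noise_amp)."""
        if self.noise_scaling == "sqrt":
            return math.sqrt(self.drive_dc)
        return self.drive_dc

    def with_(self, **kwargs) -> "CorticalParams":
        return replace(self, **kwargs)


def firing_rate(V, pop: str, params: CorticalParams):
    """Sigmoid voltage-to-firing-rate map Q = Qmax / (1 + exp(-C (V-theta)/sigma)).

    Strictly increasing in V with range (0, Qmax); the exponent is clipped to
    guard against overflow in the saturating tails.
    """
    V = np.asarray(V, dtype=float)
    if pop == "e":
        qmax, theta, sigma = params.Qmax_e, params.theta_e, params.sigma_e
    elif pop == "i":
        qmax, theta, sigma = params.Qmax_i, params.theta_i, params.sigma_i
    else:
        raise ValueError("pop must be 'e' or 'i'")
    z = np.clip(-params.C_sigmoid * (V - theta) / sigma, -500.0, 500.0)
    return qmax / (1.0 + np.exp(z))


def firing_rate_deriv(V, pop: str, params: CorticalParams):
    """dQ/dV = C Q (1 - Q/Qmax) / sigma (analytic sigmoid derivative)."""
    q = firing_rate(V, pop, params)
    if pop == "e":
        qmax, sigma = params.Qmax_e, params.sigma_e
    else:
        qmax, sigma = params.Qmax_i, params.sigma_i
    return params.C_sigmoid * q * (1.0 - q / qmax) / sigma


def alpha_response(t, gamma: float):
    """Dendritic alpha-function impulse response H(t) = gamma^2 t exp(-gamma t).

    Peaks at t = 1/gamma with value gamma/e; unit time-integral.  The
    dynamics use the equivalent critically damped second-order ODE form; this
    closed form is for reference and testing.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("alpha response is defined for t >= 0")
    return gamma * gamma * t * np.exp(-gamma * t)


def psi_weight(V, presyn: str, postsyn: str, params: CorticalParams):
    """Linear reversal-potential weight psi_ab(V_b).

    psi = (V_a^rev - V_b) / (V_a^rev - V_b^rest), equal to 1 at the
    normalisation rest level and 0 at the presynaptic reversal potential.
    """
    if presyn not in "ei" or postsyn not in "ei":
        raise ValueError("presyn/postsyn must be 'e' or 'i'")
    V = np.asarray(V, dtype=float)
    vrev = params.rev(presyn)
    vrest = params.psi_rest(postsyn)
    return (vrev - V) / (vrev - vrest)


def psi_weight_deriv(presyn: str, postsyn: str, params: CorticalParams) -> float:
    """d(psi_ab)/dV_b = -1 / (V_a^rev - V_b^rest): constant for the linear form."""
    return -1.0 / (params.rev(presyn) - params.psi_rest(postsyn))


def subcortical_drive(t, params: CorticalParams, grid: GridSpec | None = None,
                      rng: np.random.Generator | None = None, step: int = 0):
    """Subcortical excitatory flux phi_sc entering the e->b dendrites.

    The deterministic part is the uniform tone s * <phi_sc>.  In mode "kick"
    a single Gaussian spatial perturbation is added on the first step only
    (step == 1); in mode "continuous" noise is added every step.  During
    integration the stochastic part is injected by the driver through
    :func:`cortical_noise_spec`; sampling here (rng given) serves direct
    inspection and tests.
    """
    shape = () if grid is None else grid.shape
    out = np.full(shape, params.drive_dc)
    active = (params.noise_mode == "continuous") or (
        params.noise_mode == "kick" and step == 1
    )
    if rng is not None and params.noise_amp != 0.0 and active:
        out = out + params.noise_amp * params.noise_scale_flux * rng.standard_normal(
            shape
        )
    return out


class CorticalState:
    """The 14 component fields of the cortical model on one grid."""

    def __init__(self, grid: GridSpec, data: np.ndarray | None = None):
        self.grid = grid
        self.layout = StateLayout(names=CORTICAL_COMPONENTS, shape=grid.shape)
        if data is None:
            data = np.zeros((14,) + grid.shape)
        data = np.asarray(data, dtype=float)
        if data.shape != (14,) + grid.shape:
            raise ValueError(
                f"state shape {data.shape} != {(14,) + grid.shape}"
            )
        self.data = data

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[CORTICAL_COMPONENTS.index(name)]

    def __setitem__(self, name: str, value) -> None:
        self.data[CORTICAL_COMPONENTS.index(name)] = value

    def flatten(self) -> np.ndarray:
        return self.data.ravel().copy()

    @classmethod
    def from_flat(cls, flat: np.ndarray, grid: GridSpec) -> "CorticalState":
        return cls(grid, np.asarray(flat).reshape((14,) + grid.shape).copy())

    @classmethod
    def homogeneous(cls, grid: GridSpec, params: CorticalParams,
                    Ve: float, Vi: float) -> "CorticalState":
        """Uniform state implied by soma voltages (Ve, Vi).

        Fluxes take their fixed-point values: phi_eb = Q_e,
        Phi_eb = (N_alpha + N_beta_eb) Q_e + s <phi_sc>, Phi_ib = N_beta_ib Q_i,
        all time-derivative components zero.
        """
        qe = float(firing_rate(Ve, "e", params))
        qi = float(firing_rate(Vi, "i", params))
        phi_eb = qe
        # summation order matches the RHS so the fixed point is exact in
        # floating point (the dendrite rows multiply any mismatch by gamma^2)
        Phi_eb = params.N_alpha_eb * qe + params.N_beta_eb * qe + params.drive_dc
        Phi_ib = params.N_beta_ib * qi
        st = cls(grid)
        for name, val in (
            ("phi_ee", phi_eb), ("phi_ei", phi_eb),
            ("Phi_ee", Phi_eb), ("Phi_ei", Phi_eb),
            ("Phi_ie", Phi_ib), ("Phi_ii", Phi_ib),
            ("V_e", Ve), ("V_i", Vi),
        ):
            st[name] = val
        return st


def cortical_rhs(state: CorticalState, params: CorticalParams, grid: GridSpec,
                 t: float = 0.0, drive: np.ndarray | float | None = None
                 ) -> CorticalState:
    """Time derivative of a cortical state (field form).

    ``drive`` is the subcortical flux entering the e->b dendrite equations;
    None means the deterministic tone s * <phi_sc>.
    """
    flat_rhs = make_cortical_rhs(params, grid, drive=drive)
    return CorticalState.from_flat(flat_rhs(t, state.flatten()), grid)


def make_cortical_rhs(params: CorticalParams, grid: GridSpec,
                      drive: np.ndarray | float | None = None):
    """Fast flat RHS callable over the 14-field state."""
    p = params
    vL = p.v_axon * p.Lambda_eb
    vL2 = vL * vL
    v2 = p.v_axon * p.v_axon
    ge, gi = p.gamma_e, p.gamma_i
    ge2, gi2 = ge * ge, gi * gi
    D1, D2 = p.D1_eff, p.D2
    rest_e, rest_i = p.soma_rest("e"), p.soma_rest("i")
    drive_val = p.drive_dc if drive is None else drive
    shape = grid.shape
    layout = StateLayout(names=CORTICAL_COMPONENTS, shape=shape)
    tau_div_e = p.tau_e if p.diffusion_in_tau else 1.0
    tau_div_i = p.tau_i if p.diffusion_in_tau else 1.0

    def rhs(t, flat):
        s = flat.reshape((14,) + shape)
        (phi_ee, phi_ei, chi_ee, chi_ei,
         Phi_ee, Phi_ei, Phi_ie, Phi_ii,
         Psi_ee, Psi_ei, Psi_ie, Psi_ii,
         V_e, V_i) = s
        out = np.empty_like(s)

        Qe = firing_rate(V_e, "e", p)
        Qi = firing_rate(V_i, "i", p)

        # damped wave equations for long-range flux
        out[0] = chi_ee
        out[1] = chi_ei
        src = vL2 * Qe
        out[2] = v2 * laplacian(phi_ee, grid) - 2.0 * vL * chi_ee - vL2 * phi_ee + src
        out[3] = v2 * laplacian(phi_ei, grid) - 2.0 * vL * chi_ei - vL2 * phi_ei + src

        # dendritic alpha-function filters
        out[4] = Psi_ee
        out[5] = Psi_ei
        out[6] = Psi_ie
        out[7] = Psi_ii
        Me = p.N_alpha_eb * phi_ee + p.N_beta_eb * Qe + drive_val
        Mi = p.N_alpha_eb * phi_ei + p.N_beta_eb * Qe + drive_val
        out[8] = -2.0 * ge * Psi_ee - ge2 * Phi_ee + ge2 * Me
        out[9] = -2.0 * ge * Psi_ei - ge2 * Phi_ei + ge2 * Mi
        Qi_loc = p.N_beta_ib * Qi
        out[10] = -2.0 * gi * Psi_ie - gi2 * Phi_ie + gi2 * Qi_loc
        out[11] = -2.0 * gi * Psi_ii - gi2 * Phi_ii + gi2 * Qi_loc

        # soma voltages
        syn_e = (p.rho_e * psi_weight(V_e, "e", "e", p) * Phi_ee
                 + p.rho_i * psi_weight(V_e, "i", "e", p) * Phi_ie)
        syn_i = (p.rho_e * psi_weight(V_i, "e", "i", p) * Phi_ei
                 + p.rho_i * psi_weight(V_i, "i", "i", p) * Phi_ii)
        out[12] = (rest_e - V_e + syn_e
                   + D1 * laplacian(V_e, grid) * (p.tau_e / tau_div_e)) / p.tau_e
        out[13] = (rest_i - V_i + syn_i
                   + D2 * laplacian(V_i, grid) * (p.tau_i / tau_div_i)) / p.tau_i
        return out.ravel()

    rhs.layout = layout
    return rhs


def cortical_noise_spec(params: CorticalParams, grid: GridSpec):
    """NoiseSpec injecting subcortical flux fluctuations into the Psi_eb rows.

    The stochastic part of phi_sc enters d(Psi_eb)/dt multiplied by
    gamma_e^2, so the per-component scale is gamma_e^2 * noise_scale_flux
    on Psi_ee and Psi_ei, zero elsewhere.  Returns None when noise is off.
    """
    from ..integrators import NoiseSpec

    if params.noise_mode == "off" or params.noise_amp == 0.0:
        return None
    layout = StateLayout(names=CORTICAL_COMPONENTS, shape=grid.shape)
    scale = np.zeros(layout.size)
    val = params.gamma_e**2 * params.noise_scale_flux
    scale[layout.slice_of("Psi_ee")] = val
    scale[layout.slice_of("Psi_ei")] = val
    return NoiseSpec(scale=scale, amplitude=params.noise_amp,
                     mode=params.noise_mode)
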