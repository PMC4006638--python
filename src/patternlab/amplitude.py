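"""Amplitude equations for the Brusselator Turing mode.

Near the Turing onset B_c the pattern is a superposition of three critical
wavevectors at 120 degrees whose slowly varying complex amplitudes Z1, Z2,
Z3 obey (cyclic in the indices)

    dZ1/dt = mu Z1 + v conj(Z2) conj(Z3) - g |Z1|^2 Z1
             - h (|Z2|^2 + |Z3|^2) Z1

with mu = (B - B_c)/B_c the distance to threshold.  With e = A*eta and
eta = sqrt(D_X / D_Y):

    B_c = (1 + e)^2
    v(mu) = 2 (1 - e) / (A (1 + e)) + 2 mu / A
    g = [38 e + 5 e^2 - 8 - 8 e^3] / [9 A^3 eta (1 + e)]
    h = [ 5 e + 7 e^2 - 3 - 3 e^3] / [  A^3 eta (1 + e)]

The eta convention and the coefficient grouping are validated behaviourally:
B_c must coincide with the linear-stability Turing threshold, and the
resulting mode-stability map must show the classical
hexagon -> stripe -> reentrant-hexagon exchange.  The quadratic coefficient
v depends on mu and changes sign at mu_p = (e - 1)/(e + 1); below mu_p the
stable hexagon class has total phase pi (H_pi, honeycomb), above it total
phase 0 (H_0, reentrant honeycomb).

Stationary solutions are stripes (R, 0, 0) with R = sqrt(mu/g) and
equal-amplitude hexagon branches with |Z_j| = r solving
(g + 2h) r^2 - P v r - mu = 0, where P = +1 for H_0 and P = -1 for H_pi
(P is the product of the real amplitude signs, i.e. the cosine of the total
phase).  Stability is decided numerically from the 6-real-dimensional
linearisation of the amplitude flow, excluding the neutral phase modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linstab import critical_value
from .models.brusselator import BrusselatorParams

#: default finite-difference step for the stability Jacobian
FD_STEP = 1e-7
#: eigenvalue real parts with magnitude below this count as neutral
EIG_TOL = 1e-8

MODES = ("stripes", "H_pi", "H_0")


@dataclass
class AmplitudeCoefficients:
    """Coefficients of the three-mode Turing amplitude equations."""

    mu: float
    v_coef: float       # quadratic (resonant) coefficient at this mu
    g: float            # self-saturation
    h: float            # cross-saturation
    eta: float          # sqrt(D_X / D_Y)
    B_c: float
    A: float

    def v_at(self, mu: float) -> float:
        """Quadratic coefficient evaluated at another distance to threshold."""
        e = self.A * self.eta
        return 2.0 * (1.0 - e) / (self.A * (1.0 + e)) + 2.0 * mu / self.A

    @property
    def mu_p(self) -> float:
        """Hexagon phase-exchange point, where v(mu) = 0."""
        e = self.A * self.eta
        return (e - 1.0) / (e + 1.0)


@dataclass
class StationaryMode:
    """One stationary solution of the amplitude equations."""

    name: str                 # stripes | H_pi | H_0
    amplitudes: np.ndarray    # real triple (signs encode the total phase)
    residual: float


@dataclass
class ModeStabilityReport:
    mu: float
    status: dict              # mode name -> "stable" | "unstable" | "nonexistent"
    amplitudes: dict          # mode name -> list of stationary amplitude triples

    def stable_modes(self) -> set[str]:
        return {m for m, s in self.status.items() if s == "stable"}


def turing_coefficients(params: BrusselatorParams, mu: float | None = None,
                        validate: bool = True) -> AmplitudeCoefficients:
    """Amplitude-equation coefficients for a Brusselator parameter set.

    ``mu`` defaults to the value implied by params.B.  When ``validate`` is
    on, B_c is cross-checked against the numeric linear-stability Turing
    bisection to 1e-6 relative.
    """
    A = params.A
    if not params.D_X < params.D_Y:
        raise ValueError(
            "Turing branch requires the inhibitor to diffuse faster "
            "(D_X < D_Y)"
        )
    eta = float(np.sqrt(params.D_X / params.D_Y))
    e = A * eta
    B_c = (1.0 + e) ** 2
    if validate:
        B_num = critical_value(
            "brusselator", params, "B", "turing_qne0",
            bracket=(0.9 * B_c, 1.1 * B_c), tol=1e-9 * B_c,
        )
        if abs(B_num - B_c) > 1e-6 * B_c:
            raise RuntimeError(
                f"B_c mismatch: closed form {B_c} vs LSA bisection {B_num}"
            )
    if mu is None:
        mu = (params.B - B_c) / B_c
    g = (38.0 * e + 5.0 * e**2 - 8.0 - 8.0 * e**3) / (9.0 * A**3 * eta * (1.0 + e))
    h = (5.0 * e + 7.0 * e**2 - 3.0 - 3.0 * e**3) / (A**3 * eta * (1.0 + e))
    coeffs = AmplitudeCoefficients(mu=float(mu), v_coef=0.0, g=g, h=h,
                                   eta=eta, B_c=B_c, A=A)
    coeffs.v_coef = coeffs.v_at(float(mu))
    return coeffs


def amplitude_rhs(Z: np.ndarray, mu: float, v: float, g: float,
                  h: float) -> np.ndarray:
    """Right-hand side of the three coupled amplitude equations."""
    Z = np.asarray(Z, dtype=complex)
    mags = np.abs(Z) ** 2
    out = np.empty(3, dtype=complex)
    for j in range(3):
        k, l = (j + 1) % 3, (j + 2) % 3
        out[j] = (mu * Z[j] + v * np.conj(Z[k]) * np.conj(Z[l])
                  - g * mags[j] * Z[j] - h * (mags[k] + mags[l]) * Z[j])
    return out


def _real_flow(x: np.ndarray, mu: float, v: float, g: float,
               h: float) -> np.ndarray:
    Z = x[:3] + 1j * x[3:]
    dZ = amplitude_rhs(Z, mu, v, g, h)
    return np.concatenate([dZ.real, dZ.imag])


def stationary_modes(coeffs: AmplitudeCoefficients,
                     mu: float | None = None) -> list[StationaryMode]:
    """All stationary stripe and hexagon solutions at a given mu.

    Each solution is verified to zero the amplitude equations to 1e-12
    (relative to the cubic scale).  The list may be empty (below threshold
    with no resonant branch).
    """
    mu = coeffs.mu if mu is None else float(mu)
    v, g, h = coeffs.v_at(mu), coeffs.g, coeffs.h
    out: list[StationaryMode] = []

    def _push(name: str, amps: np.ndarray) -> None:
        res = float(np.max(np.abs(amplitude_rhs(amps.astype(complex),
                                                mu, v, g, h))))
        scale = max(1.0, float(np.max(np.abs(amps))) ** 3)
        if res <= 1e-12 * scale:
            out.append(StationaryMode(name, amps, res))

    if mu > 0 and g > 0:
        R = np.sqrt(mu / g)
        _push("stripes", np.array([R, 0.0, 0.0]))

    gh = g + 2.0 * h
    for P, name in ((1.0, "H_0"), (-1.0, "H_pi")):
        # (g + 2h) r^2 - P v r - mu = 0
        disc = v * v + 4.0 * mu * gh
        if disc < 0 or gh <= 0:
            continue
        for sign in (+1.0, -1.0):
            r = (P * v + sign * np.sqrt(disc)) / (2.0 * gh)
            if r > 1e-12:
                _push(name, np.array([P * r, r, r]))
    return out


def mode_stability(coeffs: AmplitudeCoefficients, mu: float | None = None,
                   fd_step: float = FD_STEP,
                   eig_tol: float = EIG_TOL) -> ModeStabilityReport:
    """Numeric stability of every stationary mode at a given mu.

    The 6-real-dimensional amplitude flow is linearised about each
    stationary solution by central finite differences.  Hexagons carry two
    neutral phase modes and stripes one (translations of the pattern); the
    corresponding number of eigenvalues nearest zero is excluded, and the
    mode is stable iff every remaining eigenvalue has real part below
    ``eig_tol``.  A mode with several stationary branches is stable if any
    branch is stable (the physically realised one).
    """
    mu = coeffs.mu if mu is None else float(mu)
    v, g, h = coeffs.v_at(mu), coeffs.g, coeffs.h
    sols = stationary_modes(coeffs, mu)
    status = {m: "nonexistent" for m in MODES}
    amplitudes: dict[str, list] = {m: [] for m in MODES}
    for sol in sols:
        x0 = np.concatenate([sol.amplitudes, np.zeros(3)])
        J = np.empty((6, 6))
        for j in range(6):
            dx = np.zeros(6)
            dx[j] = fd_step
            J[:, j] = (_real_flow(x0 + dx, mu, v, g, h)
                       - _real_flow(x0 - dx, mu, v, g, h)) / (2.0 * fd_step)
        ev = np.linalg.eigvals(J)
        n_neutral = 1 if sol.name == "stripes" else 2
        order = np.argsort(np.abs(ev.real))
        rest = ev[order[n_neutral:]]
        stable = bool(np.all(rest.real < eig_tol))
        amplitudes[sol.name].append(sol.amplitudes.copy())
        if stable:
            status[sol.name] = "stable"
        elif status[sol.name] != "stable":
            status[sol.name] = "unstable"
    return ModeStabilityReport(mu=mu, status=status, amplitudes=amplitudes)


def stability_boundaries(params: BrusselatorParams,
                         mu_range: tuple[float, float] = (5e-3, 2.0),
                         n_scan: int = 160, tol: float = 1e-5) -> dict:
    """Stability-exchange boundaries of the mode map over a mu range.

    Returns {mu_s_minus, mu_s_plus, mu_h_minus, mu_h_plus, mu_p}: stripes
    are stable on (mu_s_minus, mu_s_plus); hexagons below mu_h_minus and
    above mu_h_plus; the two hexagon classes exchange at mu_p (where the
    quadratic coefficient vanishes, reported in closed form).  Boundaries
    not bracketed by the range are reported as None.  Each flip is located
    by bisection of the stability flag to ``tol``.
    """
    coeffs = turing_coefficients(params, validate=False)

    def stripe_flag(mu: float) -> bool:
        return mode_stability(coeffs, mu).status["stripes"] == "stable"

    def hex_flag(mu: float) -> bool:
        st = mode_stability(coeffs, mu).status
        return st["H_pi"] == "stable" or st["H_0"] == "stable"

    def _flips(flag, grid) -> list[float]:
        vals = [flag(m) for m in grid]
        found = []
        for k in range(len(grid) - 1):
            if vals[k] != vals[k + 1]:
                lo, hi = grid[k], grid[k + 1]
                while hi - lo > tol:
                    mid = 0.5 * (lo + hi)
                    if flag(mid) == vals[k]:
                        lo = mid
                    else:
                        hi = mid
                found.append(0.5 * (lo + hi))
        return found

    grid = np.linspace(mu_range[0], mu_range[1], n_scan)
    s_flips = _flips(stripe_flag, grid)
    h_flips = _flips(hex_flag, grid)
    out = {
        "mu_s_minus": s_flips[0] if len(s_flips) > 0 else None,
        "mu_s_plus": s_flips[1] if len(s_flips) > 1 else None,
        "mu_h_minus": h_flips[0] if len(h_flips) > 0 else None,
        "mu_h_plus": h_flips[1] if len(h_flips) > 1 else None,
        "mu_p": coeffs.mu_p,
    }
    return out
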