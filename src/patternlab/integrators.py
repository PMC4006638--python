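"""Time-stepping drivers: fixed-step explicit schemes and adaptive RK45.

The right-hand side contract is ``rhs(t, y) -> dy/dt`` on a flat state vector.
Stochastic forcing is injected by the fixed-step driver (Euler-Maruyama
convention: per-step Gaussian increments scaled by sqrt(dt)), never hidden
inside the RHS, so a given RHS is always deterministic in (t, y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

RHSFunction = Callable[[float, np.ndarray], np.ndarray]

_SCHEMES = ("euler", "rk4")


class IntegrationError(RuntimeError):
    """Raised when a state turns non-finite or a step size underflows."""


@dataclass
class NoiseSpec:
    """Additive white-noise forcing for the fixed-step driver.

    Each step, ``amplitude * sqrt(dt) * scale * N(0,1)`` is added to the
    state, with independent standard normals per driven component (spatially
    and temporally uncorrelated).  ``scale`` is a vector over the flat state
    that is zero outside the driven components; it carries any physical
    prefactor (e.g. the dendrite rate constant squared for a flux drive).

    mode "kick" applies a single Gaussian perturbation on the first step only;
    mode "continuous" applies it every step.
    """

    scale: np.ndarray
    amplitude: float = 1.0
    mode: str = "continuous"

    def __post_init__(self) -> None:
        if self.mode not in ("kick", "continuous"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        self.scale = np.asarray(self.scale, dtype=float)


@dataclass
class Trajectory:
    """Time-stamped sequence of saved states with run provenance."""

    times: np.ndarray
    states: np.ndarray  # time axis first
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("one state per saved time required")


def _check_finite(y: np.ndarray, t: float, step: int, layout=None) -> None:
    if np.all(np.isfinite(y)):
        return
    bad = int(np.flatnonzero(~np.isfinite(y))[0])
    name = f"component {bad}"
    if layout is not None:
        name = layout.component_of(bad)
    raise IntegrationError(
        f"non-finite state at t={t:.6g} (step {step}): {name}; "
        "the scheme is unstable at this step size"
    )


def step_fixed(
    rhs: RHSFunction, state: np.ndarray, t: float, dt: float, scheme: str = "rk4"
) -> np.ndarray:
    """One explicit step of the named scheme ('euler' or classical 'rk4')."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = np.asarray(state, dtype=float)
    if scheme == "euler":
        return y + dt * rhs(t, y)
    if scheme == "rk4":
        k1 = rhs(t, y)
        k2 = rhs(t + 0.5 * dt, y + 0.5 * dt * k1)
        k3 = rhs(t + 0.5 * dt, y + 0.5 * dt * k2)
        k4 = rhs(t + dt, y + dt * k3)
        return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    raise ValueError(f"unknown scheme {scheme!r}; supported: {_SCHEMES}")


def integrate_fixed(
    rhs: RHSFunction,
    init: np.ndarray,
    t_span: tuple[float, float],
    dt: float,
    scheme: str = "rk4",
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    save_every: int = 1,
    layout=None,
) -> Trajectory:
    """Fixed-step integration, deterministic for a given seed.

    Noise (if any) is added after each deterministic step as
    ``amplitude * sqrt(dt) * scale * xi`` with ``xi ~ N(0, 1)`` i.i.d.
    per component and step (Euler-Maruyama convention).  Saving is thinned
    to every ``save_every``-th step; the initial and final states are always
    saved.  A non-finite state aborts with a diagnostic naming the offending
    component.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; supported: {_SCHEMES}")
    t0, t1 = map(float, t_span)
    if t1 < t0:
        raise ValueError("t_span must be increasing")
    if dt <= 0:
        raise ValueError("dt must be positive")
    nsteps = int(round((t1 - t0) / dt))
    if abs(t0 + nsteps * dt - t1) > dt:
        raise ValueError("dt must divide the time span to within one step")
    rng = np.random.default_rng(seed)
    y = np.array(init, dtype=float)
    have_noise = noise is not None and noise.amplitude != 0.0
    sqrt_dt = np.sqrt(dt)

    times = [t0]
    states = [y.copy()]
    t = t0
    for step in range(1, nsteps + 1):
        y = step_fixed(rhs, y, t, dt, scheme)
        if have_noise and (noise.mode == "continuous" or step == 1):
            y = y + noise.amplitude * sqrt_dt * noise.scale * rng.standard_normal(
                y.shape
            )
        t = t0 + step * dt
        _check_finite(y, t, step, layout)
        if step % save_every == 0 or step == nsteps:
            times.append(t)
            states.append(y.copy())
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        provenance={
            "scheme": scheme,
            "dt": dt,
            "seed": seed,
            "save_every": save_every,
            "noise_mode": None if noise is None else noise.mode,
            "noise_amplitude": 0.0 if noise is None else noise.amplitude,
        },
    )


def integrate_adaptive(
    rhs: RHSFunction,
    init: np.ndarray,
    t_span: tuple[float, float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dense_times: Sequence[float] | None = None,
    noise: NoiseSpec | None = None,
) -> Trajectory:
    """Adaptive embedded Runge-Kutta 4(5) integration via SciPy's RK45.

    Reports the solution at ``dense_times`` (default: solver steps).  Refuses
    stochastic forcing: white noise under step-size control is ill-defined;
    use :func:`integrate_fixed` for noisy runs.
    """
    if noise is not None and noise.amplitude != 0.0:
        raise ValueError(
            "adaptive stepping with white noise is ill-defined; "
            "use integrate_fixed for stochastic runs"
        )
    if rtol <= 0 or atol <= 0:
        raise ValueError("rtol and atol must be positive")
    t0, t1 = map(float, t_span)
    y0 = np.asarray(init, dtype=float)
    if t1 == t0:
        return Trajectory(
            times=np.array([t0]),
            states=y0[None, :].copy(),
            provenance={"scheme": "rk45", "rtol": rtol, "atol": atol},
        )
    t_eval = None if dense_times is None else np.asarray(dense_times, dtype=float)
    sol = solve_ivp(
        rhs, (t0, t1), y0, method="RK45", rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        raise IntegrationError(
            f"adaptive solver failed: {sol.message} "
            "(possible stiffness; consider a smaller span or different solver)"
        )
    return Trajectory(
        times=sol.t,
        states=sol.y.T.copy(),
        provenance={"scheme": "rk45", "rtol": rtol, "atol": atol},
    )


def observed_order(errors: Sequence[float]) -> float:
    """Richardson estimate of convergence order from errors under dt halving."""
    errors = np.asarray(errors, dtype=float)
    rates = np.log2(errors[:-1] / errors[1:])
    return float(np.mean(rates))
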