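"""Van der Pol oscillator, the classical integrator test problem.

x'' - mu (1 - x^2) x' + x = 0, reduced to the first-order pair
x' = y, y' = mu (1 - x^2) y - x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import StateLayout


@dataclass(frozen=True)
class VanDerPolParams:
    """mu is the damping/nonlinearity parameter (mu = 0: harmonic oscillator)."""

    mu: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")


VDP_LAYOUT = StateLayout(names=("x", "y"), shape=())


def vdp_rhs(state, params: VanDerPolParams):
    """(dx/dt, dy/dt) = (y, mu (1 - x^2) y - x)."""
    x, y = state
    return (y, params.mu * (1.0 - x * x) * y - x)


def make_vdp_rhs(params: VanDerPolParams):
    """Flat RHS callable for the integrators, with layout attached."""

    def rhs(t, state):
        x, y = state
        return np.array([y, params.mu * (1.0 - x * x) * y - x])

    rhs.layout = VDP_LAYOUT
    return rhs
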