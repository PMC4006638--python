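"""Brusselator reaction-diffusion model.

dX/dt = A - (B+1) X + X^2 Y + D_X lap(X)
dY/dt = B X     - X^2 Y + D_Y lap(Y)

X is the activator, Y the inhibitor; A is a fixed feed constant and B the
bifurcation parameter.  The homogeneous steady state is (X*, Y*) = (A, B/A).
Negative concentrations are permitted (as in Turing's original setting);
non-finite values propagate to the integrator abort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grid import GridSpec, laplacian
from .layout import StateLayout


@dataclass(frozen=True)
class BrusselatorParams:
    A: float = 2.0
    B: float = 4.8
    D_X: float = 2.0
    D_Y: float = 10.0

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError("A must be positive")
        if self.D_X < 0 or self.D_Y < 0:
            raise ValueError("diffusion constants must be non-negative")


def brusselator_steady_state(params: BrusselatorParams) -> tuple[float, float]:
    """Closed-form homogeneous steady state (A, B/A)."""
    return (params.A, params.B / params.A)


def reaction_jacobian(params: BrusselatorParams) -> np.ndarray:
    """2x2 Jacobian of the reaction kinetics at the steady state (A, B/A)."""
    A, B = params.A, params.B
    return np.array([[B - 1.0, A * A], [-B, -A * A]])


def brusselator_rhs(X, Y, params: BrusselatorParams, grid: GridSpec):
    """(dX/dt, dY/dt) fields: reaction terms plus D * Laplacian."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != grid.shape or Y.shape != grid.shape:
        raise ValueError("X, Y must match the grid shape")
    X2Y = X * X * Y
    dX = params.A - (params.B + 1.0) * X + X2Y + params.D_X * laplacian(X, grid)
    dY = params.B * X - X2Y + params.D_Y * laplacian(Y, grid)
    return dX, dY


def make_brusselator_rhs(params: BrusselatorParams, grid: GridSpec):
    """Flat RHS over [X, Y] for the integrators."""
    layout = StateLayout(names=("X", "Y"), shape=grid.shape)
    block = layout.block

    def rhs(t, flat):
        X = flat[:block].reshape(grid.shape)
        Y = flat[block:].reshape(grid.shape)
        dX, dY = brusselator_rhs(X, Y, params, grid)
        return np.concatenate([dX.ravel(), dY.ravel()])

    rhs.layout = layout
    return rhs
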