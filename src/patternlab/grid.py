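"""Discrete spatial operators on toroidal (periodic) uniform grids.

The simulation domain is a 1-D ring or a 2-D torus of equally spaced nodes.
The Laplacian is the classical second-difference stencil, applied by circular
convolution so that grid edges wrap around.  Axis convention: axis 0 is x
(rows), axis 1 is y (columns); all shipped configurations use square grids
(h_x = h_y = h), although :func:`periodic_convolve` itself is agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a uniform periodic grid.

    Parameters
    ----------
    ndim : int
        1 or 2.
    npoints : tuple of int
        Number of grid nodes per axis; at least 3 per axis so the
        second-difference kernel fits.
    spacing : float
        Grid spacing ``h`` in cm (square grid: the same along every axis).
    """

    ndim: int
    npoints: tuple[int, ...]
    spacing: float
    topology: str = "toroidal"

    def __post_init__(self) -> None:
        if self.ndim not in (1, 2):
            raise ValueError(f"ndim must be 1 or 2, got {self.ndim}")
        object.__setattr__(self, "npoints", tuple(int(n) for n in self.npoints))
        if len(self.npoints) != self.ndim:
            raise ValueError("npoints must give one count per axis")
        if any(n < 3 for n in self.npoints):
            raise ValueError("need at least 3 grid points per axis")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.topology != "toroidal":
            raise ValueError("only toroidal topology is supported")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.npoints

    @property
    def nnodes(self) -> int:
        return int(np.prod(self.npoints))

    @property
    def side_lengths(self) -> tuple[float, ...]:
        """Physical extent N*h of each axis in cm."""
        return tuple(n * self.spacing for n in self.npoints)

    def wavenumbers(self, axis: int = 0) -> np.ndarray:
        """Angular wavenumbers q = 2*pi*k/(N*h) (rad/cm) resolved on one axis."""
        n = self.npoints[axis]
        return 2.0 * np.pi * np.fft.fftfreq(n, d=self.spacing)


@dataclass
class Field:
    """A real scalar field sampled on a :class:`GridSpec`."""

    values: np.ndarray
    grid: GridSpec
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")


def _values(field) -> np.ndarray:
    return field.values if isinstance(field, Field) else np.asarray(field, dtype=float)


def laplacian_kernel(ndim: int, spacing: float = 1.0) -> np.ndarray:
    """Second-difference Laplacian stencil scaled by 1/h^2.

    ``ndim=1`` gives ``[1, -2, 1]/h^2``; ``ndim=2`` the five-point cross
    ``[[0,1,0],[1,-4,1],[0,1,0]]/h^2`` (sum of the two orthogonal 1-D
    operators).  The weights sum to exactly zero.
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    inv_h2 = 1.0 / spacing**2
    if ndim == 1:
        return inv_h2 * np.array([1.0, -2.0, 1.0])
    if ndim == 2:
        return inv_h2 * np.array(
            [[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]
        )
    raise ValueError(f"unsupported ndim {ndim}; supported: 1, 2")


def periodic_convolve(field, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution of a field with a small stencil.

    Implemented as wrap-padding followed by a "valid" convolution, so each
    output node is the kernel-weighted sum over periodically wrapped
    neighbours.  Output shape equals input shape.
    """
    values = _values(field)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != values.ndim:
        raise ValueError("kernel and field dimensionality differ")
    if any(k > n for k, n in zip(kernel.shape, values.shape)):
        raise ValueError(
            f"kernel {kernel.shape} larger than grid {values.shape}"
        )
    pad = [((k - 1) - (k - 1) // 2, (k - 1) // 2) for k in kernel.shape]
    wrapped = np.pad(values, pad, mode="wrap")
    return convolve(wrapped, kernel, mode="valid")


def laplacian(field, grid: GridSpec | None = None) -> np.ndarray:
    """Discrete periodic Laplacian of a field.

    Equivalent to ``periodic_convolve(field, laplacian_kernel(ndim, h))`` but
    evaluated with cyclic shifts, which is faster in the integrator hot loop;
    the two paths agree to machine precision (asserted in the test-suite).
    """
    values = _values(field)
    if isinstance(field, Field) and grid is None:
        grid = field.grid
    if grid is None:
        raise ValueError("grid required when passing a bare array")
    if values.shape != grid.shape:
        raise ValueError(
            f"field shape {values.shape} does not match grid {grid.shape}"
        )
    inv_h2 = 1.0 / grid.spacing**2
    out = -2.0 * grid.ndim * values
    for axis in range(grid.ndim):
        out += np.roll(values, 1, axis=axis) + np.roll(values, -1, axis=axis)
    return inv_h2 * out


def laplacian_symbol(q: np.ndarray, spacing: float) -> np.ndarray:
    """Eigenvalue -(2 - 2 cos(q h))/h^2 of the 1-D circulant second difference.

    This is the exact action of the discrete operator on a grid plane wave of
    angular wavenumber ``q``; it tends to -q^2 as q h -> 0.
    """
    q = np.asarray(q, dtype=float)
    return -(2.0 - 2.0 * np.cos(q * spacing)) / spacing**2
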