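"""Flat-vector layout descriptor for multi-component grid states."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StateLayout:
    """Maps named component fields to slices of a flat state vector.

    All components share one grid shape; flattening and unflattening
    round-trip exactly.
    """

    names: tuple[str, ...]
    shape: tuple[int, ...]

    @property
    def ncomp(self) -> int:
        return len(self.names)

    @property
    def block(self) -> int:
        return int(np.prod(self.shape))

    @property
    def size(self) -> int:
        return self.ncomp * self.block

    def index(self, name: str) -> int:
        return self.names.index(name)

    def slice_of(self, name: str) -> slice:
        i = self.index(name)
        return slice(i * self.block, (i + 1) * self.block)

    def component_of(self, flat_index: int) -> str:
        """Name of the component owning a flat index (for diagnostics)."""
        return self.names[flat_index // self.block]

    def pack(self, fields: dict[str, np.ndarray]) -> np.ndarray:
        flat = np.empty(self.size)
        for i, name in enumerate(self.names):
            arr = np.asarray(fields[name], dtype=float)
            if arr.shape != self.shape:
                raise ValueError(f"{name}: shape {arr.shape} != {self.shape}")
            flat[i * self.block : (i + 1) * self.block] = arr.ravel()
        return flat

    def unpack(self, flat: np.ndarray) -> dict[str, np.ndarray]:
        flat = np.asarray(flat)
        if flat.shape[-1] != self.size:
            raise ValueError(f"flat state has size {flat.shape[-1]}, expected {self.size}")
        return {
            name: flat[..., i * self.block : (i + 1) * self.block].reshape(
                flat.shape[:-1] + self.shape
            )
            for i, name in enumerate(self.names)
        }

    def view(self, flat: np.ndarray) -> np.ndarray:
        """Reshape (no copy) to (ncomp, *shape)."""
        return np.asarray(flat).reshape((self.ncomp,) + self.shape)
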