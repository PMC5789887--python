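"""Uniform energy-transfer grids for spectra and resolution kernels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnergyGrid", "default_energy_grid"]


@dataclass(frozen=True)
class EnergyGrid:
    """A strictly increasing, uniformly spaced energy-transfer grid (meV).

    The grid must contain E = 0 within one grid step — the elastic line has to
    live on the grid for resolution-shaped delta components to be placed.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 3:
            raise ValueError("energy grid needs at least 3 points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("energy grid must be strictly increasing")
        step = d.mean()
        if np.max(np.abs(d - step)) > 1e-9 * max(abs(step), 1e-30):
            raise ValueError("energy grid must be uniform (1e-9 relative)")
        if np.min(np.abs(v)) > step:
            raise ValueError("energy grid must contain 0 within one grid step")

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def window(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    @property
    def izero(self) -> int:
        """Index of the grid point closest to E = 0."""
        return int(np.argmin(np.abs(self.values)))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return isinstance(other, EnergyGrid) and np.array_equal(
            self.values, other.values
        )


def default_energy_grid(
    window_lo: float = -0.3, window_hi: float = 1.0, n: int = 1301
) -> EnergyGrid:
    """The IRIS-like window: −0.3 → +1.0 meV, 1 μeV bins by default."""
    return EnergyGrid(np.linspace(window_lo, window_hi, n))
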