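"""Grouped-spectra I/O, solvent subtraction and resolution convolution.

File formats:

* grouped CSV — blocks introduced by ``# Q=<value> A^-1`` headers followed by
  ``E_meV,intensity,sigma`` columns;
* HDF5 — ``/spectra/Q{i}/{q,energies,intensity,sigma}`` plus
  ``/resolution/{energies,profile}``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .constants import DODAB_MOLAR_VOLUME_L_PER_MOL
from .grids import EnergyGrid

__all__ = [
    "Spectrum",
    "ResolutionKernel",
    "gaussian_kernel",
    "read_grouped_spectra",
    "write_grouped_spectra",
    "read_resolution",
    "subtract_solvent",
    "convolve_resolution",
    "convolve_resolution_profile",
    "default_solvent_fraction",
]


@dataclass
class Spectrum:
    """Per-Q intensity vs energy transfer with 1-σ uncertainties."""

    q: float
    energies: EnergyGrid
    intensity: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.energies)
        if self.intensity.shape != (n,) or self.sigma.shape != (n,):
            raise ValueError("intensity and sigma must match the energy grid")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


@dataclass
class ResolutionKernel:
    """Measured (or modelled) instrument resolution, normalized to unit area."""

    energies: EnergyGrid
    profile: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.profile, dtype=float)
        if p.shape != (len(self.energies),):
            raise ValueError("profile must match the energy grid")
        if np.any(p < 0):
            raise ValueError("resolution profile must be non-negative")
        area = p.sum() * self.energies.step
        if area <= 0:
            raise ValueError("resolution profile has zero area")
        if abs(area - 1.0) > 1e-6:
            p = p / area
        self.profile = p

    @property
    def fwhm(self) -> float:
        """Numerical full width at half-maximum (meV)."""
        e, p = self.energies.values, self.profile
        half = 0.5 * p.max()
        above = np.where(p >= half)[0]
        lo, hi = int(above[0]), int(above[-1])
        if lo > 0:
            f = (half - p[lo - 1]) / (p[lo] - p[lo - 1])
            e_lo = e[lo - 1] + f * (e[lo] - e[lo - 1])
        else:
            e_lo = e[lo]
        if hi < len(e) - 1:
            f = (p[hi] - half) / (p[hi] - p[hi + 1])
            e_hi = e[hi] + f * (e[hi + 1] - e[hi])
        else:
            e_hi = e[hi]
        return float(e_hi - e_lo)

    def interpolated(self, grid: EnergyGrid) -> "ResolutionKernel":
        """Linearly interpolate onto another grid, renormalized."""
        p = np.interp(grid.values, self.energies.values, self.profile,
                      left=0.0, right=0.0)
        return ResolutionKernel(grid, p)


def gaussian_kernel(grid: EnergyGrid, fwhm_ueV: float = 17.0,
                    center: float = 0.0) -> ResolutionKernel:
    """Gaussian resolution of given FWHM in μeV on an energy grid (meV)."""
    sigma = fwhm_ueV * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    e = grid.values
    p = np.exp(-0.5 * ((e - center) / sigma) ** 2)
    return ResolutionKernel(grid, p / (p.sum() * grid.step))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_Q_HEADER = re.compile(r"#\s*Q\s*=\s*([0-9.eE+-]+)\s*A\^-1")


def write_grouped_spectra(path, spectra: list[Spectrum],
                          resolution: ResolutionKernel | None = None) -> None:
    """Write spectra to grouped CSV (by suffix .csv) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix == ".csv":
        with open(path, "w") as fh:
            for sp in spectra:
                fh.write(f"# Q={sp.q:g} A^-1\n")
                fh.write("E_meV,intensity,sigma\n")
                for e, y, s in zip(sp.energies.values, sp.intensity, sp.sigma):
                    fh.write(f"{e:.9g},{y:.9g},{s:.9g}\n")
        return
    with h5py.File(path, "w") as fh:
        for i, sp in enumerate(spectra):
            g = fh.create_group(f"spectra/Q{i}")
            g.create_dataset("q", data=sp.q)
            g.create_dataset("energies", data=sp.energies.values)
            g.create_dataset("intensity", data=sp.intensity)
            g.create_dataset("sigma", data=sp.sigma)
        if resolution is not None:
            g = fh.create_group("resolution")
            g.create_dataset("energies", data=resolution.energies.values)
            g.create_dataset("profile", data=resolution.profile)


def read_grouped_spectra(path, fmt: str | None = None) -> list[Spectrum]:
    """Read grouped spectra from CSV or HDF5 (format inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("csv-grouped" if path.suffix == ".csv" else "hdf5")
    if fmt == "csv-grouped":
        return _read_csv_grouped(path)
    if fmt == "hdf5":
        spectra = []
        with h5py.File(path, "r") as fh:
            keys = sorted(fh["spectra"], key=lambda k: int(k[1:]))
            for k in keys:
                g = fh[f"spectra/{k}"]
                spectra.append(Spectrum(
                    q=float(g["q"][()]),
                    energies=EnergyGrid(g["energies"][:]),
                    intensity=g["intensity"][:],
                    sigma=g["sigma"][:],
                ))
        return spectra
    raise ValueError(f"unknown format {fmt!r}")


def read_resolution(path) -> ResolutionKernel:
    """Read the resolution kernel from an HDF5 file's /resolution group."""
    with h5py.File(path, "r") as fh:
        if "resolution" not in fh:
            raise KeyError(f"no /resolution group in {path}")
        g = fh["resolution"]
        return ResolutionKernel(EnergyGrid(g["energies"][:]), g["profile"][:])


def _read_csv_grouped(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    q = None
    rows: list[tuple[float, float, float]] = []

    def flush(lineno: int) -> None:
        nonlocal rows, q
        if q is None:
            return
        if not rows:
            raise ValueError(f"{path}:{lineno}: empty Q group")
        arr = np.array(rows)
        try:
            grid = EnergyGrid(arr[:, 0])
        except ValueError as exc:
            raise ValueError(f"{path}: bad energy grid in Q={q} block: {exc}") from exc
        spectra.append(Spectrum(q, grid, arr[:, 1], arr[:, 2]))
        rows = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            m = _Q_HEADER.match(line)
            if m:
                flush(lineno)
                q = float(m.group(1))
                continue
            if line.startswith("E_meV"):
                if line != "E_meV,intensity,sigma":
                    raise ValueError(f"{path}:{lineno}: missing columns, "
                                     f"expected 'E_meV,intensity,sigma'")
                continue
            if q is None:
                raise ValueError(f"{path}:{lineno}: data before any Q header")
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            rows.append(tuple(float(x) for x in parts))
    flush(-1)
    if not spectra:
        raise ValueError(f"{path}: no Q groups found")
    return spectra


# ---------------------------------------------------------------------------
# solvent subtraction
# ---------------------------------------------------------------------------

def default_solvent_fraction(concentration_M: float = 0.070,
                             molar_volume_L: float = DODAB_MOLAR_VOLUME_L_PER_MOL) -> float:
    """Volume fraction of D₂O in the solution, φ ≈ 1 − v·c.

    Approximates the solute volume from its molarity and an approximate molar
    volume; override with a measured value when available.
    """
    phi = 1.0 - molar_volume_L * concentration_M
    if not 0.0 < phi <= 1.0:
        raise ValueError("computed phi outside (0, 1]")
    return phi


def subtract_solvent(solution: Spectrum, solvent: Spectrum, phi: float) -> Spectrum:
    """Bilayer signal I_bl = I_solution − φ·I_D2O with propagated errors.

    σ_out = sqrt(σ_sol² + φ²·σ_D2O²).  Negative bins are retained (unbiased
    least squares) and counted in ``meta['n_negative_bins']``.
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must be in (0, 1]")
    if solution.energies != solvent.energies or solution.q != solvent.q:
        raise ValueError("solution and solvent must share Q and energy grid")
    intensity = solution.intensity - phi * solvent.intensity
    sigma = np.sqrt(solution.sigma**2 + phi**2 * solvent.sigma**2)
    return Spectrum(
        q=solution.q,
        energies=solution.energies,
        intensity=intensity,
        sigma=sigma,
        meta={"phi": phi, "n_negative_bins": int((intensity < 0).sum())},
    )


# ---------------------------------------------------------------------------
# resolution convolution
# ---------------------------------------------------------------------------

def _lag_kernel(kernel: ResolutionKernel, step: float, n_signal: int) -> np.ndarray:
    """Resample the kernel onto a symmetric lag grid centred on its peak."""
    e, p = kernel.energies.values, kernel.profile
    peak = e[np.argmax(p)]
    support = np.abs(e - peak)[p > 1e-12 * p.max()].max()
    m_needed = max(int(np.ceil(support / step)) + 2, 3)
    # keep the kernel shorter than the signal so mode='same' stays aligned
    m = min(m_needed, (n_signal - 1) // 2)
    if m < m_needed:
        warnings.warn("resolution kernel wider than the energy window; "
                      "tails truncated", RuntimeWarning, stacklevel=3)
    lags = np.arange(-m, m + 1) * step
    k = np.interp(lags + peak, e, p, left=0.0, right=0.0)
    area = k.sum() * step
    if area <= 0:
        raise ValueError("kernel vanishes on the target grid")
    return k / area


def convolve_resolution_profile(values: np.ndarray, kernel_profile: np.ndarray,
                                step: float) -> np.ndarray:
    """Centre-aligned discrete convolution × grid step with an on-grid kernel.

    ``kernel_profile`` is the unit-area kernel on the same (uniform) grid as
    ``values``, peaked at E = 0; it is internally re-centred onto a symmetric
    lag window so that a delta-like kernel acts as the identity.
    """
    values = np.asarray(values, dtype=float)
    i_peak = int(np.argmax(kernel_profile))
    nz = np.where(kernel_profile > 1e-12 * kernel_profile.max())[0]
    m = min(max(int(max(i_peak - nz[0], nz[-1] - i_peak)) + 2, 1),
            (values.size - 1) // 2)
    idx = np.arange(i_peak - m, i_peak + m + 1)
    k = np.where((idx >= 0) & (idx < kernel_profile.size),
                 kernel_profile[np.clip(idx, 0, kernel_profile.size - 1)], 0.0)
    k = k / (k.sum() * step)
    return np.convolve(values, k, mode="same") * step


def convolve_resolution(values: np.ndarray, kernel: ResolutionKernel,
                        grid: EnergyGrid, warn_tol: float = 1e-3) -> np.ndarray:
    """Convolve model values on ``grid`` with the measured resolution.

    The kernel is linearly interpolated onto a symmetric lag grid with the
    signal's spacing and renormalized; the discrete convolution preserves the
    total integral up to edge losses, reported via a warning above
    ``warn_tol``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(grid),):
        raise ValueError("values must live on the target grid")
    k = _lag_kernel(kernel, grid.step, values.size)
    out = np.convolve(values, k, mode="same") * grid.step
    before = values.sum() * grid.step
    after = out.sum() * grid.step
    if before > 0 and abs(after - before) / before > warn_tol:
        warnings.warn(
            f"convolution edge losses {abs(after-before)/before:.2e} exceed "
            f"{warn_tol:g}", RuntimeWarning, stacklevel=2)
    return out
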