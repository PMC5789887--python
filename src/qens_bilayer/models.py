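"""Incoherent scattering laws for lipid-bilayer dynamics.

Every model here decomposes into an elastic line plus a finite mixture of
Lorentzians centred at E = 0, represented by :class:`LorentzianMixture`.
That makes resolution convolution, composition of independent motions
(lateral ⊗ internal — a convolution of Lorentzians is a Lorentzian with
summed HWHMs) and numerical HWHM extraction exact and cheap.

Models implemented:

* uniaxial rotational diffusion of all-trans alkyl chains, approximated by
  jumps among N_s equivalent sites on a circle of radius a (gel/coagel);
* 3-fold jump reorientation of head-group methyl hydrogens;
* localized translational diffusion (LTD) inside reflecting spheres with
  linearly distributed radii and diffusivities (fluid), using the
  Volino–Dianoux eigenmode expansion;
* Fickian lateral diffusion of whole lipids, Γ_lat = ħ·D_lat·Q².

Units: Q in Å⁻¹, lengths in Å, times in ps, energies in meV, diffusivities
in Å²/ps (see :mod:`qens_bilayer.constants`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import spherical_jn

from .constants import HBAR_MEV_PS as HBAR
from .constants import CM2_PER_S_TO_A2_PER_PS, P_HEAD, P_TAIL

__all__ = [
    "GelCoagelModelParams",
    "FluidModelParams",
    "LateralModel",
    "SphereEigenvalues",
    "LorentzianMixture",
    "lorentzian",
    "j0",
    "jump_rotation_structure_factors",
    "uniaxial_rotation_components",
    "uniaxial_rotation_sqw",
    "methyl_3fold_components",
    "methyl_3fold_sqw",
    "sphere_eigenvalues",
    "sphere_structure_factors",
    "confined_sphere_components",
    "confined_sphere_sqw",
    "eisf_gel_coagel",
    "eisf_fluid",
    "composite_internal_components",
    "composite_internal_sqw",
    "bilayer_components",
    "bilayer_sqw",
    "model_hwhm",
    "hwhm_of_mixture",
]


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def lorentzian(gamma: float, e) -> np.ndarray:
    """Unit-area Lorentzian (1/π)·γ/(γ² + E²) with HWHM ``gamma`` (meV)."""
    if gamma <= 0:
        raise ValueError(f"Lorentzian HWHM must be positive, got {gamma}")
    e = np.asarray(e, dtype=float)
    return (gamma / np.pi) / (gamma * gamma + e * e)


def j0(x) -> np.ndarray:
    """Spherical Bessel function of order zero, sin(x)/x, safe at x = 0."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def _j1_over_x(x: np.ndarray) -> np.ndarray:
    """j₁(x)/x with its x→0 limit 1/3."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 / 3.0, spherical_jn(1, xs) / xs)


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass
class GelCoagelModelParams:
    """Internal-motion parameters for the ordered (gel/coagel) phases.

    p_x : fraction of alkyl-chain hydrogens mobile on the instrument
        time scale; a : radius of gyration of chain hydrogens about the chain
        axis (Å); b : methyl H–H distance (Å); tau : mean inter-site residence
        time of the N_s-site uniaxial jump rotation (ps); tau_MG : methyl
        residence time (ps); p_head/p_tail : head/tail hydrogen fractions.
    """

    p_x: float
    a: float
    tau: float
    tau_MG: float
    b: float = 1.8
    n_s: int = 12
    p_head: float = P_HEAD
    p_tail: float = P_TAIL

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_x <= 1.0:
            raise ValueError("p_x must be in [0, 1]")
        if self.n_s < 2:
            raise ValueError("n_s must be >= 2")
        for name in ("a", "b", "tau", "tau_MG"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.p_head + self.p_tail - 1.0) > 1e-9:
            raise ValueError("p_head + p_tail must equal 1")

    @property
    def d_r(self) -> float:
        """Rotational diffusion constant D_r = (2/τ)·sin²(π/N_s), in ps⁻¹."""
        return 2.0 / self.tau * np.sin(np.pi / self.n_s) ** 2

    @classmethod
    def from_d_r(cls, p_x, a, d_r_per_ps, tau_MG, **kw) -> "GelCoagelModelParams":
        tau = 2.0 * np.sin(np.pi / kw.get("n_s", 12)) ** 2 / d_r_per_ps
        return cls(p_x=p_x, a=a, tau=tau, tau_MG=tau_MG, **kw)


@dataclass
class FluidModelParams:
    """Internal-motion parameters for the fluid phase (LTD + methyl rotation).

    Hydrogens of the i-th CH₂ unit diffuse inside a reflecting sphere of
    radius R_i with diffusivity D_i, both linearly interpolated between
    (R_min, D_min) at the head end and (R_max, D_max) at the tail end over
    N_c CH₂ units.  Diffusivities in Å²/ps.
    """

    r_min: float
    r_max: float
    d_min: float
    d_max: float
    tau_MG: float
    n_c: int = 18
    b: float = 1.8
    p_head: float = P_HEAD
    p_tail: float = P_TAIL

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= self.r_max:
            raise ValueError("need 0 < r_min <= r_max")
        if not 0 < self.d_min <= self.d_max:
            raise ValueError("need 0 < d_min <= d_max")
        if self.tau_MG <= 0 or self.b <= 0:
            raise ValueError("tau_MG and b must be positive")
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")
        if abs(self.p_head + self.p_tail - 1.0) > 1e-9:
            raise ValueError("p_head + p_tail must equal 1")

    def _interp(self, lo: float, hi: float) -> np.ndarray:
        if self.n_c == 1:
            return np.array([lo])
        i = np.arange(self.n_c, dtype=float)
        return (i / (self.n_c - 1)) * (hi - lo) + lo

    @property
    def radii(self) -> np.ndarray:
        """Per-site sphere radii R_i (Å), R_1 = r_min ... R_{N_c} = r_max."""
        return self._interp(self.r_min, self.r_max)

    @property
    def diffusivities(self) -> np.ndarray:
        """Per-site diffusivities D_i (Å²/ps)."""
        return self._interp(self.d_min, self.d_max)


@dataclass
class LateralModel:
    """Whole-lipid lateral diffusion within a leaflet (Fick's law).

    ``d_lat`` is stored in cm²/s as reported; Γ_lat(Q) = ħ·D·Q² with D
    converted to Å²/ps internally.  Optional Arrhenius parameters carry the
    temperature dependence D(T) = D_0·exp(−E_a/(R·T)).
    """

    d_lat: float  # cm²/s
    e_a: float | None = None  # kcal/mol
    d_0: float | None = None  # cm²/s

    def __post_init__(self) -> None:
        if self.d_lat < 0:
            raise ValueError("d_lat must be >= 0")

    @property
    def d_lat_A2_ps(self) -> float:
        return self.d_lat * CM2_PER_S_TO_A2_PER_PS

    def gamma_lat(self, q) -> np.ndarray:
        """HWHM of the lateral Lorentzian, ħ·D·Q² (meV)."""
        q = np.asarray(q, dtype=float)
        return HBAR * self.d_lat_A2_ps * q * q


# ---------------------------------------------------------------------------
# mixture container
# ---------------------------------------------------------------------------

@dataclass
class LorentzianMixture:
    """Elastic weight plus a finite set of unit-area Lorentzians.

    ``density(e)`` omits the elastic delta; place it explicitly (e.g. as a
    resolution-shaped line) when rendering onto a grid.
    """

    elastic: float
    weights: np.ndarray
    gammas: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        g = np.atleast_1d(np.asarray(self.gammas, dtype=float))
        if w.shape != g.shape:
            raise ValueError("weights and gammas must have the same shape")
        keep = w > 0
        self.weights = w[keep]
        self.gammas = g[keep]
        if np.any(self.gammas <= 0):
            raise ValueError("all Lorentzian HWHMs must be positive")

    @property
    def total_weight(self) -> float:
        return float(self.elastic + self.weights.sum())

    @property
    def quasielastic_weight(self) -> float:
        return float(self.weights.sum())

    def density(self, e) -> np.ndarray:
        """Quasielastic spectral density Σ wᵢ·L(γᵢ, E) (1/meV)."""
        e = np.atleast_1d(np.asarray(e, dtype=float))
        out = np.zeros_like(e)
        e2 = e * e
        amp = self.weights * self.gammas / np.pi
        g2 = self.gammas * self.gammas
        for a, g in zip(amp, g2):  # cache-friendly: one 1-D temp per term
            out += a / (g + e2)
        return out

    def broadened(self, gamma: float) -> "LorentzianMixture":
        """Convolve with a Lorentzian of HWHM ``gamma`` (lateral motion).

        The elastic delta becomes a Lorentzian of width ``gamma``; every
        quasielastic width gains ``gamma``.  With gamma = 0 this is a no-op.
        """
        if gamma < 0:
            raise ValueError("gamma must be >= 0")
        if gamma == 0:
            return LorentzianMixture(self.elastic, self.weights.copy(),
                                     self.gammas.copy())
        w = np.concatenate([[self.elastic], self.weights])
        g = np.concatenate([[gamma], self.gammas + gamma])
        return LorentzianMixture(0.0, w, g)

    def on_grid(self, grid, kernel_profile: np.ndarray | None = None) -> np.ndarray:
        """Render S(E) on an :class:`~qens_bilayer.grids.EnergyGrid`.

        With ``kernel_profile`` (unit-area resolution on the same grid) the
        elastic delta becomes elastic·kernel and the quasielastic part is
        numerically convolved.  Without it the delta is a nearest-bin impulse
        of height elastic/ΔE.
        """
        from .reduction import convolve_resolution_profile

        qe = self.density(grid.values)
        if kernel_profile is None:
            out = qe.copy()
            out[grid.izero] += self.elastic / grid.step
            return out
        out = convolve_resolution_profile(qe, kernel_profile, grid.step)
        out += self.elastic * kernel_profile
        return out


# ---------------------------------------------------------------------------
# uniaxial jump rotation (gel/coagel alkyl chains)
# ---------------------------------------------------------------------------

def jump_rotation_structure_factors(q_a: float, n_s: int) -> np.ndarray:
    """Structure factors B_0..B_{N_s−1} for jumps among N_s sites on a circle.

    B_n(Qa) = (1/N_s) Σ_{i=1}^{N_s} j₀(2Qa·sin(πi/N_s))·cos(2πni/N_s).
    They satisfy Σ_n B_n = 1 exactly.
    """
    if n_s < 2:
        raise ValueError("n_s must be >= 2")
    if q_a < 0:
        raise ValueError("q_a must be >= 0")
    i = np.arange(1, n_s + 1, dtype=float)
    j = j0(2.0 * q_a * np.sin(np.pi * i / n_s))
    n = np.arange(n_s, dtype=float)
    cos = np.cos(2.0 * np.pi * np.outer(n, i) / n_s)
    return cos @ j / n_s


def uniaxial_rotation_components(q: float, params: GelCoagelModelParams) -> LorentzianMixture:
    """Scattering law of N_s-site uniaxial jump rotation as a mixture.

    Elastic weight B_0(Qa); N_s−1 Lorentzians of HWHM ħ/τ_n with
    τ_n⁻¹ = 2τ⁻¹·sin²(nπ/N_s).
    """
    b = jump_rotation_structure_factors(q * params.a, params.n_s)
    n = np.arange(1, params.n_s, dtype=float)
    gammas = HBAR * 2.0 / params.tau * np.sin(np.pi * n / params.n_s) ** 2
    return LorentzianMixture(float(b[0]), np.maximum(b[1:], 0.0), gammas)


def uniaxial_rotation_sqw(q: float, e, params: GelCoagelModelParams) -> np.ndarray:
    """S(Q,E) of the uniaxial jump-rotation model, quasielastic part.

    The elastic term B_0(Qa)·δ(E) is carried by the mixture; use
    :func:`uniaxial_rotation_components` for weight bookkeeping.
    """
    return uniaxial_rotation_components(q, params).density(e)


# ---------------------------------------------------------------------------
# methyl three-fold rotation (head group)
# ---------------------------------------------------------------------------

def methyl_3fold_components(q: float, b: float = 1.8, tau_MG: float = 5.0) -> LorentzianMixture:
    """Three-site jump reorientation of methyl hydrogens.

    Elastic fraction (1 + 2j₀(Qb))/3; a single quasielastic Lorentzian of
    HWHM 3ħ/τ_MG carries the rest.
    """
    if b <= 0 or tau_MG <= 0:
        raise ValueError("b and tau_MG must be positive")
    el = float((1.0 + 2.0 * j0(q * b)) / 3.0)
    return LorentzianMixture(el, np.array([1.0 - el]),
                             np.array([3.0 * HBAR / tau_MG]))


def methyl_3fold_sqw(q: float, e, b: float = 1.8, tau_MG: float = 5.0) -> np.ndarray:
    """Quasielastic density of the methyl 3-fold rotation model."""
    return methyl_3fold_components(q, b, tau_MG).density(e)


# ---------------------------------------------------------------------------
# diffusion inside a reflecting sphere (Volino–Dianoux)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereEigenvalues:
    """Roots x_n^l of d j_l(x)/dx = 0 (reflecting boundary), x > 0.

    ``roots[l, n-1]`` is the n-th positive stationary point of the l-th
    spherical Bessel function.  For l = 0 these are the roots of j₁(x) = 0.
    """

    roots: np.ndarray  # shape (l_max+1, n_max)

    @property
    def l_max(self) -> int:
        return self.roots.shape[0] - 1

    @property
    def n_max(self) -> int:
        return self.roots.shape[1]


@lru_cache(maxsize=8)
def sphere_eigenvalues(l_max: int = 20, n_max: int = 20) -> SphereEigenvalues:
    """Find the reflecting-sphere eigenvalues by bracketing + Brent's method."""
    if l_max < 1 or n_max < 1:
        raise ValueError("l_max and n_max must be >= 1")
    roots = np.empty((l_max + 1, n_max))
    for l in range(l_max + 1):
        def f(x, l=l):
            return spherical_jn(l, x, derivative=True)

        x_hi = (n_max + l / 2.0 + 3.0) * np.pi
        grid = np.arange(1e-4, x_hi, 0.02)
        vals = f(grid)
        sign_change = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        found = []
        for k in sign_change:
            try:
                found.append(brentq(f, grid[k], grid[k + 1], xtol=1e-12))
            except ValueError as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"eigenvalue bracketing failed at l={l}, n={len(found)+1}"
                ) from exc
            if len(found) == n_max:
                break
        if len(found) < n_max:  # pragma: no cover - defensive
            raise RuntimeError(f"only {len(found)} roots found for l={l}")
        roots[l] = found
    return SphereEigenvalues(roots)


def sphere_structure_factors(qr: float, eig: SphereEigenvalues) -> tuple[float, np.ndarray]:
    """Elastic A₀⁰(QR) and quasielastic weights (2l+1)·A_n^l(QR).

    A₀⁰(QR) = [3j₁(QR)/QR]²; for (l,n) ≠ (0,0)

        A_n^l = 6(x_n^l)²/((x_n^l)² − l(l+1)) · [QR·j_l'(QR)/((QR)² − (x_n^l)²)]²

    with the removable singularity at QR = x_n^l evaluated analytically.
    The full set satisfies A₀⁰ + Σ (2l+1)A_n^l = 1 (up to truncation).
    Returns (A00, W) with W shaped like ``eig.roots``.
    """
    x = eig.roots
    a00 = float(9.0 * _j1_over_x(np.asarray(qr)) ** 2)
    ls = np.arange(eig.l_max + 1, dtype=float)[:, None]
    jlp = np.array(
        [spherical_jn(l, qr, derivative=True) for l in range(eig.l_max + 1)]
    )[:, None]
    x2 = x * x
    den = qr * qr - x2
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (6.0 * x2 / (x2 - ls * (ls + 1.0))) * (qr * jlp / den) ** 2
    near = np.abs(den) < 1e-9 * np.maximum(x2, 1.0)
    if np.any(near):
        jl = np.array(
            [spherical_jn(l, x[l]) for l in range(eig.l_max + 1)]
        )
        limit = 1.5 * jl**2 * (x2 - ls * (ls + 1.0)) / x2
        a = np.where(near, limit, a)
    w = (2.0 * ls + 1.0) * a
    return a00, w


def confined_sphere_components(
    q: float,
    radius: float,
    diffusivity: float,
    eig: SphereEigenvalues | None = None,
    weight_tol: float = 1e-3,
    on_truncation: str = "warn",
) -> LorentzianMixture:
    """Scattering law of diffusion inside a reflecting sphere.

    Lorentzian HWHMs are ħ·(x_n^l)²·D/R² (meV); weights (2l+1)·A_n^l(QR).
    A vanishing radius collapses to the analytic elastic limit (weight 1).
    """
    if radius < 0 or diffusivity <= 0:
        raise ValueError("radius must be >= 0 and diffusivity > 0")
    if radius < 1e-8:
        return LorentzianMixture(1.0, np.empty(0), np.empty(0))
    if eig is None:
        eig = sphere_eigenvalues()
    a00, w = sphere_structure_factors(q * radius, eig)
    gammas = HBAR * eig.roots**2 * diffusivity / radius**2
    mix = LorentzianMixture(a00, np.maximum(w, 0.0).ravel(), gammas.ravel())
    missing = 1.0 - mix.total_weight
    if missing > weight_tol:
        msg = (f"sphere-model truncation misses {missing:.2e} spectral weight "
               f"at QR={q*radius:.2f}; increase l_max/n_max")
        if on_truncation == "raise":
            raise RuntimeError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return mix


def confined_sphere_sqw(
    q: float, e, radius: float, diffusivity: float,
    eig: SphereEigenvalues | None = None,
) -> np.ndarray:
    """Quasielastic density of the reflecting-sphere diffusion model."""
    return confined_sphere_components(q, radius, diffusivity, eig).density(e)


# ---------------------------------------------------------------------------
# EISFs
# ---------------------------------------------------------------------------

def eisf_gel_coagel(q, params: GelCoagelModelParams) -> np.ndarray:
    """EISF of the ordered phases: methyl head term + partially mobile chains.

    A(Q) = (P_h/3)(1 + 2j₀(Qb)) + P_t(1−p_x)
           + P_t·(p_x/N_s)·Σ_{i=1}^{N_s} j₀(2Qa·sin(πi/N_s))
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    head = params.p_head / 3.0 * (1.0 + 2.0 * j0(q * params.b))
    i = np.arange(1, params.n_s + 1, dtype=float)
    ring = j0(2.0 * np.outer(q, np.ones_like(i)) * params.a
              * np.sin(np.pi * i / params.n_s)).mean(axis=1)
    out = head + params.p_tail * (1.0 - params.p_x) + params.p_tail * params.p_x * ring
    return out if out.size > 1 else float(out[0])


def eisf_fluid(q, params: FluidModelParams) -> np.ndarray:
    """EISF of the fluid phase: methyl head term + per-site sphere terms.

    A(Q) = (P_h/3)(1 + 2j₀(Qb)) + (P_t/N_c)·Σ_i [3j₁(QR_i)/(QR_i)]²
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    head = params.p_head / 3.0 * (1.0 + 2.0 * j0(q * params.b))
    qr = np.outer(q, params.radii)
    spheres = (9.0 * _j1_over_x(qr) ** 2).mean(axis=1)
    out = head + params.p_tail * spheres
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# composite internal scattering laws
# ---------------------------------------------------------------------------

def composite_internal_components(
    q: float,
    phase: str,
    params: GelCoagelModelParams | FluidModelParams,
    eig: SphereEigenvalues | None = None,
) -> LorentzianMixture:
    """Full internal-motion scattering law of one phase at one Q.

    gel/coagel: methyl 3-fold term (weight P_h) + uniaxial jump rotation of
    the mobile chain fraction (weight p_x·P_t) + immobile chain elastic.
    fluid: methyl term + localized translational diffusion over N_c spheres
    (weight P_t).  The elastic weight equals the corresponding EISF.
    """
    if phase in ("gel", "coagel"):
        if not isinstance(params, GelCoagelModelParams):
            raise TypeError(f"phase {phase!r} needs GelCoagelModelParams")
        methyl = methyl_3fold_components(q, params.b, params.tau_MG)
        ring = uniaxial_rotation_components(q, params)
        elastic = (params.p_head * methyl.elastic
                   + params.p_tail * (1.0 - params.p_x)
                   + params.p_tail * params.p_x * ring.elastic)
        weights = np.concatenate([
            params.p_head * methyl.weights,
            params.p_tail * params.p_x * ring.weights,
        ])
        gammas = np.concatenate([methyl.gammas, ring.gammas])
        return LorentzianMixture(elastic, weights, gammas)
    if phase == "fluid":
        if not isinstance(params, FluidModelParams):
            raise TypeError("phase 'fluid' needs FluidModelParams")
        if eig is None:
            eig = sphere_eigenvalues()
        methyl = methyl_3fold_components(q, params.b, params.tau_MG)
        elastic = params.p_head * methyl.elastic
        weights = [params.p_head * methyl.weights]
        gammas = [methyl.gammas]
        frac = params.p_tail / params.n_c
        for r, d in zip(params.radii, params.diffusivities):
            sph = confined_sphere_components(q, r, d, eig)
            elastic += frac * sph.elastic
            weights.append(frac * sph.weights)
            gammas.append(sph.gammas)
        return LorentzianMixture(elastic, np.concatenate(weights),
                                 np.concatenate(gammas))
    raise ValueError(f"unknown phase {phase!r}")


def composite_internal_sqw(
    q: float, e, phase: str,
    params: GelCoagelModelParams | FluidModelParams,
    eig: SphereEigenvalues | None = None,
) -> np.ndarray:
    """Quasielastic density of the composite internal model at one Q."""
    return composite_internal_components(q, phase, params, eig).density(e)


def bilayer_components(
    q: float,
    lateral: LateralModel | None,
    phase: str,
    params: GelCoagelModelParams | FluidModelParams,
    eig: SphereEigenvalues | None = None,
) -> LorentzianMixture:
    """Full bilayer scattering law: lateral ⊗ internal.

    For the gel and fluid phases the elastic line is replaced by the lateral
    Lorentzian L(Γ_lat) and every internal width gains Γ_lat (exact Lorentzian
    convolution).  The coagel phase has no observable lateral motion and
    keeps its elastic delta.
    """
    internal = composite_internal_components(q, phase, params, eig)
    if phase == "coagel" or lateral is None:
        return internal
    return internal.broadened(float(lateral.gamma_lat(q)))


def bilayer_sqw(
    q: float, e,
    lateral: LateralModel | None,
    phase: str,
    params: GelCoagelModelParams | FluidModelParams,
    eig: SphereEigenvalues | None = None,
) -> np.ndarray:
    """Quasielastic density of the full bilayer law at one Q."""
    return bilayer_components(q, lateral, phase, params, eig).density(e)


# ---------------------------------------------------------------------------
# numerical HWHM of a multi-Lorentzian quasielastic profile
# ---------------------------------------------------------------------------

def hwhm_of_mixture(mix: LorentzianMixture) -> float:
    """Half-width at half-maximum of the quasielastic part of a mixture.

    The quasielastic profile of a centred Lorentzian mixture is even and
    strictly decreasing in |E|, so the half height is crossed exactly once;
    found by bracketing + Brent's method.
    """
    if mix.quasielastic_weight <= 0:
        raise ValueError("mixture has no quasielastic weight")
    w, g = mix.weights, mix.gammas

    def s(e: float) -> float:
        return float((w * (g / np.pi) / (g * g + e * e)).sum())

    s0 = s(0.0)
    target = 0.5 * s0
    lo = float(g.min()) * 1e-3
    hi = float(g.max())
    while s(hi) > target:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - defensive
            raise RuntimeError("HWHM search failed to bracket the half height")
    return brentq(lambda e: s(e) - target, lo if s(lo) > target else 0.0, hi,
                  xtol=1e-15, rtol=1e-10, maxiter=200)


def model_hwhm(
    q,
    phase: str,
    params: GelCoagelModelParams | FluidModelParams,
    eig: SphereEigenvalues | None = None,
) -> np.ndarray:
    """Numerical Γ_int(Q) of the composite internal model (meV).

    No closed form exists for the HWHM of a multi-Lorentzian profile; each Q
    is solved numerically on the elastic-removed quasielastic profile.
    """
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if eig is None and phase == "fluid":
        eig = sphere_eigenvalues()
    out = np.array([
        hwhm_of_mixture(composite_internal_components(qi, phase, params, eig))
        for qi in q_arr
    ])
    return out if np.ndim(q) else float(out[0])
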