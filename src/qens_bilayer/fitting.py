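"""The QENS inference chain.

Per-Q spectra are decomposed phenomenologically (no a-priori Q model):

* gel/fluid: S(Q,E) = scale·[A·L(Γ_lat) + (1−A)·L(Γ_lat+ΔΓ)] ⊗ R + bg,
  parameterized with ΔΓ = Γ_int ≥ 0 so Γ_tot ≥ Γ_lat by construction;
* coagel: S(Q,E) = scale·[A·δ(E) + (1−A)·L(Γ_int)] ⊗ R + bg, the elastic
  line rendered resolution-shaped.

The Q dependences of the extracted parameters are then confronted with the
physical models: the EISF A(Q) with the phase-specific geometry (mobile
fraction p_x and gyration radius a, or sphere radii R_min..R_max); the
internal width Γ_int(Q) with the numerically computed model HWHM; and the
lateral width Γ_lat(Q) with Fick's law ħ·D·Q², whose temperature dependence
gives an Arrhenius activation energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .constants import (
    A2_PER_PS_TO_CM2_PER_S,
    HBAR_MEV_PS as HBAR,
    R_GAS_KCAL_PER_MOL_K,
)
from .models import (
    FluidModelParams,
    GelCoagelModelParams,
    composite_internal_components,
    eisf_fluid,
    eisf_gel_coagel,
    hwhm_of_mixture,
    lorentzian,
    sphere_eigenvalues,
    sphere_structure_factors,
)
from .reduction import ResolutionKernel, Spectrum, convolve_resolution_profile

__all__ = [
    "FitConfig",
    "PerQFitResult",
    "ArrheniusFit",
    "fit_per_q",
    "fit_eisf",
    "fit_hwhm_internal",
    "fit_fickian",
    "fit_arrhenius",
]


@dataclass
class FitConfig:
    """Optimizer settings shared by the spectral fits."""

    n_starts: int = 8
    seed: int = 1234
    background: str = "linear"  # 'linear' | 'flat' | 'none'
    max_gamma: float = 2.0  # meV, upper bound for any HWHM


@dataclass
class PerQFitResult:
    """Phenomenological parameters extracted from one spectrum."""

    q: float
    eisf: float
    gamma_lat: float
    gamma_int: float
    scale: float
    background: tuple[float, float]
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    chi2_reduced: float = float("nan")

    @property
    def gamma_tot(self) -> float:
        return self.gamma_lat + self.gamma_int


@dataclass
class ArrheniusFit:
    """ln D = ln D_0 − E_a/(R·T) least-squares result."""

    e_a: float  # kcal/mol
    d_0: float  # cm²/s
    covariance: np.ndarray  # of (slope, intercept) in ln-D space
    e_a_stderr: float = float("nan")


# ---------------------------------------------------------------------------
# per-Q spectral decomposition
# ---------------------------------------------------------------------------

def _lorentz_pair(e, a, g_lat, dg):
    narrow = a * lorentzian(g_lat, e)
    broad = (1.0 - a) * lorentzian(g_lat + dg, e)
    return narrow + broad


def fit_per_q(spectrum: Spectrum, kernel: ResolutionKernel, phase: str,
              config: FitConfig | None = None) -> PerQFitResult:
    """Least-squares decomposition of one spectrum into elastic/lateral and
    total components convolved with the measured resolution.

    Multi-start bounded least squares (seeded); parameter uncertainties from
    the Jacobian at the optimum.  When A pins at 1 the broad width is
    unidentifiable and the result is flagged.
    """
    cfg = config or FitConfig()
    if phase not in ("coagel", "gel", "fluid"):
        raise ValueError(f"unknown phase {phase!r}")
    grid = spectrum.energies
    e = grid.values
    y = spectrum.intensity
    sig = np.where(spectrum.sigma > 0, spectrum.sigma, 1.0)
    kern = kernel.interpolated(grid).profile
    step = grid.step
    izero = grid.izero

    has_lat = phase != "coagel"
    bg_n = {"none": 0, "flat": 1, "linear": 2}[cfg.background]
    scale0 = max(float(np.trapezoid(np.clip(y, 0, None), e)), 1e-12)

    def model(p):
        if has_lat:
            a, g_lat, dg, scale = p[0], p[1], p[2], p[3]
            qe = _lorentz_pair(e, a, g_lat, dg)
            out = scale * convolve_resolution_profile(qe, kern, step)
        else:
            a, g_int, scale = p[0], p[1], p[2]
            qe = (1.0 - a) * lorentzian(g_int, e)
            out = scale * (convolve_resolution_profile(qe, kern, step)
                           + a * kern)
        nb = 4 if has_lat else 3
        if bg_n >= 1:
            out = out + p[nb]
        if bg_n == 2:
            out = out + p[nb + 1] * e
        return out

    def resid(p):
        return (model(p) - y) / sig

    if has_lat:
        lo = [0.0, 1e-5, 0.0, 1e-12] + [-np.inf] * bg_n
        hi = [1.0, cfg.max_gamma, cfg.max_gamma, np.inf] + [np.inf] * bg_n
        p0_base = [0.6, 0.01, 0.1, scale0] + [0.0] * bg_n
    else:
        lo = [0.0, 1e-5, 1e-12] + [-np.inf] * bg_n
        hi = [1.0, cfg.max_gamma, np.inf] + [np.inf] * bg_n
        p0_base = [0.8, 0.1, scale0] + [0.0] * bg_n

    rng = np.random.default_rng(cfg.seed)
    best = None
    for start in range(max(cfg.n_starts, 1)):
        p0 = np.array(p0_base, dtype=float)
        if start > 0:
            p0[0] = rng.uniform(0.05, 0.95)
            if has_lat:
                p0[1] = 10 ** rng.uniform(-4, -1.2)
                p0[2] = 10 ** rng.uniform(-2, np.log10(cfg.max_gamma) - 0.3)
            else:
                p0[1] = 10 ** rng.uniform(-3, np.log10(cfg.max_gamma) - 0.3)
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                x_scale="jac")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"per-Q fit failed to converge at Q={spectrum.q}")

    p = best.x
    dof = max(y.size - p.size, 1)
    chi2red = 2.0 * best.cost / dof
    # covariance from J^T J (residuals already σ-weighted)
    stderr: dict[str, float] = {}
    names = (["eisf", "gamma_lat", "gamma_int", "scale"] if has_lat
             else ["eisf", "gamma_int", "scale"])
    names += ["bg0", "bg1"][:bg_n]
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * chi2red
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = dict(zip(names, err))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    flags: list[str] = []
    a_val = p[0]
    if has_lat:
        g_lat, g_int = p[1], p[2]
        if a_val > 1.0 - max(2.0 * stderr.get("eisf", 0.0), 1e-3):
            flags.append("gamma_tot_unidentifiable")
        result = PerQFitResult(
            q=spectrum.q, eisf=a_val, gamma_lat=g_lat, gamma_int=g_int,
            scale=p[3],
            background=(p[4] if bg_n >= 1 else 0.0,
                        p[5] if bg_n == 2 else 0.0),
            stderr=stderr, flags=flags, chi2_reduced=chi2red)
    else:
        if a_val > 1.0 - max(2.0 * stderr.get("eisf", 0.0), 1e-3):
            flags.append("gamma_int_unidentifiable")
        result = PerQFitResult(
            q=spectrum.q, eisf=a_val, gamma_lat=0.0, gamma_int=p[1],
            scale=p[2],
            background=(p[3] if bg_n >= 1 else 0.0,
                        p[4] if bg_n == 2 else 0.0),
            stderr=stderr, flags=flags, chi2_reduced=chi2red)
    return result


# ---------------------------------------------------------------------------
# EISF model fits
# ---------------------------------------------------------------------------

def fit_eisf(q, a_obs, phase: str, sigma=None,
             fixed: dict | None = None) -> dict:
    """Fit the observed EISF with the phase-specific geometric model.

    gel/coagel → free (p_x, a); fluid → free (R_min, R_max), R_min bounded
    below at 0.05 Å (reported but physically a nuisance).  Fixed parameters
    (b, N_s, N_c, P_h, P_t) may be overridden through ``fixed``.

    Returns a dict with the fitted parameters, stderr, and flags.
    """
    q = np.asarray(q, dtype=float)
    a_obs = np.asarray(a_obs, dtype=float)
    if q.size < 4:
        raise ValueError("need >= 4 Q points")
    fixed = dict(fixed or {})
    out_of_range = a_obs > 1.0
    if sigma is not None:
        out_of_range = (a_obs - 2.0 * np.asarray(sigma)) > 1.0
    if np.any(out_of_range) or np.any(a_obs < 0):
        warnings.warn("EISF values outside [0, 1] beyond uncertainty",
                      RuntimeWarning, stacklevel=2)
    kw = {}
    if sigma is not None:
        kw = {"sigma": np.asarray(sigma, dtype=float), "absolute_sigma": True}

    if phase in ("gel", "coagel"):
        b = fixed.pop("b", 1.8)
        n_s = fixed.pop("n_s", 12)

        def f(qv, p_x, a):
            pars = GelCoagelModelParams(p_x=p_x, a=a, tau=1.0, tau_MG=1.0,
                                        b=b, n_s=n_s, **fixed)
            return np.atleast_1d(eisf_gel_coagel(qv, pars))

        popt, pcov = curve_fit(f, q, a_obs, p0=[0.5, 1.5],
                               bounds=([0.0, 0.1], [1.0, 10.0]), **kw)
        err = np.sqrt(np.diag(pcov))
        flags = []
        if popt[0] < 1e-3:
            flags.append("a_unidentifiable")  # no mobile chain hydrogens
        return {"phase": phase, "p_x": popt[0], "a": popt[1],
                "stderr": {"p_x": err[0], "a": err[1]}, "flags": flags}

    if phase == "fluid":
        b = fixed.pop("b", 1.8)
        n_c = fixed.pop("n_c", 18)

        def f(qv, r_min, r_max):
            pars = FluidModelParams(r_min=min(r_min, r_max), r_max=r_max,
                                    d_min=1.0, d_max=1.0, tau_MG=1.0,
                                    b=b, n_c=n_c, **fixed)
            return np.atleast_1d(eisf_fluid(qv, pars))

        popt, pcov = curve_fit(f, q, a_obs, p0=[0.3, 3.0],
                               bounds=([0.05, 0.1], [5.0, 20.0]), **kw)
        err = np.sqrt(np.diag(pcov))
        return {"phase": phase, "r_min": min(popt[0], popt[1]),
                "r_max": popt[1],
                "stderr": {"r_min": err[0], "r_max": err[1]}, "flags": []}

    raise ValueError(f"unknown phase {phase!r}")


# ---------------------------------------------------------------------------
# internal HWHM model fits
# ---------------------------------------------------------------------------

def _fluid_hwhm_fast(q_values, params: FluidModelParams, eig):
    """Γ_int(Q) for the fluid model with geometry-dependent weights cached.

    The sphere structure factors depend only on (Q, R_i); for fixed radii the
    HWHM objective re-solves only for new widths, which scale per site with
    D_i/R_i².
    """
    radii = params.radii
    rates = eig.roots.ravel() ** 2  # x², per (l,n)
    per_q = []
    for qv in q_values:
        ws, gs_scale = [], []
        methyl = params.p_head * 2.0 / 3.0 * (
            1.0 - np.sinc(qv * params.b / np.pi))
        for r in radii:
            _, w = sphere_structure_factors(qv * r, eig)
            ws.append(np.maximum(w.ravel(), 0.0))
            gs_scale.append(rates / r**2)
        per_q.append((methyl, np.array(ws), np.array(gs_scale)))

    def gamma_int(d_min, d_max, tau_MG):
        dp = FluidModelParams(r_min=params.r_min, r_max=params.r_max,
                              d_min=d_min, d_max=d_max, tau_MG=tau_MG,
                              n_c=params.n_c, b=params.b,
                              p_head=params.p_head, p_tail=params.p_tail)
        ds = dp.diffusivities
        frac = params.p_tail / params.n_c
        out = np.empty(len(per_q))
        for i, (m_w, ws, gsc) in enumerate(per_q):
            w = np.concatenate([[m_w], (frac * ws).ravel()])
            g = np.concatenate([[3.0 * HBAR / tau_MG],
                                HBAR * (gsc * ds[:, None]).ravel()])
            from .models import LorentzianMixture
            out[i] = hwhm_of_mixture(LorentzianMixture(0.0, w, g))
        return out

    return gamma_int


def fit_hwhm_internal(q, gamma_obs, phase: str, geometry: dict,
                      sigma=None, n_starts: int = 4, seed: int = 0) -> dict:
    """Fit observed Γ_int(Q) with the numerically computed model HWHM.

    ``geometry`` carries the EISF-stage parameters held fixed: for
    gel/coagel {p_x, a [, b, n_s]}, for fluid {r_min, r_max [, b, n_c]}.
    Free parameters: gel/coagel → (τ, τ_MG), reported also as D_r;
    fluid → (D_min, D_max, τ_MG) with D_min ≤ D_max enforced.
    """
    q = np.asarray(q, dtype=float)
    gamma_obs = np.asarray(gamma_obs, dtype=float)
    w = 1.0 / np.asarray(sigma, dtype=float) if sigma is not None else np.ones_like(gamma_obs)
    rng = np.random.default_rng(seed)

    if phase in ("gel", "coagel"):
        gp = dict(p_x=geometry["p_x"], a=geometry["a"],
                  b=geometry.get("b", 1.8), n_s=geometry.get("n_s", 12))

        def resid(x):
            tau, tau_mg = np.exp(x)
            pars = GelCoagelModelParams(tau=tau, tau_MG=tau_mg, **gp)
            model = np.array([
                hwhm_of_mixture(
                    composite_internal_components(qv, phase, pars))
                for qv in q])
            return w * (model - gamma_obs)

        best = None
        starts = [np.log([2.0, 5.0])] + [
            np.log([10 ** rng.uniform(-0.5, 1.5), 10 ** rng.uniform(0, 1.5)])
            for _ in range(n_starts - 1)]
        for x0 in starts:
            try:
                res = least_squares(resid, x0)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("HWHM fit did not converge")
        tau, tau_mg = np.exp(best.x)
        pars = GelCoagelModelParams(tau=tau, tau_MG=tau_mg, **gp)
        return {"phase": phase, "tau": tau, "tau_MG": tau_mg,
                "d_r_per_ps": pars.d_r, "d_r_per_s": pars.d_r * 1e12,
                "cost": float(best.cost)}

    if phase == "fluid":
        eig = sphere_eigenvalues()
        base = FluidModelParams(
            r_min=geometry["r_min"], r_max=geometry["r_max"],
            d_min=1e-3, d_max=1e-3, tau_MG=1.0,
            b=geometry.get("b", 1.8), n_c=geometry.get("n_c", 18))
        gamma_model = _fluid_hwhm_fast(q, base, eig)

        def resid(x):
            d_min, d_delta, tau_mg = np.exp(x)
            return w * (gamma_model(d_min, d_min + d_delta, tau_mg)
                        - gamma_obs)

        best = None
        starts = [np.log([5e-3, 0.2, 3.0])] + [
            np.log([10 ** rng.uniform(-3.3, -1.3),
                    10 ** rng.uniform(-1.3, 0.0),
                    10 ** rng.uniform(0.0, 1.0)])
            for _ in range(n_starts - 1)]
        for x0 in starts:
            try:
                res = least_squares(resid, x0)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("HWHM fit did not converge")
        d_min, d_delta, tau_mg = np.exp(best.x)
        return {"phase": phase, "d_min": d_min, "d_max": d_min + d_delta,
                "d_min_cm2_s": d_min * A2_PER_PS_TO_CM2_PER_S,
                "d_max_cm2_s": (d_min + d_delta) * A2_PER_PS_TO_CM2_PER_S,
                "tau_MG": tau_mg, "cost": float(best.cost)}

    raise ValueError(f"unknown phase {phase!r}")


# ---------------------------------------------------------------------------
# Fickian and Arrhenius fits
# ---------------------------------------------------------------------------

def fit_fickian(q, gamma_lat, sigma=None) -> dict:
    """Zero-intercept weighted fit of Γ_lat = ħ·D·Q² (Γ in meV, Q in Å⁻¹).

    Returns D in cm²/s with its standard error.
    """
    q = np.asarray(q, dtype=float)
    g = np.asarray(gamma_lat, dtype=float)
    if q.size < 3:
        raise ValueError("need >= 3 points")
    x = q * q
    w = 1.0 / np.asarray(sigma, dtype=float) ** 2 if sigma is not None else np.ones_like(g)
    sxx = np.sum(w * x * x)
    slope = np.sum(w * x * g) / sxx
    if slope < 0:
        raise ValueError("negative Fickian slope: widths decrease with Q²")
    dof = max(q.size - 1, 1)
    s2 = np.sum(w * (g - slope * x) ** 2) / dof
    slope_err = np.sqrt(s2 / sxx)
    d_A2_ps = slope / HBAR
    return {
        "d_lat_cm2_s": d_A2_ps * A2_PER_PS_TO_CM2_PER_S,
        "d_lat_stderr_cm2_s": slope_err / HBAR * A2_PER_PS_TO_CM2_PER_S,
        "slope_meVA2": slope,
    }


def fit_arrhenius(temperatures, d_values) -> ArrheniusFit:
    """Least squares of ln D vs 1/T; E_a = −slope·R in kcal/mol."""
    t = np.asarray(temperatures, dtype=float)
    d = np.asarray(d_values, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 (T, D) pairs")
    if np.any(d <= 0):
        raise ValueError("all diffusion coefficients must be positive")
    x = 1.0 / t
    y = np.log(d)
    if t.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        cov = np.full((2, 2), np.nan)
        e_a_err = float("nan")
    else:
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
        e_a_err = float(np.sqrt(cov[0, 0]) * R_GAS_KCAL_PER_MOL_K)
    return ArrheniusFit(
        e_a=-slope * R_GAS_KCAL_PER_MOL_K,
        d_0=float(np.exp(intercept)),
        covariance=cov,
        e_a_stderr=e_a_err,
    )
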