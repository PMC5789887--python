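"""Synthetic-data generators.

Every generator realizes exactly the statistical structure the analysis
assumes, so each stage of the pipeline can be exercised and calibrated
without measured data:

* QENS spectra drawn from the package's own bilayer scattering laws,
  convolved with a Gaussian (17 μeV FWHM, backscattering-like) or measured
  resolution, with Poisson counting noise;
* elastic window scans following the Gaussian approximation
  I_el ∝ exp(−⟨u²⟩Q²/6) with configurable transition features in ⟨u²⟩(T);
* particle trajectories combining 2D lateral Brownian motion, diffusion
  inside a reflecting sphere and a fast two-site jump — the three processes
  of the intermediate-scattering-function decomposition;
* ideal-geometry alkyl chains with known gauche/trans dihedral states.

All randomness flows through an explicit integer seed; fixed seed means
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .elastic import ElasticScanSeries
from .grids import EnergyGrid, default_energy_grid
from .models import (
    FluidModelParams,
    GelCoagelModelParams,
    LateralModel,
    bilayer_components,
    sphere_eigenvalues,
)
from .reduction import ResolutionKernel, Spectrum, gaussian_kernel
from .trajectory import TrajectoryBundle

__all__ = [
    "SpectrumGeneratorConfig",
    "TrajectoryGeneratorConfig",
    "generate_qens_dataset",
    "simulate_noiseless",
    "apply_counting_noise",
    "generate_elastic_scan",
    "generate_trajectory",
    "generate_chain_conformations",
    "DEFAULT_Q_VALUES",
]

#: IRIS-like detector grouping over the accessible momentum-transfer range,
#: ~0.1 Å⁻¹ apart (the density of the reported EISF/HWHM curves).
DEFAULT_Q_VALUES = tuple(np.round(np.arange(0.5, 1.81, 0.1), 2))


@dataclass
class SpectrumGeneratorConfig:
    """Conditions for one synthetic QENS dataset.

    ``spectral_form`` picks the generative model:

    * ``'two_lorentzian'`` (default) — the measured-spectrum form the
      analysis assumes: A(Q)·L(Γ_lat) + (1−A(Q))·L(Γ_lat+Γ_int(Q)) (elastic
      delta instead of L(Γ_lat) for the coagel), with A(Q) the phase EISF
      and Γ_int(Q) the numerically computed model HWHM;
    * ``'multi_lorentzian'`` — the full composite internal scattering law
      with every eigenmode Lorentzian resolved.
    """

    phase: str
    params: GelCoagelModelParams | FluidModelParams
    lateral: LateralModel | None = None
    q_values: tuple = DEFAULT_Q_VALUES
    grid: EnergyGrid = field(default_factory=default_energy_grid)
    resolution_fwhm_ueV: float = 17.0
    kernel: ResolutionKernel | None = None
    peak_counts: float = 1e4
    noise: str = "poisson"  # 'none' | 'poisson' | 'gaussian'
    spectral_form: str = "two_lorentzian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_counts <= 0:
            raise ValueError("peak_counts must be positive")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.spectral_form not in ("two_lorentzian", "multi_lorentzian"):
            raise ValueError(f"unknown spectral form {self.spectral_form!r}")
        if self.phase in ("gel", "fluid") and self.lateral is None:
            raise ValueError(f"phase {self.phase!r} needs a LateralModel")


def simulate_noiseless(cfg: SpectrumGeneratorConfig) -> tuple[list[Spectrum], ResolutionKernel, dict]:
    """Noise-free model ⊗ resolution, scaled to the requested peak counts.

    Returns (spectra with σ = 0, kernel, truth record).  Reuse the output
    across noise realizations: the model evaluation dominates the cost.
    """
    from .models import (LorentzianMixture, eisf_fluid, eisf_gel_coagel,
                         model_hwhm)

    kernel = cfg.kernel or gaussian_kernel(cfg.grid, cfg.resolution_fwhm_ueV)
    kern = kernel.interpolated(cfg.grid).profile
    eig = sphere_eigenvalues() if cfg.phase == "fluid" else None
    spectra = []
    for q in cfg.q_values:
        if cfg.spectral_form == "multi_lorentzian":
            mix = bilayer_components(q, cfg.lateral, cfg.phase, cfg.params, eig)
        else:
            a = float(eisf_fluid(q, cfg.params) if cfg.phase == "fluid"
                      else eisf_gel_coagel(q, cfg.params))
            g_int = float(model_hwhm(q, cfg.phase, cfg.params, eig))
            internal = LorentzianMixture(a, np.array([1.0 - a]),
                                         np.array([g_int]))
            if cfg.phase == "coagel" or cfg.lateral is None:
                mix = internal
            else:
                mix = internal.broadened(float(cfg.lateral.gamma_lat(q)))
        y = mix.on_grid(cfg.grid, kern)
        y *= cfg.peak_counts / y.max()
        spectra.append(Spectrum(q=q, energies=cfg.grid, intensity=y,
                                sigma=np.zeros_like(y)))
    truth = {"phase": cfg.phase, "params": asdict(cfg.params),
             "lateral": asdict(cfg.lateral) if cfg.lateral else None,
             "peak_counts": cfg.peak_counts, "noise": cfg.noise,
             "spectral_form": cfg.spectral_form,
             "resolution_fwhm_ueV": cfg.resolution_fwhm_ueV}
    return spectra, kernel, truth


def apply_counting_noise(spectra: list[Spectrum], noise: str, seed: int) -> list[Spectrum]:
    """Counting noise on noiseless spectra.

    σ is taken from the Poisson mean (the noiseless intensity), the exact
    per-bin standard deviation; weighting by the square root of the observed
    counts instead would down-weight downward fluctuations and bias widths
    low (the classic Neyman-χ² bias).
    """
    rng = np.random.default_rng(seed)
    out = []
    for sp in spectra:
        y = sp.intensity
        if noise == "none":
            yn, sig = y.copy(), np.ones_like(y)
        elif noise == "poisson":
            yn = rng.poisson(np.clip(y, 0, None)).astype(float)
            sig = np.sqrt(np.maximum(y, 1.0))
        elif noise == "gaussian":
            sig = np.sqrt(np.maximum(y, 1.0))
            yn = y + rng.normal(0.0, sig)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        out.append(Spectrum(q=sp.q, energies=sp.energies, intensity=yn,
                            sigma=sig, meta=dict(sp.meta, seed=seed)))
    return out


def generate_qens_dataset(cfg: SpectrumGeneratorConfig) -> tuple[list[Spectrum], ResolutionKernel, dict]:
    """Full synthetic dataset: model ⊗ resolution, scaled, noised."""
    spectra, kernel, truth = simulate_noiseless(cfg)
    truth["seed"] = cfg.seed
    return apply_counting_noise(spectra, cfg.noise, cfg.seed), kernel, truth


# ---------------------------------------------------------------------------
# elastic scans
# ---------------------------------------------------------------------------

def generate_elastic_scan(temperatures, u2_schedule, q_values,
                          base_t: float = 10.0, noise: float = 0.0,
                          seed: int = 0, cycle: str = "heating",
                          base_counts: float = 1e4) -> ElasticScanSeries:
    """Elastic scan from a ⟨u²⟩(T) schedule (Å²), Gaussian approximation.

    I_el(Q,T) = I_base·exp(−u²(T)·Q²/6); transition features (steps, kinks)
    are encoded in the schedule itself.  ``noise`` is a relative Gaussian
    noise level on the intensities.
    """
    temps = np.asarray(temperatures, dtype=float)
    u2 = np.asarray(u2_schedule(temps) if callable(u2_schedule) else u2_schedule,
                    dtype=float)
    if np.any(u2 < 0):
        raise ValueError("u2 schedule must be non-negative")
    q = np.asarray(q_values, dtype=float)
    base = np.full(q.size, base_counts)
    intensity = base_counts * np.exp(-np.outer(u2, q * q) / 6.0)
    sigma = None
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = noise * intensity
        intensity = intensity + rng.normal(0.0, sigma)
        intensity = np.clip(intensity, 1e-6 * base_counts, None)
    return ElasticScanSeries(temperatures=temps, q_values=q,
                             intensity=intensity, base_intensity=base,
                             base_t=base_t, sigma=sigma, cycle=cycle)


# ---------------------------------------------------------------------------
# trajectories: lateral + confined + fast jump
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryGeneratorConfig:
    """Conditions for the three-process toy trajectory."""

    n_particles: int = 200
    n_frames: int = 400
    dt: float = 1.0  # ps
    d_lat_A2_ps: float = 0.0  # 2D lateral diffusivity
    sphere_radius_A: float = 0.0  # 0 disables the confined process
    d_sphere_A2_ps: float = 0.0
    jump_distance_A: float = 0.0  # 0 disables the fast two-site jump
    jump_rate_per_ps: float = 0.0  # per-site hop rate; ISF decays as 2·rate
    box_A: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dt",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("d_lat_A2_ps", "sphere_radius_A", "d_sphere_A2_ps",
                     "jump_distance_A", "jump_rate_per_ps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _reflect_into_sphere(pos: np.ndarray, radius: float) -> np.ndarray:
    """Radial specular reflection of points that left the sphere.

    Preserves the equilibrium uniform density for small steps; iterated for
    the rare large overshoot.
    """
    for _ in range(16):
        r = np.linalg.norm(pos, axis=-1)
        out = r > radius
        if not out.any():
            break
        rr = r[out]
        # new radius |2R − r|; a (rare) overshoot past the centre flips the
        # direction via the sign and is fixed up by the next iteration
        pos[out] *= ((2.0 * radius - rr) / rr)[:, None]
    return pos


def generate_trajectory(cfg: TrajectoryGeneratorConfig) -> TrajectoryBundle:
    """Toy trajectory: per particle, a 2D Brownian centre of mass (xy plane),
    a reflecting-sphere Brownian internal offset, and an optional fast
    two-site telegraph jump along a random fixed axis.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_frames, cfg.n_particles
    pos = np.zeros((n, m, 3))

    # lateral: variance 2·D·dt per in-plane axis
    if cfg.d_lat_A2_ps > 0:
        steps = rng.normal(0.0, np.sqrt(2.0 * cfg.d_lat_A2_ps * cfg.dt),
                           size=(n - 1, m, 2))
        com = np.concatenate([np.zeros((1, m, 2)), np.cumsum(steps, axis=0)])
        pos[:, :, :2] += com

    # confined: reflecting Brownian offset inside a sphere
    if cfg.sphere_radius_A > 0 and cfg.d_sphere_A2_ps > 0:
        R = cfg.sphere_radius_A
        off = np.empty((n, m, 3))
        # start from the uniform equilibrium distribution
        u = rng.random(m) ** (1.0 / 3.0) * R
        direction = rng.normal(size=(m, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        off[0] = u[:, None] * direction
        sd = np.sqrt(2.0 * cfg.d_sphere_A2_ps * cfg.dt)
        for i in range(1, n):
            trial = off[i - 1] + rng.normal(0.0, sd, size=(m, 3))
            off[i] = _reflect_into_sphere(trial, R)
        pos += off

    # fast two-site jump: telegraph process, sites at ±d/2 along a fixed axis
    if cfg.jump_distance_A > 0 and cfg.jump_rate_per_ps > 0:
        axis = rng.normal(size=(m, 3))
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        p_flip = 1.0 - np.exp(-cfg.jump_rate_per_ps * cfg.dt)
        state = rng.choice([-1.0, 1.0], size=m)
        states = np.empty((n, m))
        states[0] = state
        flips = rng.random((n - 1, m)) < p_flip
        for i in range(1, n):
            state = np.where(flips[i - 1], -state, state)
            states[i] = state
        pos += 0.5 * cfg.jump_distance_A * states[:, :, None] * axis[None, :, :]

    labels = pd.DataFrame({
        "chain": np.arange(m),
        "carbon": np.full(m, -1),
        "role": ["H"] * m,
        "region": ["tail"] * m,
    })
    return TrajectoryBundle(
        positions=pos, dt=cfg.dt, labels=labels,
        box=np.array([cfg.box_A] * 3), normal_axis=2,
        meta={"seed": cfg.seed, "config": asdict(cfg), "static_ok": True},
    )


# ---------------------------------------------------------------------------
# ideal-geometry alkyl chains
# ---------------------------------------------------------------------------

_BOND_CC = 1.54  # Å
_BOND_CH = 1.09  # Å
_ANGLE_CCC = np.radians(109.47)  # ideal tetrahedral
_ANGLE_HCH = np.radians(109.47)


def _extend_chain(p0, p1, p2, bond, angle, dihedral_deg):
    """Next backbone position from the three previous ones (NeRF)."""
    phi = np.radians(dihedral_deg)
    b1 = p1 - p0
    b2 = p2 - p1
    b2h = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2h)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(phi),
        bond * np.sin(angle) * np.sin(phi),
    ])
    return p2 + d[0] * b2h + d[1] * m + d[2] * n


def _build_backbone(dihedrals_deg: np.ndarray, n_carbons: int) -> np.ndarray:
    pos = np.zeros((n_carbons, 3))
    pos[1] = [_BOND_CC, 0.0, 0.0]
    pos[2] = pos[1] + [
        -_BOND_CC * np.cos(_ANGLE_CCC), _BOND_CC * np.sin(_ANGLE_CCC), 0.0]
    for k in range(3, n_carbons):
        pos[k] = _extend_chain(pos[k - 3], pos[k - 2], pos[k - 1],
                               _BOND_CC, _ANGLE_CCC, dihedrals_deg[k - 3])
    return pos


def _methylene_hydrogens(backbone: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two H per interior carbon, ideal tetrahedral geometry.

    Returns (h_positions (n_h, 3), carbon_index (n_h,)).
    """
    hs, owners = [], []
    half = _ANGLE_HCH / 2.0
    for i in range(1, backbone.shape[0] - 1):
        u1 = backbone[i - 1] - backbone[i]
        u2 = backbone[i + 1] - backbone[i]
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bis = -(u1 + u2)
        bis /= np.linalg.norm(bis)
        perp = np.cross(u1, u2)
        perp /= np.linalg.norm(perp)
        for s in (+1.0, -1.0):
            hs.append(backbone[i] + _BOND_CH * (np.cos(half) * bis
                                                + s * np.sin(half) * perp))
            owners.append(i)
    return np.array(hs), np.array(owners, dtype=int)


def generate_chain_conformations(n_chains: int, gauche_fraction: float,
                                 seed: int = 0, n_carbons: int = 18,
                                 orientation: str = "random") -> TrajectoryBundle:
    """Single-frame ideal-geometry alkyl chains with known dihedral states.

    Each backbone dihedral is trans (180°) with probability 1−g and ±gauche
    (±60°, equal split) with probability g.  ``orientation='aligned'``
    rotates every chain so its long axis lies along z (the bilayer normal) —
    with g = 0 this is the perpendicular C–H fixture for order parameters.
    Ground-truth states live in ``meta['dihedral_states']``.
    """
    if not 0.0 <= gauche_fraction <= 1.0:
        raise ValueError("gauche_fraction must be in [0, 1]")
    if n_carbons < 4:
        raise ValueError("need at least 4 carbons for a dihedral")
    rng = np.random.default_rng(seed)
    n_dih = n_carbons - 3
    choices = np.array([180.0, 60.0, -60.0])
    probs = np.array([1.0 - gauche_fraction, gauche_fraction / 2.0,
                      gauche_fraction / 2.0])
    states = rng.choice(3, size=(n_chains, n_dih), p=probs)
    positions, chain_ids, carbon_idx, roles = [], [], [], []
    ch_pairs, backbones = [], []
    offset = 0
    for c in range(n_chains):
        backbone = _build_backbone(choices[states[c]], n_carbons)
        h_pos, h_owner = _methylene_hydrogens(backbone)
        if orientation == "aligned":
            rot = _rotation_onto_z(backbone[-1] - backbone[0])
        elif orientation == "random":
            rot = _random_rotation(rng)
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        backbone = backbone @ rot.T
        h_pos = h_pos @ rot.T
        shift = rng.uniform(-50, 50, size=3) if orientation == "random" else np.zeros(3)
        atoms = np.vstack([backbone, h_pos]) + shift
        positions.append(atoms)
        nb = backbone.shape[0]
        chain_ids += [c] * atoms.shape[0]
        carbon_idx += list(range(nb)) + list(h_owner)
        roles += ["C"] * nb + ["H"] * h_pos.shape[0]
        backbones.append(np.arange(nb) + offset)
        for k, owner in enumerate(h_owner):
            ch_pairs.append((offset + owner, offset + nb + k))
        offset += atoms.shape[0]
    all_pos = np.vstack(positions)[None, :, :]  # single frame
    labels = pd.DataFrame({
        "chain": chain_ids,
        "carbon": carbon_idx,
        "role": roles,
        "region": ["tail"] * len(roles),
    })
    return TrajectoryBundle(
        positions=all_pos, dt=1.0, labels=labels, box=None, normal_axis=2,
        ch_pairs=np.array(ch_pairs, dtype=int),
        backbones=backbones,
        meta={"seed": seed, "gauche_fraction": gauche_fraction,
              "dihedral_states": states, "static_ok": True},
    )


def _rotation_onto_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction v onto +z."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation via QR of a Gaussian matrix."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
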