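"""Trajectory-derived observables.

* incoherent intermediate scattering function I(Q,t) with the exact isotropic
  orientation average ⟨e^{iQ·d}⟩ = sin(Q|d|)/(Q|d|);
* three-process decay decomposition
  I(Q,t) = e^{−Γ_lat t}·[A₁+(1−A₁)e^{−Γ_int t}]·[A₂+(1−A₂)e^{−Γ_fast t}];
* C–H bond order parameter S_CH = ½[3⟨cos²θ⟩ − 1] vs the bilayer normal;
* gauche/trans dihedral statistics of alkyl chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import HBAR_MEV_PS as HBAR
from .fitting import fit_fickian

__all__ = [
    "TrajectoryBundle",
    "IsfCurve",
    "IsfDecomposition",
    "compute_isf",
    "fit_isf_three_process",
    "order_parameter_profile",
    "gauche_trans_ratio",
    "lateral_diffusivity_from_isf",
    "dihedral_angles",
    "load_trajectory",
]


@dataclass
class TrajectoryBundle:
    """Labelled particle coordinates over time (unwrapped, Å).

    positions : (n_frames, n_atoms, 3); dt in ps; labels : per-atom DataFrame
    with columns chain (int), carbon (int, −1 for non-backbone), role
    ('C'/'H'), region ('head'/'tail'); ch_pairs : (n, 2) carbon/hydrogen index
    pairs for order parameters; backbones : per-chain ordered carbon indices
    for dihedrals; box : periodic lengths or None; normal_axis : bilayer
    normal (default z).
    """

    positions: np.ndarray
    dt: float
    labels: pd.DataFrame
    box: np.ndarray | None = None
    normal_axis: int = 2
    ch_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    backbones: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_atoms, 3)")
        if self.positions.shape[0] < 2 and not self.meta.get("static_ok"):
            raise ValueError("need at least 2 frames")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.labels) != self.positions.shape[1]:
            raise ValueError("labels must have one row per atom")
        self.ch_pairs = np.asarray(self.ch_pairs, dtype=int).reshape(-1, 2)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def select(self, role: str | None = None, region: str | None = None) -> np.ndarray:
        """Indices of atoms matching the label filters."""
        mask = np.ones(len(self.labels), dtype=bool)
        if role is not None:
            mask &= (self.labels.role == role).to_numpy()
        if region is not None:
            mask &= (self.labels.region == region).to_numpy()
        return np.where(mask)[0]


@dataclass
class IsfCurve:
    """I(Q,t) at one Q with block-averaged uncertainties."""

    q: float
    times: np.ndarray
    isf: np.ndarray
    stderr: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.isf[0] - 1.0) > 1e-9:
            raise ValueError("I(Q, 0) must be 1")


@dataclass
class IsfDecomposition:
    """Three-process decay parameters (rates in 1/ps; ħΓ gives meV)."""

    q: float
    a1: float
    a2: float
    gamma_lat: float
    gamma_int: float
    gamma_fast: float
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.gamma_fast >= self.gamma_int >= self.gamma_lat >= 0):
            raise ValueError("rates must satisfy Γ_fast ≥ Γ_int ≥ Γ_lat ≥ 0")


# ---------------------------------------------------------------------------
# I(Q, t)
# ---------------------------------------------------------------------------

def _check_unwrapped(traj: TrajectoryBundle, atoms: np.ndarray) -> None:
    if traj.box is None or traj.n_frames < 2:
        return
    half = np.asarray(traj.box, dtype=float) / 2.0
    jumps = np.abs(np.diff(traj.positions[:, atoms, :], axis=0))
    if np.any(jumps > half):
        raise ValueError(
            "frame-to-frame displacement exceeds box/2: coordinates look "
            "wrapped; unwrap the trajectory first")


def compute_isf(traj: TrajectoryBundle, q_list, atoms=None,
                max_lag: int | None = None,
                origin_stride: int | None = None,
                average: str = "isotropic") -> list[IsfCurve]:
    """Incoherent intermediate scattering function per Q.

    Orientation averages (exact identities, no Q-direction sampling):

    * ``'isotropic'`` — ⟨e^{iQ·d}⟩ over the full sphere of Q directions,
      sin(Q|d|)/(Q|d|);
    * ``'planar'`` — Q uniformly distributed in the membrane plane
      (perpendicular to the bilayer normal), J₀(Q·|d_∥|); the natural choice
      for lateral dynamics of a planar patch, for which in-plane Brownian
      motion decays as a single exponential exp(−DQ²t).

    Averaged over the selected atoms and sliding time origins (default
    stride max_lag/2, i.e. 50 % overlap); stderr from the variance across
    origin blocks (origins overlap, so treat it as a scale estimate).
    """
    from scipy.special import j0 as bessel_j0

    if average not in ("isotropic", "planar"):
        raise ValueError(f"unknown average {average!r}")
    atoms = np.arange(traj.positions.shape[1]) if atoms is None else np.asarray(atoms)
    _check_unwrapped(traj, atoms)
    n_frames = traj.n_frames
    max_lag = max_lag if max_lag is not None else n_frames - 1
    if max_lag >= n_frames:
        raise ValueError("max_lag must be smaller than the frame count")
    stride = origin_stride or max(max_lag // 2, 1)
    pos = traj.positions[:, atoms, :]
    if average == "planar":
        in_plane = [ax for ax in range(3) if ax != traj.normal_axis]
        pos = pos[:, :, in_plane]
    q_arr = np.atleast_1d(np.asarray(q_list, dtype=float))
    lags = np.arange(max_lag + 1)
    nq = q_arr.size
    means = np.empty((nq, lags.size))
    errs = np.empty((nq, lags.size))
    means[:, 0] = 1.0
    errs[:, 0] = 0.0
    for j, lag in enumerate(lags[1:], start=1):
        origins = np.arange(0, n_frames - lag, stride)
        d = np.linalg.norm(pos[origins + lag] - pos[origins], axis=2)  # (o, a)
        for iq, qv in enumerate(q_arr):
            if average == "isotropic":
                vals = np.sinc(qv * d / np.pi)
            else:
                vals = bessel_j0(qv * d)
            per_origin = vals.mean(axis=1)
            means[iq, j] = per_origin.mean()
            errs[iq, j] = (per_origin.std(ddof=1) / np.sqrt(origins.size)
                           if origins.size > 1 else 0.0)
    return [IsfCurve(q=qv, times=lags * traj.dt, isf=means[iq],
                     stderr=errs[iq]) for iq, qv in enumerate(q_arr)]


def _three_process(t, a1, a2, g_lat, g_int, g_fast):
    return (np.exp(-g_lat * t)
            * (a1 + (1.0 - a1) * np.exp(-g_int * t))
            * (a2 + (1.0 - a2) * np.exp(-g_fast * t)))


def fit_isf_three_process(curve: IsfCurve, weights=None) -> IsfDecomposition:
    """Bounded least squares of the three-exponential decay model.

    Parameterized with ordered rate gaps (Γ_int = Γ_lat + δ₁,
    Γ_fast = Γ_int + δ₂, δᵢ ≥ 0) so the lateral < internal < fast ordering
    holds by construction; deterministic multi-start over log-spaced rate
    guesses.

    The product form is degenerate when a plateau fraction reaches 1 (a
    single exponential can be split arbitrarily between factors), so the
    one- and two-process nested models are fitted as well and the winner is
    chosen by AIC; processes dropped that way are flagged unidentifiable.
    """
    t = curve.times
    y = curve.isf
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    span = t[-1] if t[-1] > 0 else 1.0
    n = t.size

    def unpack(x):
        a1, a2 = x[0], x[1]
        g_lat = x[2]
        g_int = g_lat + np.exp(x[3])
        g_fast = g_int + np.exp(x[4])
        return a1, a2, g_lat, g_int, g_fast

    def multistart(resid, starts, lo, hi):
        best = None
        for x0 in starts:
            try:
                res = least_squares(resid, x0, bounds=(lo, hi), x_scale="jac")
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        return best

    # --- full three-process model ------------------------------------
    def resid3(x):
        return w * (_three_process(t, *unpack(x)) - y)

    # log-gaps capped at e^25 ps⁻¹ — far beyond any resolvable rate
    lo3 = [0.0, 0.0, 0.0, -25.0, -25.0]
    hi3 = [1.0, 1.0, np.inf, 25.0, 25.0]
    starts3 = []
    for g0 in (1.0 / span, 10.0 / span, 0.1 / span):
        for ratio in (10.0, 100.0):
            starts3.append([0.6, 0.8, g0, np.log(g0 * (ratio - 1.0)),
                            np.log(g0 * ratio * (ratio - 1.0))])
    best3 = multistart(resid3, starts3, lo3, hi3)

    # --- nested: two processes (A2 = 1) and one process (A1 = A2 = 1) --
    def resid2(x):
        a1, g_lat, lngap = x
        g_int = g_lat + np.exp(lngap)
        return w * (np.exp(-g_lat * t) * (a1 + (1 - a1) * np.exp(-g_int * t))
                    - y)

    best2 = multistart(
        resid2,
        [[0.6, g0 / 2, np.log(g0 * 9)] for g0 in (1 / span, 10 / span)],
        [0.0, 0.0, -25.0], [1.0, np.inf, 25.0])

    def resid1(x):
        return w * (np.exp(-x[0] * t) - y)

    best1 = multistart(resid1, [[1.0 / span], [10.0 / span], [0.1 / span]],
                       [0.0], [np.inf])

    if best3 is None:
        raise RuntimeError("three-process fit did not converge")

    def aic(res, k):
        return n * np.log(max(2.0 * res.cost, 1e-300) / n) + 2 * k

    candidates = [(aic(best3, 5), 3, best3)]
    if best2 is not None:
        candidates.append((aic(best2, 3), 2, best2))
    if best1 is not None:
        candidates.append((aic(best1, 1), 1, best1))
    _, order, best = min(candidates, key=lambda c: (c[0], c[1]))

    flags = []
    if order == 3:
        a1, a2, g_lat, g_int, g_fast = unpack(best.x)
        if g_fast > 0 and abs(g_fast - g_int) / g_fast < 0.1:
            flags.append("rate_collision")
        if a1 > 1.0 - 1e-6:
            flags.append("gamma_int_unidentifiable")
        if a2 > 1.0 - 1e-6:
            flags.append("gamma_fast_unidentifiable")
    elif order == 2:
        a1, g_lat = best.x[0], best.x[1]
        g_int = g_lat + np.exp(best.x[2])
        a2, g_fast = 1.0, g_int
        flags.append("gamma_fast_unidentifiable")
    else:
        g_lat = best.x[0]
        a1 = a2 = 1.0
        g_int = g_fast = g_lat
        flags += ["gamma_int_unidentifiable", "gamma_fast_unidentifiable"]
    return IsfDecomposition(q=curve.q, a1=a1, a2=a2, gamma_lat=g_lat,
                            gamma_int=g_int, gamma_fast=g_fast, flags=flags)


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------

def order_parameter_profile(traj: TrajectoryBundle,
                            normal_axis: int | None = None) -> pd.DataFrame:
    """S_CH = ½[3⟨cos²θ⟩ − 1] per carbon index, averaged over molecules and
    frames; θ is the C–H bond angle to the bilayer normal.

    Requires ``traj.ch_pairs``; raises when the bond topology is missing.
    """
    if traj.ch_pairs.size == 0:
        raise ValueError("trajectory carries no C–H bond pairs")
    axis = traj.normal_axis if normal_axis is None else normal_axis
    c_idx = traj.ch_pairs[:, 0]
    h_idx = traj.ch_pairs[:, 1]
    v = traj.positions[:, h_idx, :] - traj.positions[:, c_idx, :]
    cos2 = (v[..., axis] ** 2) / np.sum(v * v, axis=2)
    carbon = traj.labels.carbon.to_numpy()[c_idx]
    rows = []
    for ci in np.unique(carbon):
        sel = carbon == ci
        c2 = cos2[:, sel]
        rows.append({"carbon": int(ci),
                     "s_ch": 0.5 * (3.0 * c2.mean() - 1.0),
                     "n_samples": int(c2.size)})
    return pd.DataFrame(rows).sort_values("carbon").reset_index(drop=True)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Dihedral φ (degrees, IUPAC sign convention) for stacked coordinates."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


@dataclass
class DihedralStats:
    """Gauche/trans/other counts per backbone bond and their totals."""

    per_bond: pd.DataFrame
    gauche: int
    trans: int
    other: int
    excluded: int

    @property
    def total(self) -> int:
        return self.gauche + self.trans + self.other

    @property
    def ratio(self) -> float:
        if self.trans == 0:
            return float("inf") if self.gauche else 0.0
        return self.gauche / self.trans


def gauche_trans_ratio(traj: TrajectoryBundle,
                       gauche_window: tuple[float, float] = (45.0, 75.0),
                       trans_lo: float = 165.0) -> DihedralStats:
    """Classify backbone dihedrals and form the gauche/trans ratio.

    φ is folded to |φ| ∈ [0°, 180°] so both +gauche and −gauche count;
    gauche iff |φ| ∈ [45°, 75°], trans iff |φ| ∈ [165°, 180°] (the nominal
    165°–195° window maps onto [165°, 180°] after folding).  Near-colinear
    triplets are excluded and counted.
    """
    if not traj.backbones:
        raise ValueError("trajectory carries no backbone topology")
    g_lo, g_hi = gauche_window
    records: dict[int, list[int]] = {}
    excluded = 0
    for chain in traj.backbones:
        chain = np.asarray(chain, dtype=int)
        if chain.size < 4:
            raise ValueError("need >= 4 consecutive backbone atoms")
        p = traj.positions[:, chain, :]
        b = np.diff(p, axis=1)
        cross = np.cross(b[:, :-1], b[:, 1:])
        norm = np.linalg.norm(cross, axis=-1)
        phi = dihedral_angles(p[:, :-3], p[:, 1:-2], p[:, 2:-1], p[:, 3:])
        bad = (norm[:, :-1] < 1e-10) | (norm[:, 1:] < 1e-10)
        aphi = np.abs(phi)
        gauche = (aphi >= g_lo) & (aphi <= g_hi) & ~bad
        trans = (aphi >= trans_lo) & ~bad
        other = ~gauche & ~trans & ~bad
        excluded += int(bad.sum())
        for bond in range(phi.shape[1]):
            rec = records.setdefault(bond, [0, 0, 0])
            rec[0] += int(gauche[:, bond].sum())
            rec[1] += int(trans[:, bond].sum())
            rec[2] += int(other[:, bond].sum())
    per_bond = pd.DataFrame(
        [{"bond": b, "gauche": r[0], "trans": r[1], "other": r[2]}
         for b, r in sorted(records.items())])
    return DihedralStats(
        per_bond=per_bond,
        gauche=int(per_bond.gauche.sum()),
        trans=int(per_bond.trans.sum()),
        other=int(per_bond.other.sum()),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# lateral diffusivity from the ISF stack
# ---------------------------------------------------------------------------

def lateral_diffusivity_from_isf(decompositions: list[IsfDecomposition]) -> dict:
    """Fickian fit of the lateral decay rates: Γ_lat(Q) = D·Q².

    Rates in 1/ps are converted to meV (ħΓ) and delegated to
    :func:`qens_bilayer.fitting.fit_fickian`; D returned in cm²/s and Å²/ps.
    """
    if len(decompositions) < 3:
        raise ValueError("need >= 3 Q points")
    q = np.array([d.q for d in decompositions])
    gamma_meV = HBAR * np.array([d.gamma_lat for d in decompositions])
    out = fit_fickian(q, gamma_meV)
    out["d_lat_A2_ps"] = out["d_lat_cm2_s"] * 1e4
    return out


# ---------------------------------------------------------------------------
# file loading (optional, via MDAnalysis)
# ---------------------------------------------------------------------------

def load_trajectory(topology, trajectory=None, dt: float | None = None,
                    normal_axis: int = 2) -> TrajectoryBundle:
    """Read a trajectory file pair (e.g. PDB+DCD, or XYZ) into a bundle.

    Delegates parsing to MDAnalysis.  Chain/region labels are inferred from
    residues (one chain per residue; N/C-methyl atoms as head, the rest tail);
    C–H pairs and backbones are derived from bonds when present.
    """
    import MDAnalysis as mda  # deferred: optional dependency

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    n_atoms = len(u.atoms)
    pos = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    labels = pd.DataFrame({
        "chain": u.atoms.resindices,
        "carbon": np.arange(n_atoms),
        "role": [name[0] if name else "X" for name in u.atoms.names],
        "region": ["tail"] * n_atoms,
    })
    frame_dt = dt if dt is not None else (u.trajectory.dt or 1.0)
    return TrajectoryBundle(positions=pos, dt=frame_dt, labels=labels,
                            box=None, normal_axis=normal_axis)
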