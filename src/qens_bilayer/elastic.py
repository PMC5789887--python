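"""Fixed-elastic-window-scan analysis.

The elastic intensity within the instrument resolution, tracked against
temperature, probes dynamical transitions: motions entering the instrument
time window drain the elastic line.  Within the Gaussian approximation the
Q² decay of the base-temperature-normalized elastic intensity yields the
mean-squared displacement,

    ln[I_el(Q,T)/I_el(Q,T_min)] = −⟨u²⟩·Q²/6,

and slope changes of the Q-averaged intensity locate phase transitions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ElasticScanSeries",
    "fit_msd",
    "q_average_elastic",
    "detect_transitions",
    "read_elastic_scan_csv",
    "write_elastic_scan_csv",
]


@dataclass
class ElasticScanSeries:
    """Elastic intensity vs temperature per Q, plus the base-T reference.

    ``intensity[t, q]`` is I_el at ``temperatures[t]``, ``q_values[q]``;
    ``base_intensity[q]`` is the reference measured at ``base_t`` (e.g. 10 K).
    """

    temperatures: np.ndarray
    q_values: np.ndarray
    intensity: np.ndarray
    base_intensity: np.ndarray
    base_t: float = 10.0
    sigma: np.ndarray | None = None
    cycle: str = "heating"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.base_intensity = np.asarray(self.base_intensity, dtype=float)
        d = np.diff(self.temperatures)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("temperatures must be strictly monotone in a cycle")
        if self.cycle not in ("heating", "cooling"):
            raise ValueError("cycle must be 'heating' or 'cooling'")
        shape = (self.temperatures.size, self.q_values.size)
        if self.intensity.shape != shape:
            raise ValueError(f"intensity must have shape {shape}")
        if self.base_intensity.shape != (self.q_values.size,):
            raise ValueError("base_intensity must have one value per Q")
        if np.any(self.intensity <= 0) or np.any(self.base_intensity <= 0):
            raise ValueError("elastic intensities must be positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != shape:
                raise ValueError(f"sigma must have shape {shape}")


def fit_msd(scan: ElasticScanSeries, q_lo: float = 0.5,
            q_hi: float = 0.95) -> pd.DataFrame:
    """Mean-squared displacement ⟨u²⟩(T) from the Q² decay of ln ratios.

    Weighted linear fit of ln[I(Q,T)/I(Q,T_min)] vs Q² over [q_lo, q_hi] with
    a free intercept (absorbs normalization drift); slope = −⟨u²⟩/6.
    Non-positive ratios are excluded with a warning; fewer than 3 usable
    Q bins raise.

    Returns a DataFrame with columns T_K, u2_A2, stderr_A2, n_q.
    """
    mask = (scan.q_values >= q_lo) & (scan.q_values <= q_hi)
    if mask.sum() < 3:
        raise ValueError("need >= 3 Q points in the fit range")
    q2 = scan.q_values[mask] ** 2
    rows = []
    for it, temp in enumerate(scan.temperatures):
        ratio = scan.intensity[it, mask] / scan.base_intensity[mask]
        ok = ratio > 0
        if (~ok).any():
            warnings.warn(
                f"T={temp:g} K: {int((~ok).sum())} non-positive intensity "
                "ratio(s) excluded", RuntimeWarning, stacklevel=2)
        if ok.sum() < 3:
            raise ValueError(f"T={temp:g} K: fewer than 3 usable Q bins")
        y = np.log(ratio[ok])
        x = q2[ok]
        if scan.sigma is not None:
            w = (ratio[ok] / scan.sigma[it, mask][ok]) ** 2  # σ_ln = σ/I
        else:
            w = np.ones_like(y)
        # weighted LS for y = c + m x
        W = np.sum(w)
        xm = np.sum(w * x) / W
        ym = np.sum(w * y) / W
        sxx = np.sum(w * (x - xm) ** 2)
        slope = np.sum(w * (x - xm) * (y - ym)) / sxx
        resid = y - (ym + slope * (x - xm))
        dof = max(ok.sum() - 2, 1)
        s2 = np.sum(w * resid**2) / dof
        slope_err = np.sqrt(s2 / sxx)
        rows.append({"T_K": temp, "u2_A2": -6.0 * slope,
                     "stderr_A2": 6.0 * slope_err, "n_q": int(ok.sum())})
    return pd.DataFrame(rows)


def q_average_elastic(scan: ElasticScanSeries, q_lo: float = 0.5,
                      q_hi: float = 1.8) -> pd.DataFrame:
    """Unweighted mean elastic intensity over Q in [q_lo, q_hi] vs T."""
    mask = (scan.q_values >= q_lo) & (scan.q_values <= q_hi)
    if not mask.any():
        raise ValueError("empty Q window")
    return pd.DataFrame({
        "T_K": scan.temperatures,
        "I_el": scan.intensity[:, mask].mean(axis=1),
    })


def _piecewise_design(t: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for b in breaks:
        cols.append(np.maximum(t - b, 0.0))
    return np.column_stack(cols)


def detect_transitions(temperatures, intensity, max_breaks: int = 3,
                       min_segment: int = 3) -> list[float]:
    """Transition temperatures from slope changes of I_el(T).

    Fits continuous piecewise-linear models with 0..max_breaks breakpoints
    placed on interior grid temperatures (each segment at least
    ``min_segment`` points) and picks the breakpoint count by BIC,
    n·ln(RSS/n) + p·ln(n) with p = 2 + 2k.  Returns the winning break
    temperatures, sorted ascending (empty list for a pure linear trend).
    The selection is invariant to affine rescaling of the intensity.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(intensity, dtype=float)
    n = t.size
    if n < 7:
        raise ValueError("need at least 7 temperature points")
    if n < (max_breaks + 1) * min_segment:
        raise ValueError("fewer points than requested breakpoints allow")
    order = np.argsort(t)
    t, y = t[order], y[order]
    scale = np.std(y) or 1.0
    y = (y - y.mean()) / scale  # affine invariance + conditioning

    def rss(breaks: tuple[float, ...]) -> float:
        X = _piecewise_design(t, breaks)
        coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if res.size:
            return float(res[0])
        r = y - X @ coef
        return float(r @ r)

    candidates = t[min_segment - 1: n - min_segment + 1]
    best: tuple[float, tuple[float, ...]] | None = None
    for k in range(max_breaks + 1):
        combos = itertools.combinations(range(candidates.size), k) if k else [()]
        for idx in combos:
            # min_segment only guards the edges; adjacent interior breaks
            # stay allowed — a sharp step needs two breaks one grid step
            # apart, and the BIC penalty already discourages overfitting
            brk = tuple(candidates[list(idx)])
            # floor at numerical noise so an exact fit cannot out-vote the
            # penalty through machine-epsilon RSS differences
            r = max(rss(brk), n * 1e-20)
            bic = n * np.log(r / n) + (2 + 2 * k) * np.log(n)
            if best is None or bic < best[0]:
                best = (bic, brk)
    assert best is not None
    return sorted(best[1])


# ---------------------------------------------------------------------------
# CSV interface: columns T_K,cycle,Q_invA,I_el,sigma (base rows at T=base_t)
# ---------------------------------------------------------------------------

def write_elastic_scan_csv(path, scan: ElasticScanSeries) -> None:
    rows = []
    for q, ib in zip(scan.q_values, scan.base_intensity):
        rows.append((scan.base_t, "base", q, ib, 0.0))
    for it, temp in enumerate(scan.temperatures):
        for iq, q in enumerate(scan.q_values):
            s = scan.sigma[it, iq] if scan.sigma is not None else 0.0
            rows.append((temp, scan.cycle, q, scan.intensity[it, iq], s))
    pd.DataFrame(rows, columns=["T_K", "cycle", "Q_invA", "I_el", "sigma"]
                 ).to_csv(path, index=False)


def read_elastic_scan_csv(path, cycle: str | None = None) -> ElasticScanSeries:
    df = pd.read_csv(path)
    need = {"T_K", "cycle", "Q_invA", "I_el"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    base = df[df.cycle == "base"].sort_values("Q_invA")
    if base.empty:
        raise ValueError(f"{path}: no base-temperature rows (cycle='base')")
    data = df[df.cycle != "base"]
    if cycle is not None:
        data = data[data.cycle == cycle]
    cyc = data.cycle.iloc[0]
    piv = data.pivot_table(index="T_K", columns="Q_invA", values="I_el")
    temps = piv.index.to_numpy()
    if cyc == "cooling":
        temps = temps[::-1]
        piv = piv.iloc[::-1]
    sig = None
    if "sigma" in df.columns and (data.sigma > 0).any():
        sig = data.pivot_table(index="T_K", columns="Q_invA", values="sigma"
                               ).loc[piv.index].to_numpy()
    return ElasticScanSeries(
        temperatures=temps,
        q_values=piv.columns.to_numpy(),
        intensity=piv.to_numpy(),
        base_intensity=base.I_el.to_numpy(),
        base_t=float(base.T_K.iloc[0]),
        sigma=sig,
        cycle=cyc,
    )
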