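"""End-to-end pipeline orchestration.

A single config drives an ordered list of stages (synth → reduce → fews →
fit-qens → traj as configured); each stage consumes files produced earlier
and appends a machine-readable entry to the run report.  For a fixed seed
the report content is a pure function of config + inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import synthetic
from .elastic import detect_transitions, fit_msd, q_average_elastic, read_elastic_scan_csv
from .fitting import FitConfig, fit_eisf, fit_fickian, fit_per_q
from .models import FluidModelParams, GelCoagelModelParams, LateralModel
from .reduction import (
    default_solvent_fraction,
    read_grouped_spectra,
    read_resolution,
    subtract_solvent,
    write_grouped_spectra,
)

__all__ = ["run_pipeline", "validate_config"]

_KNOWN_STAGES = ("synth-spectra", "reduce", "fews", "fit-qens")


def validate_config(cfg: dict) -> None:
    stages = cfg.get("stages", [])
    if not isinstance(stages, list):
        raise ValueError("config 'stages' must be a list")
    for st in stages:
        if "stage" not in st:
            raise ValueError("each stage needs a 'stage' key")
        if st["stage"] not in _KNOWN_STAGES:
            raise ValueError(f"unknown stage {st['stage']!r}; "
                             f"known: {_KNOWN_STAGES}")


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"pipeline input does not exist: {p}")
    return p


def _params_from_dict(phase: str, d: dict):
    if phase in ("gel", "coagel"):
        return GelCoagelModelParams(**d)
    return FluidModelParams(**d)


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Execute the configured stages; return (and write) the run report."""
    validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    report: dict = {"seed": seed, "stages": []}

    for st in cfg.get("stages", []):
        name = st["stage"]
        entry: dict = {"stage": name}
        if name == "synth-spectra":
            phase = st["phase"]
            params = _params_from_dict(phase, st["params"])
            lateral = (LateralModel(**st["lateral"])
                       if st.get("lateral") else None)
            gcfg = synthetic.SpectrumGeneratorConfig(
                phase=phase, params=params, lateral=lateral,
                noise=st.get("noise", "poisson"),
                peak_counts=st.get("peak_counts", 1e4), seed=seed)
            spectra, kernel, truth = synthetic.generate_qens_dataset(gcfg)
            out = out_dir / st.get("output", "spectra.h5")
            write_grouped_spectra(out, spectra, resolution=kernel)
            (out_dir / (out.stem + "_truth.json")).write_text(
                json.dumps(truth, default=_jsonable, indent=1))
            entry["output"] = str(out)
        elif name == "reduce":
            solution = read_grouped_spectra(_require(st["solution"]))
            solvent = read_grouped_spectra(_require(st["solvent"]))
            phi = float(st.get("phi", default_solvent_fraction()))
            reduced = [subtract_solvent(a, b, phi)
                       for a, b in zip(solution, solvent)]
            out = out_dir / st.get("output", "reduced.h5")
            write_grouped_spectra(out, reduced)
            entry.update(output=str(out), phi=phi,
                         n_negative_bins=sum(sp.meta["n_negative_bins"]
                                             for sp in reduced))
        elif name == "fews":
            scan = read_elastic_scan_csv(_require(st["scan"]))
            msd = fit_msd(scan, *st.get("q_range_msd", (0.5, 0.95)))
            avg = q_average_elastic(scan, *st.get("q_range_avg", (0.5, 1.8)))
            breaks = detect_transitions(avg.T_K.to_numpy(),
                                        avg.I_el.to_numpy())
            msd_path = out_dir / st.get("output", "msd.csv")
            msd.to_csv(msd_path, index=False)
            entry.update(output=str(msd_path),
                         transitions_K=[round(b, 3) for b in breaks])
        elif name == "fit-qens":
            spectra = read_grouped_spectra(_require(st["input"]))
            kernel = read_resolution(_require(st.get("resolution",
                                                     st["input"])))
            phase = st["phase"]
            fit_cfg = FitConfig(n_starts=st.get("n_starts", 8), seed=seed)
            per_q = [fit_per_q(sp, kernel, phase, fit_cfg) for sp in spectra]
            q = np.array([r.q for r in per_q])
            table = [{
                "q": r.q, "eisf": r.eisf, "gamma_lat": r.gamma_lat,
                "gamma_int": r.gamma_int, "stderr": r.stderr,
                "flags": r.flags} for r in per_q]
            entry["per_q"] = table
            if phase != "coagel":
                fick = fit_fickian(q, [r.gamma_lat for r in per_q],
                                   sigma=[max(r.stderr.get("gamma_lat", 1e-4),
                                              1e-6) for r in per_q])
                entry["d_lat_cm2_s"] = fick["d_lat_cm2_s"]
            eisf = fit_eisf(q, [r.eisf for r in per_q], phase,
                            sigma=[max(r.stderr.get("eisf", 1e-3), 1e-4)
                                   for r in per_q])
            eisf.pop("stderr", None)
            entry["eisf_fit"] = eisf
        report["stages"].append(entry)

    (out_dir / "report.json").write_text(
        json.dumps(report, default=_jsonable, indent=1, sort_keys=True))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
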