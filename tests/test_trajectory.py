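"""Trajectory observables: I(Q,t), decay decomposition, S_CH, dihedrals."""

import numpy as np
import pandas as pd
import pytest

from qens_bilayer.synthetic import (
    TrajectoryGeneratorConfig,
    generate_chain_conformations,
    generate_trajectory,
)
from qens_bilayer.trajectory import (
    IsfCurve,
    TrajectoryBundle,
    compute_isf,
    dihedral_angles,
    fit_isf_three_process,
    gauche_trans_ratio,
    lateral_diffusivity_from_isf,
    order_parameter_profile,
)


def _bundle(positions, dt=1.0, **kw):
    n_atoms = positions.shape[1]
    labels = pd.DataFrame({
        "chain": np.arange(n_atoms), "carbon": -1,
        "role": ["H"] * n_atoms, "region": ["tail"] * n_atoms})
    return TrajectoryBundle(positions, dt, labels,
                            meta={"static_ok": True}, **kw)


class TestComputeIsf:
    def test_static_particles_stay_at_unity(self):
        pos = np.broadcast_to(np.arange(30.0).reshape(1, 10, 3),
                              (50, 10, 3)).copy()
        curves = compute_isf(_bundle(pos), [0.7, 1.4], max_lag=20)
        for c in curves:
            assert np.allclose(c.isf, 1.0, atol=1e-12)

    def test_time_zero_is_exactly_one(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(40, 20, 3))
        for c in compute_isf(_bundle(pos), [1.0], max_lag=10):
            assert c.isf[0] == 1.0

    def test_free_diffusion_matches_closed_form(self):
        # 3D Brownian particles: I(Q,t) = exp(−DQ²t), checked at a few lags
        # against the block standard error (3 SE, 1000 particles)
        rng = np.random.default_rng(42)
        D, dt, n, m = 0.1, 0.5, 161, 1000
        steps = rng.normal(0, np.sqrt(2 * D * dt), size=(n - 1, m, 3))
        pos = np.concatenate([np.zeros((1, m, 3)), np.cumsum(steps, axis=0)])
        c = compute_isf(_bundle(pos, dt=dt), [1.0], max_lag=40)[0]
        expected = np.exp(-D * 1.0**2 * c.times)
        for lag in (4, 10, 20, 40):
            se = max(c.stderr[lag], 1e-4)
            assert abs(c.isf[lag] - expected[lag]) < 3 * se

    def test_planar_average_of_2d_diffusion_is_exponential(self):
        rng = np.random.default_rng(7)
        D, dt, n, m = 0.2, 0.5, 121, 800
        steps = rng.normal(0, np.sqrt(2 * D * dt), size=(n - 1, m, 2))
        pos = np.zeros((n, m, 3))
        pos[1:, :, :2] = np.cumsum(steps, axis=0)
        c = compute_isf(_bundle(pos, dt=dt), [0.8], max_lag=30,
                        average="planar")[0]
        expected = np.exp(-D * 0.8**2 * c.times)
        assert np.allclose(c.isf[:15], expected[:15], atol=0.02)

    def test_wrapped_coordinates_rejected(self):
        pos = np.zeros((3, 2, 3))
        pos[1, 0, 0] = 40.0  # jump beyond box/2
        traj = _bundle(pos, box=np.array([50.0, 50.0, 50.0]))
        with pytest.raises(ValueError, match="unwrap"):
            compute_isf(traj, [1.0], max_lag=2)


class TestThreeProcessFit:
    def test_noiseless_exact_inversion(self):
        t = np.arange(0.0, 200.5, 0.5)
        y = (np.exp(-0.002 * t) * (0.6 + 0.4 * np.exp(-0.05 * t))
             * (0.8 + 0.2 * np.exp(-1.5 * t)))
        d = fit_isf_three_process(IsfCurve(1.0, t, y, np.zeros_like(t)))
        assert d.gamma_lat == pytest.approx(0.002, rel=1e-6)
        assert d.gamma_int == pytest.approx(0.05, rel=1e-6)
        assert d.gamma_fast == pytest.approx(1.5, rel=1e-6)
        assert d.a1 == pytest.approx(0.6, abs=1e-6)
        assert d.a2 == pytest.approx(0.8, abs=1e-6)

    def test_single_exponential_flags_unused_processes(self):
        t = np.arange(0.0, 100.5, 0.5)
        y = np.exp(-0.01 * t)
        d = fit_isf_three_process(IsfCurve(1.0, t, y, np.zeros_like(t)))
        assert d.gamma_lat == pytest.approx(0.01, rel=1e-4)
        assert ("gamma_int_unidentifiable" in d.flags
                or "gamma_fast_unidentifiable" in d.flags
                or "rate_collision" in d.flags)

    def test_noisy_monte_carlo_rate_recovery(self):
        # 1% noise, median relative error on all rates < 5%; the time grid
        # mirrors the two-run sampling (dense 0.02 ps short-time block for
        # the fast process, coarser long-time block for the slow ones)
        t = np.concatenate([np.arange(0.0, 10.0, 0.02),
                            np.arange(10.0, 300.5, 0.5)])
        y0 = (np.exp(-0.002 * t) * (0.6 + 0.4 * np.exp(-0.05 * t))
              * (0.8 + 0.2 * np.exp(-1.5 * t)))
        errs = {"lat": [], "int": [], "fast": []}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = y0 + 0.01 * rng.standard_normal(t.size)
            d = fit_isf_three_process(IsfCurve(1.0, np.concatenate([[0], t[1:]]),
                                               np.concatenate([[1.0], y[1:]]),
                                               np.zeros_like(t)))
            errs["lat"].append(abs(d.gamma_lat / 0.002 - 1))
            errs["int"].append(abs(d.gamma_int / 0.05 - 1))
            errs["fast"].append(abs(d.gamma_fast / 1.5 - 1))
        for k, v in errs.items():
            assert np.median(v) < 0.05, k

    def test_rate_ordering_enforced(self):
        t = np.arange(0.0, 50.5, 0.5)
        rng = np.random.default_rng(3)
        y = np.exp(-0.1 * t) + 0.02 * rng.standard_normal(t.size)
        y[0] = 1.0
        d = fit_isf_three_process(IsfCurve(1.0, t, y, np.zeros_like(t)))
        assert d.gamma_fast >= d.gamma_int >= d.gamma_lat >= 0


class TestOrderParameter:
    @staticmethod
    def _ch_bundle(h_offsets):
        """One carbon + one hydrogen per molecule with given C→H vectors."""
        n = len(h_offsets)
        pos = np.zeros((1, 2 * n, 3))
        for i, off in enumerate(h_offsets):
            pos[0, 2 * i + 1] = np.asarray(off)
        labels = pd.DataFrame({
            "chain": np.repeat(np.arange(n), 2),
            "carbon": [5, 5] * n,
            "role": ["C", "H"] * n,
            "region": ["tail"] * (2 * n)})
        pairs = np.array([[2 * i, 2 * i + 1] for i in range(n)])
        return TrajectoryBundle(pos, 1.0, labels, ch_pairs=pairs,
                                meta={"static_ok": True})

    def test_parallel_bonds_give_unity(self):
        traj = self._ch_bundle([[0, 0, 1.09]] * 10)
        prof = order_parameter_profile(traj)
        assert prof.s_ch.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_perpendicular_bonds_give_minus_half(self):
        traj = self._ch_bundle([[1.09, 0, 0], [0, 1.09, 0]] * 5)
        prof = order_parameter_profile(traj)
        assert prof.s_ch.iloc[0] == pytest.approx(-0.5, abs=1e-12)

    def test_isotropic_orientations_vanish(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        traj = self._ch_bundle(list(1.09 * v))
        prof = order_parameter_profile(traj)
        assert abs(prof.s_ch.iloc[0]) < 0.01

    def test_missing_topology_rejected(self):
        pos = np.zeros((1, 4, 3))
        traj = _bundle(pos)
        with pytest.raises(ValueError, match="bond"):
            order_parameter_profile(traj)

    def test_aligned_all_trans_chains_perpendicular(self):
        # ideal all-trans chains along the normal: C–H ⊥ normal → S_CH ≈ −1/2
        traj = generate_chain_conformations(10, 0.0, seed=2,
                                            orientation="aligned")
        prof = order_parameter_profile(traj)
        assert np.allclose(prof.s_ch, -0.5, atol=5e-3)


class TestDihedrals:
    def test_classifier_exact_on_generated_states(self):
        traj = generate_chain_conformations(50, 0.3, seed=4)
        stats = gauche_trans_ratio(traj)
        states = traj.meta["dihedral_states"]
        assert stats.gauche == int((states > 0).sum())
        assert stats.trans == int((states == 0).sum())
        assert stats.other == 0

    def test_all_trans_ratio_zero(self):
        traj = generate_chain_conformations(20, 0.0, seed=1)
        assert gauche_trans_ratio(traj).ratio == 0.0

    def test_counting_example(self):
        # 15 dihedrals: 3 gauche at |φ|=60°, 12 trans at 180° → ratio 0.25
        phis = np.array([60.0] * 3 + [180.0] * 12)
        # build one long chain realizing these dihedrals
        from qens_bilayer.synthetic import _build_backbone
        backbone = _build_backbone(phis, phis.size + 3)
        labels = pd.DataFrame({
            "chain": 0, "carbon": np.arange(backbone.shape[0]),
            "role": "C", "region": "tail"})
        traj = TrajectoryBundle(backbone[None], 1.0, labels,
                                backbones=[np.arange(backbone.shape[0])],
                                meta={"static_ok": True})
        stats = gauche_trans_ratio(traj)
        assert (stats.gauche, stats.trans) == (3, 12)
        assert stats.ratio == pytest.approx(0.25)

    def test_boundary_angle_is_other(self):
        from qens_bilayer.synthetic import _build_backbone
        backbone = _build_backbone(np.array([100.0, 180.0]), 5)
        labels = pd.DataFrame({
            "chain": 0, "carbon": np.arange(5), "role": "C",
            "region": "tail"})
        traj = TrajectoryBundle(backbone[None], 1.0, labels,
                                backbones=[np.arange(5)],
                                meta={"static_ok": True})
        stats = gauche_trans_ratio(traj)
        assert stats.other == 1 and stats.gauche == 0 and stats.trans == 1

    def test_invariance_under_chain_reversal_and_mirror(self):
        traj = generate_chain_conformations(10, 0.4, seed=9)
        base = gauche_trans_ratio(traj)
        rev = TrajectoryBundle(traj.positions, traj.dt, traj.labels,
                               backbones=[b[::-1] for b in traj.backbones],
                               meta={"static_ok": True})
        assert gauche_trans_ratio(rev).ratio == pytest.approx(base.ratio)
        mirror = TrajectoryBundle(traj.positions * np.array([1, 1, -1.0]),
                                  traj.dt, traj.labels,
                                  backbones=traj.backbones,
                                  meta={"static_ok": True})
        assert gauche_trans_ratio(mirror).ratio == pytest.approx(base.ratio)

    def test_dihedral_sign_convention(self):
        # trans butane: φ = ±180; the helper matches the IUPAC convention
        p = np.array([[0.0, 1.0, 0.0], [0, 0, 0], [1.0, 0, 0],
                      [1.0, -1.0, 0.0]])
        assert abs(dihedral_angles(p[0], p[1], p[2], p[3])) == pytest.approx(180.0)


class TestLateralFromIsf:
    def test_2d_brownian_recovery(self):
        # D = 0.32 Å²/ps in-plane; planar ISF → Γ_lat = DQ² within 10%
        cfg = TrajectoryGeneratorConfig(n_particles=600, n_frames=400,
                                        dt=0.5, d_lat_A2_ps=0.32, seed=5)
        traj = generate_trajectory(cfg)
        curves = compute_isf(traj, [0.4, 0.6, 0.8, 1.0], max_lag=40,
                             average="planar")
        decs = [fit_isf_three_process(c) for c in curves]
        out = lateral_diffusivity_from_isf(decs)
        assert out["d_lat_A2_ps"] == pytest.approx(0.32, rel=0.10)

    def test_zero_displacement_gives_zero(self):
        decs = []
        t = np.arange(0.0, 50.5, 0.5)
        for q in (0.5, 0.8, 1.1):
            decs.append(fit_isf_three_process(
                IsfCurve(q, t, np.ones_like(t), np.zeros_like(t))))
        assert lateral_diffusivity_from_isf(decs)["d_lat_cm2_s"] == pytest.approx(
            0.0, abs=1e-12)

    def test_displacement_scaling_quadruples_d(self):
        cfg = TrajectoryGeneratorConfig(n_particles=400, n_frames=300,
                                        dt=0.5, d_lat_A2_ps=0.1, seed=6)
        traj = generate_trajectory(cfg)
        doubled = TrajectoryBundle(2.0 * traj.positions, traj.dt, traj.labels,
                                   meta={"static_ok": True})
        qs = [0.3, 0.45, 0.6]
        d1 = lateral_diffusivity_from_isf(
            [fit_isf_three_process(c)
             for c in compute_isf(traj, qs, max_lag=30, average="planar")])
        d2 = lateral_diffusivity_from_isf(
            [fit_isf_three_process(c)
             for c in compute_isf(doubled, qs, max_lag=30, average="planar")])
        assert d2["d_lat_A2_ps"] == pytest.approx(4 * d1["d_lat_A2_ps"],
                                                  rel=0.15)
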