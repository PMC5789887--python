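"""Scattering-law models: closed forms, sum rules, limits and HWHM oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import spherical_jn

from qens_bilayer.constants import HBAR_MEV_PS as HBAR
from qens_bilayer.models import (
    FluidModelParams,
    GelCoagelModelParams,
    LateralModel,
    LorentzianMixture,
    bilayer_components,
    composite_internal_components,
    confined_sphere_components,
    eisf_fluid,
    eisf_gel_coagel,
    hwhm_of_mixture,
    jump_rotation_structure_factors,
    lorentzian,
    methyl_3fold_components,
    model_hwhm,
    sphere_eigenvalues,
    sphere_structure_factors,
    uniaxial_rotation_components,
)


class TestLorentzian:
    @pytest.mark.parametrize("gamma,e,expected", [
        (0.1, 0.0, 1.0 / (0.1 * np.pi)),
        (0.1, 0.1, (1.0 / np.pi) * (0.1 / 0.02)),
    ])
    def test_closed_form(self, gamma, e, expected):
        assert lorentzian(gamma, e) == pytest.approx(expected, rel=1e-12)

    def test_unit_area_and_symmetry(self):
        e = np.linspace(-400.0, 400.0, 2_000_001)
        y = lorentzian(0.1, e)
        assert np.trapezoid(y, e) == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(y, y[::-1])

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            lorentzian(0.0, 1.0)


class TestJumpRotation:
    def test_zero_argument_is_elastic(self):
        b = jump_rotation_structure_factors(0.0, 12)
        assert b[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(b[1:]) < 1e-12)

    @pytest.mark.parametrize("qa", [0.5, 2.0, 7.3])
    def test_sum_rule(self, qa):
        assert jump_rotation_structure_factors(qa, 12).sum() == pytest.approx(
            1.0, abs=1e-12)

    def test_large_qa_limit(self):
        # only the i = N_s term (argument 0) survives: B_0 → 1/N_s
        b = jump_rotation_structure_factors(200.0, 12)
        assert b[0] == pytest.approx(1.0 / 12.0, abs=1e-3)

    def test_rejects_too_few_sites(self):
        with pytest.raises(ValueError):
            jump_rotation_structure_factors(1.0, 1)


class TestUniaxialRotation:
    def test_q_zero_is_pure_elastic(self):
        p = GelCoagelModelParams(p_x=1.0, a=1.7, tau=2.0, tau_MG=5.0)
        mix = uniaxial_rotation_components(0.0, p)
        assert mix.elastic == pytest.approx(1.0, abs=1e-12)
        assert mix.quasielastic_weight == pytest.approx(0.0, abs=1e-12)

    def test_total_weight_conserved(self):
        p = GelCoagelModelParams(p_x=1.0, a=1.7, tau=2.0, tau_MG=5.0)
        mix = uniaxial_rotation_components(1.5 / 1.7, p)
        assert mix.total_weight == pytest.approx(1.0, abs=1e-12)

    def test_narrowest_width_closed_form(self):
        # τ₁⁻¹ = 2 sin²(π/12)/τ with τ = 2 ps → ħ/τ₁ ≈ 0.0441 meV
        p = GelCoagelModelParams(p_x=1.0, a=1.7, tau=2.0, tau_MG=5.0)
        mix = uniaxial_rotation_components(1.0, p)
        expected = HBAR * 2.0 * np.sin(np.pi / 12) ** 2 / 2.0
        assert mix.gammas.min() == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0441, abs=2e-4)


class TestMethylRotation:
    def test_q_zero_fully_elastic(self):
        assert methyl_3fold_components(0.0, 1.8, 6.7).elastic == pytest.approx(1.0)

    def test_width_from_residence_time(self):
        mix = methyl_3fold_components(1.0, 1.8, 6.7)
        assert mix.gammas[0] == pytest.approx(3 * HBAR / 6.7, rel=1e-12)
        assert mix.gammas[0] == pytest.approx(0.2947, abs=2e-4)

    def test_high_q_elastic_limit_one_third(self):
        assert methyl_3fold_components(800.0, 1.8, 6.7).elastic == pytest.approx(
            1.0 / 3.0, abs=1e-3)


class TestSphereEigenvalues:
    def test_known_roots(self, eig):
        assert eig.roots[1, 0] == pytest.approx(2.0816, abs=1e-3)
        assert eig.roots[0, 0] == pytest.approx(4.4934, abs=1e-3)

    def test_ordering_and_positivity(self, eig):
        assert np.all(eig.roots > 0)
        assert np.all(np.diff(eig.roots, axis=1) > 0)

    @pytest.mark.parametrize("l", [0, 1, 5, 12])
    def test_matches_brute_force_sign_scan(self, eig, l):
        # independent oracle: fine-grid sign scan of d j_l/dx + bisection
        f = lambda x: spherical_jn(l, x, derivative=True)
        xs = np.arange(1e-4, 40.0, 1e-3)
        vals = f(xs)
        flips = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        roots = [brentq(f, xs[k], xs[k + 1], xtol=1e-12) for k in flips]
        n_cmp = min(len(roots), eig.n_max)
        assert np.allclose(eig.roots[l, :n_cmp], roots[:n_cmp], atol=1e-6)


class TestConfinedSphere:
    def test_qr_zero_fully_elastic(self, eig):
        mix = confined_sphere_components(1e-9, 3.0, 0.1, eig)
        assert mix.elastic == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("qr", [0.5, 2.0, 9.7])
    def test_structure_factor_completeness(self, eig, qr):
        a00, w = sphere_structure_factors(qr, eig)
        assert a00 + w.sum() == pytest.approx(1.0, abs=1e-3)

    def test_low_q_hwhm_limit(self, eig):
        # dominated by the lowest mode: Γ → (x_1^1)²·ħD/R² = 4.333·ħD/R²
        mix = confined_sphere_components(0.01, 3.0, 0.1, eig)
        expected = 2.0816**2 * HBAR * 0.1 / 9.0
        assert hwhm_of_mixture(mix) == pytest.approx(expected, rel=0.01)

    def test_approaches_free_diffusion_from_below(self, eig):
        # HWHM → ħDQ² monotonically from below as QR grows
        R, D = 3.0, 0.1
        qs = np.array([1.0, 3.0, 6.0, 10.0])
        hw = np.array([hwhm_of_mixture(confined_sphere_components(q, R, D, eig))
                       for q in qs])
        free = HBAR * D * qs**2
        ratio = hw / free
        assert np.all(ratio < 1.0)
        assert np.all(np.diff(ratio) > 0)

    def test_degenerate_radius_is_elastic(self, eig):
        mix = confined_sphere_components(1.0, 0.0, 0.1, eig)
        assert mix.elastic == 1.0 and mix.quasielastic_weight == 0.0


class TestEisf:
    def test_unity_at_q_zero(self, coagel_params, fluid_params):
        assert eisf_gel_coagel(0.0, coagel_params) == pytest.approx(1.0)
        assert eisf_fluid(0.0, fluid_params) == pytest.approx(1.0)

    def test_gel_coagel_high_q_limit(self):
        # P_h/3 + P_t(1−p_x) + P_t·p_x/N_s with the DODAB fractions
        p = GelCoagelModelParams(p_x=0.15, a=1.7, tau=1.0, tau_MG=1.0)
        expected = 0.075 / 3 + 0.925 * 0.85 + 0.925 * 0.15 / 12
        assert eisf_gel_coagel(600.0, p) == pytest.approx(expected, abs=2e-3)
        assert expected == pytest.approx(0.8228, abs=1e-3)

    def test_immobile_chain_gives_unity(self):
        p = GelCoagelModelParams(p_x=0.0, a=1.7, tau=1.0, tau_MG=1.0,
                                 p_head=0.0, p_tail=1.0)
        q = np.linspace(0.0, 5.0, 50)
        assert np.allclose(eisf_gel_coagel(q, p), 1.0)

    def test_fluid_high_q_limit(self, fluid_params):
        assert eisf_fluid(700.0, fluid_params) == pytest.approx(0.025, abs=1e-3)

    def test_fluid_degenerate_radii_single_sphere(self):
        p = FluidModelParams(r_min=2.0, r_max=2.0, d_min=0.1, d_max=0.1,
                             tau_MG=2.6)
        q = 1.3
        single = 9.0 * (spherical_jn(1, q * 2.0) / (q * 2.0)) ** 2
        expected = p.p_head / 3 * (1 + 2 * np.sinc(q * 1.8 / np.pi)) \
            + p.p_tail * single
        assert eisf_fluid(q, p) == pytest.approx(expected, rel=1e-12)

    @given(
        p_x=st.floats(0.0, 1.0),
        a=st.floats(0.5, 3.0),
        q=st.floats(0.0, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_gel_coagel_bounded(self, p_x, a, q):
        p = GelCoagelModelParams(p_x=p_x, a=a, tau=1.0, tau_MG=1.0)
        val = eisf_gel_coagel(q, p)
        assert -1e-9 <= val <= 1.0 + 1e-9

    @given(
        r_max=st.floats(0.5, 8.0),
        q=st.floats(0.0, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_fluid_bounded(self, r_max, q):
        p = FluidModelParams(r_min=0.1, r_max=r_max, d_min=0.01, d_max=0.1,
                             tau_MG=2.6)
        val = eisf_fluid(q, p)
        assert -1e-9 <= val <= 1.0 + 1e-9


class TestCompositeModels:
    @pytest.mark.parametrize("phase", ["coagel", "gel"])
    def test_elastic_weight_equals_eisf(self, phase, coagel_params):
        mix = composite_internal_components(1.0, phase, coagel_params)
        assert mix.elastic == pytest.approx(
            eisf_gel_coagel(1.0, coagel_params), rel=1e-12)

    def test_fluid_elastic_weight_equals_eisf(self, fluid_params, eig):
        mix = composite_internal_components(1.0, "fluid", fluid_params, eig)
        assert mix.elastic == pytest.approx(eisf_fluid(1.0, fluid_params),
                                            rel=1e-6)

    @pytest.mark.parametrize("q", [0.5, 1.0, 1.8])
    def test_weight_conservation(self, q, fluid_params, coagel_params, eig):
        for phase, params in (("gel", coagel_params),
                              ("fluid", fluid_params)):
            mix = composite_internal_components(q, phase, params, eig)
            assert mix.total_weight == pytest.approx(1.0, abs=1e-3)

    def test_phase_params_mismatch_raises(self, coagel_params):
        with pytest.raises(TypeError):
            composite_internal_components(1.0, "fluid", coagel_params)


class TestModelHwhm:
    def test_single_lorentzian(self):
        mix = LorentzianMixture(0.0, np.array([1.0]), np.array([0.2]))
        assert hwhm_of_mixture(mix) == pytest.approx(0.2, rel=1e-9)

    def test_two_lorentzian_mix_vs_bisection_oracle(self):
        mix = LorentzianMixture(0.0, np.array([0.5, 0.5]),
                                np.array([0.1, 0.3]))

        def s(e):
            return sum(w * (g / np.pi) / (g * g + e * e)
                       for w, g in ((0.5, 0.1), (0.5, 0.3)))

        lo, hi = 1e-6, 10.0
        target = s(0.0) / 2
        for _ in range(80):  # independent bisection oracle
            mid = 0.5 * (lo + hi)
            if s(mid) > target:
                lo = mid
            else:
                hi = mid
        assert hwhm_of_mixture(mix) == pytest.approx(0.5 * (lo + hi),
                                                     rel=1e-9)

    def test_fluid_low_q_plateau(self, fluid_params, eig):
        # confined motion: Γ_int flattens to a finite nonzero low-Q limit
        g_low = model_hwhm(0.05, "fluid", fluid_params, eig)
        g_lower = model_hwhm(0.02, "fluid", fluid_params, eig)
        assert g_low > 1e-3
        assert g_lower == pytest.approx(g_low, rel=0.05)

    def test_agrees_with_dense_grid_oracle_on_random_draws(self, eig):
        rng = np.random.default_rng(1234)
        for _ in range(20):
            phase = rng.choice(["gel", "fluid"])
            q = rng.uniform(0.4, 1.8)
            if phase == "gel":
                params = GelCoagelModelParams(
                    p_x=rng.uniform(0.1, 0.9), a=rng.uniform(1.0, 2.5),
                    tau=rng.uniform(1.0, 10.0), tau_MG=rng.uniform(2.0, 10.0))
            else:
                r_max = rng.uniform(2.0, 6.0)
                d_max = rng.uniform(0.05, 0.4)
                params = FluidModelParams(
                    r_min=rng.uniform(0.05, 0.5), r_max=r_max,
                    d_min=rng.uniform(1e-3, 0.02), d_max=d_max,
                    tau_MG=rng.uniform(1.0, 8.0))
            mix = composite_internal_components(q, phase, params, eig)
            # dense-grid oracle: double the span until the half height is
            # inside, then locate the crossing by linear interpolation
            half = mix.density(0.0)[0] / 2
            hi = mix.gammas.min()
            while mix.density(hi)[0] > half:
                hi *= 2.0
            e = np.linspace(0.0, hi, 40_001)
            s = mix.density(e)
            k = np.argmax(s < half)
            frac = (s[k - 1] - half) / (s[k - 1] - s[k])
            oracle = e[k - 1] + frac * (e[k] - e[k - 1])
            assert model_hwhm(q, phase, params, eig) == pytest.approx(
                oracle, rel=0.01)


class TestBilayerLaw:
    def test_zero_lateral_reduces_to_internal(self, coagel_params):
        internal = composite_internal_components(1.0, "gel", coagel_params)
        full = bilayer_components(1.0, LateralModel(d_lat=0.0), "gel",
                                  coagel_params)
        assert full.elastic == pytest.approx(internal.elastic)
        assert np.allclose(np.sort(full.gammas), np.sort(internal.gammas))

    def test_lorentzian_width_additivity(self, coagel_params):
        lat = LateralModel(d_lat=1.5e-6)
        g_lat = float(lat.gamma_lat(1.0))
        internal = composite_internal_components(1.0, "gel", coagel_params)
        full = bilayer_components(1.0, lat, "gel", coagel_params)
        assert full.elastic == 0.0
        assert np.allclose(np.sort(full.gammas),
                           np.sort(np.concatenate([[g_lat],
                                                   internal.gammas + g_lat])))

    def test_printed_lateral_width_unit_chain(self):
        # D = 1.5×10⁻⁶ cm²/s at Q = 1 Å⁻¹ → ħDQ² ≈ 9.87×10⁻³ meV
        lat = LateralModel(d_lat=1.5e-6)
        assert float(lat.gamma_lat(1.0)) == pytest.approx(
            HBAR * 0.015, rel=1e-12)
        assert float(lat.gamma_lat(1.0)) == pytest.approx(9.87e-3, abs=1e-5)

    def test_coagel_keeps_elastic_line(self, coagel_params):
        full = bilayer_components(1.0, LateralModel(d_lat=1e-6), "coagel",
                                  coagel_params)
        assert full.elastic > 0


class TestParamValidation:
    def test_rotational_diffusion_constant(self):
        p = GelCoagelModelParams(p_x=0.5, a=1.7, tau=2.0, tau_MG=5.0)
        assert p.d_r == pytest.approx(2 / 2.0 * np.sin(np.pi / 12) ** 2)
        p2 = GelCoagelModelParams.from_d_r(p_x=0.5, a=1.7, d_r_per_ps=p.d_r,
                                           tau_MG=5.0)
        assert p2.tau == pytest.approx(2.0, rel=1e-12)

    def test_fluid_linear_site_distributions(self, fluid_params):
        r = fluid_params.radii
        d = fluid_params.diffusivities
        assert r[0] == fluid_params.r_min and r[-1] == fluid_params.r_max
        assert d[0] == fluid_params.d_min and d[-1] == fluid_params.d_max
        assert np.all(np.diff(r) >= 0) and np.all(np.diff(d) >= 0)

    @pytest.mark.parametrize("kwargs", [
        dict(p_x=1.2, a=1.7, tau=1.0, tau_MG=1.0),
        dict(p_x=0.5, a=-1.0, tau=1.0, tau_MG=1.0),
        dict(p_x=0.5, a=1.7, tau=1.0, tau_MG=1.0, n_s=1),
    ])
    def test_invalid_gel_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            GelCoagelModelParams(**kwargs)

    def test_invalid_fluid_params_raise(self):
        with pytest.raises(ValueError):
            FluidModelParams(r_min=2.0, r_max=1.0, d_min=0.1, d_max=0.2,
                             tau_MG=1.0)
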