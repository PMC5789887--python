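# qens-bilayer

Quasielastic neutron scattering (QENS) and trajectory analysis of lipid-bilayer
dynamics, built around the phase behaviour of DODAB
((C₁₈H₃₇)₂N(CH₃)₂Br) vesicles: a crystalline, dehydrated **coagel** phase, an
intermediate **gel** phase, and a melted **fluid** phase. The package is aimed
at neutron-scattering practitioners who fit backscattering spectra
(IRIS-like: 17 μeV resolution, −0.3 to +1.0 meV window, Q = 0.5–1.8 Å⁻¹) and
at simulators who compute the same observables from particle trajectories.

## What it computes

**Scattering laws.** The bilayer spectrum factorizes into lateral and internal
motion, S_bl(Q,E) = S_lat ⊗ S_int. Lateral diffusion is Fickian,
Γ_lat = ħ·D_lat·Q². Internal motion is phase specific:

* *coagel/gel* — uniaxial rotational diffusion of all-trans chains,
  approximated by jumps among N_s = 12 sites on a circle of radius *a*, with
  only a fraction p_x of chain hydrogens mobile, plus 3-fold methyl rotation
  of the head groups (H–H distance b = 1.8 Å, residence time τ_MG). EISF:

      A(Q) = (P_h/3)(1 + 2j₀(Qb)) + P_t(1 − p_x)
             + P_t (p_x/N_s) Σᵢ j₀(2Qa sin(πi/N_s))

* *fluid* — localized translational diffusion: each CH₂ site's hydrogens
  diffuse inside a reflecting sphere, with radii R_i and diffusivities D_i
  linearly distributed along the chain (R_min…R_max, D_min…D_max over
  N_c = 18 sites). The sphere scattering law is the standard eigenmode
  expansion with elastic factor [3j₁(QR)/QR]² and Lorentzian rates
  ħ(x_nˡ)²D/R².

Hydrogen weights are counted from the molecular formula: P_h = 6/80,
P_t = 74/80.

**The inference chain.** Per-Q spectra are decomposed into
A·L(Γ_lat) + (1−A)·L(Γ_lat+Γ_int) convolved with the measured resolution
(pure elastic line instead of L(Γ_lat) in the coagel). The Q dependence of A
gives the geometry (p_x, a or R_min, R_max); the numerically computed model
HWHM fitted to Γ_int(Q) gives the rates (D_r, τ_MG or D_min, D_max, τ_MG);
Γ_lat(Q²) gives D_lat; and ln D_lat vs 1/T gives the Arrhenius activation
energy.

**Elastic window scans.** ⟨u²⟩(T) from the Gaussian approximation
ln[I(Q,T)/I(Q,T_min)] = −⟨u²⟩Q²/6, and transition temperatures from
BIC-selected piecewise-linear slope changes of the Q-averaged intensity.

**Trajectories.** Incoherent intermediate scattering function I(Q,t) with
exact orientation averages (isotropic sinc or in-plane J₀), the
three-process decomposition
I(Q,t) = e^{−Γ_lat t}[A₁+(1−A₁)e^{−Γ_int t}][A₂+(1−A₂)e^{−Γ_fast t}],
C–H order parameters S_CH = ½[3⟨cos²θ⟩−1], and gauche/trans dihedral
statistics (gauche: |φ| ∈ 45–75°, trans: |φ| ≥ 165°).

**Synthetic data.** Generators produce QENS spectra (from the package's own
scattering laws, resolution-convolved, Poisson-noised), elastic scans, and
three-process trajectories with known ground truth, so the whole chain is
testable without measured data.

## Worked example

Recover the fluid-phase parameters from synthetic spectra generated at the
published 345 K values, then the activation energy across temperatures:

```sh
python analysis/03_fluid_phase_qens.py
```

prints (seed 1):

```
315 K: D_lat=1.50e-6 (gen 1.5e-6 cm2/s), R_max=3.34 A (gen 3.3), D_max=12.9e-6 (gen 12.8e-6)
330 K: D_lat=2.40e-6 (gen 2.4e-6 cm2/s), R_max=4.22 A (gen 4.2), D_max=19.4e-6 (gen 19.4e-6)
345 K: D_lat=3.50e-6 (gen 3.5e-6 cm2/s), R_max=5.43 A (gen 5.4), D_max=26.1e-6 (gen 26.1e-6)
Arrhenius over the recovered fluid D_lat: E_a = 6.12 kcal/mol
```

Each line is one temperature: the lateral diffusion coefficient from the
Fickian fit of Γ_lat(Q²), the largest confinement radius from the EISF fit,
and the largest internal diffusivity from the HWHM fit — all against the
values the spectra were generated with. The final line is the Arrhenius
activation energy of lateral diffusion in the fluid phase.

The other drivers follow the same pattern: `analysis/01_elastic_scans.py`
(transition temperatures 327 K heating, 311/299 K cooling, and ⟨u²⟩(T)),
`analysis/02_ordered_phase_qens.py` (coagel/gel p_x, a, D_r, τ_MG),
`analysis/04_trajectory_analysis.py` (I(Q,t) rates, S_CH, gauche/trans).
Each writes its tables under `results/`.

A `qens-bilayer` CLI wraps the same library for file-based work:
`synth`, `reduce` (solvent subtraction I_bl = I_solution − φ·I_D2O), `fews`,
`fit-qens`, and `run` (multi-stage pipeline from a YAML config).

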