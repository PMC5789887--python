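# Methods

## Models

All spectral models are finite mixtures of an elastic line and unit-area
Lorentzians centred at E = 0 (`LorentzianMixture`). This representation is
exact for every law implemented here and makes three operations trivial:
composition of independent motions (a convolution of Lorentzians is a
Lorentzian with summed HWHMs, so lateral ⊗ internal only shifts widths by
Γ_lat), resolution convolution (done once, numerically, on the rendered
grid), and numerical HWHM extraction (the quasielastic profile of a centred
mixture is even and strictly decreasing in |E|, so the half height is a
single bracketed root).

Units: Å, ps, meV throughout; ħ = 0.65821 meV·ps converts rates to widths;
diffusivities are stored in Å²/ps and reported in cm²/s (factor 10⁻⁴).

**Uniaxial rotation (coagel/gel).** Jump rotation among N_s equivalent sites
on a circle of radius *a* approximates continuous uniaxial diffusion for
N_s > 6 and Qa ≲ π; N_s defaults to 12. Structure factors
B_n(Qa) = (1/N_s)Σ_{i=1}^{N_s} j₀(2Qa sin(πi/N_s))cos(2πni/N_s); both sums
run over i = 1…N_s (the printed B₀ sum starting at i = 0 double-counts an
endpoint whose two terms are identical, and would break the B₀ + ΣB_n = 1
sum rule). Widths ħ/τ_n with τ_n⁻¹ = 2τ⁻¹sin²(nπ/N_s); the rotational
diffusion constant is D_r = (2/τ)sin²(π/N_s).

**Methyl 3-fold rotation.** Elastic fraction (1+2j₀(Qb))/3 with b = 1.8 Å,
quasielastic width 3ħ/τ_MG.

**Diffusion in a sphere (fluid).** Eigenvalues x_nˡ are the stationary
points of the spherical Bessel functions (reflecting boundary), found by a
0.02-spaced sign scan plus Brent refinement; the table is cached
(l_max = n_max = 20, enough to close the structure-factor sum rule to 10⁻³
for QR ≲ 10). Lorentzian rates use the squared eigenvalue, (x_nˡ)²D/R²
— the standard form of the eigenmode expansion; sources that print the rate
with an unsquared x_nˡ are treated as typesetting loss of the exponent.
Site radii and diffusivities are linear in the site index. A radius below
10⁻⁸ Å short-circuits to the analytic elastic limit (weight 1), avoiding
0/0 in j₁(QR)/QR.

**Numerical HWHM.** No closed form exists for the half width of a
multi-Lorentzian profile; `model_hwhm` brackets and solves
S_qe(Γ) = S_qe(0)/2 with Brent's method (relative tolerance 10⁻¹⁰). An
independent dense-grid bisection oracle in the test suite agrees to better
than 1% over random gel and fluid parameter draws.

## Inference chain

Per-Q spectra are fitted with
scale·[A·L(Γ_lat) + (1−A)·L(Γ_lat+ΔΓ)] ⊗ R (+ background) for gel/fluid, and
scale·[A·(δ⊗R) + (1−A)·L(Γ_int)⊗R] for the coagel, by bounded trust-region
least squares with seeded multi-start (default 8 starts; multi-Lorentzian
objectives are multimodal). The elastic line is rendered resolution-shaped
(δ⊗R = R), standard backscattering practice. ΔΓ = Γ_int ≥ 0 is a fit
parameter, so Γ_tot ≥ Γ_lat holds by construction rather than by post-hoc
subtraction. The background defaults to flat+slope and can be forced to
zero; parameter uncertainties come from the Jacobian at the optimum scaled
by the reduced χ². When A pins at 1 the broad width is unidentifiable and
the result is flagged rather than trusted.

EISF and HWHM stages fit the geometric and rate parameters with fixed
hydrogen weights (P_h = 6/80, P_t = 74/80 from the formula). R_min is
bounded below at 0.05 Å and treated as a nuisance: the EISF is nearly flat
in R_min below ~0.3 Å, so its fitted value is not interpretable — consistent
with reported fits finding unrealistically small values. The Fickian fit is
weighted, zero-intercept; the Arrhenius fit is ordinary least squares of
ln D on 1/T with E_a = −slope·R (R = 1.98720×10⁻³ kcal/mol/K).

## Elastic scans

⟨u²⟩(T) comes from a weighted linear fit of ln[I(Q,T)/I(Q,T_min)] against Q²
over 0.5–0.95 Å⁻¹ with a *free* intercept: the intercept absorbs
normalization drift and the estimator reduces to the forced-zero form when
the data follow the Gaussian approximation exactly. Transition detection
fits continuous piecewise-linear models (hinge basis) with 0–3 breakpoints
on the temperature grid and selects by BIC with p = 2 + 2k parameters;
adjacent breakpoints are allowed so a one-grid-step intensity drop is
representable. The RSS is floored at numerical noise so machine-epsilon
differences between exact fits cannot out-vote the penalty, and the
standardization of the intensity makes the selection affine-invariant.

## Trajectory observables

I(Q,t) uses exact orientation averages instead of sampling Q directions:
sin(Qd)/(Qd) for an isotropic powder, J₀(Q·|d_∥|) for Q confined to the
membrane plane. The planar average is the right tool for lateral dynamics
of a planar patch: powder-averaging a purely 2D Gaussian process mixes
decay rates Q²sin²θ·D and is strongly non-exponential, which drives the
slowest factor of a multi-exponential fit toward zero; with in-plane Q the
lateral factor is exactly exp(−DQ²t). Time origins slide with 50 % overlap
by default (denser origins can be requested when the long-lag tail must be
quiet); quoted errors are origin-block standard errors and mildly
underestimate because overlapping origins correlate.

The three-process decay fit is parameterized with ordered rate gaps so
Γ_fast ≥ Γ_int ≥ Γ_lat by construction. The product form is degenerate
whenever a plateau fraction reaches 1 — a single exponential can be split
arbitrarily across factors — so the nested one- and two-process models are
fitted alongside and the winner chosen by AIC; dropped processes are
flagged unidentifiable instead of reporting an arbitrary split.

Dihedrals use the standard atan2 formula with the IUPAC sign convention and
are folded to |φ|, so +gauche and −gauche both count (the stated gauche
window covers one sign only; symmetry is assumed). Trans is |φ| ∈ 165–180°
after folding of the nominal 165–195° window. Near-colinear triplets are
excluded and counted. S_CH averages cos²θ of C–H bond vectors against the
bilayer normal per carbon index; terminal carbons carry no reconstructed
hydrogens.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes:

* **Spectra.** Default generation uses the measured-spectrum form the per-Q
  analysis is built on — two Lorentzians with A(Q) equal to the phase EISF
  and Γ_int(Q) equal to the numerically computed model HWHM (elastic line
  instead of the narrow Lorentzian in the coagel) — convolved with a
  Gaussian 17 μeV kernel on the −0.3…+1.0 meV grid (1301 points) and scaled
  to 10⁴ peak counts per Q group. The full multi-Lorentzian composite law is
  available (`spectral_form='multi_lorentzian'`) for model-level work; note
  that refitting *that* form with the two-Lorentzian measurement model
  carries an intrinsic ≈20 % lumping bias on A(Q) and the widths, which is a
  property of the measurement model, not of the optimizer. Poisson σ is
  taken from the Poisson mean (the noiseless intensity): weighting by
  √(observed counts) biases fitted widths low (Neyman χ²).
  Q groups default to 0.5–1.8 Å⁻¹ in 0.1 Å⁻¹ steps, the density of
  reported per-Q curves.
* **Elastic scans.** I_el = exp(−⟨u²⟩Q²/6) from a ⟨u²⟩(T) schedule;
  transition features are encoded as steps/kinks of the schedule;
  multiplicative Gaussian noise.
* **Trajectories.** Per particle, a 2D Brownian centre of mass (per-axis
  step variance 2·D_lat·dt), a reflecting-sphere Brownian offset (radial
  specular reflection, which preserves the uniform equilibrium density and
  starts from it), and a fast two-site telegraph jump (sites ±d/2, per-site
  hop rate k, correlation decay 2k). Labels, C–H pairs and backbone
  topology are emitted for the chain ensembles, which are built with ideal
  geometry (C–C 1.54 Å, C–H 1.09 Å, tetrahedral angles) by natural-extension
  internal-to-Cartesian construction from sampled dihedral states, with the
  ground-truth states recorded.

All randomness flows through explicit integer seeds; a fixed seed gives
byte-identical output.

## Identifiability limits

Two fitted quantities are intrinsically sloppy at backscattering counting
statistics (10⁴ peak counts, 14 Q groups), and results involving them should
be read as order-of-magnitude:

* **τ_MG in the fluid phase.** The methyl line (width 3ħ/τ_MG ≈ 0.8 meV at
  τ_MG = 2.6 ps) carries ≲5 % of the quasielastic weight and its effect on
  the composite HWHM curve is degenerate with small shifts of D_min/D_max.
  The Fisher information gives σ(ln τ_MG) ≈ 2.6 per dataset — a factor ~13
  confidence band — so even a 50-dataset median of the recovered τ_MG
  scatters by tens of percent. The gel-phase τ_MG is better but still wide
  (σ(ln τ_MG) ≈ 0.9 at 2 % width noise). D_lat, R_max, D_max and D_r are
  tight (≲1–3 %).
* **R_min / D_min.** Spheres smaller than ~0.3 Å are spectroscopically
  silent in this Q window; R_min is reported but not interpretable.

## Problem sizes

The test suite and the acceptance script size their Monte-Carlo loops for a
single CPU: 50 seeds for the EISF and ordered-phase HWHM recoveries, 50 for
the full fluid chain in the test suite and 12 in the acceptance script, 25
for the HWHM-only fluid recovery, 8 for the gel lateral recovery, 5
trajectories for the ISF diffusivity, 100–200 replicates for the unbiasedness
checks. Medians are reported throughout; the recovered values at these sizes
are stable to well under the quoted identifiability widths.

## Known limitations

* The generators emulate counting noise, resolution width and the assumed
  spectral form — not detector efficiency, absorption, multiple scattering,
  detailed balance, or coherent scattering. Passing recovery tests show the
  chain inverts its own assumptions, not that those assumptions hold for a
  given instrument.
* The solvent volume fraction φ defaults to an estimate from concentration
  and an approximate molar volume; measured values should override it.
* Sequential per-temperature fitting only; no global multi-temperature fit,
  no Bayesian posterior.
* Trajectory file loading is a thin optional MDAnalysis wrapper; the
  in-memory `TrajectoryBundle` built by the generators is the primary input
  path.
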