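"""Physical constants and unit conventions.

Internal units throughout the package: lengths in Å, times in ps, energies in
meV, momentum transfer Q in Å⁻¹.  Diffusivities are stored in Å²/ps and
reported in cm²/s (1 Å²/ps = 1e-4 cm²/s).
"""

from __future__ import annotations

from fractions import Fraction

#: ħ in meV·ps — converts a rate 1/τ (ps⁻¹) to a Lorentzian HWHM (meV).
HBAR_MEV_PS = 0.65821

#: Gas constant in kcal/(mol·K), for Arrhenius activation energies.
R_GAS_KCAL_PER_MOL_K = 1.98720e-3

#: Unit conversions for diffusivities.
A2_PER_PS_TO_CM2_PER_S = 1e-4
CM2_PER_S_TO_A2_PER_PS = 1e4

#: Approximate molar volume of DODAB (L/mol), from MW ≈ 631 g/mol and a bulk
#: density near 0.94 g/cm³.  Only used for the default solvent volume-fraction
#: estimate; overridable everywhere it appears.
DODAB_MOLAR_VOLUME_L_PER_MOL = 0.67


def hydrogen_partition(
    n_chains: int = 2,
    hydrogens_per_chain: int = 37,
    n_head_methyls: int = 2,
) -> tuple[Fraction, Fraction]:
    """Fractions of hydrogens in the head group vs the alkyl tails.

    For DODAB, (C18H37)2N(CH3)2: two octadecyl chains of 37 H each and two
    head-group methyls of 3 H each, so P_h = 6/80 and P_t = 74/80.

    Returns
    -------
    (P_h, P_t) as exact rationals; ``float()`` them for numeric use.
    """
    head = 3 * n_head_methyls
    tail = n_chains * hydrogens_per_chain
    total = head + tail
    return Fraction(head, total), Fraction(tail, total)


#: DODAB defaults, as floats.
P_HEAD, P_TAIL = (float(f) for f in hydrogen_partition())
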