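"""Physical constants and unit conversions.

Everything internal is CGS (cm, s, g, erg, dyn) with concentrations in
mol/cm^3 and molecular quantities per molecule.  The experimental
literature on channel water permeability quotes p_f in cm^3/s, D in
cm^2/s and activation energies in kcal/mol, so CGS keeps every formula
free of conversion factors.  Helpers below move between laboratory units
(mM, nm, um) and internal ones at the I/O boundary only.
"""

from __future__ import annotations

import math

# --- constants (CGS + molar) -------------------------------------------------

K_BOLTZMANN = 1.380649e-16
"""Boltzmann constant, erg/K."""

N_AVOGADRO = 6.02214076e23
"""Avogadro number, 1/mol."""

R_GAS_ERG = K_BOLTZMANN * N_AVOGADRO
"""Gas constant, erg/(mol K)."""

R_KCAL = 1.98720e-3
"""Gas constant, kcal/(mol K)."""

V_W_MOLAR = 18.0
"""Partial molar volume of water, cm^3/mol."""

V_W_MOLECULE = 3.0e-23
"""Volume of one water molecule, cm^3 (18 cm^3/mol / Avogadro)."""

Z_WATER = 2.8e-8
"""Water-water spacing in a single file, cm (one water diameter)."""

NU0_TST = 1e13
"""Universal transition-state-theory attempt frequency, 1/s."""

T_DEFAULT = 298.15
"""Default absolute temperature, K."""


# --- conversions -------------------------------------------------------------

def mM_to_mol_cm3(c_mM: float) -> float:
    """1 mM = 1e-3 mol/L = 1e-6 mol/cm^3."""
    return c_mM * 1e-6


def mol_cm3_to_mM(c: float) -> float:
    return c * 1e6


def nm_to_cm(x_nm: float) -> float:
    return x_nm * 1e-7


def cm_to_nm(x_cm: float) -> float:
    return x_cm * 1e7


def um_to_cm(x_um: float) -> float:
    return x_um * 1e-4


def cm_to_um(x_cm: float) -> float:
    return x_cm * 1e4


def osmotic_pressure(delta_c: float, T: float = T_DEFAULT) -> float:
    """Ideal (van 't Hoff) osmotic pressure, dyn/cm^2.

    Parameters
    ----------
    delta_c : osmolyte concentration difference, mol/cm^3.
    T : absolute temperature, K.
    """
    return R_GAS_ERG * T * delta_c


def number_density(c: float) -> float:
    """mol/cm^3 -> molecules/cm^3."""
    return c * N_AVOGADRO


def power_of_ten(x: float) -> int:
    """Order of magnitude, floor(log10 |x|)."""
    if x == 0:
        raise ValueError("power_of_ten undefined for 0")
    return math.floor(math.log10(abs(x)))
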