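"""Centralized unit conversions for membrane mechanics.

Conventions used throughout the package: membrane tension in mN/m at the user
interface (SI N/m internally), energies in J with a helper to express them in
units of kBT at 25 degC, lengths in nm or um as stated per function, areal
densities in molecules per um^2.
"""

# Thermal energy at 25 degC.
KBT_J = 4.11e-21

NM_PER_M = 1e9
UM2_PER_M2 = 1e12
MN_PER_M_TO_N_PER_M = 1e-3


def tension_si(sigma_mn_per_m: float) -> float:
    """Convert a membrane tension from mN/m to N/m."""
    return sigma_mn_per_m * MN_PER_M_TO_N_PER_M


def joules_to_kbt(energy_j: float) -> float:
    """Express an energy in units of kBT (25 degC)."""
    return energy_j / KBT_J


def kbt_to_joules(energy_kbt: float) -> float:
    """Convert an energy in kBT (25 degC) to joules."""
    return energy_kbt * KBT_J


def per_um2_to_per_m2(density: float) -> float:
    """Convert an areal density from um^-2 to m^-2."""
    return density * UM2_PER_M2


def m_to_nm(length_m: float) -> float:
    return length_m * NM_PER_M
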