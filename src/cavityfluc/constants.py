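"""Physical constants and unit conversions.

Internal unit system: lengths in Å, energies in kJ/mol, temperature in K.
Pressures are supplied in atm and converted once to kJ/(mol·Å³); surface
tensions are supplied in dyn/cm (= mN/m) and converted once to kJ/(mol·Å²).
All conversions live here so the rest of the package never repeats them.
"""

# Molar gas constant in kJ/(mol K); plays the role of k_B in molar units.
KB_KJ_PER_MOL_K = 8.31446261815324e-3

# 1 atm expressed in kJ/(mol Å³): 101325 Pa × N_A × 1e-30 m³/Å³ / 1000.
ATM_TO_KJ_PER_MOL_A3 = 101325.0 * 6.02214076e23 * 1e-30 / 1000.0

# 1 dyn/cm (= 1 mN/m) expressed in kJ/(mol Å²).
DYN_PER_CM_TO_KJ_PER_MOL_A2 = 1e-3 * 6.02214076e23 * 1e-20 / 1000.0

KCAL_TO_KJ = 4.184


def kT(temperature: float) -> float:
    """Thermal energy k_B·T in kJ/mol at the given temperature in K."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_KJ_PER_MOL_K * temperature


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    return 1.0 / kT(temperature)


def pressure_to_internal(pressure_atm: float) -> float:
    """Convert a pressure in atm to kJ/(mol Å³)."""
    return pressure_atm * ATM_TO_KJ_PER_MOL_A3


def surface_tension_to_internal(gamma_dyn_cm: float) -> float:
    """Convert a surface tension in dyn/cm to kJ/(mol Å²)."""
    return gamma_dyn_cm * DYN_PER_CM_TO_KJ_PER_MOL_A2


def compressibility_to_internal(kappa_per_atm: float) -> float:
    """Convert an isothermal compressibility in atm⁻¹ to (kJ/(mol Å³))⁻¹."""
    return kappa_per_atm / ATM_TO_KJ_PER_MOL_A3
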