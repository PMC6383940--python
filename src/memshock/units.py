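"""Unit system and conversion constants.

Internal units throughout the simulator: length in Angstrom (A), time in
picoseconds (ps), mass in atomic mass units (amu).  The derived internal
units are therefore

* velocity  : A/ps            (= 100 m/s)
* energy    : amu A^2 ps^-2   (= 1.66054e-23 J ~= 1.2 kT at 310 K / 258)
* pressure  : amu A^-1 ps^-2  (= 16.605 MPa)
* pressure impulse : amu A^-1 ps^-1 (= 1.66054e-5 Pa s)

All public reports use SI (m/s, ps, GPa, mPa s); this module is the single
place where the conversion factors live.
"""

# CODATA 2018
BOLTZMANN_J_PER_K = 1.380649e-23
AMU_KG = 1.66053906660e-27

ANGSTROM_M = 1e-10
PS_S = 1e-12

# internal energy unit in joule: amu * A^2 / ps^2
ENERGY_INTERNAL_J = AMU_KG * ANGSTROM_M**2 / PS_S**2

#: Boltzmann constant in internal units, amu A^2 ps^-2 K^-1
KB = BOLTZMANN_J_PER_K / ENERGY_INTERNAL_J  # ~0.83144626

#: one internal pressure unit (amu A^-1 ps^-2) in pascal
PRESSURE_INTERNAL_PA = AMU_KG / (ANGSTROM_M * PS_S**2)  # ~1.6605e7 Pa
PRESSURE_INTERNAL_GPA = PRESSURE_INTERNAL_PA * 1e-9

#: one internal pressure-impulse unit (amu A^-1 ps^-1) in Pa s
IMPULSE_INTERNAL_PA_S = AMU_KG / (ANGSTROM_M * PS_S)  # ~1.6605e-5 Pa s

#: one mPa s (1e-3 Pa s) in internal impulse units
MPA_S_INTERNAL = 1e-3 / IMPULSE_INTERNAL_PA_S  # ~60.22

#: one internal mass density unit (amu/A^3) in kg/m^3
DENSITY_INTERNAL_KG_M3 = AMU_KG / ANGSTROM_M**3  # ~1660.54

#: one A/ps in m/s
VELOCITY_INTERNAL_M_S = 100.0


def si_impulse_to_internal(impulse_pa_s: float) -> float:
    """Pa s -> amu A^-1 ps^-1."""
    return impulse_pa_s / IMPULSE_INTERNAL_PA_S


def si_density_to_internal(density_kg_m3: float) -> float:
    """kg/m^3 -> amu/A^3."""
    return density_kg_m3 / DENSITY_INTERNAL_KG_M3


def internal_pressure_to_gpa(p_internal: float) -> float:
    """amu A^-1 ps^-2 -> GPa."""
    return p_internal * PRESSURE_INTERNAL_GPA
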