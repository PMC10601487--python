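"""Unit conversions.

All internal computation is in Hartree atomic units (hbar = 1, mass-weighted
nuclear coordinates). I/O accepts the conventional units of the field:
cm^-1 for frequencies, eV and kcal/mol for energies, K for temperature,
fs for time.
"""

from __future__ import annotations

# 1 hartree in other energy units
HARTREE_TO_CM1 = 219474.6313632
HARTREE_TO_KCALMOL = 627.509474
HARTREE_TO_EV = 27.211386245988

# 1 atomic unit of time in femtoseconds
AU_TIME_TO_FS = 0.02418884254

# Boltzmann constant in hartree/K
KB_HARTREE = 3.166811563e-6

CM1_TO_HARTREE = 1.0 / HARTREE_TO_CM1
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV
FS_TO_AU_TIME = 1.0 / AU_TIME_TO_FS

_ENERGY_FACTORS = {
    "hartree": 1.0,
    "au": 1.0,
    "ev": EV_TO_HARTREE,
    "kcal/mol": KCALMOL_TO_HARTREE,
    "kcalmol": KCALMOL_TO_HARTREE,
    "cm-1": CM1_TO_HARTREE,
    "cm^-1": CM1_TO_HARTREE,
}


def energy_to_au(value, unit: str):
    """Convert an energy (or frequency, via hbar=1) to hartree."""
    try:
        return value * _ENERGY_FACTORS[unit.lower()]
    except KeyError:
        raise ValueError(f"unrecognized energy unit: {unit!r}") from None


def beta_from_temperature(temperature_K: float) -> float:
    """Inverse temperature 1/(k_B T) in 1/hartree."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (KB_HARTREE * temperature_K)
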