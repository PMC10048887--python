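"""Physical constants and unit-conversion factors.

Energies are carried internally in hartree (Eh); conversion to kcal/mol
happens only at reporting boundaries so that rounding never accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Constants:
    """Immutable bundle of physical constants used throughout the package.

    Attributes
    ----------
    hartree_to_kcal
        kcal·mol⁻¹ per hartree.
    boltzmann_hartree
        Boltzmann constant in Eh·K⁻¹ — applied directly to free energies in
        hartree, so Boltzmann weights need no per-mole conversion.
    gas_constant_kcal
        Molar gas constant in kcal·mol⁻¹·K⁻¹ (Eyring exponents on kcal/mol
        barriers).
    planck, boltzmann_si, speed_of_light
        SI values; ``speed_of_light`` is in cm·s⁻¹ because vibrational
        frequencies arrive as wavenumbers.
    hartree_joule, avogadro, atm_pascal
        Bridges between the molecular (SI) and molar/atomic-unit scales.
    default_temperature
        K; the temperature at which all study-condition populations and
        barriers are evaluated.
    """

    hartree_to_kcal: float = 627.5095
    boltzmann_hartree: float = 3.166811563e-6
    gas_constant_kcal: float = 1.98720425864e-3
    planck: float = 6.62607015e-34
    boltzmann_si: float = 1.380649e-23
    speed_of_light: float = 2.99792458e10
    hartree_joule: float = 4.3597447222071e-18
    avogadro: float = 6.02214076e23
    atm_pascal: float = 101325.0
    default_temperature: float = 298.15
    default_pressure: float = 1.0

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"constant {name} must be positive, got {value}")


#: Shared default constant set (CODATA 2018 where applicable).
CODATA = Constants()
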