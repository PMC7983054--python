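"""Physical constants and unit conversions.

All internal computation in this package is carried out in the CGS-Gaussian
(e.s.u.) system; user-facing quantities use the practical units of the
fluorescent-protein literature (Debye, Å³, MV/cm, GM, ns, kcal/mol).  This
module is the single source of truth for the constants and for the closed
set of conversions the other modules need.  It is deliberately not a
general-purpose unit-algebra system.

Conventions
-----------
* 1 statvolt = 299.792458 V exactly (CODATA-derived, since c is exact).
  Consequently 1 D/Å³ = 1e6 statvolt/cm = 299.792458 MV/cm exactly.
* Spectroscopic wavenumbers (cm⁻¹) are treated as an energy unit through
  the factor h·c.
* kcal/mol is a per-molecule energy unit through the thermochemical
  calorie (1 cal = 4.184 J) and Avogadro's number.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "convert",
    "thermal_energy",
    "ThermalEnergy",
    "UNIT_REGISTRY",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-2018 constants in CGS-Gaussian units."""

    h: float = 6.62607015e-27          # Planck constant, erg s
    c: float = 2.99792458e10           # speed of light, cm/s
    kB: float = 1.380649e-16           # Boltzmann constant, erg/K
    NA: float = 6.02214076e23          # Avogadro number, 1/mol
    e: float = 4.80320425e-10          # elementary charge, esu
    debye: float = 1e-18               # 1 D in esu cm
    gm: float = 1e-50                  # 1 GM in cm^4 s / photon
    statvolt_per_cm_in_V_per_cm: float = 299.792458

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"constant {name!r} must be strictly positive")

    @property
    def hc(self) -> float:
        """h·c in erg·cm: energy of a 1 cm⁻¹ photon."""
        return self.h * self.c

    @property
    def kcal_per_mol_in_erg(self) -> float:
        """1 kcal/mol expressed per molecule, in erg."""
        return 4.184e10 / self.NA


CONSTANTS = PhysicalConstants()

# Unit registry: tag -> (dimension, factor to the dimension's CGS base unit).
# Base units: dipole esu·cm, volume cm³, field statvolt/cm, energy erg,
# two-photon cross section cm⁴·s.
UNIT_REGISTRY: dict[str, tuple[str, float]] = {
    "D": ("dipole", CONSTANTS.debye),
    "esu.cm": ("dipole", 1.0),
    "A3": ("volume", 1e-24),
    "cm3": ("volume", 1.0),
    "MV/cm": ("field", 1e6 / CONSTANTS.statvolt_per_cm_in_V_per_cm),
    "statvolt/cm": ("field", 1.0),
    # dipole change per polarizability volume is dimensionally a field;
    # 1e-18 esu cm / 1e-24 cm^3 = 1e6 statvolt/cm, written exactly
    "D/A3": ("field", 1e6),
    "cm^-1": ("energy", CONSTANTS.hc),
    "erg": ("energy", 1.0),
    "kcal/mol": ("energy", CONSTANTS.kcal_per_mol_in_erg),
    "GM": ("tpa_cross_section", CONSTANTS.gm),
    "cm4.s": ("tpa_cross_section", 1.0),
}

# Friendly aliases for the unicode spellings used in the literature.
_ALIASES = {
    "esu·cm": "esu.cm",
    "Å³": "A3",
    "Å^3": "A3",
    "cm³": "cm3",
    "cm⁻¹": "cm^-1",
    "cm-1": "cm^-1",
    "1/cm": "cm^-1",
    "kcal/mole": "kcal/mol",
    "cm⁴·s": "cm4.s",
    "cm4s": "cm4.s",
    "D/Å³": "D/A3",
}


def _resolve(tag: str) -> tuple[str, float]:
    key = _ALIASES.get(tag, tag)
    try:
        return UNIT_REGISTRY[key]
    except KeyError:
        raise ValueError(
            f"unknown unit tag {tag!r}; registry: {sorted(UNIT_REGISTRY)}"
        ) from None


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two registered, dimensionally compatible units.

    Raises
    ------
    ValueError
        If either tag is unknown or the two tags belong to different
        dimensions (both tags are named in the message).
    """
    dim_from, f_from = _resolve(from_unit)
    dim_to, f_to = _resolve(to_unit)
    if dim_from != dim_to:
        raise ValueError(
            f"incompatible units: {from_unit!r} is {dim_from}, "
            f"{to_unit!r} is {dim_to}"
        )
    return value * (f_from / f_to)


class ThermalEnergy(NamedTuple):
    erg: float
    kcal_per_mol: float


def thermal_energy(T: float, constants: PhysicalConstants = CONSTANTS) -> ThermalEnergy:
    """kB·T at absolute temperature ``T`` (K), in erg and kcal/mol."""
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T}")
    erg = constants.kB * T
    return ThermalEnergy(erg=erg, kcal_per_mol=erg / constants.kcal_per_mol_in_erg)
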