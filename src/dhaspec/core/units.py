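"""Physical constants and unit conversions.

Every factor is derived from the CODATA 2022 set as shipped by
:mod:`scipy.constants`; nothing is hard-coded twice.  The registry groups
units by dimension and only converts within a dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import constants as _cd

from dhaspec.core.errors import UnsupportedElementError, ValidationError

CODATA_YEAR = 2022

# Base SI values pulled from scipy.constants (CODATA 2022)
_BOHR_M = _cd.physical_constants["Bohr radius"][0]
_HARTREE_J = _cd.physical_constants["Hartree energy"][0]
_AMU_KG = _cd.physical_constants["atomic mass constant"][0]
_ME_KG = _cd.physical_constants["electron mass"][0]
_E_C = _cd.elementary_charge
_C_MS = _cd.speed_of_light
_H_JS = _cd.Planck
_NA = _cd.Avogadro
_EPS0 = _cd.epsilon_0
_CAL_J = 4.184  # thermochemical calorie, exact by definition

BOHR_TO_ANGSTROM = _BOHR_M * 1e10
HARTREE_TO_KCAL_PER_MOL = _HARTREE_J * _NA / (_CAL_J * 1000.0)
AMU_TO_ELECTRON_MASS = _AMU_KG / _ME_KG
DEBYE_CM = 1e-21 / _C_MS  # 1 Debye in C*m
AU_DIPOLE_TO_DEBYE = _E_C * _BOHR_M / DEBYE_CM

#: sqrt(eigenvalue of the mass-weighted FCM in Eh/(a0^2 amu)) -> wavenumber, cm^-1.
#: nu~ = (1/2 pi c) * sqrt(eps * Eh / (amu * a0^2)), with c in cm/s.
EIGENVALUE_TO_WAVENUMBER = math.sqrt(_HARTREE_J / (_AMU_KG * _BOHR_M**2)) / (
    2.0 * math.pi * _C_MS * 100.0
)

#: 1 cm^-1 of photon energy in kcal/mol.
WAVENUMBER_TO_KCAL_PER_MOL = _H_JS * _C_MS * 100.0 * _NA / (_CAL_J * 1000.0)

#: |dmu/dQ|^2 in e^2/amu -> integral absorption coefficient in km/mol:
#: A = N_A / (12 eps0 c^2) * |dmu/dQ|^2, evaluated in SI and divided by 1000.
DIPOLE_DERIV_SQ_TO_KM_PER_MOL = (
    _NA * _E_C**2 / (12.0 * _EPS0 * _C_MS**2 * _AMU_KG) / 1000.0
)


@dataclass(frozen=True)
class UnitRegistry:
    """Conversion factors grouped by physical dimension.

    Within each dimension, every unit maps to a scale relative to the
    dimension's base unit; conversion multiplies by from-scale and divides
    by to-scale, so round trips are exact to floating-point associativity.
    """

    codata_year: int = CODATA_YEAR
    dimensions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "length": {
                "bohr": 1.0,
                "a0": 1.0,
                "angstrom": 1.0 / BOHR_TO_ANGSTROM,
                "m": 1.0 / (_BOHR_M),
            },
            "energy": {
                "hartree": 1.0,
                "kcal/mol": 1.0 / HARTREE_TO_KCAL_PER_MOL,
                "cm^-1": WAVENUMBER_TO_KCAL_PER_MOL / HARTREE_TO_KCAL_PER_MOL,
                "ev": _cd.electron_volt / _HARTREE_J,
            },
            "mass": {
                "amu": 1.0,
                "m_e": 1.0 / AMU_TO_ELECTRON_MASS,
                "kg": 1.0 / _AMU_KG,
            },
            "dipole": {
                "au": 1.0,
                "e*a0": 1.0,
                "debye": 1.0 / AU_DIPOLE_TO_DEBYE,
            },
        }
    )

    def _lookup(self, unit: str) -> tuple[str, float]:
        key = unit.lower()
        for dim, table in self.dimensions.items():
            if key in table:
                return dim, table[key]
        raise ValidationError(f"unregistered unit: {unit!r}")

    def convert(self, value: float, from_unit: str, to_unit: str) -> float:
        """Convert ``value`` between two registered units of the same dimension."""
        dim_a, scale_a = self._lookup(from_unit)
        dim_b, scale_b = self._lookup(to_unit)
        if dim_a != dim_b:
            raise ValidationError(
                f"incompatible units: {from_unit!r} ({dim_a}) -> {to_unit!r} ({dim_b})"
            )
        if scale_a == scale_b:
            return value
        return value * (scale_a / scale_b)


#: Module-level registry; all boundary conversions in the package go through it.
units = UnitRegistry()


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between registered units (see :class:`UnitRegistry`)."""
    return units.convert(value, from_unit, to_unit)


# Standard atomic weights (amu), abridged from the IUPAC 2021 table.  One
# value per element; isotopes are not modeled.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "He": 4.002602,
    "Li": 6.94,
    "Be": 9.0121831,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403162,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Al": 26.9815384,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.95,
    "K": 39.0983,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.90447,
}


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in amu for an element symbol.

    Raises
    ------
    UnsupportedElementError
        If the symbol is not in the embedded table.
    """
    key = symbol.strip()
    key = key[:1].upper() + key[1:].lower()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        raise UnsupportedElementError(symbol) from None
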