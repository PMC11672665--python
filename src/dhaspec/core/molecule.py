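"""The Molecule type and standard XYZ reading/writing.

Coordinates are stored as a flat, atom-major 3N vector in Bohr; the XYZ
boundary is in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dhaspec.core.errors import ValidationError
from dhaspec.core.units import BOHR_TO_ANGSTROM, atomic_mass


@dataclass
class Molecule:
    """A molecular geometry with per-atom masses.

    Parameters
    ----------
    symbols
        Element symbols, one per atom.
    coords
        Flat 3N Cartesian coordinates in Bohr, atom-major.
    masses
        Per-atom masses in amu.  Filled from the standard atomic weight
        table when omitted.
    charge
        Total molecular charge (metadata only).
    """

    symbols: list[str]
    coords: np.ndarray
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]
    charge: int = 0

    def __post_init__(self) -> None:
        self.symbols = list(self.symbols)
        self.coords = np.asarray(self.coords, dtype=float).ravel().copy()
        n = len(self.symbols)
        if n < 1:
            raise ValidationError("a molecule needs at least one atom")
        if self.coords.size != 3 * n:
            raise ValidationError(
                f"expected {3 * n} coordinates for {n} atoms, got {self.coords.size}"
            )
        if self.masses is None:
            self.masses = np.array([atomic_mass(s) for s in self.symbols])
        else:
            self.masses = np.asarray(self.masses, dtype=float).copy()
        if self.masses.size != n:
            raise ValidationError("len(masses) must equal len(symbols)")
        if not np.all(self.masses > 0):
            raise ValidationError("all masses must be positive")

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    @property
    def coords3(self) -> np.ndarray:
        """Coordinates reshaped to (N, 3), Bohr. A view of ``coords``."""
        return self.coords.reshape(-1, 3)

    @property
    def coordinate_masses(self) -> np.ndarray:
        """Per-coordinate masses: each atom's mass repeated three times."""
        return np.repeat(self.masses, 3)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of this molecule with replaced (flat, Bohr) coordinates."""
        return Molecule(self.symbols, coords, masses=self.masses, charge=self.charge)

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords3 / self.masses.sum()


def read_xyz(path: str | Path) -> Molecule:
    """Read a standard XYZ file (Angstrom) into a :class:`Molecule` (Bohr).

    Tolerates blank trailing lines and integer-formatted coordinates.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty XYZ file (line 1)")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValidationError(f"{path}: line 1 must start with the atom count") from None
    if len(lines) < natoms + 2:
        raise ValidationError(
            f"{path}: expected {natoms + 2} lines, found {len(lines)}"
        )
    symbols: list[str] = []
    coords = np.empty((natoms, 3))
    for i in range(natoms):
        lineno = i + 3
        fields = lines[i + 2].split()
        if len(fields) < 4:
            raise ValidationError(f"{path}: line {lineno}: expected 'symbol x y z'")
        symbols.append(fields[0])
        try:
            coords[i] = [float(v) for v in fields[1:4]]
        except ValueError:
            raise ValidationError(
                f"{path}: line {lineno}: non-numeric coordinate"
            ) from None
    for extra in lines[natoms + 2 :]:
        if extra.strip():
            raise ValidationError(f"{path}: unexpected trailing content: {extra!r}")
    return Molecule(symbols, coords.ravel() / BOHR_TO_ANGSTROM)


def write_xyz(mol: Molecule, path: str | Path, comment: str = "") -> None:
    """Write ``mol`` as standard XYZ (Angstrom, fixed-width, 10 decimals)."""
    out = [str(mol.natoms), comment.replace("\n", " ")]
    for sym, xyz in zip(mol.symbols, mol.coords3 * BOHR_TO_ANGSTROM):
        out.append(f"{sym:<3s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")
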