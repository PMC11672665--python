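"""Shared toy-model fixtures: every molecule here has an exact analytic
Hessian and dipole gradient, so downstream numerics can be checked against
closed forms."""

from __future__ import annotations

import numpy as np
import pytest

from dhaspec.calculators import AngleTerm, BondTerm, HarmonicFF, PointChargeDipole
from dhaspec.core import Molecule


class ToySystem:
    """Bundle of molecule + force field + dipole model for one toy."""

    def __init__(self, mol, ff, dipole_model, **params):
        self.mol = mol
        self.ff = ff
        self.dipole_model = dipole_model
        self.params = params

    def fresh_ff(self) -> HarmonicFF:
        """A new force field instance with zeroed counters."""
        return HarmonicFF(self.ff.bonds, self.ff.angles)

    def fresh_dipole(self) -> PointChargeDipole:
        return PointChargeDipole(self.dipole_model.charges)


@pytest.fixture
def diatomic() -> ToySystem:
    """CO-like diatomic: one bond, charges +/-0.2 e."""
    k, r0 = 0.5, 2.132
    mol = Molecule(["C", "O"], np.array([0.0, 0.0, 0.0, r0, 0.0, 0.0]))
    ff = HarmonicFF([BondTerm(0, 1, k, r0)])
    return ToySystem(mol, ff, PointChargeDipole([0.2, -0.2]), k=k, r0=r0)


@pytest.fixture
def bent_triatomic() -> ToySystem:
    """Water-like bent triatomic: two bonds plus a harmonic angle bend."""
    r0, theta0 = 1.81, np.deg2rad(104.5)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],  # O (central)
            [r0 * np.sin(theta0 / 2), r0 * np.cos(theta0 / 2), 0.0],
            [-r0 * np.sin(theta0 / 2), r0 * np.cos(theta0 / 2), 0.0],
        ]
    )
    mol = Molecule(["O", "H", "H"], coords.ravel())
    ff = HarmonicFF(
        [BondTerm(1, 0, 0.2, r0), BondTerm(2, 0, 0.2, r0)],
        [AngleTerm(1, 0, 2, 0.06, theta0)],
    )
    return ToySystem(
        mol, ff, PointChargeDipole([-0.4, 0.2, 0.2]), r0=r0, theta0=theta0
    )


@pytest.fixture
def linear_triatomic() -> ToySystem:
    """CO2-like linear symmetric triatomic with charges (-q, +2q, -q)."""
    r0, q = 2.2, 0.15
    coords = np.array([[-r0, 0.0, 0.0], [0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    mol = Molecule(["O", "C", "O"], coords.ravel())
    ff = HarmonicFF(
        [BondTerm(0, 1, 0.5, r0), BondTerm(2, 1, 0.5, r0)],
        [AngleTerm(0, 1, 2, 0.2, None)],  # linear bend
    )
    return ToySystem(mol, ff, PointChargeDipole([-q, 2 * q, -q]), r0=r0, q=q)


@pytest.fixture
def five_atom() -> ToySystem:
    """A 5-atom chain used for evaluation-count checks."""
    n = 5
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * 2.0
    coords[1:, 1] = 0.1 * np.arange(1, n)  # slight zig to avoid linearity
    mol = Molecule(["C"] * n, coords.ravel())
    bonds = [BondTerm(i, i + 1, 0.8, float(np.linalg.norm(coords[i + 1] - coords[i])))
             for i in range(n - 1)]
    charges = np.array([0.1, -0.05, 0.0, 0.05, -0.1])
    return ToySystem(mol, HarmonicFF(bonds), PointChargeDipole(charges))


def rotation_matrix(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * kmat + (1 - np.cos(angle)) * (kmat @ kmat)


def transform_system(system: ToySystem, rot=None, shift=None) -> ToySystem:
    """Rigidly rotate/translate a toy system (geometry only; the force field
    and charges are internal-coordinate/geometry-independent)."""
    coords = system.mol.coords3.copy()
    if rot is not None:
        coords = coords @ np.asarray(rot).T
    if shift is not None:
        coords = coords + np.asarray(shift)
    return ToySystem(
        system.mol.with_coords(coords.ravel()),
        system.fresh_ff(),
        system.fresh_dipole(),
        **system.params,
    )
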