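"""Pluggable calculator contract and analytic toy models.

The toy models (harmonic force field + fixed point-charge dipole) provide
exact analytic gradients, Hessians and dipole derivatives, and are used as
oracles and fixture generators for every downstream stage.  External
engines plug in through the same :class:`Calculator` interface.
"""

from __future__ import annotations

from abc import ABC
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from dhaspec.core import Molecule, ValidationError

CAPABILITIES = ("energy", "gradient", "dipole")


class Calculator(ABC):
    """Base class for energy/gradient/dipole providers.

    Subclasses implement ``_energy``/``_gradient``/``_dipole`` for the
    capabilities they advertise; the public wrappers maintain an exact
    per-capability evaluation counter.
    """

    capabilities: frozenset = frozenset()

    def __init__(self) -> None:
        self.counters: dict[str, int] = {c: 0 for c in CAPABILITIES}

    def reset_counters(self) -> None:
        for c in self.counters:
            self.counters[c] = 0

    def _require(self, capability: str) -> None:
        if capability not in self.capabilities:
            raise ValidationError(
                f"{type(self).__name__} does not provide {capability!r}"
            )

    def energy(self, mol: Molecule) -> float:
        self._require("energy")
        self.counters["energy"] += 1
        return float(self._energy(mol))

    def gradient(self, mol: Molecule) -> np.ndarray:
        """Energy gradient, flat 3N vector in Eh/a0."""
        self._require("gradient")
        self.counters["gradient"] += 1
        return np.asarray(self._gradient(mol), dtype=float).ravel()

    def dipole(self, mol: Molecule) -> np.ndarray:
        """Dipole moment 3-vector in atomic units (e*a0)."""
        self._require("dipole")
        self.counters["dipole"] += 1
        return np.asarray(self._dipole(mol), dtype=float).ravel()

    def _energy(self, mol: Molecule) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def _gradient(self, mol: Molecule) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _dipole(self, mol: Molecule) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond: E = 1/2 k (r_ij - r0)^2; k in Eh/a0^2, r0 in a0."""

    i: int
    j: int
    force_constant: float
    r0: float


@dataclass(frozen=True)
class AngleTerm:
    """Angle bend at central atom ``j`` between atoms ``i`` and ``k``.

    ``theta0`` given: harmonic in the angle, E = 1/2 kf (theta - theta0)^2
    (valid away from theta = 0 or pi, where the angle derivative is
    singular).  ``theta0=None``: linear-bend form E = kf (1 + cos theta),
    which is smooth at theta = pi and quadratic around it with curvature kf.
    """

    i: int
    j: int
    k: int
    force_constant: float
    theta0: float | None = None


@lru_cache(maxsize=2)
def _angle_functions(kind: str):
    """Sympy-generated energy/gradient/Hessian for one angle term (9 coords)."""
    import sympy as sp

    xs = sp.symbols("ax ay az bx by bz cx cy cz", real=True)
    a, b, c = sp.Matrix(xs[0:3]), sp.Matrix(xs[3:6]), sp.Matrix(xs[6:9])
    u, v = a - b, c - b
    cos_t = u.dot(v) / (sp.sqrt(u.dot(u)) * sp.sqrt(v.dot(v)))
    kf = sp.Symbol("kf", positive=True)
    if kind == "harmonic":
        t0 = sp.Symbol("t0", real=True)
        energy = sp.Rational(1, 2) * kf * (sp.acos(cos_t) - t0) ** 2
        params = (kf, t0)
    elif kind == "linear":
        energy = kf * (1 + cos_t)
        params = (kf,)
    else:  # pragma: no cover - internal
        raise ValueError(kind)
    grad = sp.Matrix([sp.diff(energy, x) for x in xs])
    hess = sp.hessian(energy, xs)
    args = xs + params
    return (
        sp.lambdify(args, energy, "numpy"),
        sp.lambdify(args, grad, "numpy"),
        sp.lambdify(args, hess, "numpy"),
    )


class HarmonicFF(Calculator):
    """Harmonic force field over explicit bond and angle terms.

    Energy is exactly zero at the reference geometry the terms were built
    for.  Analytic gradient and analytic Hessian are implemented alongside
    the energy so the model can serve as an exact oracle for the
    seminumerical differentiation machinery.
    """

    capabilities = frozenset({"energy", "gradient"})

    def __init__(self, bonds: list[BondTerm] = (), angles: list[AngleTerm] = ()):
        super().__init__()
        self.bonds = list(bonds)
        self.angles = list(angles)

    def _check_indices(self, mol: Molecule) -> None:
        n = mol.natoms
        for t in self.bonds:
            if not (0 <= t.i < n and 0 <= t.j < n) or t.i == t.j:
                raise ValidationError(f"bond term indices out of range: {t}")
        for t in self.angles:
            idx = (t.i, t.j, t.k)
            if len(set(idx)) != 3 or not all(0 <= q < n for q in idx):
                raise ValidationError(f"angle term indices out of range: {t}")

    def _energy(self, mol: Molecule) -> float:
        self._check_indices(mol)
        r3 = mol.coords3
        e = 0.0
        for t in self.bonds:
            r = np.linalg.norm(r3[t.i] - r3[t.j])
            e += 0.5 * t.force_constant * (r - t.r0) ** 2
        for t in self.angles:
            fe, _, _ = _angle_functions("harmonic" if t.theta0 is not None else "linear")
            args = (*r3[t.i], *r3[t.j], *r3[t.k], t.force_constant)
            if t.theta0 is not None:
                args += (t.theta0,)
            e += float(fe(*args))
        return e

    def _gradient(self, mol: Molecule) -> np.ndarray:
        self._check_indices(mol)
        r3 = mol.coords3
        g = np.zeros((mol.natoms, 3))
        for t in self.bonds:
            u = r3[t.i] - r3[t.j]
            r = np.linalg.norm(u)
            pull = t.force_constant * (r - t.r0) * (u / r)
            g[t.i] += pull
            g[t.j] -= pull
        for t in self.angles:
            _, fg, _ = _angle_functions("harmonic" if t.theta0 is not None else "linear")
            args = (*r3[t.i], *r3[t.j], *r3[t.k], t.force_constant)
            if t.theta0 is not None:
                args += (t.theta0,)
            gt = np.asarray(fg(*args), dtype=float).ravel()
            for slot, atom in enumerate((t.i, t.j, t.k)):
                g[atom] += gt[3 * slot : 3 * slot + 3]
        return g.ravel()

    def analytic_hessian(self, mol: Molecule) -> np.ndarray:
        """Exact 3N x 3N second-derivative matrix in Eh/a0^2."""
        self._check_indices(mol)
        r3 = mol.coords3
        n3 = 3 * mol.natoms
        hess = np.zeros((n3, n3))
        eye = np.eye(3)
        for t in self.bonds:
            u = r3[t.i] - r3[t.j]
            r = np.linalg.norm(u)
            uh = u / r
            proj = np.outer(uh, uh)
            # d2E/du2 for E(u) = 1/2 k (|u| - r0)^2
            block = t.force_constant * proj + t.force_constant * (r - t.r0) * (
                eye - proj
            ) / r
            for aa, sa in ((t.i, 1.0), (t.j, -1.0)):
                for bb, sb in ((t.i, 1.0), (t.j, -1.0)):
                    hess[3 * aa : 3 * aa + 3, 3 * bb : 3 * bb + 3] += sa * sb * block
        for t in self.angles:
            _, _, fh = _angle_functions("harmonic" if t.theta0 is not None else "linear")
            args = (*r3[t.i], *r3[t.j], *r3[t.k], t.force_constant)
            if t.theta0 is not None:
                args += (t.theta0,)
            ht = np.asarray(fh(*args), dtype=float)
            atoms = (t.i, t.j, t.k)
            for sa, aa in enumerate(atoms):
                for sb, bb in enumerate(atoms):
                    hess[3 * aa : 3 * aa + 3, 3 * bb : 3 * bb + 3] += ht[
                        3 * sa : 3 * sa + 3, 3 * sb : 3 * sb + 3
                    ]
        return hess


class PointChargeDipole(Calculator):
    """Fixed per-atom partial charges; mu = sum_j q_j r_j (atomic units).

    Geometry-independent charges make the analytic dipole gradient exact:
    D[3j+gamma, alpha] = q_j * delta(gamma, alpha).  For neutral charge sets
    the dipole is origin- and translation-invariant.
    """

    capabilities = frozenset({"dipole"})

    def __init__(self, charges):
        super().__init__()
        self.charges = np.asarray(charges, dtype=float).ravel()

    def _dipole(self, mol: Molecule) -> np.ndarray:
        if self.charges.size != mol.natoms:
            raise ValidationError(
                f"{self.charges.size} charges for {mol.natoms} atoms"
            )
        return self.charges @ mol.coords3

    def analytic_dipole_gradient(self, mol: Molecule) -> np.ndarray:
        """Exact 3N x 3 dipole-derivative matrix (atomic units)."""
        if self.charges.size != mol.natoms:
            raise ValidationError(
                f"{self.charges.size} charges for {mol.natoms} atoms"
            )
        return np.kron(self.charges[:, None], np.eye(3)).reshape(3 * mol.natoms, 3)


class CompositeCalculator(Calculator):
    """Combine an energy/gradient provider with a dipole provider."""

    def __init__(self, potential: Calculator | None, dipole_model: Calculator | None):
        super().__init__()
        self.potential = potential
        self.dipole_model = dipole_model
        caps = set()
        if potential is not None:
            caps |= potential.capabilities & {"energy", "gradient"}
        if dipole_model is not None and "dipole" in dipole_model.capabilities:
            caps.add("dipole")
        self.capabilities = frozenset(caps)

    def _energy(self, mol: Molecule) -> float:
        return self.potential.energy(mol)

    def _gradient(self, mol: Molecule) -> np.ndarray:
        return self.potential.gradient(mol)

    def _dipole(self, mol: Molecule) -> np.ndarray:
        return self.dipole_model.dipole(mol)


def ff_energy_gradient(model: HarmonicFF, mol: Molecule) -> tuple[float, np.ndarray]:
    """Energy (Eh) and exact analytic gradient (flat 3N, Eh/a0)."""
    return model.energy(mol), model.gradient(mol)


def point_charge_dipole(charges, mol: Molecule) -> np.ndarray:
    """Dipole 3-vector mu_alpha = sum_j q_j x_{j,alpha} in atomic units."""
    return PointChargeDipole(charges).dipole(mol)


@dataclass(frozen=True)
class FixturePair:
    """One synthetic molecule's reference and test-method spectra sticks."""

    reference_frequencies: np.ndarray  # cm^-1
    reference_intensities: np.ndarray  # km/mol
    test_frequencies: np.ndarray
    test_intensities: np.ndarray


def make_fixture_set(
    n_molecules: int,
    seed: int,
    scaling_factor: float = 1.0,
    frequency_noise: float = 0.0,
    intensity_jitter: float = 0.0,
    modes_per_molecule: tuple[int, int] = (6, 30),
    frequency_range: tuple[float, float] = (200.0, 3800.0),
) -> list[FixturePair]:
    """Reproducible synthetic (frequencies, intensities) pairs.

    Emulates a reference method and a test method: the test frequencies are
    the reference frequencies divided by ``scaling_factor`` plus zero-mean
    Gaussian noise of width ``frequency_noise`` (cm^-1), so that the linear
    scaling factor recovered from ZPVE ratios downstream equals
    ``scaling_factor``.  Test intensities are perturbed multiplicatively by
    ``exp(intensity_jitter * normal())``.
    """
    if n_molecules <= 0:
        raise ValidationError("n_molecules must be positive")
    if scaling_factor <= 0:
        raise ValidationError("scaling_factor must be positive")
    rng = np.random.default_rng(seed)
    out: list[FixturePair] = []
    lo, hi = modes_per_molecule
    for _ in range(n_molecules):
        nmodes = int(rng.integers(lo, hi + 1))
        freqs = np.sort(rng.uniform(*frequency_range, size=nmodes))
        intens = rng.exponential(scale=50.0, size=nmodes)
        tfreq = freqs / scaling_factor
        if frequency_noise > 0:
            tfreq = tfreq + rng.normal(0.0, frequency_noise, size=nmodes)
        tint = intens * np.exp(intensity_jitter * rng.standard_normal(nmodes))
        out.append(FixturePair(freqs, intens, np.sort(np.abs(tfreq)), tint))
    return out
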