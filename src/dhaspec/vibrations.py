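"""Seminumerical Hessians, mass weighting, rigid-motion projection and
normal-mode analysis.

The Hessian is assembled column-wise by two-sided central differences of
analytic gradients (6N gradient evaluations), symmetrized, mass-weighted
into the force constant matrix (FCM), projected free of translation and
rotation, and diagonalized.  FCM eigenvalues convert to signed wavenumbers
in cm^-1, with imaginary modes reported as negative numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dhaspec.core import Molecule, NumericalError, ValidationError
from dhaspec.core.units import EIGENVALUE_TO_WAVENUMBER

DEFAULT_STEP = 1.0e-3  # displacement in a0
RIGID_MODE_THRESHOLD = 1.0  # |wavenumber| below this is a residual rigid mode, cm^-1
LINEARITY_RATIO = 1.0e-8  # smallest/largest principal moment of inertia


@dataclass
class HessianMatrix:
    """3N x 3N second-derivative matrix in Eh/a0^2 with provenance."""

    matrix: np.ndarray
    provenance: str = "analytic"
    step: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n3 = self.matrix.shape[0]
        if self.matrix.shape != (n3, n3) or n3 % 3:
            raise ValidationError(f"Hessian must be 3N x 3N, got {self.matrix.shape}")

    @property
    def natoms(self) -> int:
        return self.matrix.shape[0] // 3

    def symmetrized(self) -> "HessianMatrix":
        return HessianMatrix(
            0.5 * (self.matrix + self.matrix.T), self.provenance, self.step
        )


@dataclass
class NormalModeSet:
    """Eigen-decomposition of the (projected) mass-weighted FCM.

    ``modes`` columns are orthonormal mass-weighted eigenvectors;
    ``wavenumbers`` are signed cm^-1 values sorted ascending (imaginary
    modes negative); ``rigid_mode_count`` counts the near-zero modes that
    were projected out and are excluded from spectra and ZPVE.
    """

    eigenvalues: np.ndarray
    wavenumbers: np.ndarray
    modes: np.ndarray
    rigid_mode_count: int = 0
    rigid_threshold: float = RIGID_MODE_THRESHOLD

    @property
    def internal(self) -> np.ndarray:
        """Boolean mask selecting internal (non-rigid) modes."""
        return np.abs(self.wavenumbers) >= self.rigid_threshold

    @property
    def internal_wavenumbers(self) -> np.ndarray:
        return self.wavenumbers[self.internal]

    @property
    def has_imaginary(self) -> bool:
        return bool(np.any(self.wavenumbers[self.internal] < 0))


def seminumerical_hessian(
    calc, mol: Molecule, step: float = DEFAULT_STEP
) -> HessianMatrix:
    """Two-sided finite-difference Hessian from analytic gradients.

    Column i is (g(x + step e_i) - g(x - step e_i)) / (2 step); exactly 6N
    gradient evaluations are issued.  The result is symmetrized by
    averaging with its transpose.
    """
    if step <= 0:
        raise ValidationError("displacement step must be positive")
    n3 = 3 * mol.natoms
    hess = np.empty((n3, n3))
    x0 = mol.coords
    for i in range(n3):
        cols = []
        for sign in (+1.0, -1.0):
            x = x0.copy()
            x[i] += sign * step
            g = calc.gradient(mol.with_coords(x))
            if g.shape != (n3,):
                raise ValidationError(
                    f"gradient has shape {g.shape}, expected ({n3},)"
                )
            if not np.all(np.isfinite(g)):
                atom, comp = divmod(i, 3)
                raise NumericalError(
                    "non-finite gradient at displaced coordinate "
                    f"atom {atom}, {'xyz'[comp]}{'+' if sign > 0 else '-'}"
                )
            cols.append(g)
        hess[:, i] = (cols[0] - cols[1]) / (2.0 * step)
    return HessianMatrix(hess, provenance="seminumerical", step=step).symmetrized()


def mass_weight(hessian: HessianMatrix | np.ndarray, mol: Molecule) -> np.ndarray:
    """Mass-weighted FCM: F_ij = H_ij / sqrt(m_i m_j), per-coordinate masses."""
    h = hessian.matrix if isinstance(hessian, HessianMatrix) else np.asarray(hessian)
    inv_sqrt_m = 1.0 / np.sqrt(mol.coordinate_masses)
    return h * np.outer(inv_sqrt_m, inv_sqrt_m)


def is_linear(mol: Molecule) -> bool:
    """Linearity via moment-of-inertia eigenvalue ratio threshold."""
    if mol.natoms < 3:
        return True
    r = mol.coords3 - mol.center_of_mass()
    m = mol.masses
    inertia = np.einsum("i,ij->", m, r * r) * np.eye(3) - np.einsum(
        "i,ij,ik->jk", m, r, r
    )
    moments = np.linalg.eigvalsh(inertia)
    return moments[0] < LINEARITY_RATIO * moments[-1]


def rigid_motion_vectors(mol: Molecule) -> np.ndarray:
    """Orthonormal mass-weighted translation and rotation vectors (columns).

    Returns 3N x k with k = 5 for linear and 6 for nonlinear molecules
    (3 for a single atom).
    """
    n = mol.natoms
    sqrt_m = np.sqrt(mol.masses)
    r = mol.coords3 - mol.center_of_mass()
    vecs = []
    for alpha in range(3):
        t = np.zeros((n, 3))
        t[:, alpha] = sqrt_m
        vecs.append(t.ravel())
    for alpha in range(3):
        axis = np.zeros(3)
        axis[alpha] = 1.0
        rot = np.cross(axis, r) * sqrt_m[:, None]
        vecs.append(rot.ravel())
    basis = np.column_stack(vecs)
    # Orthonormalize and drop null directions (vanishing rotations for
    # linear molecules / single atoms).
    q, s, _ = np.linalg.svd(basis, full_matrices=False)
    keep = s > 1e-10 * max(s[0], 1.0)
    return q[:, keep]


def project_rigid_motions(fcm: np.ndarray, mol: Molecule) -> np.ndarray:
    """Project translations and rotations out of the mass-weighted FCM.

    The returned matrix maps every rigid direction to zero exactly
    (Eckart-style projector P F P with P = I - V V^T).
    """
    fcm = np.asarray(fcm, dtype=float)
    v = rigid_motion_vectors(mol)
    p = np.eye(fcm.shape[0]) - v @ v.T
    out = p @ fcm @ p
    return 0.5 * (out + out.T)


def eigenvalue_to_wavenumber(eigenvalue):
    """Signed wavenumber in cm^-1 from an FCM eigenvalue in Eh/(a0^2 amu)."""
    eps = np.asarray(eigenvalue, dtype=float)
    return np.sign(eps) * np.sqrt(np.abs(eps)) * EIGENVALUE_TO_WAVENUMBER


def normal_modes(fcm: np.ndarray, rigid_mode_count: int | None = None) -> NormalModeSet:
    """Diagonalize a symmetric FCM into a :class:`NormalModeSet`.

    Eigenvalues ascend; modes are orthonormal columns.  Issues a warning
    naming the imaginary modes when negative internal eigenvalues appear
    (the geometry must correspond to a minimum for a meaningful spectrum).
    """
    fcm = np.asarray(fcm, dtype=float)
    if not np.allclose(fcm, fcm.T, atol=1e-10):
        raise ValidationError("FCM must be symmetric")
    eigenvalues, modes = np.linalg.eigh(fcm)
    wavenumbers = eigenvalue_to_wavenumber(eigenvalues)
    if rigid_mode_count is None:
        rigid_mode_count = int(np.sum(np.abs(wavenumbers) < RIGID_MODE_THRESHOLD))
    nms = NormalModeSet(eigenvalues, wavenumbers, modes, rigid_mode_count)
    if nms.has_imaginary:
        bad = wavenumbers[(np.abs(wavenumbers) >= RIGID_MODE_THRESHOLD) & (wavenumbers < 0)]
        warnings.warn(
            f"{bad.size} imaginary mode(s) at {np.round(bad, 2)} cm^-1: "
            "the structure must correspond to a minimum",
            stacklevel=2,
        )
    return nms


def analyze(
    calc,
    mol: Molecule,
    step: float = DEFAULT_STEP,
    hessian: HessianMatrix | None = None,
    project: bool = True,
) -> NormalModeSet:
    """Full pipeline: Hessian -> mass weighting -> projection -> modes."""
    if hessian is None:
        hessian = seminumerical_hessian(calc, mol, step=step)
    fcm = mass_weight(hessian.symmetrized(), mol)
    if project:
        fcm = project_rigid_motions(fcm, mol)
    return normal_modes(fcm)


# ---------------------------------------------------------------------------
# Hessian text format: header `N <atom count>`, then 3N rows x 3N floats in
# Eh/a0^2, atom-major; `#` comment lines anywhere.  A `$hessian` block
# dialect is readable behind fmt="block".


def write_hessian(
    hessian: HessianMatrix, path: str | Path, metadata: dict | None = None
) -> None:
    lines = [f"# provenance {hessian.provenance}"]
    if hessian.step is not None:
        lines.append(f"# step {hessian.step!r}")
    for key, value in (metadata or {}).items():
        lines.append(f"# {key} {value}")
    lines.append(f"N {hessian.natoms}")
    for row in hessian.matrix:
        lines.append(" ".join(f"{v: .14e}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hessian(path: str | Path, fmt: str = "plain") -> HessianMatrix:
    text = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    if fmt == "block":
        values: list[float] = []
        in_block = False
        for line in text:
            s = line.strip()
            if s.startswith("$hessian"):
                in_block = True
                continue
            if s.startswith("$"):
                in_block = False
                continue
            if in_block and s and not s.startswith("#"):
                values.extend(float(v) for v in s.split())
        n3 = int(round(len(values) ** 0.5))
        if n3 * n3 != len(values) or n3 % 3:
            raise ValidationError(f"{path}: $hessian block is not 3N x 3N")
        return HessianMatrix(np.array(values).reshape(n3, n3))
    if fmt != "plain":
        raise ValidationError(f"unknown Hessian format {fmt!r}")
    natoms = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(text, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            parts = s[1:].split(None, 1)
            if len(parts) == 2:
                meta[parts[0]] = parts[1].strip()
            continue
        if natoms is None:
            fields = s.split()
            if fields[0] != "N" or len(fields) != 2:
                raise ValidationError(f"{path}: line {lineno}: expected 'N <atoms>'")
            natoms = int(fields[1])
            continue
        try:
            rows.append([float(v) for v in s.split()])
        except ValueError:
            raise ValidationError(f"{path}: line {lineno}: non-numeric entry") from None
    if natoms is None:
        raise ValidationError(f"{path}: missing 'N <atoms>' header")
    n3 = 3 * natoms
    if len(rows) != n3 or any(len(r) != n3 for r in rows):
        raise ValidationError(f"{path}: expected {n3} rows of {n3} floats")
    step = float(meta["step"]) if "step" in meta else None
    hm = HessianMatrix(np.array(rows), meta.get("provenance", "analytic"), step)
    hm.metadata = meta  # type: ignore[attr-defined]
    return hm
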