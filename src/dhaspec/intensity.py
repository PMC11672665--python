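"""Numerical dipole gradients and double-harmonic IR intensities.

The Cartesian dipole gradient (3N x 3, atomic units) is contracted with
the mass-back-transformed normal modes to give per-mode dipole derivatives
dmu/dQ_p, whose squared norms convert to integral absorption coefficients
in km/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from dhaspec.core import Molecule, NumericalError, ValidationError
from dhaspec.core.units import DIPOLE_DERIV_SQ_TO_KM_PER_MOL
from dhaspec.vibrations import DEFAULT_STEP, NormalModeSet


@dataclass
class DipoleGradient:
    """3N x 3 matrix D with D[3j+gamma, alpha] = dmu_alpha/dx_{j,gamma} (a.u.)."""

    matrix: np.ndarray
    provenance: str = "analytic"
    step: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 3 or self.matrix.shape[0] % 3:
            raise ValidationError(
                f"dipole gradient must be 3N x 3, got {self.matrix.shape}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise NumericalError("dipole gradient contains non-finite entries")

    @property
    def natoms(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class ModeDipoleDerivatives:
    """Per-mode dipole derivatives dmu/dQ_p in e/sqrt(amu) (rows = modes)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def squared_norms(self) -> np.ndarray:
        """|dmu/dQ_p|^2 per mode, e^2/amu."""
        return np.einsum("pa,pa->p", self.matrix, self.matrix)


def seminumerical_dipole_gradient(
    calc, mol: Molecule, step: float = DEFAULT_STEP
) -> DipoleGradient:
    """Central-difference dipole derivatives; exactly 6N dipole evaluations."""
    if step <= 0:
        raise ValidationError("displacement step must be positive")
    n3 = 3 * mol.natoms
    d = np.empty((n3, 3))
    x0 = mol.coords
    for i in range(n3):
        mus = []
        for sign in (+1.0, -1.0):
            x = x0.copy()
            x[i] += sign * step
            mu = calc.dipole(mol.with_coords(x))
            if mu.shape != (3,):
                raise ValidationError(f"dipole has shape {mu.shape}, expected (3,)")
            if not np.all(np.isfinite(mu)):
                atom, comp = divmod(i, 3)
                raise NumericalError(
                    "non-finite dipole at displaced coordinate "
                    f"atom {atom}, {'xyz'[comp]}{'+' if sign > 0 else '-'}"
                )
            mus.append(mu)
        d[i] = (mus[0] - mus[1]) / (2.0 * step)
    return DipoleGradient(d, provenance="seminumerical", step=step)


def project_dipole_gradient(
    dipole_gradient: DipoleGradient, modes: NormalModeSet, mol: Molecule
) -> ModeDipoleDerivatives:
    """Transform Cartesian dipole derivatives onto normal coordinates.

    (dmu_alpha/dQ_p) = sum_j (dmu_alpha/dx_j) Q^(m)_{j,p} m_j^{-1/2}: the
    Cartesian gradient contracted with the mass-back-transformed mode
    vector (the inverse-sqrt-mass factor undoes the mass weighting of the
    eigenvectors).
    """
    d = dipole_gradient.matrix
    if d.shape[0] != modes.modes.shape[0]:
        raise ValidationError(
            f"dipole gradient rows ({d.shape[0]}) do not match mode length "
            f"({modes.modes.shape[0]})"
        )
    if d.shape[0] != 3 * mol.natoms:
        raise ValidationError("dipole gradient does not match molecule size")
    cart_modes = modes.modes / np.sqrt(mol.coordinate_masses)[:, None]
    return ModeDipoleDerivatives(cart_modes.T @ d)


def intensities(mode_derivs: ModeDipoleDerivatives) -> np.ndarray:
    """Integral absorption coefficients A_p = N_A/(12 eps0 c^2) |dmu/dQ_p|^2.

    Input derivatives are in e/sqrt(amu); output in km/mol, always >= 0.
    """
    return DIPOLE_DERIV_SQ_TO_KM_PER_MOL * mode_derivs.squared_norms


# ---------------------------------------------------------------------------
# Dipole-derivative text format: header `N <atom count>`, then 3N rows of 3
# floats (dmu_x dmu_y dmu_z per Cartesian coordinate, atom-major), atomic
# units; `#` comments.


def write_dipole_gradient(
    dg: DipoleGradient, path: str | Path, metadata: dict | None = None
) -> None:
    lines = [f"# provenance {dg.provenance}"]
    if dg.step is not None:
        lines.append(f"# step {dg.step!r}")
    for key, value in (metadata or {}).items():
        lines.append(f"# {key} {value}")
    lines.append(f"N {dg.natoms}")
    for row in dg.matrix:
        lines.append(" ".join(f"{v: .14e}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dipole_gradient(path: str | Path) -> DipoleGradient:
    meta: dict[str, str] = {}
    natoms = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
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
    if len(rows) != 3 * natoms or any(len(r) != 3 for r in rows):
        raise ValidationError(f"{path}: expected {3 * natoms} rows of 3 floats")
    step = float(meta["step"]) if "step" in meta else None
    dg = DipoleGradient(np.array(rows), meta.get("provenance", "analytic"), step)
    dg.metadata = meta  # type: ignore[attr-defined]
    return dg
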