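"""Composite spectrum jobs: assemble frequencies from one source and dipole
derivatives from another into a single IR spectrum, with provenance.

A job reads its geometry once, obtains a Hessian and a dipole gradient
either from files or from named toy calculators, and enforces that both
refer to the same geometry (checksum comparison) before combining them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dhaspec import intensity as intensity_mod
from dhaspec import spectrum as spectrum_mod
from dhaspec import vibrations
from dhaspec.calculators import (
    AngleTerm,
    BondTerm,
    Calculator,
    HarmonicFF,
    PointChargeDipole,
)
from dhaspec.core import Molecule, ValidationError, read_xyz


def geometry_checksum(path: str | Path) -> str:
    """SHA-256 of the geometry file bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_calculator(config: dict) -> Calculator:
    """Instantiate a toy calculator from a config mapping.

    Supported types: ``harmonic_ff`` (``bonds`` rows ``[i, j, k, r0]``,
    ``angles`` rows ``[i, j, k, kf]`` for linear bends or
    ``[i, j, k, kf, theta0]`` for harmonic bends) and ``point_charges``
    (``charges`` list).
    """
    kind = config.get("type")
    if kind == "harmonic_ff":
        bonds = [BondTerm(int(r[0]), int(r[1]), float(r[2]), float(r[3]))
                 for r in config.get("bonds", [])]
        angles = []
        for r in config.get("angles", []):
            theta0 = float(r[4]) if len(r) > 4 else None
            angles.append(AngleTerm(int(r[0]), int(r[1]), int(r[2]), float(r[3]), theta0))
        return HarmonicFF(bonds, angles)
    if kind == "point_charges":
        return PointChargeDipole(config["charges"])
    raise ValidationError(f"unknown calculator type {config.get('type')!r}")


@dataclass
class CompositeJobSpec:
    """Everything needed to produce one composite IR spectrum.

    Hessian and dipole sources are either file paths (``hessian_file`` /
    ``dipole_gradient_file``) or calculator configs; both must refer to the
    same geometry file, which is enforced via checksums.
    """

    geometry: str
    hessian_file: str | None = None
    hessian_calculator: dict | None = None
    hessian_step: float = vibrations.DEFAULT_STEP
    dipole_gradient_file: str | None = None
    dipole_calculator: dict | None = None
    dipole_step: float = vibrations.DEFAULT_STEP
    scale_factor: float = 1.0
    fwhm: float = spectrum_mod.DEFAULT_FWHM
    grid: tuple[float, float, float] = spectrum_mod.DEFAULT_GRID
    output_dir: str = "."
    prefix: str = "spectrum"

    def validate(self) -> None:
        if not Path(self.geometry).is_file():
            raise ValidationError(f"geometry file not found: {self.geometry}")
        if (self.hessian_file is None) == (self.hessian_calculator is None):
            raise ValidationError("exactly one Hessian source (file or calculator) required")
        if (self.dipole_gradient_file is None) == (self.dipole_calculator is None):
            raise ValidationError("exactly one dipole source (file or calculator) required")
        if self.scale_factor <= 0:
            raise ValidationError("scale factor must be positive")


def _file_checksum_guard(spec: CompositeJobSpec, geom_sha: str, meta: dict, label: str) -> None:
    recorded = meta.get("geometry_sha256")
    if recorded is not None and recorded != geom_sha:
        raise ValidationError(
            f"{label} was computed for a different geometry "
            f"(checksum {recorded[:12]}... != {geom_sha[:12]}...)"
        )


def run_spectrum_job(spec: CompositeJobSpec) -> dict:
    """Run a composite spectrum job; writes stick/broadened spectra + JSON.

    Returns the result dict (also written as ``<prefix>.json``): frequency
    table, ZPVE, warnings and a provenance block sufficient to re-run the
    job bit-identically.
    """
    spec.validate()
    mol = read_xyz(spec.geometry)
    geom_sha = geometry_checksum(spec.geometry)

    if spec.hessian_file is not None:
        hess = vibrations.read_hessian(spec.hessian_file)
        _file_checksum_guard(spec, geom_sha, getattr(hess, "metadata", {}), "Hessian")
        hessian_source = {"file": str(spec.hessian_file)}
    else:
        calc = build_calculator(spec.hessian_calculator)
        hess = vibrations.seminumerical_hessian(calc, mol, step=spec.hessian_step)
        hessian_source = {
            "calculator": spec.hessian_calculator,
            "step": spec.hessian_step,
            "gradient_calls": calc.counters["gradient"],
        }

    if spec.dipole_gradient_file is not None:
        dgrad = intensity_mod.read_dipole_gradient(spec.dipole_gradient_file)
        _file_checksum_guard(spec, geom_sha, getattr(dgrad, "metadata", {}), "dipole gradient")
        dipole_source = {"file": str(spec.dipole_gradient_file)}
    else:
        calc = build_calculator(spec.dipole_calculator)
        dgrad = intensity_mod.seminumerical_dipole_gradient(calc, mol, step=spec.dipole_step)
        dipole_source = {
            "calculator": spec.dipole_calculator,
            "step": spec.dipole_step,
            "dipole_calls": calc.counters["dipole"],
        }

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        fcm = vibrations.mass_weight(hess.symmetrized(), mol)
        fcm = vibrations.project_rigid_motions(fcm, mol)
        modes = vibrations.normal_modes(fcm)
        captured = [str(w.message) for w in wlist]

    derivs = intensity_mod.project_dipole_gradient(dgrad, modes, mol)
    amps = intensity_mod.intensities(derivs)
    mask = modes.internal & (modes.wavenumbers > 0)
    stick = spectrum_mod.from_modes(
        modes.wavenumbers[mask], amps[mask], dipole_deriv_sq=derivs.squared_norms[mask]
    )
    if spec.scale_factor != 1.0:
        stick = spectrum_mod.scale_frequencies(stick, spec.scale_factor)
    broadened = spectrum_mod.broaden(stick, fwhm=spec.fwhm, grid=spec.grid)
    zpve_value = spectrum_mod.zpve(modes.wavenumbers[mask])

    outdir = Path(spec.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stick_path = outdir / f"{spec.prefix}_sticks.dat"
    broad_path = outdir / f"{spec.prefix}_broadened.dat"
    stick.metadata["geometry_sha256"] = geom_sha
    broadened.metadata["geometry_sha256"] = geom_sha
    spectrum_mod.write_spectrum(stick, stick_path, broadened=False)
    spectrum_mod.write_spectrum(broadened, broad_path, broadened=True)

    result = {
        "geometry": str(spec.geometry),
        "geometry_sha256": geom_sha,
        "natoms": mol.natoms,
        "hessian_source": hessian_source,
        "dipole_source": dipole_source,
        "scale_factor": spec.scale_factor,
        "fwhm": spec.fwhm,
        "grid": list(spec.grid),
        "rigid_mode_threshold": modes.rigid_threshold,
        "rigid_mode_count": modes.rigid_mode_count,
        "wavenumbers_cm-1": [round(v, 6) for v in modes.wavenumbers.tolist()],
        "intensities_km_mol": [round(v, 8) for v in amps[mask].tolist()],
        "zpve_kcal_mol": zpve_value,
        "imaginary_modes": bool(modes.has_imaginary),
        "warnings": captured,
        "outputs": {"sticks": str(stick_path), "broadened": str(broad_path)},
    }
    (outdir / f"{spec.prefix}.json").write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
    return result


def job_spec_from_config(config: dict, **overrides) -> CompositeJobSpec:
    """Build a :class:`CompositeJobSpec` from a YAML-style mapping.

    Flag overrides win over config values.
    """
    known = {f for f in CompositeJobSpec.__dataclass_fields__}
    merged = {k: v for k, v in config.items() if k in known}
    unknown = set(config) - known
    if unknown:
        raise ValidationError(f"unknown job config keys: {sorted(unknown)}")
    for key, value in overrides.items():
        if value is not None:
            merged[key] = value
    if "grid" in merged:
        merged["grid"] = tuple(float(v) for v in merged["grid"])
    if "geometry" not in merged:
        raise ValidationError("job config requires a 'geometry' entry")
    return CompositeJobSpec(**merged)
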