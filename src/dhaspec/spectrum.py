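"""Stick spectra, linear frequency scaling, Lorentzian broadening and
ZPVE-based scaling factors."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dhaspec.core import ValidationError
from dhaspec.core.units import WAVENUMBER_TO_KCAL_PER_MOL

DEFAULT_FWHM = 30.0  # cm^-1, Lorentzian
DEFAULT_GRID = (0.0, 4000.0, 1.0)  # start, stop, spacing in cm^-1


@dataclass
class IRSpectrum:
    """Stick spectrum plus optional broadened grid representation.

    ``sticks`` is an (n, 2) array of (wavenumber cm^-1, intensity km/mol)
    sorted ascending in wavenumber.  ``grid_x``/``grid_y`` hold the
    broadened representation when present.  ``metadata`` records the line
    shape, fwhm, grid and applied scale factor.
    """

    sticks: np.ndarray
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sticks = np.atleast_2d(np.asarray(self.sticks, dtype=float))
        if self.sticks.size == 0:
            self.sticks = np.empty((0, 2))
        if self.sticks.shape[1] != 2:
            raise ValidationError("sticks must be (n, 2): wavenumber, intensity")
        order = np.argsort(self.sticks[:, 0], kind="stable")
        self.sticks = self.sticks[order]
        self.metadata.setdefault("scale_factor", 1.0)

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.sticks[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.sticks[:, 1]

    @property
    def is_broadened(self) -> bool:
        return self.grid_x is not None


def from_modes(wavenumbers, intensities, dipole_deriv_sq=None) -> IRSpectrum:
    """Build a stick spectrum from per-mode wavenumbers and intensities."""
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if wavenumbers.shape != intensities.shape:
        raise ValidationError("wavenumbers and intensities differ in length")
    spec = IRSpectrum(np.column_stack([wavenumbers, intensities]))
    if dipole_deriv_sq is not None:
        spec.metadata["dipole_deriv_sq"] = np.asarray(dipole_deriv_sq, dtype=float)[
            np.argsort(wavenumbers, kind="stable")
        ]
    return spec


def scale_frequencies(spec: IRSpectrum, factor: float) -> IRSpectrum:
    """Multiply every stick wavenumber by ``factor``; intensities untouched."""
    if factor <= 0:
        raise ValidationError("scale factor must be positive")
    sticks = spec.sticks.copy()
    sticks[:, 0] *= factor
    meta = dict(spec.metadata)
    meta["scale_factor"] = meta.get("scale_factor", 1.0) * factor
    return IRSpectrum(sticks, metadata=meta)


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Area-normalized Lorentzian line shape."""
    gamma = 0.5 * fwhm
    return (gamma / np.pi) / ((x - center) ** 2 + gamma**2)


def broaden(
    spec: IRSpectrum,
    fwhm: float = DEFAULT_FWHM,
    grid: tuple[float, float, float] = DEFAULT_GRID,
) -> IRSpectrum:
    """Convolve sticks with area-normalized Lorentzians onto a uniform grid.

    Each stick contributes its intensity as integrated area, so the total
    integral matches the stick sum up to tail truncation by the grid.
    """
    if fwhm <= 0:
        raise ValidationError("fwhm must be positive")
    start, stop, spacing = grid
    if spacing <= 0 or stop <= start:
        raise ValidationError("grid must be (start, stop, spacing) with stop > start")
    x = np.arange(start, stop + 0.5 * spacing, spacing)
    if x.size == 0:
        raise ValidationError("empty broadening grid")
    y = np.zeros_like(x)
    for nu, amp in spec.sticks:
        if amp != 0.0:
            y += amp * lorentzian(x, nu, fwhm)
    meta = dict(spec.metadata)
    meta.update({"line_shape": "lorentzian", "fwhm": fwhm, "grid": tuple(grid)})
    return IRSpectrum(spec.sticks.copy(), grid_x=x, grid_y=y, metadata=meta)


def zpve(wavenumbers) -> float:
    """Harmonic ZPVE = half the sum over all frequencies, in kcal/mol.

    Only real internal-mode frequencies are valid input; a negative
    (imaginary) frequency raises, since imaginary modes must be excluded
    upstream.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    if nu.size == 0:
        return 0.0
    if np.any(nu < 0):
        raise ValidationError("negative wavenumber passed to zpve; exclude imaginary modes")
    return 0.5 * float(nu.sum()) * WAVENUMBER_TO_KCAL_PER_MOL


def derive_scaling_factor(zpve_ref, zpve_method) -> float:
    """Linear frequency scaling factor: mean over molecules of ZPVE_ref/ZPVE_method."""
    ref = np.asarray(zpve_ref, dtype=float)
    method = np.asarray(zpve_method, dtype=float)
    if ref.shape != method.shape or ref.ndim != 1:
        raise ValidationError("ZPVE lists must be 1-D and equal length")
    if ref.size == 0:
        raise ValidationError("empty ZPVE lists")
    if np.any(ref <= 0) or np.any(method <= 0):
        raise ValidationError("ZPVEs must be strictly positive")
    return float(np.mean(ref / method))


def apply_mode_scale_factors(spec: IRSpectrum, factors) -> IRSpectrum:
    """Hook for externally supplied per-mode (per-stick) scale factors.

    Accepts one factor per stick; this is where nonlinear scaling schemes
    parameterized elsewhere can be plugged in.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (spec.sticks.shape[0],):
        raise ValidationError("need exactly one scale factor per stick")
    if np.any(factors <= 0):
        raise ValidationError("per-mode scale factors must be positive")
    sticks = spec.sticks.copy()
    sticks[:, 0] *= factors
    meta = dict(spec.metadata)
    meta["scale_factor"] = "per-mode"
    return IRSpectrum(sticks, metadata=meta)


# ---------------------------------------------------------------------------
# Spectrum file: two-column text (`wavenumber_cm-1  intensity`) with
# `#`-prefixed metadata header; stick and broadened files share the layout,
# distinguished by the `kind` metadata key.


def write_spectrum(spec: IRSpectrum, path: str | Path, broadened: bool = False) -> None:
    if broadened and not spec.is_broadened:
        raise ValidationError("spectrum has no broadened grid to write")
    lines = [f"# kind {'broadened' if broadened else 'stick'}"]
    for key in ("line_shape", "fwhm", "grid", "scale_factor"):
        if key in spec.metadata:
            lines.append(f"# {key} {spec.metadata[key]}")
    for key, value in spec.metadata.items():
        if key in {"line_shape", "fwhm", "grid", "scale_factor", "dipole_deriv_sq"}:
            continue
        lines.append(f"# {key} {value}")
    if not broadened and "dipole_deriv_sq" in spec.metadata:
        raw = " ".join(f"{v:.14e}" for v in spec.metadata["dipole_deriv_sq"])
        lines.append(f"# dipole_deriv_sq {raw}")
    lines.append("# columns wavenumber_cm-1 intensity")
    if broadened:
        data = zip(spec.grid_x, spec.grid_y)
    else:
        data = spec.sticks
    for nu, amp in data:
        lines.append(f"{nu:14.6f} {amp: .10e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> IRSpectrum:
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            parts = s[1:].split(None, 1)
            if len(parts) == 2:
                meta[parts[0]] = parts[1].strip()
            continue
        fields = s.split()
        if len(fields) != 2:
            raise ValidationError(f"{path}: line {lineno}: expected two columns")
        try:
            xs.append(float(fields[0]))
            ys.append(float(fields[1]))
        except ValueError:
            raise ValidationError(f"{path}: line {lineno}: non-numeric entry") from None
    kind = meta.pop("kind", "stick")
    meta.pop("columns", None)
    if "fwhm" in meta:
        meta["fwhm"] = float(meta["fwhm"])
    if "scale_factor" in meta and meta["scale_factor"] != "per-mode":
        meta["scale_factor"] = float(meta["scale_factor"])
    if "grid" in meta:
        meta["grid"] = tuple(
            float(v) for v in meta["grid"].strip("()").replace(",", " ").split()
        )
    if "dipole_deriv_sq" in meta:
        meta["dipole_deriv_sq"] = np.array(
            [float(v) for v in meta["dipole_deriv_sq"].split()]
        )
    if kind == "broadened":
        return IRSpectrum(
            np.empty((0, 2)),
            grid_x=np.array(xs),
            grid_y=np.array(ys),
            metadata=meta,
        )
    return IRSpectrum(np.column_stack([xs, ys]) if xs else np.empty((0, 2)), metadata=meta)
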