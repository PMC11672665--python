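"""Spectral similarity metrics and frequency x dipole method combination
matrices.

The primary metric is the Cauchy-Schwarz matchscore
r_msc = (sum a_i b_i)^2 / (sum a_i^2 sum b_i^2), a scale-invariant
similarity in [0, 1] that is 1 iff the two broadened spectra are
proportional.  Alternatives: a normalized Euclidean similarity, Pearson and
Spearman correlations over grid intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dhaspec.core import Molecule, UndefinedScoreError, ValidationError
from dhaspec.intensity import DipoleGradient, intensities, project_dipole_gradient
from dhaspec.spectrum import DEFAULT_FWHM, IRSpectrum, broaden, from_modes, scale_frequencies
from dhaspec.vibrations import NormalModeSet

METRICS = ("matchscore", "euclidean", "pearson", "spearman")


@dataclass(frozen=True)
class ScoreReport:
    """One pairwise similarity score with the grid it was evaluated on."""

    metric: str
    score: float
    grid: tuple | None = None


def _grid_values(spec: IRSpectrum) -> np.ndarray:
    if not spec.is_broadened:
        raise ValidationError("similarity metrics require broadened spectra")
    return spec.grid_y


def _check_grids(a: IRSpectrum, b: IRSpectrum) -> None:
    ga, gb = a.grid_x, b.grid_x
    if ga.shape != gb.shape or not np.allclose(ga, gb, rtol=0, atol=1e-9):
        raise ValidationError("spectra must share an identical grid")


def resample(spec: IRSpectrum, grid_x: np.ndarray) -> IRSpectrum:
    """Linear interpolation of a broadened spectrum onto a common grid."""
    y = np.interp(grid_x, spec.grid_x, _grid_values(spec), left=0.0, right=0.0)
    meta = dict(spec.metadata)
    meta["resampled"] = True
    return IRSpectrum(spec.sticks.copy(), grid_x=np.asarray(grid_x, float), grid_y=y, metadata=meta)


def matchscore(a: IRSpectrum, b: IRSpectrum) -> float:
    """Cauchy-Schwarz matchscore in [0, 1] on a shared grid."""
    ya, yb = _grid_values(a), _grid_values(b)
    _check_grids(a, b)
    na, nb = float(ya @ ya), float(yb @ yb)
    if na == 0.0 or nb == 0.0:
        raise UndefinedScoreError("matchscore is undefined for an all-zero spectrum")
    return float((ya @ yb) ** 2 / (na * nb))


def alt_scores(a: IRSpectrum, b: IRSpectrum, metric: str) -> float:
    """Alternative similarity: 'euclidean', 'pearson' or 'spearman'.

    Euclidean: r_euc = 1 - ||a_hat - b_hat|| / sqrt(2) with a_hat the
    L2-normalized grid vector; equals 1 for identical unit-normalized
    spectra and 0 for orthogonal (disjoint-support) non-negative spectra.
    Pearson/Spearman are standard correlations over grid intensities, with
    average-rank tie handling for Spearman.
    """
    ya, yb = _grid_values(a), _grid_values(b)
    _check_grids(a, b)
    if metric == "euclidean":
        na, nb = np.linalg.norm(ya), np.linalg.norm(yb)
        if na == 0.0 or nb == 0.0:
            raise UndefinedScoreError("euclidean score undefined for all-zero spectrum")
        return float(1.0 - np.linalg.norm(ya / na - yb / nb) / np.sqrt(2.0))
    if metric in ("pearson", "spearman"):
        if np.ptp(ya) == 0.0 or np.ptp(yb) == 0.0:
            raise UndefinedScoreError(f"{metric} undefined for a constant spectrum")
        if metric == "pearson":
            return float(stats.pearsonr(ya, yb).statistic)
        return float(stats.spearmanr(ya, yb).statistic)
    raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS[1:]}")


def score_all(a: IRSpectrum, b: IRSpectrum) -> dict[str, float]:
    """All four scores on a shared grid; undefined scores come back as nan."""
    out: dict[str, float] = {}
    for metric in METRICS:
        try:
            if metric == "matchscore":
                out[metric] = matchscore(a, b)
            else:
                out[metric] = alt_scores(a, b, metric)
        except UndefinedScoreError:
            out[metric] = float("nan")
    return out


def _spectrum_for(
    mol: Molecule,
    modes: NormalModeSet,
    dipgrad: DipoleGradient,
    fwhm: float,
    grid: tuple[float, float, float],
    scale_factor: float,
) -> IRSpectrum:
    derivs = project_dipole_gradient(dipgrad, modes, mol)
    amps = intensities(derivs)
    mask = modes.internal & (modes.wavenumbers > 0)
    spec = from_modes(modes.wavenumbers[mask], amps[mask])
    if scale_factor != 1.0:
        spec = scale_frequencies(spec, scale_factor)
    return broaden(spec, fwhm=fwhm, grid=grid)


def combination_matrix(
    molecules: dict[str, Molecule],
    freq_sources: dict[str, dict[str, NormalModeSet]],
    dipole_sources: dict[str, dict[str, DipoleGradient]],
    reference: dict[str, IRSpectrum],
    fwhm: float = DEFAULT_FWHM,
    scale_factors: dict[str, float] | None = None,
) -> dict:
    """Mean matchscore for every frequency-method x dipole-method pairing.

    Every source must cover the same molecule list, and each pairing uses
    frequencies and dipole derivatives for the same geometry.  Reference
    spectra must be broadened; their grids define the comparison grids.

    Returns a dict with ``matrix`` (DataFrame, rows = frequency sources,
    columns = dipole sources), ``per_molecule`` (DataFrame of individual
    scores) and ``best`` (the arg-max cell).
    """
    names = set(molecules)
    problems = []
    for label, source in (
        [("reference", reference)]
        + [(f"freq:{k}", v) for k, v in freq_sources.items()]
        + [(f"dipole:{k}", v) for k, v in dipole_sources.items()]
    ):
        missing = names - set(source)
        if missing:
            problems.append(f"{label} missing {sorted(missing)}")
    if problems:
        raise ValidationError("molecule-list mismatch: " + "; ".join(problems))
    scale_factors = scale_factors or {}
    rows = []
    for fname, fsource in freq_sources.items():
        factor = scale_factors.get(fname, 1.0)
        for dname, dsource in dipole_sources.items():
            for mid in sorted(names):
                ref = reference[mid]
                if not ref.is_broadened:
                    raise ValidationError(f"reference spectrum {mid!r} is not broadened")
                gx = ref.grid_x
                grid = (gx[0], gx[-1], gx[1] - gx[0])
                spec = _spectrum_for(
                    molecules[mid], fsource[mid], dsource[mid], fwhm, grid, factor
                )
                rows.append(
                    {
                        "freq_source": fname,
                        "dipole_source": dname,
                        "molecule": mid,
                        "matchscore": matchscore(spec, ref),
                    }
                )
    per_molecule = pd.DataFrame(rows)
    matrix = per_molecule.pivot_table(
        index="freq_source", columns="dipole_source", values="matchscore", aggfunc="mean"
    )
    flat = matrix.stack()
    best = flat.idxmax()
    return {
        "matrix": matrix,
        "per_molecule": per_molecule,
        "best": {"freq_source": best[0], "dipole_source": best[1], "score": float(flat.max())},
    }
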