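"""Benchmark metrics: regularized dipole errors, dipole alignment, Kabsch
RMSD and the shared error-statistics engine."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dhaspec.core import NumericalError, ValidationError


@dataclass(frozen=True)
class DipoleComparison:
    """Pairwise dipole benchmark: magnitudes, regularized error, alignment."""

    mu_test: np.ndarray  # Debye
    mu_ref: np.ndarray
    delta: float  # signed regularized magnitude error
    alignment: float  # cosine of the angle between the vectors


@dataclass(frozen=True)
class StatSummary:
    """MD/MAE/RMSE/SD plus mean and median of a signed error list."""

    md: float
    mae: float
    rmse: float
    sd: float
    mean: float
    median: float
    n: int


def regularized_dipole_error(mu_test, mu_ref) -> float:
    """Signed regularized dipole-magnitude error (dimensionless).

    delta = (|mu_test| - |mu_ref|) / max(|mu_ref|, 1 D), with both vectors
    in Debye.  Magnitudes are differenced (not vectors), so systematic
    under-estimation yields a negative mean deviation.  The 1 D floor damps
    the influence of tiny reference dipoles.
    """
    t = np.linalg.norm(np.asarray(mu_test, dtype=float))
    r = np.linalg.norm(np.asarray(mu_ref, dtype=float))
    return float((t - r) / max(r, 1.0))


def dipole_alignment(mu_test, mu_ref) -> float:
    """Dot product of the normalized dipole vectors, in [-1, 1]."""
    t = np.asarray(mu_test, dtype=float)
    r = np.asarray(mu_ref, dtype=float)
    nt, nr = np.linalg.norm(t), np.linalg.norm(r)
    if nt == 0.0 or nr == 0.0:
        raise NumericalError("dipole alignment undefined for a zero-norm vector")
    return float(np.clip(t @ r / (nt * nr), -1.0, 1.0))


def compare_dipoles(mu_test, mu_ref) -> DipoleComparison:
    t = np.asarray(mu_test, dtype=float)
    r = np.asarray(mu_ref, dtype=float)
    return DipoleComparison(
        t, r, regularized_dipole_error(t, r), dipole_alignment(t, r)
    )


def kabsch_rmsd(coords_a, coords_b, exclude_hydrogens: bool = False, symbols=None) -> float:
    """Minimum RMSD over rigid superpositions of two matched structures.

    Inputs are (N, 3) arrays in the same ordering (no graph matching or
    permutation correction).  Centroids are aligned, then the optimal
    rotation is found by SVD (Kabsch, proper rotation enforced).  Pass
    ``symbols`` with ``exclude_hydrogens=True`` to drop H atoms.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValidationError(f"atom-count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if exclude_hydrogens:
        if symbols is None:
            raise ValidationError("exclude_hydrogens requires element symbols")
        keep = np.array([s.strip().upper() != "H" for s in symbols])
        if keep.size != a.shape[0]:
            raise ValidationError("symbols length does not match coordinates")
        a, b = a[keep], b[keep]
        if a.shape[0] == 0:
            raise ValidationError("no atoms left after excluding hydrogens")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    cov = a.T @ b
    u, _, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    diff = a @ rot - b
    return float(np.sqrt((diff * diff).sum() / a.shape[0]))


def error_stats(values) -> StatSummary:
    """MD, MAE, RMSE and sample (n-1) SD of a signed error list."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("error_stats requires a nonempty list")
    return StatSummary(
        md=float(v.mean()),
        mae=float(np.abs(v).mean()),
        rmse=float(np.sqrt((v * v).mean())),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        mean=float(v.mean()),
        median=float(np.median(v)),
        n=int(v.size),
    )


def threshold_fractions(values, thresholds: dict[str, float]) -> dict[str, float]:
    """Percentage of entries satisfying each inclusive threshold.

    ``thresholds`` maps comparison strings like ``"<=0.2"`` or ``">=0.5"``
    to the threshold value; comparisons are inclusive on both forms.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("threshold_fractions requires a nonempty list")
    out: dict[str, float] = {}
    for key, thr in thresholds.items():
        op = key.strip()[:2]
        if op == "<=":
            count = np.count_nonzero(v <= thr)
        elif op == ">=":
            count = np.count_nonzero(v >= thr)
        else:
            raise ValidationError(f"threshold key must start with '<=' or '>=': {key!r}")
        out[key] = 100.0 * count / v.size
    return out


def fit_lognormal(values) -> tuple[float, float]:
    """Maximum-likelihood log-normal fit: (location, scale) of log-values.

    Location is the mean of ln(x); scale the MLE (population) standard
    deviation of ln(x).  All values must be strictly positive.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("fit_lognormal requires a nonempty list")
    if np.any(v <= 0):
        raise ValidationError("log-normal fit requires strictly positive values")
    logs = np.log(v)
    return float(logs.mean()), float(logs.std(ddof=0))
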