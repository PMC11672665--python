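# dhaspec

Composite double-harmonic-approximation (DHA) infrared spectra for gas-phase
molecules, with the frequency source and the dipole source freely mixed:

- **Seminumerical Hessians** from any gradient-capable calculator
  (two-sided central differences, 6N gradient evaluations, default
  displacement 1.0e-3 a0), mass weighting, Eckart-style rigid-motion
  projection, and normal-mode analysis with signed wavenumbers.
- **Numerical dipole-moment derivatives** from any dipole-capable calculator
  (6N dipole evaluations), projection onto normal coordinates, and DHA
  integral absorption coefficients in km/mol.
- **Spectra**: stick assembly, linear frequency scaling, area-normalized
  Lorentzian broadening (default fwhm 30 cm^-1, 0-4000 cm^-1 grid),
  harmonic ZPVE, and ZPVE-ratio linear scaling factors.
- **Similarity metrics**: the Cauchy-Schwarz matchscore `r_msc` plus
  Euclidean/Pearson/Spearman alternatives, and frequency-method x
  dipole-method combination matrices.
- **Benchmark metrics**: regularized dipole errors, dipole alignment
  cosines, Kabsch RMSD, MD/MAE/RMSE/SD statistics, threshold fractions and
  log-normal fits.

No external quantum-chemistry engine is required: the `calculators` module
ships exact analytic toy models (harmonic force field, fixed point-charge
dipoles) that act as oracles and fixture generators. External engines plug
in through the same small `Calculator` contract.

## CLI

All functionality is reachable through the `dhaspec` command
(exit codes: 0 success, 1 validation error, 2 numerical failure):

```bash
dhaspec freq geom.xyz --calc-config calcs.yaml --calc toyff --hessian-out geom.hess
dhaspec dipgrad geom.xyz --calc-config calcs.yaml --calc charges --out geom.dgrad
dhaspec spectrum --config job.yaml            # composite job: sticks + broadened + JSON
dhaspec compare a.dat b.dat                   # r_msc, r_euc, r_pcc, r_scc
dhaspec matrix manifest.yaml --json out.json  # combination matrix
dhaspec scale sticks.dat 0.9606 --out scaled.dat
dhaspec zpve sticks.dat
dhaspec rmsd a.xyz b.xyz          # or two directories of matched XYZ files
dhaspec dipstats dipoles.tsv      # id + test xyz + reference xyz (Debye)
```

A calculator config (`calcs.yaml`) defines named toy models:

```yaml
calculators:
  toyff:
    type: harmonic_ff
    bonds: [[0, 1, 0.5, 2.132]]      # i, j, k (Eh/a0^2), r0 (a0)
    angles: [[0, 1, 2, 0.06, 1.82]]  # i, j(center), k, kf[, theta0]; omit theta0 for linear bends
  charges:
    type: point_charges
    charges: [0.2, -0.2]
```

A composite job (`job.yaml`) pairs a Hessian source with a dipole source for
one geometry; the two sources must refer to the same geometry file, which is
enforced by checksum:

```yaml
geometry: geom.xyz
hessian_calculator: {type: harmonic_ff, bonds: [[0, 1, 0.5, 2.132]]}
dipole_calculator: {type: point_charges, charges: [0.2, -0.2]}
scale_factor: 1.0
fwhm: 30.0
output_dir: out
```

File sources work too (`hessian_file: geom.hess`,
`dipole_gradient_file: geom.dgrad`) using the plain-text formats written by
`freq`/`dipgrad` (`N <atoms>` header, whitespace-separated floats, `#`
metadata comments).

## Conventions

Internal units are atomic (Hartree, Bohr) with masses in amu; XYZ files are
Angstrom at the boundary. All 3N-indexed arrays are flat and atom-major.
Imaginary modes are reported as negative wavenumbers and trigger a warning;
modes with |wavenumber| < 1 cm^-1 after rigid-motion projection are treated
as residual translations/rotations and excluded from spectra and ZPVE.
Physical constants derive from CODATA 2022 via `scipy.constants`.
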