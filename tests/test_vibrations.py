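"""Tests for Hessian construction, projection and normal-mode analysis."""

import numpy as np
import pytest

from dhaspec.calculators import Calculator
from dhaspec.core import Molecule, NumericalError, ValidationError
from dhaspec.core.units import EIGENVALUE_TO_WAVENUMBER
from dhaspec.spectrum import zpve
from dhaspec.vibrations import (
    HessianMatrix,
    analyze,
    eigenvalue_to_wavenumber,
    is_linear,
    mass_weight,
    normal_modes,
    project_rigid_motions,
    read_hessian,
    rigid_motion_vectors,
    seminumerical_hessian,
    write_hessian,
)

from conftest import rotation_matrix, transform_system


class ZeroCalculator(Calculator):
    capabilities = frozenset({"energy", "gradient"})

    def _energy(self, mol):
        return 0.0

    def _gradient(self, mol):
        return np.zeros(3 * mol.natoms)


class NaNCalculator(Calculator):
    capabilities = frozenset({"gradient"})

    def _gradient(self, mol):
        g = np.zeros(3 * mol.natoms)
        g[0] = np.nan
        return g


def reduced_mass(mol):
    return 1.0 / (1.0 / mol.masses[0] + 1.0 / mol.masses[1])


class TestSeminumericalHessian:
    def test_diatomic_bond_block(self, diatomic):
        k = diatomic.params["k"]
        h = seminumerical_hessian(diatomic.ff, diatomic.mol).matrix
        # bond along x: d2E/dx1dx1 = k, d2E/dx1dx2 = -k
        assert h[0, 0] == pytest.approx(k, abs=1e-7)
        assert h[3, 3] == pytest.approx(k, abs=1e-7)
        assert h[0, 3] == pytest.approx(-k, abs=1e-7)

    def test_zero_calculator_gives_zero_matrix(self, diatomic):
        h = seminumerical_hessian(ZeroCalculator(), diatomic.mol)
        np.testing.assert_array_equal(h.matrix, 0.0)

    def test_gradient_call_count_five_atoms(self, five_atom):
        ff = five_atom.fresh_ff()
        seminumerical_hessian(ff, five_atom.mol)
        assert ff.counters["gradient"] == 6 * 5

    @pytest.mark.parametrize("system", ["diatomic", "bent_triatomic", "linear_triatomic"])
    def test_matches_analytic_hessian(self, system, request):
        toy = request.getfixturevalue(system)
        h_num = seminumerical_hessian(toy.ff, toy.mol, step=1e-3).matrix
        h_ana = toy.ff.analytic_hessian(toy.mol)
        assert np.abs(h_num - h_ana).max() < 1e-7

    def test_error_is_second_order_in_step(self, bent_triatomic):
        rng = np.random.default_rng(5)
        mol = bent_triatomic.mol.with_coords(
            bent_triatomic.mol.coords + rng.normal(0, 0.05, 9)
        )
        h_ana = bent_triatomic.ff.analytic_hessian(mol)
        errs = [
            np.abs(seminumerical_hessian(bent_triatomic.ff, mol, step=s).matrix - h_ana).max()
            for s in (2e-2, 1e-2)
        ]
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)

    def test_symmetrized_exactly(self, bent_triatomic):
        h = seminumerical_hessian(bent_triatomic.ff, bent_triatomic.mol).matrix
        assert np.abs(h - h.T).max() == 0.0

    def test_provenance_recorded(self, diatomic):
        h = seminumerical_hessian(diatomic.ff, diatomic.mol, step=2e-3)
        assert h.provenance == "seminumerical"
        assert h.step == 2e-3

    def test_nonpositive_step_rejected(self, diatomic):
        with pytest.raises(ValidationError):
            seminumerical_hessian(diatomic.ff, diatomic.mol, step=0.0)

    def test_non_finite_gradient_names_coordinate(self, diatomic):
        with pytest.raises(NumericalError, match="atom 0, x"):
            seminumerical_hessian(NaNCalculator(), diatomic.mol)


class TestMassWeight:
    def test_equal_masses(self):
        mol = Molecule(["C", "C"], np.array([0.0, 0, 0, 2, 0, 0]))
        h = np.arange(36.0).reshape(6, 6)
        h = h + h.T
        f = mass_weight(h, mol)
        np.testing.assert_allclose(f, h / mol.masses[0], rtol=1e-14)

    def test_zero_hessian(self, diatomic):
        f = mass_weight(np.zeros((6, 6)), diatomic.mol)
        np.testing.assert_array_equal(f, 0.0)

    def test_heteronuclear_eigenvalue_is_k_over_reduced_mass(self, diatomic):
        # closed form for the 1-D oscillator: nonzero FCM eigenvalue = k/mu_red
        k = diatomic.params["k"]
        h = diatomic.ff.analytic_hessian(diatomic.mol)
        f = mass_weight(h, diatomic.mol)
        eigs = np.linalg.eigvalsh(f)
        assert eigs[-1] == pytest.approx(k / reduced_mass(diatomic.mol), rel=1e-12)


class TestProjection:
    @pytest.mark.parametrize("system", ["diatomic", "bent_triatomic", "linear_triatomic"])
    def test_translation_is_null_direction(self, system, request):
        toy = request.getfixturevalue(system)
        f = mass_weight(toy.ff.analytic_hessian(toy.mol), toy.mol)
        fp = project_rigid_motions(f, toy.mol)
        n = toy.mol.natoms
        for alpha in range(3):
            t = np.zeros((n, 3))
            t[:, alpha] = np.sqrt(toy.mol.masses)
            np.testing.assert_allclose(fp @ t.ravel(), 0.0, atol=1e-12)

    def test_nonlinear_has_six_rigid_modes(self, bent_triatomic):
        modes = analyze(bent_triatomic.ff, bent_triatomic.mol)
        assert np.sum(np.abs(modes.wavenumbers) < 1.0) == 6
        assert modes.rigid_mode_count == 6

    def test_linear_has_five_rigid_modes(self, linear_triatomic):
        modes = analyze(linear_triatomic.ff, linear_triatomic.mol)
        assert np.sum(np.abs(modes.wavenumbers) < 1.0) == 5
        assert modes.rigid_mode_count == 5

    def test_linearity_detection(self, bent_triatomic, linear_triatomic):
        assert not is_linear(bent_triatomic.mol)
        assert is_linear(linear_triatomic.mol)

    def test_rigid_vectors_orthonormal(self, bent_triatomic):
        v = rigid_motion_vectors(bent_triatomic.mol)
        assert v.shape == (9, 6)
        np.testing.assert_allclose(v.T @ v, np.eye(6), atol=1e-12)


class TestNormalModes:
    def test_diagonal_fcm(self):
        f = np.diag([1.0, 2.0, 3.0])
        nm = normal_modes(f)
        np.testing.assert_allclose(nm.eigenvalues, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(np.abs(nm.modes), np.eye(3), atol=1e-14)

    def test_reconstruction(self, bent_triatomic):
        f = project_rigid_motions(
            mass_weight(bent_triatomic.ff.analytic_hessian(bent_triatomic.mol),
                        bent_triatomic.mol),
            bent_triatomic.mol,
        )
        nm = normal_modes(f)
        recon = nm.modes @ np.diag(nm.eigenvalues) @ nm.modes.T
        np.testing.assert_allclose(recon, f, atol=1e-11)

    def test_modes_orthonormal(self, linear_triatomic):
        nm = analyze(linear_triatomic.ff, linear_triatomic.mol)
        np.testing.assert_allclose(nm.modes.T @ nm.modes, np.eye(9), atol=1e-10)

    def test_hand_solved_three_by_three(self):
        # tridiagonal [[2,-1,0],[-1,2,-1],[0,-1,2]]: eigenvalues 2-sqrt(2), 2, 2+sqrt(2)
        f = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]])
        nm = normal_modes(f)
        expected = [2 - np.sqrt(2), 2.0, 2 + np.sqrt(2)]
        np.testing.assert_allclose(nm.eigenvalues, expected, rtol=1e-12)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValidationError):
            normal_modes(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_imaginary_mode_warns(self):
        f = np.diag([-0.01, 0.02, 0.03])
        with pytest.warns(UserWarning, match="minimum"):
            nm = normal_modes(f, rigid_mode_count=0)
        assert nm.wavenumbers[0] < 0
        assert nm.has_imaginary


class TestWavenumberConversion:
    def test_zero(self):
        assert eigenvalue_to_wavenumber(0.0) == 0.0

    def test_negative_sign_convention(self):
        assert eigenvalue_to_wavenumber(-0.04) == pytest.approx(
            -np.sqrt(0.04) * EIGENVALUE_TO_WAVENUMBER
        )

    def test_diatomic_closed_form(self, diatomic):
        # independent oracle: nu~ = (1/2 pi c) sqrt(k/mu_red) in cm^-1
        k = diatomic.params["k"]
        expected = np.sqrt(k / reduced_mass(diatomic.mol)) * EIGENVALUE_TO_WAVENUMBER
        modes = analyze(diatomic.ff, diatomic.mol)
        assert modes.wavenumbers[-1] == pytest.approx(expected, abs=0.01)


class TestPipelineInvariances:
    def test_rotational_invariance_of_wavenumbers(self, bent_triatomic):
        # analytic Hessians isolate the pipeline (mass weighting, projection,
        # diagonalization) from finite-difference truncation anisotropy
        nm0 = analyze(
            bent_triatomic.ff,
            bent_triatomic.mol,
            hessian=HessianMatrix(bent_triatomic.ff.analytic_hessian(bent_triatomic.mol)),
        )
        rot = rotation_matrix([1.0, 2.0, 3.0], 0.7)
        rotated = transform_system(bent_triatomic, rot=rot, shift=[0.5, -1.0, 2.0])
        nm1 = analyze(
            rotated.ff,
            rotated.mol,
            hessian=HessianMatrix(rotated.ff.analytic_hessian(rotated.mol)),
        )
        np.testing.assert_allclose(
            nm1.internal_wavenumbers, nm0.internal_wavenumbers, rtol=1e-10
        )

    def test_rotational_invariance_seminumerical(self, bent_triatomic):
        # with finite differences the invariance holds to the truncation level
        nm0 = analyze(bent_triatomic.ff, bent_triatomic.mol)
        rotated = transform_system(
            bent_triatomic, rot=rotation_matrix([0.0, 0.0, 1.0], 1.1)
        )
        nm1 = analyze(rotated.ff, rotated.mol)
        np.testing.assert_allclose(
            nm1.internal_wavenumbers, nm0.internal_wavenumbers, rtol=1e-6
        )

    def test_zpve_invariant_under_atom_permutation(self, bent_triatomic):
        nm0 = analyze(bent_triatomic.ff, bent_triatomic.mol)
        # permute atoms (H, H, O) and remap force-field indices accordingly
        perm = [1, 2, 0]  # new order: atoms 1, 2, 0
        inv = {old: new for new, old in enumerate(perm)}
        coords = bent_triatomic.mol.coords3[perm].ravel()
        symbols = [bent_triatomic.mol.symbols[p] for p in perm]
        mol = Molecule(symbols, coords)
        from dhaspec.calculators import AngleTerm, BondTerm, HarmonicFF

        bonds = [BondTerm(inv[b.i], inv[b.j], b.force_constant, b.r0)
                 for b in bent_triatomic.ff.bonds]
        angles = [AngleTerm(inv[a.i], inv[a.j], inv[a.k], a.force_constant, a.theta0)
                  for a in bent_triatomic.ff.angles]
        nm1 = analyze(HarmonicFF(bonds, angles), mol)
        z0 = zpve(nm0.internal_wavenumbers)
        z1 = zpve(nm1.internal_wavenumbers)
        assert z1 == pytest.approx(z0, rel=1e-10)


class TestHessianFile:
    def test_roundtrip(self, tmp_path, bent_triatomic):
        h = seminumerical_hessian(bent_triatomic.ff, bent_triatomic.mol)
        path = tmp_path / "h.hess"
        write_hessian(h, path, {"geometry_sha256": "abc123"})
        back = read_hessian(path)
        np.testing.assert_allclose(back.matrix, h.matrix, rtol=1e-13)
        assert back.provenance == "seminumerical"
        assert back.step == h.step
        assert back.metadata["geometry_sha256"] == "abc123"

    def test_block_dialect(self, tmp_path):
        path = tmp_path / "h.block"
        mat = np.arange(36.0).reshape(6, 6)
        body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in mat)
        path.write_text(f"$hessian\n{body}\n$end\n")
        back = read_hessian(path, fmt="block")
        np.testing.assert_allclose(back.matrix, mat)

    def test_malformed_reports_line(self, tmp_path):
        path = tmp_path / "bad.hess"
        path.write_text("N 1\n1 0 0\n0 oops 0\n0 0 1\n")
        with pytest.raises(ValidationError, match="line 3"):
            read_hessian(path)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValidationError):
            HessianMatrix(np.zeros((4, 4)))
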