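"""Voxelization physics: centering, mass conservation, Coulomb ESP, dilation."""

import numpy as np
import pytest

from edgen.chemio import Molecule
from edgen.voxelize import (COVALENT_RADIUS, DensityGrid, ESPGrid, GridSpec,
                            VoxelizeParams, center_molecule,
                            compute_density_grid, compute_esp_grid, decorate,
                            dilate_sparse)


def mol(elements, coords, charges=None):
    return Molecule(elements=elements, coords=np.asarray(coords, dtype=float),
                    charges=None if charges is None else np.asarray(charges))


class TestCentering:
    def test_single_atom_moves_to_origin(self):
        m = center_molecule(mol(["C"], [[3.0, 0.0, 0.0]]))
        np.testing.assert_allclose(m.coords, 0.0, atol=1e-12)

    def test_two_atoms_symmetric(self):
        m = center_molecule(mol(["C", "C"], [[0, 0, 0], [2, 0, 0]]))
        np.testing.assert_allclose(m.coords, [[-1, 0, 0], [1, 0, 0]], atol=1e-12)

    def test_mean_is_zero_for_random_molecule(self):
        rng = np.random.default_rng(2)
        m = center_molecule(mol(["C"] * 6, rng.uniform(-4, 4, (6, 3))))
        np.testing.assert_allclose(m.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            center_molecule(mol([], np.zeros((0, 3))))


def quadrature_integral(element: str, n_ref: int = 256, extent: float = 16.0) -> float:
    """Independent fine-quadrature integral of one atomic Gaussian."""
    alpha = 1.0 / (2.0 * COVALENT_RADIUS[element] ** 2)
    h = extent / n_ref
    ax = (np.arange(n_ref) - (n_ref - 1) / 2) * h
    g = np.exp(-alpha * ax ** 2)
    one_d = g.sum() * h
    amp = (alpha / np.pi) ** 1.5
    z = {"H": 1, "C": 6}[element]
    return z * amp * one_d ** 3


class TestDensity:
    def test_far_field_decays_below_1e8(self):
        spec = GridSpec(n_voxels=32, step=0.5)
        g = compute_density_grid(mol(["H"], [[0, 0, 0]]), spec)
        corner = g.values[0, 0, 0]  # ~13.9 A from the atom
        assert corner < 1e-8

    def test_single_h_centered_argmax_and_integral(self):
        spec = GridSpec(n_voxels=16, step=0.5)
        g = compute_density_grid(mol(["H"], [[0, 0, 0]]), spec)
        # H sits between the 8 central voxels of an even grid: argmax is one of them
        idx = np.unravel_index(np.argmax(g.values), g.values.shape)
        assert all(i in (7, 8) for i in idx)
        ref = quadrature_integral("H")
        assert ref == pytest.approx(1.0, rel=1e-6)  # oracle sanity
        assert g.integral() == pytest.approx(1.0, rel=0.02)

    def test_methane_integral_ten_electrons(self):
        # idealized tetrahedral methane, C-H 1.09 A
        d = 1.09 / np.sqrt(3)
        coords = [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
        spec = GridSpec(n_voxels=64, step=0.5)
        g = compute_density_grid(mol(["C", "H", "H", "H", "H"], coords), spec)
        assert g.integral() == pytest.approx(10.0, rel=0.02)

    def test_unknown_width_rejected(self):
        spec = GridSpec(n_voxels=16, step=0.5)
        params = VoxelizeParams(alphas={"C": 1.0})
        with pytest.raises(ValueError, match="width"):
            compute_density_grid(mol(["H"], [[0, 0, 0]]), spec, params)

    def test_boundary_atom_warns_in_provenance(self):
        spec = GridSpec(n_voxels=16, step=0.5)
        with pytest.warns(UserWarning, match="boundary"):
            g = compute_density_grid(mol(["C"], [[3.5, 0, 0]]), spec)
        assert "boundary_warning" in g.provenance

    def test_translation_equivariance_by_whole_voxels(self):
        # coordinates are exact binary fractions so the voxel shift is exact
        # in floating point and interior voxels bit-compare
        spec = GridSpec(n_voxels=16, step=0.5)
        m0 = mol(["C", "H"], [[-0.5, 0.25, 0.25], [0.75, 0.25, 0.25]])
        g0 = compute_density_grid(m0, spec).values
        k = 3
        m1 = mol(["C", "H"], np.asarray(m0.coords) + [k * spec.step, 0, 0])
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            g1 = compute_density_grid(m1, spec).values
        np.testing.assert_array_equal(g1[k:, :, :], g0[:-k, :, :])


class TestEsp:
    def test_single_positive_charge_sign_and_peak(self):
        spec = GridSpec(n_voxels=15, step=0.5)  # odd: a voxel sits at the origin
        g = compute_esp_grid(mol(["H"], [[0, 0, 0]], charges=[1.0]), spec)
        assert np.all(g.values > 0)
        assert np.unravel_index(np.argmax(g.values), g.values.shape) == (7, 7, 7)

    def test_dipole_antisymmetric_under_inversion(self):
        spec = GridSpec(n_voxels=16, step=0.5)
        g = compute_esp_grid(
            mol(["H", "H"], [[0, 0, 1.0], [0, 0, -1.0]], charges=[1.0, -1.0]), spec)
        inverted = g.values[::-1, ::-1, ::-1]
        np.testing.assert_allclose(g.values, -inverted, atol=1e-9)

    def test_matches_direct_coulomb_loop(self):
        rng = np.random.default_rng(11)
        spec = GridSpec(n_voxels=16, step=0.5)
        n_at = 5
        coords = rng.uniform(-1.5, 1.5, (n_at, 3))
        charges = rng.uniform(-0.5, 0.5, n_at)
        g = compute_esp_grid(mol(["C"] * n_at, coords, charges), spec)
        ax = spec.axis_coords()
        eps2 = 0.5 ** 2
        for _ in range(20):
            i, j, k = rng.integers(0, 16, 3)
            r = np.array([ax[i], ax[j], ax[k]])
            direct = sum(q / np.sqrt(((r - c) ** 2).sum() + eps2)
                         for q, c in zip(charges, coords))
            assert g.values[i, j, k] == pytest.approx(direct, rel=1e-6)

    def test_linearity_of_charge_sets(self):
        rng = np.random.default_rng(4)
        spec = GridSpec(n_voxels=12, step=0.5)
        ca = rng.uniform(-1, 1, (3, 3))
        cb = rng.uniform(-1, 1, (2, 3))
        qa = rng.uniform(-1, 1, 3)
        qb = rng.uniform(-1, 1, 2)
        ga = compute_esp_grid(mol(["C"] * 3, ca, qa), spec).values
        gb = compute_esp_grid(mol(["C"] * 2, cb, qb), spec).values
        gu = compute_esp_grid(mol(["C"] * 5, np.vstack([ca, cb]),
                                  np.concatenate([qa, qb])), spec).values
        np.testing.assert_allclose(gu, ga + gb, atol=1e-9)

    def test_missing_charges_instructive_error(self):
        spec = GridSpec(n_voxels=8, step=0.5)
        with pytest.raises(ValueError, match="charges"):
            compute_esp_grid(mol(["H"], [[0, 0, 0]]), spec)


class TestDilate:
    def test_radius_zero_single_voxel(self):
        spec = GridSpec(n_voxels=16, step=0.5)
        pt = np.array([[(8 - 7.5) * 0.5, 0.25, -0.75]])  # exactly on voxel (8,8,6)
        g = dilate_sparse(pt, [3.0], spec, radius_voxels=0.0)
        assert np.count_nonzero(g.values) == 1
        assert g.values[8, 8, 6] == 3.0

    def test_ball_size_matches_exhaustive_scan(self):
        spec = GridSpec(n_voxels=16, step=0.5)
        pt = np.array([[0.25, 0.25, 0.25]])  # voxel-space position (8, 8, 8)
        g = dilate_sparse(pt, [2.5], spec, radius_voxels=2.0)
        # exhaustive oracle over all voxel index offsets
        count = sum(1 for i in range(16) for j in range(16) for k in range(16)
                    if (i - 8) ** 2 + (j - 8) ** 2 + (k - 8) ** 2 <= 4)
        assert np.count_nonzero(g.values) == count
        assert set(np.unique(g.values)) == {0.0, 2.5}

    def test_tie_goes_to_lower_point_index(self):
        spec = GridSpec(n_voxels=16, step=0.5)
        # sources at voxel-space (8,8,6) and (8,8,10); voxel (8,8,8) is equidistant
        pts = np.array([[0.25, 0.25, -0.75], [0.25, 0.25, 1.25]])
        g = dilate_sparse(pts, [1.0, 2.0], spec, radius_voxels=2.0)
        assert g.values[8, 8, 8] == 1.0

    def test_empty_points_zero_grid(self):
        spec = GridSpec(n_voxels=8, step=0.5)
        g = dilate_sparse(np.zeros((0, 3)), [], spec, radius_voxels=2.0)
        np.testing.assert_array_equal(g.values, 0.0)


class TestDecorate:
    def test_channel_order(self):
        spec = GridSpec(n_voxels=8, step=0.5)
        ed = DensityGrid(spec=spec, values=np.ones((8, 8, 8)))
        esp = ESPGrid(spec=spec, values=-np.ones((8, 8, 8)))
        dv = decorate(ed, esp)
        assert dv.channels == (ed, esp)
        assert dv.array.shape == (2, 8, 8, 8)
        np.testing.assert_array_equal(dv.array[0], 1.0)
        np.testing.assert_array_equal(dv.array[1], -1.0)

    def test_mismatched_specs_rejected(self):
        ed = DensityGrid(spec=GridSpec(16, 0.5), values=np.zeros((16,) * 3))
        esp = ESPGrid(spec=GridSpec(32, 0.5), values=np.zeros((32,) * 3))
        with pytest.raises(ValueError, match="spec"):
            decorate(ed, esp)
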