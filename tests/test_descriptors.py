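"""Per-conformer descriptors: R_gyr, SASA, SA 3D PSA, hydrogen-bond counts."""

import numpy as np
import pytest

from protacfold.core import Conformer, DomainError
from protacfold.descriptors import (
    HbondCriteria,
    count_imhb,
    ensemble_descriptors,
    polar_atom_mask,
    radius_of_gyration,
    sa_3d_psa,
    sasa,
)

from conftest import make_library, make_molecule


def _conf(coords):
    return Conformer(id="t", coordinates=np.asarray(coords, float))


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(_conf([[1.0, 2.0, 3.0]]), [12.0]) == 0.0

    def test_two_equal_masses(self):
        c = _conf([[0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(c, [12.0, 12.0]) == pytest.approx(1.0)

    def test_square_of_equal_masses(self):
        c = _conf([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]])
        assert radius_of_gyration(c, [1.0] * 4) == pytest.approx(np.sqrt(2))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(9, 3)) * 2.5
        masses = rng.uniform(1, 16, size=9)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        moved = rot.apply(coords) + np.array([5.0, -3.0, 11.0])
        assert radius_of_gyration(_conf(moved), masses) == pytest.approx(
            radius_of_gyration(_conf(coords), masses), rel=1e-12
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(DomainError):
            radius_of_gyration(_conf([[0, 0, 0]]), [0.0])


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        area = sasa(_conf([[0, 0, 0]]), [1.5], probe=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 2.9**2, rel=0.01)

    def test_buried_atom_is_zero(self):
        conf = _conf([[0, 0, 0], [0.2, 0, 0]])
        areas = sasa(conf, [0.4, 3.0], probe=1.4)
        assert areas[0] == 0.0

    def test_two_atom_self_convergence(self):
        conf = _conf([[0, 0, 0], [2.5, 0, 0]])
        radii = [1.7, 1.5]
        coarse = sasa(conf, radii, n_points=960)
        fine = sasa(conf, radii, n_points=10_000)
        np.testing.assert_allclose(coarse, fine, rtol=0.02)

    def test_approach_never_increases_area(self):
        radii = [1.7, 1.7]
        totals = [
            sasa(_conf([[0, 0, 0], [d, 0, 0]]), radii).sum()
            for d in (8.0, 5.0, 3.0, 2.0, 1.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_cross_check_against_independent_implementation(self):
        """Totals agree with biotite's Shrake-Rupley on a small cluster."""
        import biotite.structure as struc

        rng = np.random.default_rng(4)
        coords = rng.normal(scale=1.5, size=(6, 3))
        radii = np.full(6, 1.7)
        mine = sasa(_conf(coords), radii, probe=1.4, n_points=2000).sum()
        arr = struc.AtomArray(6)
        arr.coord = coords
        arr.element = np.array(["C"] * 6)
        arr.atom_name = np.array([f"C{i}" for i in range(6)])
        arr.res_name = np.array(["LIG"] * 6)
        arr.res_id = np.ones(6, dtype=int)
        arr.chain_id = np.array(["A"] * 6)
        arr.hetero = np.array([True] * 6)
        ref = struc.sasa(arr, probe_radius=1.4, point_number=2000,
                         vdw_radii=radii).sum()
        assert mine == pytest.approx(ref, rel=0.02)


class TestSa3dPsa:
    def test_no_polar_atoms_gives_zero(self):
        mol = make_molecule(["C", "C"], bonds=[(0, 1)])
        conf = _conf([[0, 0, 0], [1.5, 0, 0]])
        assert sa_3d_psa(conf, mol, element_fallback=False) == 0.0

    def test_isolated_polar_atom_equals_full_sasa(self):
        mol = make_molecule(["O"], charges=[-0.4])
        conf = _conf([[0, 0, 0]])
        full = sasa(conf, mol.vdw_radii())
        assert sa_3d_psa(conf, mol) == pytest.approx(full.sum())

    def test_compositional_sum_over_polar_atoms(self):
        elements = ["C", "O", "C", "N", "C"]
        charges = [0.05, -0.5, 0.0, -0.4, 0.02]
        mol = make_molecule(elements, bonds=[(0, 1), (1, 2), (2, 3), (3, 4)],
                            charges=charges)
        rng = np.random.default_rng(1)
        conf = _conf(rng.normal(scale=2.0, size=(5, 3)))
        areas = sasa(conf, mol.vdw_radii())
        expected = areas[1] + areas[3]
        assert sa_3d_psa(conf, mol) == pytest.approx(expected)

    def test_element_fallback_engages_when_charges_absent(self):
        mol = make_molecule(["C", "O", "H"], bonds=[(0, 1), (1, 2)])
        mask = polar_atom_mask(mol)
        # O polar by element; H polar because bonded to O; C not
        np.testing.assert_array_equal(mask, [False, True, True])

    def test_containment_within_total_sasa(self, model_molecule, model_spec):
        from protacfold.synthetic import generate_ensemble

        bundle = generate_ensemble(model_molecule, model_spec)
        radii = model_molecule.vdw_radii()
        for conf in bundle.library.conformers[:5]:
            total = sasa(conf, radii).sum()
            assert 0.0 <= sa_3d_psa(conf, model_molecule) <= total + 1e-9


class TestCountImhb:
    def _nh_o_system(self, d_da, angle_deg):
        """N-H...O with given donor-acceptor distance and D-H...A angle."""
        n_pos = np.array([0.0, 0.0, 0.0])
        h_pos = np.array([1.0, 0.0, 0.0])
        # place O so that the angle at H between N and O equals angle_deg
        theta = np.radians(180.0 - angle_deg)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        # choose H...A length so that |N-O| = d_da
        from scipy.optimize import brentq
        f = lambda L: np.linalg.norm(h_pos + L * direction - n_pos) - d_da
        ha = brentq(f, 0.1, 10.0)
        o_pos = h_pos + ha * direction
        chain = [np.array([-1.5, 0.4 * i, 0.0]) for i in (1, 2, 3)]
        coords = [n_pos, h_pos, *chain, o_pos]
        mol = make_molecule(
            ["N", "H", "C", "C", "C", "O"],
            bonds=[(0, 1), (0, 2), (2, 3), (3, 4), (4, 5)],
            donor_h={1}, acceptors={5},
        )
        return _conf(coords), mol

    def test_good_geometry_counts_one(self):
        conf, mol = self._nh_o_system(d_da=2.9, angle_deg=165.0)
        assert count_imhb(conf, mol) == 1

    def test_distant_pair_counts_zero(self):
        conf, mol = self._nh_o_system(d_da=6.0, angle_deg=165.0)
        assert count_imhb(conf, mol) == 0

    def test_bent_geometry_counts_zero(self):
        conf, mol = self._nh_o_system(d_da=2.9, angle_deg=100.0)
        assert count_imhb(conf, mol) == 0

    def test_short_bond_separation_excluded(self):
        # amide-like N-H with its own adjacent carbonyl O (2 bonds apart)
        mol = make_molecule(
            ["N", "H", "C", "O"],
            bonds=[(0, 1), (0, 2), (2, 3)],
            donor_h={1}, acceptors={3},
        )
        conf = _conf([[0, 0, 0], [-0.5, -0.87, 0], [1.3, 0, 0], [1.9, 1.1, 0]])
        assert count_imhb(conf, mol) == 0

    def test_criteria_validation(self):
        with pytest.raises(DomainError):
            HbondCriteria(max_da_distance=-1.0)
        with pytest.raises(DomainError):
            HbondCriteria(min_dha_angle=200.0)


class TestEnsembleDescriptors:
    def test_identical_conformers_mean_equals_single(self):
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], float)
        lib = make_library(["C", "O", "C"], [coords, coords.copy()],
                           bonds=[(0, 1), (1, 2)])
        table, means = ensemble_descriptors(lib)
        assert means["r_gyr_A"] == pytest.approx(table["r_gyr_A"].iloc[0])
        assert means["sa3dpsa_A2"] == pytest.approx(table["sa3dpsa_A2"].iloc[0])

    def test_weighted_mean_of_polarity(self):
        rng = np.random.default_rng(2)
        lib = make_library(
            ["C", "O", "C"],
            [rng.normal(scale=2, size=(3, 3)) for _ in range(2)],
            bonds=[(0, 1), (1, 2)],
        )
        table, means = ensemble_descriptors(lib, weights=[0.5, 0.5])
        vals = table["sa3dpsa_A2"].to_numpy()
        assert means["sa3dpsa_A2"] == pytest.approx(vals.mean())

    def test_weight_count_mismatch_rejected(self):
        lib = make_library(["C"], [np.zeros((1, 3))])
        with pytest.raises(DomainError):
            ensemble_descriptors(lib, weights=[0.5, 0.5])
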