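"""Shape descriptors, PCA/K-means clustering, subset selection, fold classes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from protacfold.core import Conformer, DomainError
from protacfold.shape import (
    classify_fold,
    diverse_subset,
    kmeans_cluster,
    normalized_extension,
    npr,
    pca_conformers,
    rmsf,
    superpose,
)
from protacfold.synthetic import (
    GeneratorSpec,
    build_model_protac,
    generate_ensemble,
    ligand_atom_indices,
)

from conftest import make_library


def _conf(coords, cid="c"):
    return Conformer(id=cid, coordinates=np.asarray(coords, float))


class TestSuperpose:
    def test_identical_conformers_zero_rmsd(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(7, 3))
        _, rmsd = superpose(_conf(c), _conf(c.copy()))
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(10, 3)) * 3
        rot = Rotation.from_rotvec([0.4, 1.2, -0.6])
        moved = rot.apply(ref) + np.array([4.0, -2.0, 7.0])
        fitted, rmsd = superpose(_conf(ref), _conf(moved))
        assert rmsd < 1e-6
        np.testing.assert_allclose(fitted.coordinates, ref, atol=1e-6)

    def test_displaced_atom_rmsd_closed_form(self):
        # 3 fixed atoms define the fit; the 4th moves 2 A, so the all-atom
        # RMSD after superposition is sqrt(4/4) = 1
        ref = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        mob = ref.copy()
        mob[3, 2] += 2.0
        _, rmsd = superpose(_conf(ref), _conf(mob), atom_subset=[0, 1, 2])
        assert rmsd == pytest.approx(1.0, rel=1e-9)

    def test_collinear_fit_atoms_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        from protacfold.geometry import SuperpositionError
        with pytest.raises(SuperpositionError):
            superpose(_conf(line), _conf(line))


class TestNpr:
    def test_rod_limit(self):
        rod = np.column_stack([np.linspace(-5, 5, 11), np.zeros(11),
                               np.zeros(11)])
        s = npr(_conf(rod), np.ones(11))
        assert s.npr1 == pytest.approx(0.0, abs=1e-9)
        assert s.npr2 == pytest.approx(1.0, abs=1e-9)

    def test_tetrahedron_sphere_limit(self):
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       float)
        s = npr(_conf(tet), np.ones(4))
        assert s.npr1 == pytest.approx(1.0)
        assert s.npr2 == pytest.approx(1.0)

    def test_square_disc_limit(self):
        sq = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        s = npr(_conf(sq), np.ones(4))
        assert s.npr1 == pytest.approx(0.5)
        assert s.npr2 == pytest.approx(0.5)

    def test_triangle_constraint_on_random_clouds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            coords = rng.normal(size=(8, 3)) * rng.uniform(0.5, 4.0, size=3)
            s = npr(_conf(coords), rng.uniform(1, 16, size=8))
            assert 0.0 <= s.npr1 <= s.npr2 + 1e-12 <= 1.0 + 1e-12
            assert s.npr1 + s.npr2 >= 1.0 - 1e-9

    def test_coincident_atoms_rejected(self):
        with pytest.raises(DomainError):
            npr(_conf(np.zeros((3, 3))), np.ones(3))


class TestPca:
    def test_identical_conformers_zero_scores(self):
        coords = np.random.default_rng(0).normal(size=(6, 3))
        lib = make_library(["C"] * 6, [coords.copy() for _ in range(4)])
        res = pca_conformers(lib)
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-10)

    def test_single_hinge_dominates_variance(self):
        # rigid two-arm system opening about a hinge: one degree of freedom
        angles = np.linspace(0.3, 1.2, 12)
        frames = []
        arm = np.linspace(1, 4, 4)
        for a in angles:
            left = np.column_stack([-arm, np.zeros(4), np.zeros(4)])
            right = np.column_stack([arm * np.cos(a), arm * np.sin(a),
                                     np.zeros(4)])
            frames.append(np.vstack([[0, 0, 0], left, right]))
        lib = make_library(["C"] * 9, frames)
        res = pca_conformers(lib, n_components=3)
        assert res.explained_variance[0] > 0.95

    def test_variance_fractions_sum_and_order(self):
        rng = np.random.default_rng(5)
        lib = make_library(
            ["C"] * 7, [rng.normal(size=(7, 3)) * 2 for _ in range(10)]
        )
        res = pca_conformers(lib, n_components=4)
        assert res.explained_variance.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(res.explained_variance) <= 1e-12)


class TestKmeans:
    def test_single_cluster(self):
        pts = np.random.default_rng(0).normal(size=(10, 2))
        labels = kmeans_cluster(pts, k=1, seed=0)
        assert set(labels) == {1}

    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(loc=(0, 0), scale=0.3, size=(25, 2))
        b = rng.normal(loc=(10, 10), scale=0.3, size=(15, 2))
        labels = kmeans_cluster(np.vstack([a, b]), k=2, seed=0)
        # size-ordered labels: the bigger blob must be cluster 1
        assert set(labels[:25]) == {1}
        assert set(labels[25:]) == {2}

    def test_k_equals_n_points(self):
        pts = np.arange(5, dtype=float)[:, None] * 10
        labels = kmeans_cluster(pts, k=5, seed=0)
        assert sorted(labels) == [1, 2, 3, 4, 5]

    def test_k_too_large_rejected(self):
        with pytest.raises(DomainError):
            kmeans_cluster(np.zeros((3, 2)), k=4, seed=0)


class TestDiverseSubset:
    def test_small_cluster_returned_whole(self):
        pts = np.random.default_rng(0).normal(size=(10, 2))
        subset = diverse_subset(pts, np.ones(10, dtype=int), per_cluster=26)
        assert sorted(subset[1]) == list(range(10))

    def test_collinear_selection_includes_extremes(self):
        pts = np.arange(10, dtype=float)[:, None]
        labels = np.ones(10, dtype=int)
        subset = diverse_subset(pts, labels, per_cluster=3)
        chosen = set(subset[1].tolist())
        # brute-force max-min from the centroid-nearest start: 0 and 9 must
        # be in any 3-point farthest-point selection on the line 0..9
        assert {0, 9} <= chosen

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2)) * 3
        labels = np.ones(12, dtype=int)
        got = diverse_subset(pts, labels, per_cluster=4)[1].tolist()
        # oracle: independent re-implementation of greedy max-min
        start = int(np.argmin(np.linalg.norm(pts - pts.mean(0), axis=1)))
        chosen = [start]
        for _ in range(3):
            d = np.min(
                [np.linalg.norm(pts - pts[c], axis=1) for c in chosen], axis=0
            )
            chosen.append(int(np.argmax(d)))
        assert got == chosen

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(30, 2))
        labels = np.repeat([1, 2], 15)
        a = diverse_subset(pts, labels, per_cluster=5)
        b = diverse_subset(pts, labels, per_cluster=5)
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])


@pytest.fixture(scope="module")
def template_library():
    spec = GeneratorSpec(n_linker_atoms=12, n_conformers=3,
                         fold_fractions=(1 / 3, 1 / 3, 1 / 3),
                         noise_sigma_xyz=0.0, torsion_jitter_deg=0.0,
                         seed=0)
    mol = build_model_protac(spec)
    bundle = generate_ensemble(mol, spec)
    la, lb = ligand_atom_indices(spec)
    return mol, bundle, la, lb


class TestClassifyFold:
    def test_templates_classified_by_construction(self, template_library):
        mol, bundle, la, lb = template_library
        got = {
            label: classify_fold(conf, mol, la, lb)
            for conf, label in zip(bundle.library.conformers,
                                   bundle.fold_labels)
        }
        assert got == {"folded": "folded", "semi_folded": "semi_folded",
                       "linear": "linear"}

    def test_extended_chain_extension_range(self, template_library):
        mol, bundle, la, lb = template_library
        linear = bundle.library.conformers[bundle.fold_labels.index("linear")]
        e = normalized_extension(linear, mol, la, lb)
        assert e > 0.8

    def test_rigid_motion_invariance(self, template_library):
        mol, bundle, la, lb = template_library
        conf = bundle.library.conformers[0]
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5])
        moved = Conformer(id="m", coordinates=rot.apply(conf.coordinates)
                          + np.array([3.0, -8.0, 2.0]))
        assert (classify_fold(moved, mol, la, lb)
                == classify_fold(conf, mol, la, lb))

    def test_overlapping_ligand_sets_rejected(self, template_library):
        mol, bundle, la, lb = template_library
        with pytest.raises(DomainError):
            classify_fold(bundle.library.conformers[0], mol, la, la)


class TestRmsf:
    def test_static_trajectory_zero(self):
        coords = np.random.default_rng(0).normal(size=(5, 3))
        lib = make_library(["C"] * 5, [coords.copy() for _ in range(4)])
        assert rmsf(lib).max() < 1e-12

    def test_single_oscillating_atom(self):
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4],
                         [4, 4, 4]], float)
        frames = []
        for sign in (1, -1, 1, -1):
            f = base.copy()
            f[4, 2] += sign * 1.0
            frames.append(f)
        lib = make_library(["C"] * 5, frames)
        values = rmsf(lib, atom_subset=[0, 1, 2, 3])
        assert values[4] == pytest.approx(1.0, rel=1e-6)
        assert values[:4].max() < 1e-9

    def test_flexible_linker_fluctuates_more(self):
        spec_kwargs = dict(n_linker_atoms=10, n_conformers=15,
                           fold_fractions=(0.0, 0.0, 1.0), seed=4)
        rigid_spec = GeneratorSpec(noise_sigma_xyz=0.02,
                                   torsion_jitter_deg=0.0, **spec_kwargs)
        flex_spec = GeneratorSpec(noise_sigma_xyz=0.02,
                                  torsion_jitter_deg=10.0, **spec_kwargs)
        mol = build_model_protac(rigid_spec)
        rigid = generate_ensemble(mol, rigid_spec)
        flex = generate_ensemble(mol, flex_spec)
        linker = np.arange(6, 6 + 10)
        r_rigid = rmsf(rigid.library)[linker].mean()
        r_flex = rmsf(flex.library)[linker].mean()
        assert r_flex > r_rigid
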