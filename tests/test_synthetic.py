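"""Generator truth: model molecule, fold-mixture ensembles, NOE simulation."""

import networkx as nx
import numpy as np
import pytest

from protacfold.io import read_conformer_library, write_conformer_library
from protacfold.namfis import back_calculate, fit_populations
from protacfold.noe import WeakNOEError, derive_restraints, fit_buildup
from protacfold.shape import classify_fold
from protacfold.synthetic import (
    GeneratorSpec,
    assign_weights,
    build_model_protac,
    default_noe_pairs,
    generate_ensemble,
    ligand_atom_indices,
    simulate_noe_buildups,
)


class TestModelMolecule:
    def test_single_connected_component(self, model_molecule):
        g = nx.Graph()
        g.add_nodes_from(range(model_molecule.n_atoms))
        g.add_edges_from(model_molecule.bonds)
        assert nx.number_connected_components(g) == 1

    def test_anchor_path_length_matches_linker(self, model_spec,
                                               model_molecule):
        # shortest bonded path ring-anchor -> ring-anchor traverses the
        # whole linker: n_linker_atoms + 2 atoms including both anchors
        la, lb = ligand_atom_indices(model_spec)
        g = nx.Graph()
        g.add_edges_from(model_molecule.bonds)
        outside_a = set(range(model_molecule.n_atoms)) - set(la.tolist())
        anchor_a = next(a for a, b in model_molecule.bonds
                        if (a in la and b in outside_a)
                        or (b in la and a in outside_a))
        paths = {
            atom: nx.shortest_path(g, anchor_a, atom) for atom in lb.tolist()
        }
        shortest = min(paths.values(), key=len)
        assert len(shortest) == model_spec.n_linker_atoms + 2

    def test_round_trips_through_sdf(self, tmp_path, model_spec,
                                     model_molecule):
        spec = GeneratorSpec(n_linker_atoms=model_spec.n_linker_atoms,
                             n_conformers=2, seed=1)
        bundle = generate_ensemble(model_molecule, spec)
        path = tmp_path / "model.sdf"
        write_conformer_library(bundle.library, path, "sdf")
        back = read_conformer_library(path, "sdf")
        assert back.molecule.n_atoms == model_molecule.n_atoms
        np.testing.assert_allclose(
            back.conformers[0].coordinates,
            bundle.library.conformers[0].coordinates,
            atol=1e-3,
        )

    def test_donor_and_acceptor_present(self, model_molecule):
        assert any(a.is_hb_donor_h for a in model_molecule.atoms)
        assert any(a.is_hb_acceptor for a in model_molecule.atoms)


class TestGenerateEnsemble:
    def test_exact_label_allocation(self, model_molecule):
        spec = GeneratorSpec(n_linker_atoms=12, n_conformers=100,
                             fold_fractions=(0.6, 0.3, 0.1), seed=0)
        bundle = generate_ensemble(model_molecule, spec)
        assert len(bundle.library) == 100
        counts = {c: bundle.fold_labels.count(c)
                  for c in ("folded", "semi_folded", "linear")}
        assert counts == {"folded": 60, "semi_folded": 30, "linear": 10}

    def test_same_seed_reproduces_coordinates(self, model_molecule):
        spec = GeneratorSpec(n_linker_atoms=12, n_conformers=5, seed=99)
        a = generate_ensemble(model_molecule, spec)
        b = generate_ensemble(model_molecule, spec)
        np.testing.assert_array_equal(a.library.coordinates(),
                                      b.library.coordinates())

    def test_pure_folded_ensemble_classified_folded(self, model_molecule):
        spec = GeneratorSpec(n_linker_atoms=12, n_conformers=40,
                             fold_fractions=(1.0, 0.0, 0.0),
                             noise_sigma_xyz=0.1, seed=5)
        bundle = generate_ensemble(model_molecule, spec)
        la, lb = ligand_atom_indices(spec)
        hits = sum(
            classify_fold(c, model_molecule, la, lb) == "folded"
            for c in bundle.library.conformers
        )
        assert hits / len(bundle.library) >= 0.95

    def test_descriptor_ordering_across_fold_classes(self, model_molecule):
        """Folded ensembles are smaller and less polar than linear ones,
        and expose more internal hydrogen bonds."""
        from protacfold.descriptors import ensemble_descriptors

        means = {}
        for frac, name in [((1, 0, 0), "folded"), ((0, 1, 0), "semi"),
                           ((0, 0, 1), "linear")]:
            spec = GeneratorSpec(n_linker_atoms=12, n_conformers=15,
                                 fold_fractions=frac, seed=21)
            bundle = generate_ensemble(model_molecule, spec)
            _, m = ensemble_descriptors(bundle.library)
            means[name] = m
        assert (means["folded"]["r_gyr_A"] < means["semi"]["r_gyr_A"]
                < means["linear"]["r_gyr_A"])
        assert (means["folded"]["sa3dpsa_A2"] < means["semi"]["sa3dpsa_A2"]
                < means["linear"]["sa3dpsa_A2"])
        assert means["folded"]["n_imhb"] >= means["linear"]["n_imhb"]


@pytest.fixture(scope="module")
def weighted_bundle(model_molecule):
    spec = GeneratorSpec(n_linker_atoms=12, n_conformers=5,
                         fold_fractions=(0.4, 0.4, 0.2),
                         noise_sigma_xyz=0.05, seed=2)
    bundle = generate_ensemble(model_molecule, spec)
    return assign_weights(bundle, [0.35, 0.25, 0.2, 0.15, 0.05])


class TestSimulatedBuildups:
    def test_reference_pair_recovers_reference_distance(self, weighted_bundle):
        curves, groups, kinds = simulate_noe_buildups(
            weighted_bundle, noise_fraction=0.0, seed=0
        )
        from protacfold.noe import distance_from_rates
        fit = fit_buildup(curves[0])
        assert distance_from_rates(fit.sigma, fit.sigma) == pytest.approx(1.78)

    def test_zero_noise_round_trip_within_tolerance(self, weighted_bundle):
        t_short = np.linspace(0.005, 0.035, 7)
        curves, groups, kinds = simulate_noe_buildups(
            weighted_bundle, mixing_times=t_short, noise_fraction=0.0, seed=0
        )
        restraints, rejected = derive_restraints(curves, "ref", groups, kinds)
        assert rejected == []
        derived = {r.pair_id: r.distance for r in restraints}
        for true_r, d in zip(weighted_bundle.restraints,
                             weighted_bundle.true_restraint_distances):
            if 1.5 <= d <= 6.0:  # NOE-observable distances
                assert derived[true_r.pair_id] == pytest.approx(d, abs=0.02)

    def test_heavy_noise_rejects_weak_pairs(self, weighted_bundle):
        long_idx = int(np.argmax(weighted_bundle.true_restraint_distances))
        pid = weighted_bundle.restraints[long_idx].pair_id
        rejected_somewhere = False
        for seed in range(8):
            curves, groups, kinds = simulate_noe_buildups(
                weighted_bundle, noise_fraction=0.5, seed=seed
            )
            curve = next(c for c in curves if c.pair_id == pid)
            try:
                fit_buildup(curve)
            except WeakNOEError:
                rejected_somewhere = True
                break
        assert rejected_somewhere

    def test_end_to_end_weight_recovery(self, weighted_bundle):
        """Buildups at 1% noise -> distances -> populations within 0.05."""
        t_short = np.linspace(0.005, 0.035, 7)
        curves, groups, kinds = simulate_noe_buildups(
            weighted_bundle, mixing_times=t_short, noise_fraction=0.01, seed=3
        )
        restraints, _ = derive_restraints(curves, "ref", groups, kinds)
        matrix = back_calculate(weighted_bundle.library, restraints)
        fit = fit_populations(matrix, [r.distance for r in restraints])
        assert np.abs(fit.weights - weighted_bundle.true_weights).max() < 0.05


class TestGeneratorSpecValidation:
    def test_fraction_sum_enforced(self):
        with pytest.raises(Exception):
            GeneratorSpec(fold_fractions=(0.5, 0.2, 0.2))

    def test_restraint_list_covers_all_groups(self, model_molecule):
        pairs = default_noe_pairs(model_molecule)
        labels = {g for r in pairs for g in (r.group_a, r.group_b)}
        assert labels == set(model_molecule.proton_groups)
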