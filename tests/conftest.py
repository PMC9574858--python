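import numpy as np
import pytest

from protacfold.core import AtomRecord, Conformer, ConformerLibrary, Molecule
from protacfold.elements import atomic_mass, vdw_radius
from protacfold.synthetic import GeneratorSpec, build_model_protac


def make_molecule(elements, bonds=(), proton_groups=None, charges=None,
                  donor_h=(), acceptors=()):
    """Assemble a toy Molecule from element symbols."""
    atoms = [
        AtomRecord(
            index=i,
            element=el,
            name=f"{el}{i}",
            mass=atomic_mass(el),
            vdw_radius=vdw_radius(el),
            partial_charge=0.0 if charges is None else charges[i],
            is_hb_donor_h=i in donor_h,
            is_hb_acceptor=i in acceptors,
        )
        for i, el in enumerate(elements)
    ]
    return Molecule(atoms=atoms, bonds=list(bonds),
                    proton_groups=proton_groups or {})


def make_library(elements, coord_sets, **kwargs):
    mol = make_molecule(elements, **kwargs)
    confs = [Conformer(id=f"c{i}", coordinates=np.asarray(c, float))
             for i, c in enumerate(coord_sets)]
    return ConformerLibrary(molecule=mol, conformers=confs)


@pytest.fixture(scope="session")
def model_spec():
    return GeneratorSpec(n_linker_atoms=12, n_conformers=30, seed=7)


@pytest.fixture(scope="session")
def model_molecule(model_spec):
    return build_model_protac(model_spec)
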