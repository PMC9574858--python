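"""Readers and writers for conformer libraries and tabular inputs.

Structure formats: multi-model PDB (MODEL/ENDMDL), SDF V2000 and multi-frame
XYZ, all in Å.  PDB and SDF parsing/writing is delegated to biotite; XYZ is
a four-column plain-text format handled directly.  None of these formats
carries partial charges, so charges default to 0 with a logged warning —
supply them on the :class:`~protacfold.core.Molecule` for charge-based
descriptors.

Tabular formats are plain CSV with a header row (pandas).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.mol import SDFile, SDRecord
from biotite.structure.io.pdb import PDBFile

from .core import AtomRecord, Conformer, ConformerLibrary, Molecule
from .elements import atomic_mass, vdw_radius

logger = logging.getLogger(__name__)

FORMATS = ("pdb_multimodel", "sdf", "xyz")


class StructureParseError(ValueError):
    """A structure file is malformed or internally inconsistent."""


def _build_molecule(
    elements: list[str],
    names: list[str],
    bonds: list[tuple[int, int]],
) -> Molecule:
    atoms = [
        AtomRecord(
            index=i,
            element=el,
            name=name,
            mass=atomic_mass(el),
            vdw_radius=vdw_radius(el),
        )
        for i, (el, name) in enumerate(zip(elements, names))
    ]
    # each hydrogen becomes a singleton proton group keyed by its atom name
    groups: dict[str, list[int]] = {}
    for i, atom in enumerate(atoms):
        if atom.element.upper() == "H":
            label = atom.name if atom.name not in groups else f"{atom.name}_{i}"
            groups[label] = [i]
    return Molecule(atoms=atoms, bonds=bonds, proton_groups=groups)


def _check_model_consistency(path: Path) -> None:
    """Verify every MODEL block has the same atom count, naming the offender."""
    counts: list[int] = []
    current = 0
    in_model = False
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM") and in_model:
            current += 1
    for i, c in enumerate(counts):
        if c != counts[0]:
            raise StructureParseError(
                f"inconsistent atom count in model {i + 1}: "
                f"{c} atoms vs {counts[0]} in model 1"
            )


def _bonds_from_array(template: struc.AtomArray) -> list[tuple[int, int]]:
    if template.bonds is not None and len(template.bonds.as_array()) > 0:
        pairs = template.bonds.as_array()[:, :2]
    else:
        logger.warning("no bond records found: inferring bonds from distances")
        pairs = struc.connect_via_distances(template).as_array()[:, :2]
    return [(int(a), int(b)) for a, b in pairs]


def _read_pdb(path: Path) -> ConformerLibrary:
    _check_model_consistency(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, include_bonds=True)
    template = stack[0]
    molecule = _build_molecule(
        [str(e) for e in template.element],
        [str(n) for n in template.atom_name],
        _bonds_from_array(template),
    )
    conformers = [
        Conformer(id=f"model_{i + 1}", coordinates=np.array(stack.coord[i]))
        for i in range(stack.stack_depth())
    ]
    logger.warning("PDB carries no partial charges: defaulting to 0")
    return ConformerLibrary(molecule=molecule, conformers=conformers,
                            source=str(path))


def _read_sdf(path: Path) -> ConformerLibrary:
    sdf = SDFile.read(str(path))
    records = list(sdf.items())
    if not records:
        raise StructureParseError(f"{path}: empty SDF")
    molecule = None
    conformers = []
    n_ref = None
    for i, (name, record) in enumerate(records):
        arr = record.get_structure()
        if molecule is None:
            n_ref = arr.array_length()
            names = [f"{el}{j + 1}" for j, el in enumerate(arr.element)]
            molecule = _build_molecule(
                [str(e) for e in arr.element], names, _bonds_from_array(arr)
            )
        elif arr.array_length() != n_ref:
            raise StructureParseError(
                f"inconsistent atom count in record {i + 1} ({name}): "
                f"{arr.array_length()} vs {n_ref}"
            )
        conformers.append(Conformer(id=str(name), coordinates=np.array(arr.coord)))
    logger.warning("SDF carries no partial charges: defaulting to 0")
    return ConformerLibrary(molecule=molecule, conformers=conformers,
                            source=str(path))


def _read_xyz(path: Path) -> ConformerLibrary:
    lines = path.read_text().splitlines()
    frames: list[tuple[list[str], np.ndarray]] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise StructureParseError(
                f"{path}: expected atom count at line {pos + 1}"
            ) from exc
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise StructureParseError(
                f"{path}: truncated frame {len(frames) + 1}"
            )
        elements, coords = [], []
        for row in block:
            parts = row.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append((elements, np.array(coords)))
        pos += 2 + n
    if not frames:
        raise StructureParseError(f"{path}: no frames")
    n_ref = len(frames[0][0])
    for i, (els, _) in enumerate(frames):
        if len(els) != n_ref:
            raise StructureParseError(
                f"inconsistent atom count in frame {i + 1}: {len(els)} vs {n_ref}"
            )
    elements = frames[0][0]
    names = [f"{el}{j + 1}" for j, el in enumerate(elements)]
    molecule = _build_molecule(elements, names, [])
    logger.warning("XYZ carries no bonds or partial charges")
    conformers = [
        Conformer(id=f"frame_{i + 1}", coordinates=c)
        for i, (_, c) in enumerate(frames)
    ]
    return ConformerLibrary(molecule=molecule, conformers=conformers,
                            source=str(path))


def read_conformer_library(path, format: str) -> ConformerLibrary:
    """Read a conformer library from ``path`` in the given ``format``.

    ``format`` is one of ``pdb_multimodel``, ``sdf``, ``xyz``.  Elements,
    masses and vdW radii are filled from internal tables; partial charges
    default to 0 (logged) since none of these formats carries them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pdb_multimodel":
        return _read_pdb(path)
    if format == "sdf":
        return _read_sdf(path)
    if format == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def _to_atom_array(lib: ConformerLibrary, coords: np.ndarray) -> struc.AtomArray:
    n = lib.molecule.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=float)
    arr.element = np.array([a.element.upper() for a in lib.molecule.atoms])
    arr.atom_name = np.array([a.name[:4] for a in lib.molecule.atoms])
    arr.res_name = np.array(["LIG"] * n)
    arr.res_id = np.ones(n, dtype=int)
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.array([True] * n)
    if lib.molecule.bonds:
        arr.bonds = struc.BondList(
            n, np.array([[a, b, 1] for a, b in lib.molecule.bonds])
        )
    return arr


def write_conformer_library(lib: ConformerLibrary, path, format: str) -> None:
    """Write a conformer library to ``path`` as multi-model PDB, SDF or XYZ."""
    path = Path(path)
    if format == "pdb_multimodel":
        arrays = [_to_atom_array(lib, c.coordinates) for c in lib.conformers]
        stack = struc.stack(arrays)
        stack.bonds = arrays[0].bonds
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif format == "sdf":
        records = {}
        for conf in lib.conformers:
            rec = SDRecord()
            rec.set_structure(_to_atom_array(lib, conf.coordinates))
            records[conf.id] = rec
        SDFile(records).write(str(path))
    elif format == "xyz":
        with open(path, "w") as fh:
            for conf in lib.conformers:
                fh.write(f"{lib.molecule.n_atoms}\n{conf.id}\n")
                for atom, xyz in zip(lib.molecule.atoms, conf.coordinates):
                    fh.write(
                        f"{atom.element:<3s} {xyz[0]:12.6f} {xyz[1]:12.6f} "
                        f"{xyz[2]:12.6f}\n"
                    )
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

BUILDUP_COLUMNS = ["pair_id", "mixing_time_s", "cross1", "cross2", "diag1", "diag2"]
RESTRAINT_COLUMNS = ["pair_id", "group_a", "group_b", "distance_A", "kind",
                     "r_squared"]
ASSAY_COLUMNS = ["compound_id", "ic50_cell_uM", "ic50_bio_uM"]


def read_buildup_table(path) -> pd.DataFrame:
    """Read a NOE buildup CSV (pair_id, mixing_time_s, cross/diag intensities)."""
    df = pd.read_csv(path)
    missing = set(BUILDUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"buildup table missing columns: {sorted(missing)}")
    return df


def read_restraint_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"pair_id", "group_a", "group_b", "distance_A"} - set(df.columns)
    if missing:
        raise ValueError(f"restraint table missing columns: {sorted(missing)}")
    return df


def read_assay_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    return df
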