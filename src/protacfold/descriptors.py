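"""Per-conformer molecular descriptors and their population-weighted means.

Size is measured by the mass-weighted radius of gyration (R_gyr, Å), polarity
by the solvent-accessible 3D polar surface area (SA 3D PSA, Ų): the
solvent-accessible surface area summed over polar atoms of the specific 3D
conformation.  A conformation that folds polar groups inward therefore shows
a lower SA 3D PSA than the same molecule stretched out — the geometric basis
of chameleonic membrane permeability.  Intramolecular hydrogen bonds (IMHBs)
are counted from donor-H···acceptor geometry.

SASA uses deterministic Shrake–Rupley sphere sampling with a Fibonacci point
set, so results are reproducible bit-for-bit at a fixed point count.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import Conformer, ConformerLibrary, DomainError, Molecule, weighted_mean

#: Water-sized solvent probe radius, Å.
DEFAULT_PROBE = 1.4

#: Atoms with |partial charge| above this (e) count as polar.
DEFAULT_CHARGE_THRESHOLD = 0.1

#: Sphere sample points per atom for SASA.
DEFAULT_N_POINTS = 960

POLAR_ELEMENTS = {"N", "O", "S"}


@dataclass
class HbondCriteria:
    """Geometric hydrogen-bond criteria.

    Defaults (3.5 Å donor···acceptor, ≥135° D–H···A, donor and acceptor at
    least 4 bonds apart) are conventional trajectory-analysis values; the
    bond-separation floor excludes trivial contacts like an amide NH with
    its own carbonyl oxygen.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 135.0
    min_bond_separation: int = 4

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise DomainError("max_da_distance must be > 0")
        if not 0 < self.min_dha_angle <= 180:
            raise DomainError("min_dha_angle must be in (0, 180]")


def radius_of_gyration(conformer: Conformer, masses) -> float:
    """Mass-weighted radius of gyration about the center of mass, Å."""
    m = np.asarray(masses, float)
    if np.any(m <= 0):
        raise DomainError("masses must be positive")
    xyz = conformer.coordinates
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    sq = np.sum((xyz - com) ** 2, axis=1)
    return float(np.sqrt((m * sq).sum() / m.sum()))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(conformer: Conformer, radii, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Ų (Shrake–Rupley).

    Each atom's solvent-accessible sphere (vdW radius + probe) is sampled
    with ``n_points`` Fibonacci points; a point is accessible if it lies
    outside every other atom's accessible sphere.  Total SASA is the sum of
    the returned per-atom values.
    """
    r = np.asarray(radii, float)
    if np.any(r <= 0):
        raise DomainError("vdW radii must be positive")
    xyz = conformer.coordinates
    n_atoms = xyz.shape[0]
    expanded = r + probe
    sphere = _fibonacci_sphere(n_points)
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        points = xyz[i] + expanded[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            # skip far atoms: spheres cannot intersect
            if np.linalg.norm(xyz[j] - xyz[i]) >= expanded[i] + expanded[j]:
                continue
            d2 = np.sum((points - xyz[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def polar_atom_mask(
    molecule: Molecule,
    charge_threshold: float = DEFAULT_CHARGE_THRESHOLD,
    element_fallback: bool | None = None,
) -> np.ndarray:
    """Boolean mask of polar atoms.

    An atom is polar iff |partial charge| > ``charge_threshold``.  When
    ``element_fallback`` is on — or charges are absent entirely and the flag
    is left unset — atoms are instead polar iff their element is N/O/S or
    they are a hydrogen bonded to one.
    """
    charges = molecule.partial_charges()
    have_charges = bool(np.any(charges != 0.0))
    if element_fallback is None:
        element_fallback = not have_charges
    mask = np.abs(charges) > charge_threshold
    if element_fallback:
        neighbors = molecule.neighbor_map()
        for i, atom in enumerate(molecule.atoms):
            el = atom.element.upper()
            if el in POLAR_ELEMENTS:
                mask[i] = True
            elif el == "H" and any(
                molecule.atoms[j].element.upper() in POLAR_ELEMENTS
                for j in neighbors[i]
            ):
                mask[i] = True
    return mask


def sa_3d_psa(
    conformer: Conformer,
    molecule: Molecule,
    probe: float = DEFAULT_PROBE,
    charge_threshold: float = DEFAULT_CHARGE_THRESHOLD,
    element_fallback: bool | None = None,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Solvent-accessible 3D polar surface area of one conformer, Ų."""
    areas = sasa(conformer, molecule.vdw_radii(), probe, n_points)
    mask = polar_atom_mask(molecule, charge_threshold, element_fallback)
    return float(areas[mask].sum())


def _bond_separation_matrix(molecule: Molecule) -> dict[int, dict[int, int]]:
    g = nx.Graph()
    g.add_nodes_from(range(molecule.n_atoms))
    g.add_edges_from(molecule.bonds)
    return dict(nx.all_pairs_shortest_path_length(g))


def count_imhb(
    conformer: Conformer,
    molecule: Molecule,
    criteria: HbondCriteria | None = None,
) -> int:
    """Count intramolecular hydrogen bonds in one conformer.

    A donor-H···acceptor triple counts when the donor···acceptor distance is
    within ``max_da_distance``, the D–H···A angle is at least
    ``min_dha_angle`` and donor and acceptor heavy atoms are separated by at
    least ``min_bond_separation`` bonds along the molecular graph.
    """
    criteria = criteria or HbondCriteria()
    xyz = conformer.coordinates
    neighbors = molecule.neighbor_map()
    separations = _bond_separation_matrix(molecule)

    donors = []  # (heavy donor index, hydrogen index)
    for i, atom in enumerate(molecule.atoms):
        if atom.is_hb_donor_h:
            heavy = [j for j in neighbors[i]
                     if molecule.atoms[j].element.upper() in ("N", "O", "S")]
            if heavy:
                donors.append((heavy[0], i))
    acceptors = [i for i, a in enumerate(molecule.atoms) if a.is_hb_acceptor]

    count = 0
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            if separations.get(d, {}).get(a, np.inf) < criteria.min_bond_separation:
                continue
            da = np.linalg.norm(xyz[a] - xyz[d])
            if da > criteria.max_da_distance:
                continue
            v1 = xyz[d] - xyz[h]
            v2 = xyz[a] - xyz[h]
            cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
            if angle >= criteria.min_dha_angle:
                count += 1
    return count


def ensemble_descriptors(
    lib: ConformerLibrary,
    weights=None,
    probe: float = DEFAULT_PROBE,
    charge_threshold: float = DEFAULT_CHARGE_THRESHOLD,
    element_fallback: bool | None = None,
    hbond_criteria: HbondCriteria | None = None,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-conformer descriptor table plus population-weighted means.

    Returns a DataFrame with columns ``conformer_id, r_gyr_A, sasa_A2,
    sa3dpsa_A2, n_imhb, weight`` and a dict of weighted means of the numeric
    columns.  ``weights=None`` means a uniform ensemble.
    """
    n = len(lib.conformers)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape[0] != n:
            raise DomainError(f"{w.shape[0]} weights for {n} conformers")
    molecule = lib.molecule
    masses = molecule.masses()
    radii = molecule.vdw_radii()
    mask = polar_atom_mask(molecule, charge_threshold, element_fallback)

    rows = []
    for conf, wi in zip(lib.conformers, w):
        areas = sasa(conf, radii, probe, n_points)
        rows.append({
            "conformer_id": conf.id,
            "r_gyr_A": radius_of_gyration(conf, masses),
            "sasa_A2": float(areas.sum()),
            "sa3dpsa_A2": float(areas[mask].sum()),
            "n_imhb": count_imhb(conf, molecule, hbond_criteria),
            "weight": float(wi),
        })
    table = pd.DataFrame(rows)
    means = {
        col: weighted_mean(table[col].to_numpy(), w)
        for col in ("r_gyr_A", "sasa_A2", "sa3dpsa_A2", "n_imhb")
    }
    return table, means
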