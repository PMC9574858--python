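"""Domain types and ensemble bookkeeping.

The central object is the :class:`ConformerLibrary`: one molecule's topology
(atoms, bonds, proton groups) plus any number of conformers' Cartesian
coordinates in Å.  Every downstream stage — NOE distance derivation, NAMFIS
population fitting, descriptor and shape analysis — consumes this object.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import pairwise_rmsd

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """An input violates a mathematical precondition (sign, range, length)."""


@dataclass
class AtomRecord:
    """One atom: identity, mass, partial charge and hydrogen-bond roles.

    Partial charges are user input (e units); when a structure format does
    not carry them they default to 0 and the atom never counts as polar by
    charge (an element-based fallback exists in the descriptor layer).
    """

    index: int
    element: str
    name: str
    mass: float
    vdw_radius: float
    partial_charge: float = 0.0
    is_hb_donor_h: bool = False
    is_hb_acceptor: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise DomainError(f"atom {self.index}: mass must be > 0")
        if self.vdw_radius <= 0:
            raise DomainError(f"atom {self.index}: vdw radius must be > 0")


@dataclass
class Molecule:
    """Topology: atoms, bonds and proton groups (CH/CH2/CH3 pseudo-atoms)."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]]
    proton_groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise DomainError(f"invalid bond ({a}, {b}) for {n} atoms")
        for label, members in self.proton_groups.items():
            if not 1 <= len(members) <= 3:
                raise DomainError(
                    f"proton group {label!r} must have 1-3 members, "
                    f"has {len(members)}"
                )
            for i in members:
                if self.atoms[i].element.upper() != "H":
                    raise DomainError(
                        f"proton group {label!r} member {i} is not a hydrogen"
                    )
        self._check_donor_hydrogens()

    def _check_donor_hydrogens(self) -> None:
        neighbors = self.neighbor_map()
        for atom in self.atoms:
            if not atom.is_hb_donor_h:
                continue
            if atom.element.upper() != "H":
                raise DomainError(f"donor-H flag on non-hydrogen atom {atom.index}")
            heavy = [
                self.atoms[j].element.upper() for j in neighbors[atom.index]
            ]
            if not any(e in ("N", "O", "S") for e in heavy):
                raise DomainError(
                    f"donor hydrogen {atom.index} is not bonded to N/O/S"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbor_map(self) -> dict[int, list[int]]:
        nm: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for a, b in self.bonds:
            nm[a].append(b)
            nm[b].append(a)
        return nm

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def partial_charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_atom_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element.upper() != "H"],
            dtype=int,
        )


@dataclass
class Conformer:
    """One conformer: an ``(n_atoms, 3)`` coordinate array in Å."""

    id: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise DomainError(f"conformer {self.id}: coordinates must be (n, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise DomainError(f"conformer {self.id}: non-finite coordinates")


@dataclass
class ConformerLibrary:
    """A molecule plus its conformers — the library every stage consumes."""

    molecule: Molecule
    conformers: list[Conformer]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.conformers:
            raise DomainError("conformer library must be non-empty")
        n = self.molecule.n_atoms
        for c in self.conformers:
            if c.coordinates.shape[0] != n:
                raise DomainError(
                    f"conformer {c.id} has {c.coordinates.shape[0]} atoms, "
                    f"molecule has {n}"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    def coordinates(self) -> np.ndarray:
        """All conformers stacked as ``(n_conformers, n_atoms, 3)``."""
        return np.array([c.coordinates for c in self.conformers])

    def subset(self, indices) -> "ConformerLibrary":
        return ConformerLibrary(
            molecule=self.molecule,
            conformers=[self.conformers[i] for i in indices],
            source=self.source,
        )


def deduplicate_conformers(
    lib: ConformerLibrary, rmsd_cutoff: float = 3.0
) -> ConformerLibrary:
    """Remove redundant conformers by a greedy heavy-atom RMSD filter.

    Conformers are visited in input order; one is kept iff its
    best-superposition heavy-atom RMSD to every previously kept conformer
    exceeds ``rmsd_cutoff`` (Å).  Survivor order is preserved, so the pass
    is deterministic and idempotent.
    """
    if rmsd_cutoff <= 0:
        raise DomainError("rmsd_cutoff must be > 0")
    heavy = lib.molecule.heavy_atom_indices()
    if heavy.size == 0:
        heavy = np.arange(lib.molecule.n_atoms)
    kept: list[Conformer] = []
    kept_coords: list[np.ndarray] = []
    for conf in lib.conformers:
        coords = conf.coordinates[heavy]
        if all(pairwise_rmsd(prev, coords) > rmsd_cutoff for prev in kept_coords):
            kept.append(conf)
            kept_coords.append(coords)
    return ConformerLibrary(molecule=lib.molecule, conformers=kept,
                            source=lib.source)


def search_completeness(n_conformers: int, n_steps: int) -> float:
    """Probability estimate that a stochastic conformational search is complete.

    For a search of ``M`` steps over ``N`` distinct conformers the estimate
    is ``1 - (1 - 1/N)^M``: the chance that any given conformer was visited
    at least once when each step lands uniformly.
    """
    if n_conformers < 1 or n_steps < 1:
        raise DomainError("n_conformers and n_steps must be >= 1")
    return 1.0 - (1.0 - 1.0 / n_conformers) ** n_steps


def weighted_mean(values, weights) -> float:
    """Population-weighted mean Σwᵢvᵢ / Σwᵢ."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise DomainError("values and weights must have equal length")
    if np.any(weights < 0):
        raise DomainError("weights must be non-negative")
    total = weights.sum()
    if total <= 0 or not math.isfinite(total):
        raise DomainError("weights must sum to a positive finite value")
    return float(np.dot(values, weights) / total)
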