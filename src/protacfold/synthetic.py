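"""Synthetic study inputs with known ground truth.

Everything upstream of the analyses is testable without external data via a
geometric model of a bifunctional degrader: two planar six-membered ring
"ligands" joined by an alkyl/ether-type linker built with standard 1.5 Å
bonds and tetrahedral angles.  Polar atoms (charge ±0.4 e) are interspersed
along the linker, and a donor N–H near one ring plus an acceptor O near the
other permit an intramolecular hydrogen bond when the molecule folds.

Three torsion-built geometric templates define the fold classes exactly by
construction — no force field is involved, so truth labels are never
ambiguous:

* ``folded``      — hairpin, two backbone turns, terminal ring centroids in
                    contact (≤ 5 Å);
* ``semi_folded`` — a single backbone turn;
* ``linear``      — the all-anti extended chain.

Ensembles mix these templates in controlled proportions with seeded torsion
jitter and Cartesian noise.  NOE buildup curves are simulated from a
known-weight ensemble via σ ∝ r⁻⁶ with a mild quadratic curvature term
(1 − σt/2), so the strictly-linear window rule of the buildup fitter is
actually exercised.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .core import AtomRecord, Conformer, ConformerLibrary, DomainError, Molecule
from .elements import atomic_mass, vdw_radius
from .namfis import back_calculate
from .noe import DEFAULT_R_REF, BuildupCurve, DistanceRestraint

# geometry constants (Å, degrees)
BOND_CC = 1.5
BOND_RING = 1.4
BOND_CH = 1.09
TETRAHEDRAL = 109.47
#: canonical longest NOESY mixing time, s — σ_ref is calibrated so the
#: reference pair's normalized intensity reaches 0.3 here
CANONICAL_T_MAX = 0.7
REF_INTENSITY_AT_T_MAX = 0.3

FOLD_TEMPLATES = ("folded", "semi_folded", "linear")


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic compound.

    ``fold_fractions`` is (folded, semi_folded, linear) and must sum to 1;
    counts are allocated deterministically by largest remainder.
    ``noise_sigma_xyz`` is per-coordinate Gaussian noise and
    ``torsion_jitter_deg`` a per-backbone-bond Gaussian torsion perturbation
    that makes conformers within a fold class distinct.
    """

    n_linker_atoms: int = 12
    ligand_size: int = 6
    fold_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    n_conformers: int = 100
    noise_sigma_xyz: float = 0.1
    torsion_jitter_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_linker_atoms < 6:
            raise DomainError("linker needs >= 6 atoms")
        if self.ligand_size != 6:
            raise DomainError("only six-membered ring ligands are modeled")
        f = np.asarray(self.fold_fractions, float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise DomainError("fold_fractions must be >= 0 and sum to 1")
        if self.n_conformers < 1:
            raise DomainError("n_conformers must be positive")


#: Presets mirroring a qualitative high→low permeability series: long-linker
#: mostly-folded, mixed, and mostly-linear compounds.
PRESETS: dict[str, GeneratorSpec] = {
    "protac1": GeneratorSpec(n_linker_atoms=12, fold_fractions=(0.6, 0.3, 0.1)),
    "protac2": GeneratorSpec(n_linker_atoms=8, fold_fractions=(0.3, 0.4, 0.3)),
    "protac3": GeneratorSpec(n_linker_atoms=8, fold_fractions=(0.1, 0.2, 0.7)),
}


@dataclass
class TruthBundle:
    """A generated library plus everything needed to check recovery."""

    library: ConformerLibrary
    fold_labels: list[str]
    true_weights: np.ndarray
    restraints: list[DistanceRestraint] = field(default_factory=list)
    true_restraint_distances: np.ndarray | None = None
    averaging: str = "linear"

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise DomainError("true_weights must be a probability vector")
        self.true_weights = w
        bad = set(self.fold_labels) - set(FOLD_TEMPLATES)
        if bad:
            raise DomainError(f"unknown fold labels: {sorted(bad)}")


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _place_atom(p1, p2, p3, bond, angle_deg, torsion_deg) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of the next atom."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def _hexagon(center: np.ndarray, normal: np.ndarray,
             first_vertex: np.ndarray) -> np.ndarray:
    """Vertices of a regular hexagon given its center, plane normal and one
    vertex position."""
    radius_vec = first_vertex - center
    verts = [first_vertex]
    for k in range(1, 6):
        rot = Rotation.from_rotvec(normal / np.linalg.norm(normal)
                                   * np.radians(60.0 * k))
        verts.append(center + rot.apply(radius_vec))
    return np.array(verts)


class _ModelGeometry:
    """Deterministic construction of the extended model compound."""

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        n = spec.n_linker_atoms
        coords: list[np.ndarray] = []
        elements: list[str] = []
        names: list[str] = []
        bonds: list[tuple[int, int]] = []

        # --- ring A in the xy-plane, anchor at vertex 0
        center_a = np.array([0.0, 0.0, 0.0])
        anchor_a_pos = np.array([BOND_RING, 0.0, 0.0])
        ring_a = _hexagon(center_a, np.array([0.0, 0.0, 1.0]), anchor_a_pos)
        for k in range(6):
            coords.append(ring_a[k])
            elements.append("C")
            names.append(f"CA{k + 1}")
            bonds.append((k, (k + 1) % 6))
        self.anchor_a = 0

        # --- linker chain, all-anti zigzag
        chain_start = len(coords)
        prev2, prev1 = ring_a[1], ring_a[0]
        prev0 = _place_atom(ring_a[2], prev2, prev1, BOND_CC, 120.0, 180.0)
        coords.append(prev0)
        elements.append("C")
        names.append("CL1")
        bonds.append((self.anchor_a, chain_start))
        for k in range(1, n):
            nxt = _place_atom(prev2, prev1, prev0, BOND_CC, TETRAHEDRAL, 180.0)
            coords.append(nxt)
            elements.append("C")
            names.append(f"CL{k + 1}")
            bonds.append((chain_start + k - 1, chain_start + k))
            prev2, prev1, prev0 = prev1, prev0, nxt
        self.chain = list(range(chain_start, chain_start + n))

        # --- ring B: planar hexagon with a radial exocyclic bond, so the
        # ring extends away from the chain instead of folding back onto it
        anchor_b = len(coords)
        pos = _place_atom(prev2, prev1, prev0, BOND_CC, TETRAHEDRAL, 180.0)
        coords.append(pos)
        elements.append("C")
        names.append("CB1")
        bonds.append((self.chain[-1], anchor_b))
        u = pos - prev0
        u /= np.linalg.norm(u)
        normal = np.cross(u, prev0 - prev1)
        normal /= np.linalg.norm(normal)
        ring_b = _hexagon(pos + BOND_RING * u, normal, pos)
        for k in range(1, 6):
            coords.append(ring_b[k])
            elements.append("C")
            names.append(f"CB{k + 1}")
            bonds.append((anchor_b + k - 1, anchor_b + k))
        bonds.append((anchor_b + 5, anchor_b))
        self.anchor_b = anchor_b
        self.ring_a_atoms = list(range(6))
        self.ring_b_atoms = list(range(anchor_b, anchor_b + 6))

        # --- heteroatoms: acceptor O next to ring A, donor N next to ring B,
        # ether O interspersed along the chain (PEG-like)
        self.acceptor = self.chain[0]
        elements[self.acceptor] = "O"
        names[self.acceptor] = "OA"
        self.donor_n = self.chain[-1]
        elements[self.donor_n] = "N"
        names[self.donor_n] = "ND"
        self.ref_carbon = self.chain[n // 2]
        # exactly two ether oxygens at ~1/3 and ~2/3 of the chain, so the
        # polar-atom inventory does not depend on linker length and ensemble
        # polarity differences reflect folding, not molecule size
        blocked = {0, n - 1, n // 2 - 1, n // 2, n // 2 + 1}
        for target in (n / 3.0, 2.0 * n / 3.0):
            k = min((p for p in range(1, n - 1) if p not in blocked),
                    key=lambda p: abs(p - target))
            blocked.add(k)
            blocked.add(k + 1)  # keep ethers non-adjacent
            idx = self.chain[k]
            elements[idx] = "O"
            names[idx] = f"OL{k}"

        coords_arr = np.array(coords)

        # --- hydrogens: geminal CH2 reference pair, donor NH, ring and
        # mid-chain reporter protons
        def add_h(pos: np.ndarray, name: str, parent: int) -> int:
            idx = len(coords_arr_list)
            coords_arr_list.append(pos)
            elements.append("H")
            names.append(name)
            bonds.append((parent, idx))
            return idx

        coords_arr_list = [c for c in coords_arr]
        graph_neighbors: dict[int, list[int]] = {i: [] for i in range(len(coords))}
        for a, b in bonds:
            if a < len(coords) and b < len(coords):
                graph_neighbors[a].append(b)
                graph_neighbors[b].append(a)

        def gem_h_positions(c: int, n_h: int) -> list[np.ndarray]:
            heavy = [j for j in graph_neighbors[c]]
            p = coords_arr[c]
            u1 = coords_arr[heavy[0]] - p
            u2 = coords_arr[heavy[1]] - p
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            bisector = -(u1 + u2)
            bisector /= np.linalg.norm(bisector)
            perp = np.cross(u1, u2)
            perp /= np.linalg.norm(perp)
            half = np.radians(TETRAHEDRAL / 2.0)
            out = []
            signs = [1.0, -1.0][:n_h]
            for s in signs:
                direction = np.cos(half) * bisector + s * np.sin(half) * perp
                out.append(p + BOND_CH * direction)
            return out

        h1, h2 = gem_h_positions(self.ref_carbon, 2)
        self.ref_h = (add_h(h1, "HR1", self.ref_carbon),
                      add_h(h2, "HR2", self.ref_carbon))
        (hn,) = gem_h_positions(self.donor_n, 1)
        self.nh = add_h(hn, "HN", self.donor_n)
        mid = self.chain[n // 4]
        if elements[mid] != "C":
            mid = self.chain[n // 4 + 1]
        (hm,) = gem_h_positions(mid, 1)
        self.hm = add_h(hm, "HM", mid)
        # ring reporter protons point radially outward from the ring centers
        def ring_h(ring_atoms: list[int], pos_in_ring: int, name: str) -> int:
            center = coords_arr[ring_atoms].mean(axis=0)
            tip = ring_atoms[pos_in_ring]
            direction = coords_arr[tip] - center
            direction /= np.linalg.norm(direction)
            return add_h(coords_arr[tip] + 1.08 * direction, name, tip)

        self.ha = ring_h(self.ring_a_atoms, 3, "HA")
        self.hb = ring_h(self.ring_b_atoms, 3, "HB")
        self.ring_reporters = {
            "HA2": ring_h(self.ring_a_atoms, 2, "HA2"),
            "HA4": ring_h(self.ring_a_atoms, 4, "HA4"),
            "HB2": ring_h(self.ring_b_atoms, 2, "HB2"),
            "HB4": ring_h(self.ring_b_atoms, 4, "HB4"),
        }
        # one reporter proton on every remaining linker carbon, so the
        # restraint network samples the whole chain
        self.chain_reporters: dict[str, int] = {}
        for k, idx in enumerate(self.chain):
            if elements[idx] != "C" or idx in (self.ref_carbon, mid):
                continue
            (hp,) = gem_h_positions(idx, 1)
            self.chain_reporters[f"HL{k + 1}"] = add_h(hp, f"HL{k + 1}", idx)

        self.coords = np.array(coords_arr_list)
        self.elements = elements
        self.names = names
        self.bonds = bonds
        # rotatable backbone bonds: ringA–chain, chain internal, chain–ringB
        self.backbone_bonds = (
            [(self.anchor_a, self.chain[0])]
            + [(self.chain[k], self.chain[k + 1]) for k in range(n - 1)]
            + [(self.chain[-1], self.anchor_b)]
        )
        self._graph = nx.Graph()
        self._graph.add_nodes_from(range(len(self.elements)))
        self._graph.add_edges_from(self.bonds)
        # cache: atoms on the far side of each backbone bond, and the heavy
        # nonbonded pair list (graph separation >= 3) for clash scoring
        self._moving: dict[tuple[int, int], np.ndarray] = {}
        for i, j in self.backbone_bonds:
            g = self._graph.copy()
            g.remove_edge(i, j)
            self._moving[(i, j)] = np.array(
                sorted(nx.node_connected_component(g, j))
            )
        heavy = [k for k, e in enumerate(self.elements) if e != "H"]
        sep = dict(nx.all_pairs_shortest_path_length(self._graph, cutoff=2))
        pair_a, pair_b = [], []
        for ai in range(len(heavy)):
            for bi in range(ai + 1, len(heavy)):
                a, b = heavy[ai], heavy[bi]
                if b not in sep.get(a, {}):
                    pair_a.append(a)
                    pair_b.append(b)
        self._clash_pairs = (np.array(pair_a), np.array(pair_b))

    # -- torsion machinery ---------------------------------------------------

    def rotate_bond(self, coords: np.ndarray, bond: tuple[int, int],
                    delta_deg: float) -> np.ndarray:
        """Rotate everything on the far side of ``bond`` by ``delta_deg``."""
        i, j = bond
        if (i, j) in self._moving:
            moving = self._moving[(i, j)]
        else:
            g = self._graph.copy()
            g.remove_edge(i, j)
            moving = np.array(sorted(nx.node_connected_component(g, j)))
        axis = coords[j] - coords[i]
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * np.radians(delta_deg))
        out = coords.copy()
        out[moving] = rot.apply(out[moving] - coords[j]) + coords[j]
        return out

    def apply_pattern(self, pattern: list[tuple[int, float]]) -> np.ndarray:
        coords = self.coords
        for bond_idx, delta in pattern:
            coords = self.rotate_bond(coords, self.backbone_bonds[bond_idx], delta)
        return coords

    # -- scoring -------------------------------------------------------------

    def _heavy_nonbonded_min(self, coords: np.ndarray) -> float:
        a, b = self._clash_pairs
        return float(np.linalg.norm(coords[a] - coords[b], axis=1).min())

    def extension(self, coords: np.ndarray) -> float:
        cent_a = coords[self.ring_a_atoms].mean(axis=0)
        cent_b = coords[self.ring_b_atoms].mean(axis=0)
        d_ab = float(np.linalg.norm(cent_a - cent_b))
        contour = 0.0
        path = ([self.anchor_a] + self.chain + [self.anchor_b])
        for a, b in zip(path, path[1:]):
            contour += float(np.linalg.norm(coords[a] - coords[b]))
        return d_ab / contour

    def centroid_distance(self, coords: np.ndarray) -> float:
        cent_a = coords[self.ring_a_atoms].mean(axis=0)
        cent_b = coords[self.ring_b_atoms].mean(axis=0)
        return float(np.linalg.norm(cent_a - cent_b))

    def donor_acceptor_distance(self, coords: np.ndarray) -> float:
        return float(np.linalg.norm(coords[self.donor_n] - coords[self.acceptor]))

    def _clash_penalty(self, coords: np.ndarray) -> float:
        dmin = self._heavy_nonbonded_min(coords)
        return 10.0 * max(0.0, 2.2 - dmin)

    # -- template search -----------------------------------------------------

    def polar_exposure(self, coords: np.ndarray) -> float:
        """Mean distance of polar heavy atoms from the heavy-atom centroid —
        a cheap smooth proxy for solvent exposure of the polar groups."""
        heavy = [k for k, e in enumerate(self.elements) if e != "H"]
        polar = [k for k, e in enumerate(self.elements) if e in ("N", "O")]
        centroid = coords[heavy].mean(axis=0)
        return float(np.linalg.norm(coords[polar] - centroid, axis=1).mean())

    def imhb_geometry(self, coords: np.ndarray) -> tuple[float, float]:
        """Donor···acceptor distance (Å) and D–H···A angle (degrees)."""
        d = coords[self.donor_n]
        h = coords[self.nh]
        a = coords[self.acceptor]
        v1 = d - h
        v2 = a - h
        cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
        return float(np.linalg.norm(a - d)), angle

    def _refine(self, bond_indices: list[int], deltas0: np.ndarray,
                objective) -> np.ndarray:
        """Deterministic Nelder–Mead polish of a turn-torsion pattern."""
        from scipy.optimize import minimize

        def cost(deltas):
            coords = self.apply_pattern(list(zip(bond_indices, deltas)))
            return objective(coords)

        res = minimize(cost, deltas0, method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 0.5, "fatol": 1e-4})
        return self.apply_pattern(list(zip(bond_indices, res.x)))

    def build_templates(self) -> dict[str, np.ndarray]:
        """Deterministic torsion-pattern search for the three fold templates.

        Turns are runs of 3–4 consecutive gauche (±120°) torsions, found by
        grid search and polished by derivative-free refinement.  The hairpin
        objective drives the two ring centroids into contact and the built-in
        donor/acceptor pair into hydrogen-bond geometry; the single-turn
        template targets a normalized extension of 0.5; the linear template
        is the unmodified all-anti chain.
        """
        n_bonds = len(self.backbone_bonds)
        templates = {"linear": self.coords}

        def semi_objective(coords):
            return (abs(self.extension(coords) - 0.5)
                    + self._clash_penalty(coords))

        best, best_score = None, np.inf
        for length in (3, 4):
            for p in range(1, n_bonds - length):
                for sign in (120.0, -120.0):
                    idx = list(range(p, p + length))
                    deltas = np.full(length, sign)
                    coords = self.apply_pattern(list(zip(idx, deltas)))
                    score = semi_objective(coords)
                    if score < best_score:
                        best_score, best = score, (idx, deltas)
        templates["semi_folded"] = self._refine(best[0], best[1],
                                                semi_objective)

        def fold_objective(coords):
            d_da, angle = self.imhb_geometry(coords)
            return (
                10.0 * max(0.0, self.extension(coords) - 0.25)
                + max(0.0, d_da - 2.9)
                + 0.05 * max(0.0, 145.0 - angle)
                + 0.3 * max(0.0, self.centroid_distance(coords) - 4.0)
                + 0.2 * self.polar_exposure(coords)
                + self._clash_penalty(coords)
            )

        candidates: list[tuple[float, list[int], np.ndarray]] = []
        for l1, l2 in itertools.product((3, 4), repeat=2):
            for p1 in range(1, n_bonds - l1 - l2 - 1):
                for p2 in range(p1 + l1, n_bonds - l2):
                    for s1, s2 in itertools.product((120.0, -120.0), repeat=2):
                        idx = list(range(p1, p1 + l1)) + list(range(p2, p2 + l2))
                        deltas = np.concatenate(
                            [np.full(l1, s1), np.full(l2, s2)]
                        )
                        coords = self.apply_pattern(list(zip(idx, deltas)))
                        candidates.append((fold_objective(coords), idx, deltas))
        candidates.sort(key=lambda c: c[0])
        refined = [self._refine(idx, deltas, fold_objective)
                   for _, idx, deltas in candidates[:5]]
        templates["folded"] = min(refined, key=fold_objective)
        return templates

    # -- molecule assembly ---------------------------------------------------

    def molecule(self) -> Molecule:
        charges = np.zeros(len(self.elements))
        for k, el in enumerate(self.elements):
            if el == "O":
                charges[k] = -0.4
            elif el == "N":
                charges[k] = -0.4
        charges[self.nh] = 0.3
        atoms = [
            AtomRecord(
                index=k,
                element=el,
                name=self.names[k],
                mass=atomic_mass(el),
                vdw_radius=vdw_radius(el),
                partial_charge=float(charges[k]),
                is_hb_donor_h=(k == self.nh),
                is_hb_acceptor=(self.elements[k] in ("O", "N")
                                and k != self.donor_n),
            )
            for k, el in enumerate(self.elements)
        ]
        proton_groups = {
            "HA": [self.ha],
            "HB": [self.hb],
            "HM": [self.hm],
            "NH": [self.nh],
            "CH2ref": [self.ref_h[0], self.ref_h[1]],
        }
        for label, idx in {**self.ring_reporters,
                           **self.chain_reporters}.items():
            proton_groups[label] = [idx]
        return Molecule(atoms=atoms, bonds=self.bonds,
                        proton_groups=proton_groups)


# geometry and template search depend only on the linker length, so cache
# them across calls (the search costs ~1 s)
_GEO_CACHE: dict[int, _ModelGeometry] = {}
_TEMPLATE_CACHE: dict[int, dict[str, np.ndarray]] = {}


def _geometry(spec: GeneratorSpec) -> _ModelGeometry:
    key = spec.n_linker_atoms
    if key not in _GEO_CACHE:
        _GEO_CACHE[key] = _ModelGeometry(spec)
    return _GEO_CACHE[key]


def _templates(spec: GeneratorSpec) -> dict[str, np.ndarray]:
    key = spec.n_linker_atoms
    if key not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[key] = _geometry(spec).build_templates()
    return _TEMPLATE_CACHE[key]


def build_model_protac(spec: GeneratorSpec) -> Molecule:
    """Topology of the geometric model compound (see module docstring)."""
    return _geometry(spec).molecule()


def ligand_atom_indices(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Atom indices of the two terminal ring 'ligands'."""
    geo = _geometry(spec)
    return np.array(geo.ring_a_atoms), np.array(geo.ring_b_atoms)


def _allocate_counts(n: int, fractions) -> np.ndarray:
    raw = np.asarray(fractions, float) * n
    base = np.floor(raw).astype(int)
    order = np.argsort(-(raw - base))
    for i in order[: n - base.sum()]:
        base[i] += 1
    return base


def default_noe_pairs(mol: Molecule) -> list[DistanceRestraint]:
    """Standard inter-group restraint list for the model compound.

    Distances are placeholders (NaN) until back-calculated or derived;
    ring-to-ring and ring-to-linker pairs carry the long/medium-range
    folding information.
    """
    labels = [g for g in mol.proton_groups if g != "CH2ref"]
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    pairs += [(a, "CH2ref") for a in labels]
    return [
        DistanceRestraint(
            pair_id=f"{a}-{b}", group_a=a, group_b=b,
            distance=float("nan"),
            kind="CH2" if "CH2ref" in (a, b) else "CH",
        )
        for a, b in pairs
    ]


def generate_ensemble(mol: Molecule, spec: GeneratorSpec) -> TruthBundle:
    """Generate a conformer library with exact fold labels.

    Template counts follow ``fold_fractions`` by largest-remainder
    allocation; each conformer gets seeded torsion jitter plus Gaussian
    Cartesian noise.  True weights are uniform (reassign with
    :func:`assign_weights` for known-population studies) and the default
    restraint set is back-calculated under linear averaging.
    """
    geo = _geometry(spec)
    if len(geo.elements) != mol.n_atoms:
        raise DomainError("molecule does not match the generator spec")
    templates = _templates(spec)
    counts = _allocate_counts(spec.n_conformers, spec.fold_fractions)
    rng = np.random.default_rng(spec.seed)

    conformers: list[Conformer] = []
    labels: list[str] = []
    for label, count in zip(FOLD_TEMPLATES, counts):
        base = templates[label]
        for k in range(count):
            coords = base
            if spec.torsion_jitter_deg > 0:
                deltas = rng.normal(0.0, spec.torsion_jitter_deg,
                                    size=len(geo.backbone_bonds))
                work = coords.copy()
                for b_idx, d in enumerate(deltas):
                    work = geo.rotate_bond(work, geo.backbone_bonds[b_idx], d)
                coords = work
            coords = coords + rng.normal(0.0, spec.noise_sigma_xyz,
                                         size=coords.shape)
            conformers.append(
                Conformer(id=f"{label}_{k:03d}", coordinates=coords)
            )
            labels.append(label)

    library = ConformerLibrary(molecule=mol, conformers=conformers,
                               source=f"synthetic seed={spec.seed}")
    weights = np.full(len(conformers), 1.0 / len(conformers))
    restraints = default_noe_pairs(mol)
    matrix = back_calculate(library, restraints)
    return TruthBundle(
        library=library,
        fold_labels=labels,
        true_weights=weights,
        restraints=restraints,
        true_restraint_distances=matrix @ weights,
    )


def assign_weights(bundle: TruthBundle, weights,
                   averaging: str = "linear") -> TruthBundle:
    """Return a copy of ``bundle`` with new true weights and recomputed
    ensemble-averaged restraint distances."""
    w = np.asarray(weights, float)
    matrix = back_calculate(bundle.library, bundle.restraints)
    if averaging == "linear":
        dists = matrix @ w
    elif averaging == "r6":
        dists = (matrix ** -6.0 @ w) ** (-1.0 / 6.0)
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    return TruthBundle(
        library=bundle.library,
        fold_labels=bundle.fold_labels,
        true_weights=w,
        restraints=bundle.restraints,
        true_restraint_distances=dists,
        averaging=averaging,
    )


def _sigma_ref() -> float:
    """Reference buildup rate: normalized intensity σt(1−σt/2) reaches the
    target 0.3 at the canonical 700 ms endpoint."""
    x = 1.0 - np.sqrt(1.0 - 2.0 * REF_INTENSITY_AT_T_MAX)
    return x / CANONICAL_T_MAX


def simulate_noe_buildups(
    bundle: TruthBundle,
    mixing_times=None,
    noise_fraction: float = 0.0,
    seed: int = 0,
    ref_pair_id: str = "ref",
) -> tuple[list[BuildupCurve], dict[str, tuple[str, str]], dict[str, str]]:
    """Simulate NOESY buildup curves from the bundle's true ensemble.

    Rates follow σ_j = σ_ref (r_ref/r_j)⁶ with the ensemble-averaged
    distances of the bundle; intensities are σt(1 − σt/2) with multiplicative
    uniform noise of ±``noise_fraction``; diagonal peaks are synthesized so
    the cross/diagonal normalization recovers the intended intensity.  The
    geminal reference pair (r = 1.78 Å) is included as ``ref_pair_id``.

    Returns the curves plus the pair_id→groups and pair_id→kind maps the
    distance pipeline needs.
    """
    if bundle.true_restraint_distances is None:
        raise DomainError("bundle carries no true restraint distances")
    t = np.asarray(
        mixing_times if mixing_times is not None
        else np.arange(0.1, 0.75, 0.1),
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    sigma_ref = _sigma_ref()

    curves: list[BuildupCurve] = []
    pair_groups: dict[str, tuple[str, str]] = {}
    pair_kinds: dict[str, str] = {}

    def make_curve(pair_id: str, sigma: float) -> BuildupCurve:
        intensity = sigma * t * (1.0 - sigma * t / 2.0)
        noisy = intensity * (1.0 + rng.uniform(-noise_fraction, noise_fraction,
                                               size=t.shape))
        noisy = np.clip(noisy, 0.0, None)
        d1 = np.full_like(t, 100.0)
        d2 = np.full_like(t, 80.0)
        return BuildupCurve(
            pair_id=pair_id,
            mixing_times=t,
            cross_peak_1=noisy * d1,
            cross_peak_2=noisy * d2,
            diagonal_peak_1=d1,
            diagonal_peak_2=d2,
        )

    curves.append(make_curve(ref_pair_id, sigma_ref))
    pair_groups[ref_pair_id] = ("CH2ref", "CH2ref")
    pair_kinds[ref_pair_id] = "CH2"
    for restraint, r in zip(bundle.restraints, bundle.true_restraint_distances):
        sigma = sigma_ref * (DEFAULT_R_REF / r) ** 6
        curves.append(make_curve(restraint.pair_id, sigma))
        pair_groups[restraint.pair_id] = (restraint.group_a, restraint.group_b)
        pair_kinds[restraint.pair_id] = restraint.kind
    return curves, pair_groups, pair_kinds


def random_namfis_system(
    n_conformers: int,
    n_restraints: int,
    support_size: int,
    noise_fraction: float,
    seed: int,
    min_weight: float = 0.08,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A random well-conditioned deconvolution problem with known weights.

    Back-calculated distances are uniform in [2, 5.5] Å (distinct random
    columns), the true support has ``support_size`` conformers with every
    weight at least ``min_weight``, and the experimental distances carry
    multiplicative uniform noise of ±``noise_fraction``.

    Returns (matrix, experimental distances, true weights).
    """
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(2.0, 5.5, size=(n_restraints, n_conformers))
    support = rng.choice(n_conformers, size=support_size, replace=False)
    while True:
        w_support = rng.dirichlet(np.ones(support_size))
        if w_support.min() >= min_weight:
            break
    weights = np.zeros(n_conformers)
    weights[support] = w_support
    d_exp = matrix @ weights
    d_exp = d_exp * (1.0 + rng.uniform(-noise_fraction, noise_fraction,
                                       size=d_exp.shape))
    return matrix, d_exp, weights
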