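"""Conformer shape analysis: PMI ratios, Cartesian PCA, K-means clustering,
diverse-subset selection, fold classification and RMSF.

The normalized principal-moment-of-inertia ratios NPR1 = I₁/I₃ and
NPR2 = I₂/I₃ place every conformation inside the triangle spanned by rod
(0, 1), disc (0.5, 0.5) and sphere (1, 1).  Clustering follows the usual
trajectory-analysis route: superpose all conformers onto a converged mean
structure, run PCA on the flattened Cartesian deviations, and K-means the
leading principal-component scores.  Fold classes (folded / semi-folded /
linear) come from the normalized end-to-end extension of the molecule:
the distance between the two ligand centroids divided by the contour
length of the bonded path connecting them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import Conformer, ConformerLibrary, DomainError, Molecule
from .geometry import superpose_coords

#: Normalized-extension thresholds for fold classes.
DEFAULT_T_FOLDED = 0.35
DEFAULT_T_LINEAR = 0.65

FOLD_CLASSES = ("folded", "semi_folded", "linear")


@dataclass
class ShapeDescriptor:
    conformer_id: str
    npr1: float
    npr2: float

    def __post_init__(self) -> None:
        if not (self.npr1 <= self.npr2 + 1e-9):
            raise DomainError("NPR1 must not exceed NPR2")


@dataclass
class FoldThresholds:
    t_folded: float = DEFAULT_T_FOLDED
    t_linear: float = DEFAULT_T_LINEAR

    def __post_init__(self) -> None:
        if not 0 < self.t_folded < self.t_linear:
            raise DomainError("need 0 < t_folded < t_linear")


@dataclass
class PCAResult:
    scores: np.ndarray                # (n_conformers, n_components)
    explained_variance: np.ndarray    # fraction per component
    mean_structure: np.ndarray        # (n_atoms_subset, 3)


def superpose(reference: Conformer, mobile: Conformer,
              atom_subset=None) -> tuple[Conformer, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The transform is fitted on ``atom_subset`` (all atoms when ``None``)
    and applied to every atom; the returned RMSD is over all atoms.
    """
    idx = None if atom_subset is None else np.asarray(atom_subset)
    coords, rmsd = superpose_coords(reference.coordinates, mobile.coordinates, idx)
    return Conformer(id=mobile.id, coordinates=coords), rmsd


def npr(conformer: Conformer, masses) -> ShapeDescriptor:
    """Normalized PMI ratios from the mass-weighted inertia tensor."""
    m = np.asarray(masses, float)
    xyz = conformer.coordinates
    if xyz.shape[0] < 2:
        raise DomainError("NPR needs >= 2 atoms")
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    d = xyz - com
    if np.allclose(d, 0.0):
        raise DomainError("all atoms coincident: inertia tensor undefined")
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    tensor = np.array([
        [(m * (y**2 + z**2)).sum(), -(m * x * y).sum(), -(m * x * z).sum()],
        [-(m * x * y).sum(), (m * (x**2 + z**2)).sum(), -(m * y * z).sum()],
        [-(m * x * z).sum(), -(m * y * z).sum(), (m * (x**2 + y**2)).sum()],
    ])
    i1, i2, i3 = np.sort(np.linalg.eigvalsh(tensor))
    return ShapeDescriptor(
        conformer_id=conformer.id, npr1=float(i1 / i3), npr2=float(i2 / i3)
    )


def _aligned_frames(frames: np.ndarray, tol: float = 1e-4,
                    max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    aligned = np.array([superpose_coords(frames[0], f)[0] for f in frames])
    mean = aligned.mean(axis=0)
    for _ in range(max_iter):
        aligned = np.array([superpose_coords(mean, f)[0] for f in aligned])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return aligned, mean


def pca_conformers(lib: ConformerLibrary, atom_subset=None,
                   n_components: int = 2) -> PCAResult:
    """PCA of superposed Cartesian coordinates.

    Conformers are iteratively superposed onto their mean structure (shift
    tolerance 1e-4 Å), then PCA runs on the flattened coordinate deviations
    of ``atom_subset`` (all atoms when ``None``).
    """
    if len(lib) < 2:
        raise DomainError("PCA needs >= 2 conformers")
    idx = (np.arange(lib.molecule.n_atoms) if atom_subset is None
           else np.asarray(atom_subset))
    frames = lib.coordinates()[:, idx, :]
    aligned, mean = _aligned_frames(frames)
    flat = (aligned - mean).reshape(len(lib), -1)
    n_comp = min(n_components, len(lib) - 1, flat.shape[1])
    total_var = float(flat.var(axis=0).sum())
    if total_var < 1e-12:
        return PCAResult(
            scores=np.zeros((len(lib), n_comp)),
            explained_variance=np.zeros(n_comp),
            mean_structure=mean,
        )
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(flat)
    return PCAResult(
        scores=scores,
        explained_variance=pca.explained_variance_ratio_,
        mean_structure=mean,
    )


def kmeans_cluster(scores: np.ndarray, k: int = 5, seed: int = 0,
                   n_restarts: int = 10) -> np.ndarray:
    """Best-of-restarts K-means on PC scores.

    Returns 1-based labels renumbered by descending cluster size, so label 1
    is always the most populated cluster and runs are comparable.
    """
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if k > scores.shape[0]:
        raise DomainError(f"k={k} exceeds {scores.shape[0]} points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(scores)
    # stable size ordering: ties broken by original label for determinism
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw])


def diverse_subset(scores: np.ndarray, labels: np.ndarray,
                   per_cluster: int = 26) -> dict[int, np.ndarray]:
    """Greedy max–min (farthest-point) selection within each cluster.

    Selection runs in PC space, seeded from the member nearest the cluster
    centroid; clusters at or under ``per_cluster`` members are returned
    whole.  Deterministic.  Returns cluster label → selected indices (into
    the original score array).
    """
    if per_cluster < 1:
        raise DomainError("per_cluster must be >= 1")
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = np.asarray(labels)
    out: dict[int, np.ndarray] = {}
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        pts = scores[members]
        if members.size <= per_cluster:
            out[int(label)] = members
            continue
        centroid = pts.mean(axis=0)
        start = int(np.argmin(np.linalg.norm(pts - centroid, axis=1)))
        chosen = [start]
        min_d = np.linalg.norm(pts - pts[start], axis=1)
        while len(chosen) < per_cluster:
            nxt = int(np.argmax(min_d))
            chosen.append(nxt)
            min_d = np.minimum(min_d, np.linalg.norm(pts - pts[nxt], axis=1))
        out[int(label)] = members[np.array(chosen)]
    return out


def _anchor_atom(molecule: Molecule, ligand: np.ndarray) -> int:
    """The ligand atom bonded to an atom outside the ligand set."""
    ligand_set = set(int(i) for i in ligand)
    for a, b in molecule.bonds:
        if a in ligand_set and b not in ligand_set:
            return a
        if b in ligand_set and a not in ligand_set:
            return b
    raise DomainError("ligand set has no attachment bond to the rest")


def normalized_extension(conformer: Conformer, molecule: Molecule,
                         ligand_a_atoms, ligand_b_atoms) -> float:
    """Normalized end-to-end extension e = d_AB / contour length.

    d_AB is the distance between the two ligand-set centroids; the contour
    length is the sum of bond lengths along the shortest bonded path
    between the two ligand anchor atoms (the attachment points).
    """
    a = np.asarray(ligand_a_atoms)
    b = np.asarray(ligand_b_atoms)
    if a.size == 0 or b.size == 0:
        raise DomainError("ligand atom sets must be non-empty")
    if set(a.tolist()) & set(b.tolist()):
        raise DomainError("ligand atom sets must be disjoint")
    xyz = conformer.coordinates
    d_ab = float(np.linalg.norm(xyz[a].mean(axis=0) - xyz[b].mean(axis=0)))

    g = nx.Graph()
    g.add_nodes_from(range(molecule.n_atoms))
    for i, j in molecule.bonds:
        g.add_edge(i, j, length=float(np.linalg.norm(xyz[i] - xyz[j])))
    anchor_a = _anchor_atom(molecule, a)
    anchor_b = _anchor_atom(molecule, b)
    try:
        contour = nx.shortest_path_length(
            g, anchor_a, anchor_b, weight="length"
        )
    except nx.NetworkXNoPath as exc:
        raise DomainError("ligand anchors are not connected by bonds") from exc
    if contour <= 0:
        raise DomainError("zero contour length between ligand anchors")
    return d_ab / contour


def classify_fold(conformer: Conformer, molecule: Molecule,
                  ligand_a_atoms, ligand_b_atoms,
                  thresholds: FoldThresholds | None = None) -> str:
    """Classify one conformer as folded, semi-folded or linear.

    Uses the normalized end-to-end extension e: folded below ``t_folded``
    (hairpin with the ligand termini in contact), linear above ``t_linear``
    (near all-anti extension), semi-folded between (a single turn).
    Invariant under rigid motion by construction.
    """
    thresholds = thresholds or FoldThresholds()
    e = normalized_extension(conformer, molecule, ligand_a_atoms, ligand_b_atoms)
    if e < thresholds.t_folded:
        return "folded"
    if e > thresholds.t_linear:
        return "linear"
    return "semi_folded"


def rmsf(lib: ConformerLibrary, atom_subset=None) -> np.ndarray:
    """Per-atom root mean square fluctuation across the library, Å.

    Frames are superposed onto the converged mean structure, fitting on
    ``atom_subset`` (all atoms when ``None``); the fluctuation is reported
    for every atom.
    """
    if len(lib) < 2:
        raise DomainError("RMSF needs >= 2 frames")
    idx = None if atom_subset is None else np.asarray(atom_subset)
    frames = lib.coordinates()
    aligned = np.array(
        [superpose_coords(frames[0], f, idx)[0] for f in frames]
    )
    mean = aligned.mean(axis=0)
    for _ in range(50):
        aligned = np.array(
            [superpose_coords(mean, f, idx)[0] for f in aligned]
        )
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < 1e-4:
            break
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
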