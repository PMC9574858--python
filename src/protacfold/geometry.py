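"""Rigid-body superposition (Kabsch) and RMSD utilities.

All functions operate on plain ``(n, 3)`` float arrays in Å.  The optimal
rotation is always a proper rotation (determinant +1): mirror images are
never superposed onto each other.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


class SuperpositionError(ValueError):
    """Raised when a superposition problem is geometrically degenerate."""


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise SuperpositionError(
            f"superposition needs >= 3 fit atoms, got {coords.shape[0]}"
        )
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise SuperpositionError("fit atoms are collinear or coincident")


def superpose_coords(
    reference: np.ndarray,
    mobile: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares superpose *mobile* onto *reference*.

    The rigid transform (rotation + translation, no reflection) is determined
    on ``fit_indices`` (all atoms when ``None``) and applied to every atom.

    Returns
    -------
    transformed : (n, 3) array
        Mobile coordinates after superposition.
    rmsd : float
        RMSD over **all** atoms after the transform, Å.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape:
        raise ValueError(
            f"coordinate shapes differ: {reference.shape} vs {mobile.shape}"
        )
    idx = np.arange(reference.shape[0]) if fit_indices is None else np.asarray(fit_indices)
    ref_fit = reference[idx]
    mob_fit = mobile[idx]
    _check_fit_atoms(ref_fit)

    ref_center = ref_fit.mean(axis=0)
    mob_center = mob_fit.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_fit - ref_center, mob_fit - mob_center)
    transformed = rot.apply(mobile - mob_center) + ref_center
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - reference) ** 2, axis=1))))
    return transformed, rmsd


def pairwise_rmsd(reference: np.ndarray, mobile: np.ndarray,
                  fit_indices: np.ndarray | None = None) -> float:
    """Best-superposition RMSD between two coordinate sets, Å."""
    _, rmsd = superpose_coords(reference, mobile, fit_indices)
    return rmsd


def iterative_mean_structure(
    frames: np.ndarray, tol: float = 1e-4, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose a stack of frames onto their converged mean structure.

    Frames are first superposed onto the initial frame, then repeatedly onto
    the running mean until the mean shifts by less than ``tol`` Å (RMS).

    Returns the superposed frames ``(m, n, 3)`` and the mean ``(n, 3)``.
    """
    frames = np.asarray(frames, dtype=float)
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
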