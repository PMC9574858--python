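"""NOESY buildup analysis: normalized intensities, initial-rate fits and
interproton distances.

The cross-relaxation rate σ between two protons scales as r⁻⁶ of their
distance, so the initial slope of a NOESY buildup (normalized cross-peak
intensity vs mixing time) yields relative distances once calibrated against
a reference pair of fixed geometry.  Geminal methylene protons (r = 1.78 Å)
serve as that internal reference:

    r_ij = r_ref · (σ_ref / σ_ij)^(1/6)

Only the strictly linear initial part of a buildup is trusted: a fit uses
the longest window of at least four consecutive mixing times whose
least-squares line reaches r² > 0.95, ties broken toward the earliest
start.  Pairs with no such window are rejected as weak or distorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DomainError

#: Geminal methylene H–H distance, Å — the internal calibration standard.
DEFAULT_R_REF = 1.78

#: Restraint sanity window, Å (violations are flagged, not fatal).
DISTANCE_SANITY_WINDOW = (1.5, 6.0)


class WeakNOEError(ValueError):
    """No linear initial-rate window found; the pair must be excluded."""


@dataclass
class BuildupCurve:
    """Time-resolved NOE intensities for one proton pair.

    Cross and diagonal peaks come in symmetric pairs (both sides of the
    diagonal); all intensity lists are index-aligned with ``mixing_times``.
    """

    pair_id: str
    mixing_times: np.ndarray
    cross_peak_1: np.ndarray
    cross_peak_2: np.ndarray
    diagonal_peak_1: np.ndarray
    diagonal_peak_2: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            "mixing_times": self.mixing_times,
            "cross_peak_1": self.cross_peak_1,
            "cross_peak_2": self.cross_peak_2,
            "diagonal_peak_1": self.diagonal_peak_1,
            "diagonal_peak_2": self.diagonal_peak_2,
        }
        for name, a in arrays.items():
            setattr(self, name, np.asarray(a, dtype=float))
        n = self.mixing_times.size
        if n < 4:
            raise DomainError(
                f"pair {self.pair_id}: need >= 4 mixing times, got {n}"
            )
        for name in arrays:
            if getattr(self, name).size != n:
                raise DomainError(
                    f"pair {self.pair_id}: {name} length mismatch"
                )
        if np.any(np.diff(self.mixing_times) <= 0):
            raise DomainError(
                f"pair {self.pair_id}: mixing times must be strictly increasing"
            )


@dataclass
class BuildupFit:
    """Initial-rate fit: buildup rate σ (s⁻¹) and the window it came from."""

    pair_id: str
    sigma: float
    r_squared: float
    window: tuple[int, ...]
    intercept: float = 0.0


@dataclass
class DistanceRestraint:
    """An interproton distance between two proton groups, Å."""

    pair_id: str
    group_a: str
    group_b: str
    distance: float
    kind: str = "CH"
    r_squared: float = float("nan")
    in_sanity_window: bool = True

    def __post_init__(self) -> None:
        lo, hi = DISTANCE_SANITY_WINDOW
        self.in_sanity_window = bool(lo <= self.distance <= hi)


@dataclass
class TempCoefficient:
    """NH chemical-shift temperature coefficient Δδ/T in ppb/K."""

    nh_label: str
    delta_delta_per_T: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_delta_per_T):
            raise DomainError(f"{self.nh_label}: non-finite temperature coefficient")


def normalize_noe(cross_1, cross_2, diagonal_1, diagonal_2,
                  pair_id: str = "?") -> np.ndarray | float:
    """Normalize cross peaks to diagonal peaks: ((c1·c2)/(d1·d2))^0.5.

    The geometric mean of the two cross/diagonal ratios cancels unequal
    magnetization of the two protons.  Accepts scalars or aligned arrays.
    """
    c1, c2 = np.asarray(cross_1, float), np.asarray(cross_2, float)
    d1, d2 = np.asarray(diagonal_1, float), np.asarray(diagonal_2, float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise DomainError(f"pair {pair_id}: diagonal peaks must be positive")
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise DomainError(
            f"pair {pair_id}: cross peaks must be phase-corrected magnitudes >= 0"
        )
    result = np.sqrt((c1 * c2) / (d1 * d2))
    return float(result) if result.ndim == 0 else result


def _window_r2_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(t, y)
    return res.rvalue**2, res.slope, res.intercept


def fit_buildup(curve: BuildupCurve, min_points: int = 4,
                r2_min: float = 0.95) -> BuildupFit:
    """Fit the initial buildup rate σ from the linear part of the curve.

    Normalized intensities are regressed on mixing time (unconstrained
    intercept) over every window of >= ``min_points`` consecutive points;
    among windows with r² > ``r2_min`` the longest wins, ties going to the
    earliest start.  σ is the slope of that line.

    Raises :class:`WeakNOEError` if no window qualifies.
    """
    y = normalize_noe(
        curve.cross_peak_1, curve.cross_peak_2,
        curve.diagonal_peak_1, curve.diagonal_peak_2,
        pair_id=curve.pair_id,
    )
    t = curve.mixing_times
    n = t.size
    best: tuple[int, int] | None = None  # (length, -start) ordering key
    best_fit: tuple[float, float, float, tuple[int, ...]] | None = None
    for start in range(0, n - min_points + 1):
        for stop in range(start + min_points, n + 1):
            r2, slope, intercept = _window_r2_slope(t[start:stop], y[start:stop])
            if r2 > r2_min:
                key = (stop - start, -start)
                if best is None or key > best:
                    best = key
                    best_fit = (slope, intercept, r2,
                                tuple(range(start, stop)))
    if best_fit is None:
        raise WeakNOEError(
            f"pair {curve.pair_id}: no linear window of >= {min_points} "
            f"consecutive points with r^2 > {r2_min} (weak/distorted NOE)"
        )
    slope, intercept, r2, window = best_fit
    return BuildupFit(pair_id=curve.pair_id, sigma=slope, r_squared=r2,
                      window=window, intercept=intercept)


def distance_from_rates(sigma_ij: float, sigma_ref: float,
                        r_ref: float = DEFAULT_R_REF) -> float:
    """Interproton distance from buildup rates: r_ref · (σ_ref/σ_ij)^(1/6)."""
    if sigma_ij <= 0 or sigma_ref <= 0:
        raise DomainError("buildup rates must be positive")
    if r_ref <= 0:
        raise DomainError("reference distance must be positive")
    return float(r_ref * (sigma_ref / sigma_ij) ** (1.0 / 6.0))


def derive_restraints(
    curves: list[BuildupCurve],
    ref_pair_id: str,
    pair_groups: dict[str, tuple[str, str]],
    pair_kinds: dict[str, str] | None = None,
    r_ref: float = DEFAULT_R_REF,
    min_points: int = 4,
    r2_min: float = 0.95,
) -> tuple[list[DistanceRestraint], list[str]]:
    """Run the full buildup → distance pipeline over a set of curves.

    ``pair_groups`` maps pair ids to their (group_a, group_b) labels and
    ``pair_kinds`` to the multiplicity kind (CH/CH2/CH3, default CH).
    Returns the derived restraints plus the ids of pairs rejected as weak.
    The reference pair itself yields ``r_ref`` by construction and is not
    emitted as a restraint.
    """
    fits: dict[str, BuildupFit] = {}
    rejected: list[str] = []
    for curve in curves:
        try:
            fits[curve.pair_id] = fit_buildup(curve, min_points, r2_min)
        except WeakNOEError:
            rejected.append(curve.pair_id)
    if ref_pair_id not in fits:
        raise DomainError(f"reference pair {ref_pair_id!r} has no valid fit")
    sigma_ref = fits[ref_pair_id].sigma
    restraints = []
    for pid, fit in fits.items():
        if pid == ref_pair_id:
            continue
        ga, gb = pair_groups[pid]
        kind = (pair_kinds or {}).get(pid, "CH")
        restraints.append(
            DistanceRestraint(
                pair_id=pid, group_a=ga, group_b=gb,
                distance=distance_from_rates(fit.sigma, sigma_ref, r_ref),
                kind=kind, r_squared=fit.r_squared,
            )
        )
    return restraints, rejected


def classify_temp_coefficient(tc: TempCoefficient,
                              threshold: float = 3.0) -> str:
    """Interpret an NH temperature coefficient.

    |Δδ/T| below ``threshold`` (ppb/K) indicates an NH shielded from solvent
    or held in a strong intramolecular hydrogen bond; larger magnitudes
    indicate an environment that changes with temperature.  The inequality
    is strict, so exactly-threshold values read as variable.
    """
    if abs(tc.delta_delta_per_T) < threshold:
        return "shielded_or_strong_IMHB"
    return "variable_environment"
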