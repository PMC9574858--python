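"""Permeability surrogates from cellular vs biochemical potency, and the
descriptor-vs-permeability concordance report.

A degrader must cross the cell membrane before it can engage its target, so
the ratio between its cellular and biochemical (cell-free) potencies is a
surrogate for passive permeability: a highly permeable compound loses little
potency moving from the biochemical to the cellular assay (low ratio), a
poorly permeable one loses much (high ratio).  Caco-2 passive permeability
is summarized as the geometric mean of the apical→basolateral and
basolateral→apical apparent permeabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DomainError


@dataclass
class PotencyRecord:
    compound_id: str
    ic50_cell: float   # μM
    ic50_bio: float    # μM

    def __post_init__(self) -> None:
        if self.ic50_cell <= 0 or self.ic50_bio <= 0:
            raise DomainError(f"{self.compound_id}: IC50 values must be > 0")


@dataclass
class PermeabilityRecord:
    compound_id: str
    cell_bio_ratio: float
    papp_ab: float | None = None   # nm/s
    papp_ba: float | None = None   # nm/s
    p_passive: float | None = None  # nm/s

    def __post_init__(self) -> None:
        if self.cell_bio_ratio <= 0:
            raise DomainError(f"{self.compound_id}: ratio must be > 0")
        if self.p_passive is not None and self.p_passive <= 0:
            raise DomainError(f"{self.compound_id}: p_passive must be > 0")


def cell_bio_ratio(ic50_cell: float, ic50_bio: float) -> tuple[float, int]:
    """Cellular/biochemical IC50 ratio and its nearest-integer display value.

    Rounding is to the nearest integer with ties away from zero (so 3.5
    displays as 4), matching how such ratios are conventionally tabulated.
    """
    if ic50_cell <= 0 or ic50_bio <= 0:
        raise DomainError("IC50 values must be positive")
    ratio = ic50_cell / ic50_bio
    display = int(math.floor(ratio + 0.5))
    return ratio, display


def passive_permeability(papp_ab: float, papp_ba: float) -> float:
    """Passive permeability as the geometric mean of Papp AB and Papp BA."""
    if papp_ab <= 0 or papp_ba <= 0:
        raise DomainError("apparent permeabilities must be positive")
    return math.sqrt(papp_ab * papp_ba)


def records_from_assays(df: pd.DataFrame) -> list[PermeabilityRecord]:
    """Build permeability records from an assay table.

    Expected columns: ``compound_id, ic50_cell_uM, ic50_bio_uM`` and
    optionally either ``papp_ab_nm_s, papp_ba_nm_s`` (P_passive is then
    their geometric mean) or a precomputed ``p_passive_nm_s``.
    """
    records = []
    for _, row in df.iterrows():
        ratio, _ = cell_bio_ratio(row["ic50_cell_uM"], row["ic50_bio_uM"])
        papp_ab = row.get("papp_ab_nm_s")
        papp_ba = row.get("papp_ba_nm_s")
        has_papp = (
            papp_ab is not None and papp_ba is not None
            and np.isfinite(papp_ab) and np.isfinite(papp_ba)
        )
        p_passive = row.get("p_passive_nm_s")
        if has_papp:
            p_passive = passive_permeability(papp_ab, papp_ba)
        elif p_passive is None or not np.isfinite(p_passive):
            p_passive = None
        records.append(
            PermeabilityRecord(
                compound_id=str(row["compound_id"]),
                cell_bio_ratio=ratio,
                papp_ab=float(papp_ab) if has_papp else None,
                papp_ba=float(papp_ba) if has_papp else None,
                p_passive=p_passive,
            )
        )
    return records


def _permeability_score(record: PermeabilityRecord) -> float:
    """Higher = more permeable.  Prefers measured P_passive; falls back to
    the inverse cell/bio ratio (a low ratio means high permeability)."""
    if record.p_passive is not None:
        return record.p_passive
    return 1.0 / record.cell_bio_ratio


def rank_report(
    records: list[PermeabilityRecord],
    ensemble_means: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Join permeability surrogates to ensemble descriptor means and score
    the rank concordance between low polarity and high permeability.

    ``ensemble_means`` maps compound id to the population-weighted
    descriptor means (keys ``sa3dpsa_A2, r_gyr_A, n_imhb``) of its
    conformational ensemble.  The returned DataFrame carries one row per
    compound plus attrs ``spearman_sa3dpsa`` (Spearman correlation between
    −SA 3D PSA and the permeability score; sign agreement for only two
    compounds) and ``discordant_pairs``.
    """
    if len(records) < 2:
        raise DomainError("ranking needs >= 2 compounds")
    rows = []
    for rec in records:
        if rec.compound_id not in ensemble_means:
            raise DomainError(
                f"no descriptor table for compound {rec.compound_id!r}"
            )
        means = ensemble_means[rec.compound_id]
        rows.append({
            "compound_id": rec.compound_id,
            "cell_bio_ratio": rec.cell_bio_ratio,
            "p_passive_nm_s": rec.p_passive,
            "permeability_score": _permeability_score(rec),
            "mean_sa3dpsa_A2": means["sa3dpsa_A2"],
            "mean_r_gyr_A": means["r_gyr_A"],
            "mean_n_imhb": means["n_imhb"],
        })
    report = pd.DataFrame(rows)

    polarity = -report["mean_sa3dpsa_A2"].to_numpy()
    perm = report["permeability_score"].to_numpy()
    if len(report) == 2:
        concordance = float(np.sign(polarity[1] - polarity[0])
                            * np.sign(perm[1] - perm[0]))
    else:
        concordance = float(stats.spearmanr(polarity, perm).statistic)

    discordant = []
    ids = report["compound_id"].tolist()
    for i in range(len(report)):
        for j in range(i + 1, len(report)):
            if (polarity[i] - polarity[j]) * (perm[i] - perm[j]) < 0:
                discordant.append((ids[i], ids[j]))

    report.attrs["spearman_sa3dpsa"] = concordance
    report.attrs["discordant_pairs"] = discordant
    return report
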