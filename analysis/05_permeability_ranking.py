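#!/usr/bin/env python
"""Rank the compound series: ensemble polarity vs permeability surrogates.

Joins the assay table (cell/biochemical IC50 pairs and Caco-2 passive
permeabilities from data/assays.csv) with the population-weighted ensemble
descriptor means from 04_ensemble_descriptors.py, and reports the Spearman
concordance between low SA 3D PSA and high permeability together with any
discordant compound pairs.

Run after 04:
    python analysis/05_permeability_ranking.py
"""

import json
from pathlib import Path

import pandas as pd

from protacfold.io import read_assay_table
from protacfold.permeability import rank_report, records_from_assays

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"


def main() -> None:
    assays = read_assay_table(REPO / "data" / "assays.csv")
    records = records_from_assays(assays)
    summary = pd.read_csv(RESULTS / "descriptor_summary.csv")
    means_by = {
        row.compound_id: {
            "sa3dpsa_A2": row.mean_sa3dpsa_A2,
            "r_gyr_A": row.mean_r_gyr_A,
            "n_imhb": row.mean_n_imhb,
        }
        for row in summary.itertuples()
    }

    report = rank_report(records, means_by)
    report.to_csv(RESULTS / "permeability_ranking.csv", index=False)
    meta = {
        "spearman_sa3dpsa_vs_permeability": report.attrs["spearman_sa3dpsa"],
        "discordant_pairs": report.attrs["discordant_pairs"],
    }
    (RESULTS / "permeability_ranking.json").write_text(
        json.dumps(meta, indent=2))

    print(report.to_string(index=False))
    print(f"\nconcordance (low polarity ~ high permeability): "
          f"{meta['spearman_sa3dpsa_vs_permeability']:.2f}; "
          f"discordant pairs: {meta['discordant_pairs'] or 'none'}")


if __name__ == "__main__":
    main()
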