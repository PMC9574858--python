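#!/usr/bin/env python
"""Deconvolute a known-weight ensemble from its NOE-derived distances.

Builds a five-conformer library with assigned populations
(0.35/0.25/0.20/0.15/0.05), pushes it through the full pipeline —
simulated buildups (1% noise) → distance restraints → constrained
least-squares population fit — and validates the fit by 10% noise
injection and restraint jackknife.  The fitted populations, their
recovery error against the generator truth, and the validation verdict
are written as JSON.

Run from the repository root:
    python analysis/03_fit_populations.py [--seed 17]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from protacfold.namfis import back_calculate, fit_populations, validate_fit
from protacfold.noe import derive_restraints
from protacfold.synthetic import (
    GeneratorSpec,
    assign_weights,
    build_model_protac,
    generate_ensemble,
    simulate_noe_buildups,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
TRUE_WEIGHTS = [0.35, 0.25, 0.2, 0.15, 0.05]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()

    spec = GeneratorSpec(n_linker_atoms=12, n_conformers=5,
                         fold_fractions=(0.4, 0.4, 0.2),
                         noise_sigma_xyz=0.05, seed=args.seed)
    mol = build_model_protac(spec)
    bundle = assign_weights(generate_ensemble(mol, spec), TRUE_WEIGHTS)

    curves, groups, kinds = simulate_noe_buildups(
        bundle, mixing_times=np.linspace(0.005, 0.035, 7),
        noise_fraction=0.01, seed=args.seed,
    )
    restraints, rejected = derive_restraints(curves, "ref", groups, kinds)
    matrix = back_calculate(bundle.library, restraints)
    fit = fit_populations(matrix, [r.distance for r in restraints])
    report = validate_fit(matrix, [r.distance for r in restraints], fit,
                          noise_fraction=0.10, n_trials=50, seed=args.seed)

    out = {
        "seed": args.seed,
        "n_restraints": fit.n_restraints,
        "rejected_pairs": rejected,
        "true_weights": TRUE_WEIGHTS,
        "fitted_weights": [round(float(w), 4) for w in fit.weights],
        "degenerate_conformer_pairs": fit.degenerate_pairs,
        "max_weight_error": round(
            float(np.abs(fit.weights - bundle.true_weights).max()), 4),
        "fit_rmsd_A": round(fit.fit_rmsd, 4),
        "aic": round(fit.aic, 2),
        "selected_conformers": fit.selected.tolist(),
        "validation": {
            "mean_noise_drift": round(float(report.noise_perturbation.mean()), 4),
            "max_jackknife_drift": round(float(report.jackknife.max()), 4),
            "stable": report.stable,
        },
    }
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / "population_fit.json"
    path.write_text(json.dumps(out, indent=2))
    print(f"fitted populations {out['fitted_weights']} vs truth "
          f"{TRUE_WEIGHTS}; max error {out['max_weight_error']}; "
          f"stable={report.stable} -> {path}")
    if not report.stable and fit.degenerate_pairs:
        print("note: conformers from the same fold template have "
              f"near-duplicate distance columns {fit.degenerate_pairs}; "
              "noise shuffles population between them, which the "
              "validation correctly flags (total per-template population "
              "is what the data determine)")


if __name__ == "__main__":
    main()
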