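# protacfold

Conformational-ensemble analysis for bifunctional degraders (PROTACs):
from NOESY buildup intensities to solution conformer populations, and from
those populations to the ensemble polarity and shape descriptors that
rationalize passive cell permeability.

PROTACs live far beyond rule-of-5 space, yet some cross cell membranes
well. The working explanation is *chameleonicity*: in an apolar environment
a flexible degrader can fold, form intramolecular hydrogen bonds, and hide
its polarity, presenting a smaller and less polar surface to the membrane.
This package implements the complete analysis chain used to test that idea
on a ligand–linker–ligand architecture:

1. **NOE distances** (`protacfold.noe`) — normalized NOESY buildup
   intensities ((c₁·c₂)/(d₁·d₂))^½, initial-rate fits over the strictly
   linear window (≥ 4 consecutive mixing times, r² > 0.95), and distances
   from the isolated spin-pair relation r_ij = r_ref·(σ_ref/σ_ij)^(1/6)
   with the geminal methylene reference r_ref = 1.78 Å.  NH temperature
   coefficients are classified by the |Δδ/T| < 3 ppb/K rule.
2. **Population deconvolution** (`protacfold.namfis`) — NAMFIS-style
   constrained least squares: min‖d_exp − d_ens(w)‖² over the probability
   simplex, with CH₂/CH₃ pseudo-atoms combined by r⁻⁶ averaging,
   d = (((d₁⁻⁶)+(d₂⁻⁶))/2)^(−1/6).  Fits are scored by
   AIC = n·ln(SSE/n) + 2k and validated by 10 % noise injection and
   restraint jackknife.
3. **Ensemble descriptors** (`protacfold.descriptors`) — mass-weighted
   radius of gyration, Shrake–Rupley SASA (probe 1.4 Å), solvent-accessible
   3D polar surface area (SA 3D PSA), and geometric intramolecular
   hydrogen-bond counts, all population-weighted.
4. **Shape and clustering** (`protacfold.shape`) — normalized PMI ratios
   (NPR1 = I₁/I₃, NPR2 = I₂/I₃), Kabsch superposition, Cartesian PCA,
   K-means clustering (k = 5), diverse max–min subsets, automated
   folded / semi-folded / linear classification, and RMSF.
5. **Permeability surrogates** (`protacfold.permeability`) — the
   cellular/biochemical IC50 ratio (low ratio ⇒ high permeability),
   P_passive = (P_app,AB·P_app,BA)^½, and the rank-concordance report
   linking low ensemble polarity to high permeability.
6. **Synthetic truth** (`protacfold.synthetic`) — a geometric model
   degrader (two ring "ligands", tetrahedral linker, built-in donor/acceptor
   pair) whose folded / semi-folded / linear templates, fold mixtures and
   NOE buildups are generated with exactly known ground truth, so every
   stage above is testable end to end.

Everything I/O-facing goes through standard formats: multi-model PDB, SDF
V2000, multi-frame XYZ for conformer libraries (biotite underneath), plain
CSV for buildup, restraint and assay tables.

## Worked example

The numbered scripts under `analysis/` run the whole study on the three
synthetic compounds (`protac1` mostly folded with a 12-atom linker,
`protac2` mixed, `protac3` mostly linear):

```bash
python analysis/01_simulate_ensembles.py   # libraries + NOE buildups
python analysis/02_derive_distances.py     # buildups -> distance restraints
python analysis/03_fit_populations.py      # NAMFIS fit + validation
python analysis/04_ensemble_descriptors.py # descriptors, PCA, clusters, folds
python analysis/05_permeability_ranking.py # polarity vs permeability
```

Step 03 deconvolutes a five-conformer ensemble with assigned populations
0.35/0.25/0.20/0.15/0.05 from its simulated buildups and prints

```
fitted populations [0.3452, 0.2572, 0.1985, 0.1518, 0.0473] vs truth
[0.35, 0.25, 0.2, 0.15, 0.05]; max error 0.0072; stable=False
```

— the populations come back within 0.01 although the validation correctly
flags that two conformers built from the same fold template are
near-degenerate (noise shuffles population between them; only their sum is
determined by the data).  Steps 04–05 then show the permeability story:

```
protac1: mean R_gyr 4.20 A, SA 3D PSA 61.4 A^2, #IMHB 0.43
protac2: mean R_gyr 4.00 A, SA 3D PSA 64.1 A^2, #IMHB 0.17
protac3: mean R_gyr 4.93 A, SA 3D PSA 74.0 A^2, #IMHB 0.05
concordance (low polarity ~ high permeability): 1.00; discordant pairs: none
```

The mostly-folded compound hides the most polar surface and forms the most
internal hydrogen bonds; ranking compounds by −SA 3D PSA reproduces the
permeability ordering implied by the assay surrogates (cell/bio IC50
ratios 4, 12, 27; P_passive 30, 11, 6 nm/s) exactly.

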