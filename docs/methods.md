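# Methods

## The problem and the model

A flexible bifunctional degrader samples an ensemble of conformations in
solution. NMR observables are time averages over that ensemble, so a single
structure cannot explain them; instead, the analysis deconvolutes
time-averaged interproton distances into a discrete set of conformers with
population weights, then asks whether the population-weighted polarity and
size of the ensemble track the molecule's passive membrane permeability.
The package implements that chain as a library (`src/protacfold/`) with
numbered analysis drivers (`analysis/`).

## NOE distances

Normalized intensity for a proton pair is the geometric mean of the two
cross/diagonal ratios, ((c₁·c₂)/(d₁·d₂))^½, which cancels unequal
equilibrium magnetization. The buildup rate σ is the slope of normalized
intensity vs mixing time over the **longest** window of at least
`min_points = 4` consecutive mixing times whose regression reaches
r² > 0.95, ties broken toward the earliest start; the intercept is left
free (nothing forces the line through the origin, and a free intercept
absorbs small zero-offsets). Pairs with no qualifying window are rejected
as weak/distorted and excluded downstream. Distances follow the isolated
spin-pair relation r_ij = r_ref·(σ_ref/σ_ij)^(1/6) against the geminal
methylene reference r_ref = 1.78 Å. Restraints outside a configurable
1.5–6.0 Å sanity window are flagged (`in_sanity_window=False`) but not
dropped: distances beyond ~6 Å are outside the NOE's observable range and
should not be trusted quantitatively.

NH temperature coefficients classify as shielded/strong-IMHB when
|Δδ/T| < 3 ppb/K (strict inequality), else variable-environment.

## Population deconvolution

Given a back-calculation matrix D (restraints × conformers, every CH₂/CH₃
pseudo-atom distance combined by the r⁻⁶ mean over member proton pairs —
the group-to-group generalization reduces to d = (((d₁⁻⁶)+(d₂⁻⁶))/2)^(−1/6)
for a methylene), the fit solves

    min_w ‖d_exp − d_ens(w)‖²,  w ≥ 0, Σw = 1

with linear ensemble averaging d_ens = D·w by default; r⁻⁶ ensemble
averaging (d_ens = (D⁻⁶·w)^(−1/6)) is available by flag since the
literature is not unanimous on the convention. The linear problem is a
convex NNLS solved on an augmented system (the simplex constraint as a
heavily weighted row, weight 10⁶ × the matrix scale, followed by exact
renormalization); the r⁻⁶ problem uses SLSQP with an analytic gradient from
a uniform start. Both are deterministic. Conformer pairs whose
back-calculated distance columns correlate above 0.999 are reported as
degenerate rather than silently resolved — any weight split between them
fits equally well.

Model comparison uses the least-squares AIC, n·ln(SSE/n) + 2k, with k the
number of conformers at or above the 1 % report threshold; |ΔAIC| < 2
reads as "equivalent".

**Validation.** Noise trials refit with every distance multiplied by
(1+u), u ~ U(−0.10, 0.10); the jackknife refits with each restraint
removed. A fit is *stable* iff the mean per-trial noise drift and the
maximum jackknife drift are both below 0.10 absolute population. The noise
scheme is summarized by its mean because the maximum of a bounded-noise
statistic grows with the number of trials, which would tie the verdict to
`n_trials` rather than to the conditioning of the system. A jackknife step
that removes the last restraint leaves the populations unconstrained and is
reported as the maximal drift of 1.

## Descriptors

* **R_gyr** — mass-weighted, about the center of mass; masses from
  standard atomic weights.
* **SASA** — Shrake–Rupley with Bondi radii, probe 1.4 Å, and a
  deterministic Fibonacci point set (960 points/atom by default), so
  results are reproducible bit-for-bit at fixed `n_points`. An independent
  implementation (biotite) cross-checks totals in the test suite.
* **SA 3D PSA** — SASA summed over polar atoms. An atom is polar iff
  |partial charge| > 0.1 e; when charges are absent (structure formats do
  not carry them) an element fallback engages automatically: N/O/S, plus
  hydrogens bonded to them. The threshold is a config knob because
  published per-atom-charge protocols differ; absolute values therefore
  support *ordering* claims, not cross-software bit equality.
* **IMHB** — donor-H···acceptor triples with D···A ≤ 3.5 Å,
  D–H···A ≥ 135°, donor and acceptor ≥ 4 bonds apart. Conventional
  trajectory-analysis defaults; all three are configurable.

## Shape, clustering, fold classes

Superposition is proper-rotation Kabsch (no reflection); PCA runs on
flattened Cartesian deviations after iterative superposition onto the mean
structure (shift tolerance 1e-4 Å). K-means (k = 5, best of 10 restarts,
seeded) labels are renumbered by descending cluster size so runs are
comparable. Diverse subsets (26 per cluster by default) use deterministic
greedy max–min selection in PC space seeded from the centroid-nearest
member.

Fold classification is automated: e = d_AB / L, where d_AB is the distance
between the two ligand-set centroids and L the contour length of the
shortest bonded path between the ligand attachment atoms. e < 0.35 reads
folded, e > 0.65 linear, between semi-folded. The thresholds were placed
against the generator's template geometry (hairpin e ≈ 0.20–0.25,
single-turn ≈ 0.50, all-anti > 0.9) and are configurable; the classifier is
rigid-motion invariant by construction.

## The synthetic generator

The model compound is geometric, not physical: two planar six-membered
rings joined by a tetrahedral-chain linker (1.5 Å bonds; 1.4 Å in rings),
an acceptor ether oxygen next to ring A, a donor N–H next to ring B, and
exactly two more ether oxygens at ~1/3 and ~2/3 of the chain regardless of
linker length — so polarity differences between compounds reflect folding,
not atom count. Reporter protons sit on both rings and on every remaining
linker carbon (~14 proton groups, ~50–100 restraints), matching the density
of a real NOE network; a geminal CH₂ pair provides the 1.78 Å reference.

Fold templates are built by a deterministic torsion search: runs of 3–4
gauche (±120°) torsions placed by grid search and polished by Nelder–Mead.
The hairpin objective drives extension below 0.25, ring centroids into
contact (≤ 4–5 Å), and the donor/acceptor pair into hydrogen-bond geometry
(D···A ≤ 2.9 Å, angle ≥ 145°) while penalizing heavy-atom clashes
(< 2.2 Å) and polar-atom exposure; the single-turn template targets
e = 0.5; the linear template is the unmodified all-anti chain. No force
field is involved, so fold labels are exact by construction.

Ensembles mix templates in stated proportions (largest-remainder
allocation, so counts are exact), then perturb each conformer with Gaussian
torsion jitter (default 5°) and Cartesian noise (default 0.1 Å). The
presets span the permeability series: `protac1` = 12-atom linker,
fractions (0.6, 0.3, 0.1); `protac2` = 8 atoms, (0.3, 0.4, 0.3);
`protac3` = 8 atoms, (0.1, 0.2, 0.7).

Simulated buildups follow σ_j = σ_ref·(r_ref/r_j)⁶ on the ensemble-averaged
distances, with intensities σt·(1 − σt/2): the quadratic term mimics the
curvature that truncates real initial-rate windows, and its magnitude is
set by calibrating σ_ref so the reference intensity reaches 0.3 at the
canonical 700 ms endpoint of the seven-point 100–700 ms experiment design.
That calibration is deliberately independent of the schedule passed to the
simulator, so short schedules (e.g. 5–35 ms) genuinely probe the
initial-rate regime: at 100–700 ms the linear fit understates the reference
slope by ~2 % (a ~0.4 % distance bias), at 5–35 ms the round trip recovers
observable-range distances to better than 0.02 Å. Diagonal peaks are
synthesized (100/80 intensity units) so the cross/diagonal normalization
returns exactly the intended value.

**What the generator does not emulate:** force-field energetics and
Boltzmann populations, spin diffusion and relaxation-pathway interference,
chemical-shift overlap, solvent effects, and real PROTAC chemistry
(valences are geometric). Passing tests therefore demonstrate that the
*analysis chain* is correct and well-conditioned under realistic geometry
and noise — not that any particular real compound folds.

## Problem sizes

The analysis drivers and the acceptance script use 60-conformer ensembles
per preset, 5-conformer known-weight systems for deconvolution round trips,
100 random deconvolution problems (5–20 conformers, 15–40 restraints,
1 % multiplicative noise) for recovery statistics, and 50 noise trials for
validation — sizes at which every stage's behavior is already asymptotic
while the full pipeline runs in a few minutes on one CPU.

## Known limitations

* Linear vs r⁻⁶ ensemble averaging changes fitted populations when
  ensembles are broad; the package defaults to linear and exposes the
  switch rather than claiming one convention is right.
* Conformers with near-duplicate back-calculated distances are
  fundamentally non-identifiable; the fit reports the degeneracy and the
  validation flags the resulting instability, but only external information
  can split such populations.
* Absolute SA 3D PSA values depend on the polar-atom definition and radii;
  use them for within-study ordering.
* The fold classifier is a geometric proxy; for molecules whose ligands are
  flexible or whose linker branches, the extension statistic needs
  re-calibration.
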