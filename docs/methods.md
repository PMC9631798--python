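# Methods

## The binding model

`icbind` models the equilibrium binding of IL-2-bearing ligands — free IL-2
(valency 1) or single-chain immunocytokines carrying two IL-2 modules
(valency 2) — to cells displaying IL-2Rα and a composite IL-2Rβ/γc site.
Each IL-2 module can engage one IL-2Rα and one IL-2Rβ/γc simultaneously, so a
bivalent ligand can hold up to two receptors of each class. The first
ligand–cell bond forms from solution with the monomeric affinity; every
additional bond by the tethered ligand forms with weight proportional to the
free receptor abundance, the monomeric association constant, and a
crosslinking constant Kx\* that converts a solution affinity into an
on-surface crosslinking weight.

With χ_j = Kx\*·R_j,eq/K_D,j for receptor class j, each IL-2 module
contributes a factor m = (1 + χ_α)(1 + χ_βγ) to the bound-ligand partition
sum, giving closed forms

- bound-ligand weight W = (L0/Kx\*)(m^v − 1),
- bound receptors of class j: B_j = (L0/Kx\*)·v·m^(v−1)·χ_j·(1 + χ_other).

These are the derivative identities of the product form: Σ_configs (#j bonds)
× weight = χ_j ∂/∂χ_j of the partition sum. The test suite verifies the
closed forms against an exhaustive enumeration of all 4^v module-state
configurations, which shares no code with the solver.

Free receptor abundances are fixed by receptor conservation
R_j,tot = R_j,eq + B_j(R_eq); ligand is not depleted (cell-culture
stimulation at these receptor densities consumes a negligible ligand
fraction). pSTAT5 is taken proportional to bound IL-2Rβ/γc — the species
that signals through JAK/STAT — with a scale factor per (experiment, cell
type).

Assumptions worth keeping in mind: β and γc are collapsed into one composite
site (no trimeric assembly sequence), binding is at equilibrium (20-minute
stimulations are treated as equilibrated), and Fc–FcγR interactions are
ignored.

### Numerics

The two conservation equations are solved by a damped (λ = 0.5) Picard
iteration on the map R_j ← R_j,tot/(1 + B_j/R_j), taken in log space so
iterates stay positive; B_j/R_j,eq is independent of R_j,eq at fixed χ of the
other class, which makes the map well conditioned. Convergence is declared at
a relative conservation residual ≤ 1e−10 per class (iteration cap 1e5); a
`scipy.optimize.root` (hybr) fallback on log-abundances covers the rare
non-contracting corner, and failure past both raises a solver error carrying
the final residual. Two limits are handled analytically: L0 = 0 (nothing
bound) and Kx\* = 0, where the classes decouple into independent single-bond
Langmuir isotherms. A "non-binding" IL-2Rβ/γc site (the fully blocked
epitope of an intramolecularly assembled IC) is the sentinel χ = 0 exactly,
not a large K_D, to avoid overflow; a receptor class with zero surface
abundance is likewise exactly unengaged.

### Units

Concentrations and dissociation constants are molar; receptor abundances are
receptors/cell; Kx\* is molar·(receptors/cell)⁻¹ so every χ is
dimensionless. Half-lives are hours; distances are Å.

## Global fitting

`fit_global_model` estimates one shared Kx\*, one K_D,βγ per ligand flagged
for inference, and one scale factor per (experiment, cell type), by least
squares on processed curves. Processing subtracts each curve's unstimulated
MFI and divides by the maximal background-subtracted signal *of its
(experiment, cell type) group* — normalizing per group rather than per curve
preserves the relative amplitudes of different ligands measured on the same
cells, which is exactly the information the shared scale factor needs; a
per-curve normalization would erase it and leave amplitude-carrying
parameters unidentifiable.

Nonlinear parameters are optimized in log10 space with bounds
(log10 Kx\* ∈ [−18, −6], log10 K_D,βγ ∈ [−12, −3]) by trust-region least
squares from 8 Latin-hypercube start points (seeded). Scale factors are not
optimizer dimensions: for fixed nonlinear parameters the optimal scale of a
group is the closed-form projection Σ(pred·y)/Σ(pred²) (variable projection),
computed at every objective evaluation and clipped to [1e−6, 1e6]. This
removes dozens of linear dimensions from the search and makes the noiseless
optimum exact. Diagnostics record every start's RSS, the best start index,
and the monotone sequence of accepted (improving) objective values. A
dataset needs at least one ligand with a fixed, finite K_D,βγ to anchor the
Kx\*/scale ambiguity. A dataset with no positive signal anywhere returns a
degeneracy flag instead of estimates.

The identifiability of Kx\* requires crosslinking to be an order-one effect
in the data: the synthetic generator's default Kx\* = 1e−10 gives χ_α ≈ 30 on
the high-IL-2Rα profile, the avidity-dominated regime the model is meant for.
At χ ≪ 1 the model degenerates to Langmuir binding and the likelihood is flat
in Kx\* from below.

## Dose–response summaries

`fit_4pl` fits the four-parameter logistic in log10-concentration space
(baseline, Emax, EC50, Hill), Hill bounded to [0.1, 5], EC50 bounded to the
data range extended 100-fold each side, three bracketing starts. Flat curves
return a no-fit flag rather than raising. `fit_gaussian_optimum` fits a
zero-baseline Gaussian to expansion ratio vs log10 EC50 — zero baseline
because the ratios decay to background at both affinity extremes — and warns
when the fitted peak falls outside the data range (monotone data cannot
localize an optimum).

## Assay analytics

- Equilibrium titrations: R(c) = Rmax·c/(K_d + c) after background
  subtraction (reference sensor when present, else the zero-concentration
  row) and normalization to the curve maximum, so K_d carries all the
  information and the fit is scale-invariant. A titration whose largest
  concentration is below the fitted K_d is flagged as weakly constrained.
- Pharmacokinetics: C(t) = A·2^(−t/t_fast) + B·2^(−t/t_slow), half-life
  parameterization directly (no rate-constant conversion in the interface);
  phases sorted so t_fast ≤ t_slow. A mono-exponential fit is attempted
  first; if it already explains the data to numerical precision, or the
  two-phase fit collapses (vanishing amplitude, indistinguishable phases, no
  RSS improvement), the result is a flagged single phase.
- Percent suppression: ((%CTV⁻ alone − %CTV⁻ with Treg)/%CTV⁻ alone)×100,
  negative values (proliferation enhancement) passed through unclipped.

## Expansion NNMF

Counts are converted to log10 fold changes against the control (vehicle) row,
which is then dropped. Negative fold changes are preserved by the
preprocessing and clipped to zero only at the factorization input (the
factorization requires non-negativity; how the original analysis handled
negatives is not documented, so clipping is a declared choice here). The
k = 2 factorization initializes with NNDSVD (zeros filled with small seeded
values) and refines by alternating exact non-negative least-squares sweeps;
each half-step solves its subproblem to optimality, so the Frobenius error
trace is monotone non-increasing by construction. Plain multiplicative
updates were rejected: on exact rank-2 instances they plateau around 1e−4
relative error after thousands of sweeps, far from the 1e−6 tolerance the
alternating-NNLS scheme reaches in tens of sweeps. Stopping is on relative
per-sweep improvement < 1e−6 (cap 2000 sweeps).

## Structure and linker geometry

`termini_distance` reads a PDB-format file (gemmi) and measures the
Euclidean distance between the Cα atoms of two chain termini, using the
first/last *resolved* residue per chain — unmodeled terminal residues shift
such measurements by a few Å, which is why a ±2 Å ambiguity is attached to
any literature comparison. `linker_reach` multiplies the (Gly4Ser)n residue
count by a per-residue extension (default 3.5 Å/residue, a near-extended
glycine-serine chain) and compares against a required span. The reach is an
upper bound: feasibility is necessary for intramolecular assembly, not
sufficient, because an entropically relaxed linker spans much less than its
contour length.

## Synthetic data

The generators stand in for unpublished raw data and define the conditions
the tests run under: 12 four-fold dilutions from 1 µM, triplicate
experiments, 10% multiplicative log-normal noise (unit mean; flow-MFI noise
scales with signal), receptor panels with IL-2Rα high on Tregs
(3000/cell vs 100–200 on effectors) and IL-2Rβ/γc on all subsets
(700–1500/cell), K_D,α = 10 nM for the IL-2/IL-2Rα interaction, K_D,βγ =
0.5 µM for unblocked ligands and 30 µM for the antibody-attenuated IC. The
receptor numbers are placeholders of realistic magnitude, not measured
quantitation values — the shipped panel is labelled synthetic and real
analyses should supply their own. All randomness derives from one seed
through per-dataset substreams, so every generator/fitter pair is a seeded
closure test: at zero noise, fitting the generated data returns the
generating parameters to numerical precision.

What passing these tests shows — and does not. They establish that the
solver is exact against enumeration, that the inference machinery recovers
parameters under the stated noise when the model is correctly specified, and
that each analytic step reproduces its defining arithmetic. They do not
establish robustness to model misspecification (real receptor counts vary
cell-to-cell, pSTAT5 saturates downstream of receptor occupancy, gating is
imperfect), which only real flow-cytometry data can probe.

## Problem sizes

Default test and acceptance runs use 100-point oracle grids, 20 noisy
recovery datasets (three experiments × three cell types × two ligands × 12
concentrations each), 100-replicate rate estimates for EC50/K_d recovery,
and 8×4 expansion matrices — sizes at which every quantity stabilizes to
well inside its tolerance.
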