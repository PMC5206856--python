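# Methods

## Structural model

Peptides are modeled at heavy-atom resolution (united-atom: aliphatic and
aromatic hydrogens are folded into their parent carbon's nonbonded
parameters). `build_ideal_helix` places the backbone by natural-extension
(internal-coordinate) construction at canonical α-helical dihedrals
φ = −57°, ψ = −47°, planar trans peptide bonds (ω = 180°), and standard bond
lengths and angles (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å;
N–CA–C 111.0°, CA–C–N 116.6°, C–N–CA 121.7°). The carbonyl oxygen is placed
anti to the next amide nitrogen. The resulting geometry has the expected
helical signatures (consecutive Cα–Cα 3.81 Å, i→i+4 O···N ≈ 3.1 Å).

Side chains are placed as one template conformer per residue type: the
ideal-coordinate heavy atoms of the chemical component dictionary bundled
with biotite, grafted by superimposing the template's N/CA/C triad onto the
target backbone frame. This mirrors fixed-backbone mutant-modelling
practice but deliberately skips a rotamer-library search — placement is
deterministic, mutations are exact side-chain swaps on a bit-identical
backbone, and steric clash relief is delegated to minimization. Intra-residue
covalent connectivity (including rings) also comes from the component
dictionary; peptide bonds C(i)–N(i+1) are added at assembly.

Protonation is fixed at neutral pH (Asp/Glu −1, Lys/Arg +1, His neutral) and
termini are modeled uncharged (free NH₂ / COOH without the terminal
oxygen). This choice makes the net formal charge of a sequence equal to
(#K + #R) − (#D + #E), the convention the published charge column follows.

## Energy model

E = E_solv + E_LJ + E_Coulomb, in kcal/mol, with lower values more stable.

* **Nonbonded pairs.** All pairs are included except atoms of the same
  residue and 1-2/1-3 bonded pairs (which only adds exclusions across the
  peptide bond). Excluding intra-residue pairs means the score measures
  inter-residue packing and electrostatics, not intra-residue strain — a
  deliberate simplification that suits a fixed-template side-chain model,
  where intra-residue geometry is constant by construction. A plain
  10 Å distance cutoff is applied (no periodic boundary, no lattice-sum
  electrostatics; the system is a single short peptide in implicit solvent).
* **Lennard-Jones.** 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combining;
  element-class σ/ε (C 3.55/0.070, N 3.25/0.170, O 2.96/0.210,
  S 3.60/0.250).
* **Coulomb.** k·qᵢqⱼ/(εᵣ·r), k = 332.0636 kcal·Å/(mol·e²), εᵣ = 1. Partial
  charges are an embedded per-(residue, atom) table that sums exactly to
  each residue's formal charge (backbone N −0.40, CA +0.25, C +0.60,
  O −0.45; side-chain dipoles on polar groups; +1/−1 distributed over the
  terminal groups of K/R/D/E).
* **Solvation.** The default backend is a surface-area model:
  Σᵢ σᵢ·SASAᵢ with classical atomic solvation parameters (apolar C +0.016,
  S +0.021, neutral N/O −0.006, carboxylate O −0.024, charged N −0.050
  kcal/(mol·Å²)). SASA uses a Shrake–Rupley-style estimate with a 1.4 Å
  water probe and a deterministic golden-spiral point set (960 points/atom
  by default; the estimator converges to ~1% of closed-form sphere areas).
  SASA is evaluated in a molecule-fixed canonical frame (principal axes of
  the gyration tensor with a sign convention), so all three energy terms
  are invariant under global rotation and translation. The backend registry
  accepts alternative solvation models under other identifiers; the
  `SolvationConfig` also carries the dipolar-solvent parameters
  (p₀ = 3.00 D, C_dip = 55 M, grid spacing 2.8 Å, T = 300 K) that a
  grid-based dipolar Poisson–Boltzmann backend would consume.

The parameter set is embedded and versioned (`httscan-params-1`). Absolute
energies and ΔE values are internally consistent and reproducible but are
not comparable to landscapes computed with other force fields or solvation
models — the package's published-data checks are therefore confined to
quantities that do not depend on the energy parameterization (charges,
additive structure, selection logic).

## Minimization

Steepest descent on the LJ+Coulomb gradient with adaptive step length: the
maximum per-atom displacement starts at 0.1 Å, grows 1.2× per accepted step
(capped at 0.5 Å) and halves on uphill trials; termination at a maximum
gradient component below `force_tol` (default 0.1 kcal/(mol·Å), a documented
choice), at `max_steps` accepted steps, or on step underflow. By default the
solvation term is held constant during each line search, re-evaluated once
per accepted step, and a step is only accepted if the total energy does not
increase — so the recorded energy trace is non-increasing. Backbone atoms
are frozen by default (`backbone_fixed=True`), matching the fixed-backbone
design of the scan.

## Scan protocol

`scan_single_point` relaxes the native once (backbone fixed, ≤ `max_steps`)
to obtain E₀ and the relaxed frame, then builds each of the positions × 19
mutants on that frame, relaxes side chains with the same protocol, and
scores ΔE = E − E₀. Within the scan, minimization optimizes LJ+Coulomb only
and solvation is re-scored once on the relaxed structure
(`track_solvation=False`): the SASA term varies slowly along a side-chain
relaxation, and evaluating it at every accepted step would dominate the
cost of the 323-mutant scan by two orders of magnitude. Cells are computed
independently from the same native frame, so the scan is deterministic and
order-independent. The full 17-mer scan (323 mutants, 200-step cap) runs in
about a minute on one CPU.

## Additive estimates and top-k search

ΔẼ for a combination at pairwise-distinct positions is the exact sum of the
constituent table entries — no structure energies are re-evaluated, so
additivity over disjoint sets holds exactly. The estimate ignores pairwise
coupling between introduced side chains; on the ideal helix the package's
own check (two tryptophan substitutions ~16 Å apart) agrees with direct
2-point recomputation within max(10%, 2 kcal/mol), but the approximation
degrades for adjacent sites.

`enumerate_top_k` is a lazy best-first search: position subsets are expanded
in ascending order of their per-position minima through one heap, and
residue choices within a subset through another, with lexicographic
(position, residue) tie-breaking. Because tied states can surface in any
order, the search keeps popping until the heap minimum exceeds the k-th
best value and sorts the collected pool — making the result provably equal
to exhaustive enumeration, which the tests assert on random tables
including tie-heavy ones.

## Selection criteria

* *Stability*: membership in the ranked input (optionally capped by rank) —
  the filters are meant to run on an already top-ranked list.
* *Hydrophobic→charged*: at least one mutation with wild type in
  {A, V, I, L, M} and mutant in {D, E, K, R}. The aliphatic default (rather
  than a broader hydrophobic set with F/W) exactly reproduces the published
  twelve-combination list, which counts A2R combinations but not
  F17D/F17E-only ones; the sets are configurable and this ambiguity is
  deliberately surfaced rather than resolved.
* *Contact breaking*: any substitution at positions {6, 15}. Position 6 is
  included because the lysine 6/15 pair forms the intermolecular contact,
  even though no published top-20 combination happens to mutate it.

## Published-table recovery

The twenty embedded 3-point sums over nine distinct single-point mutations
form a 20×9 linear system (each row the sum of its three parameters),
solved by unweighted least squares — all rows are printed at the same 0.1
precision, so there is no heteroscedasticity information to exploit. The
design has full rank 9; the anchor is the one row with no position-15
mutation, without which a one-dimensional gauge (a constant shifted between
the position-15 parameters and the rest) is unresolvable. Consequently
leave-one-out validation is possible for 19 of the 20 rows (all predictions
fall within ±0.5 of the printed sums; full-fit residuals are ≤ 0.05), while
excluding the anchor row is correctly rejected as rank-deficient.
Exchange identities between row differences (e.g. the two independent
printed estimates of K15D − K15E) agree within 0.1, consistent with
rounding alone.

## Trajectory statistics

RMSD superposes frames by centroid alignment plus the SVD-based optimal
rotation with reflection correction (cross-checked against an independent
quaternion implementation at 1e-8); RMSF is the per-atom RMS displacement
about a reference position, by default the time-averaged structure (the
variance-minimizing choice), with first-frame and user-supplied references
available. Cα-only selections are supported at the trajectory level. The
synthetic generator emulates harmonic positional fluctuation about a stable
structure — reference coordinates plus i.i.d. per-axis Gaussian noise,
frames 10 ps apart, seeded and reproducible; for noise σ the expected RMSF
is σ√3, which the tests verify to 3% at 10,000 frames. The generator has no
time correlation, anisotropy, or collective motion, so passing tests
validate the estimators, not any claim about real dynamics.

## Problem sizes and determinism

Default test and acceptance runs use: the full 17×19 scan at a 200-step
minimization cap; random toy tables of ≤ 6 positions for enumeration
oracles; ≤ 30-atom clouds for brute-force energy oracles; 10,000-frame
synthetic trajectories for RMSF calibration. Every stochastic component
(synthetic trajectories, test clouds) is seeded; the scan, the fit, and the
CLI pipeline are fully deterministic, and the pipeline manifest records the
seed and the energy-config hash that landscape files also carry as
provenance.

## Known limitations

* The energy function is a self-contained stand-in parameterization; it
  ranks mutations within this package's model and does not reproduce
  absolute published landscape values computed with other pipelines.
* One template conformer per residue type: rotamer preferences and
  backbone-dependent side-chain packing are not explored; badly clashing
  templates rely on minimization for relief.
* Compositional sequence features cannot capture window or gatekeeper
  effects that profile-based aggregation predictors model.
* No molecular dynamics: trajectory operators are exercised on synthetic
  fluctuations only.
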