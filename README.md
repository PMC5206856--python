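# httscan

Mutational stability landscape and rational mutant design for the
huntingtin N-terminal helix.

## The problem

The 17-residue N-terminal segment of huntingtin exon 1
(`MATLEKLMKAFESLKSF`, the "Htt N-term") is α-helical in the native state and
sits immediately upstream of the polyglutamine tract whose expansion causes
Huntington's disease. Two mechanisms link this segment to aggregation:
helical self-association into oligomers — mediated in part by a
solvent-inaccessible intermolecular contact involving lysines 6 and 15 — and
hydrophobic cross-talk between the segment and the polyQ domain. A mutant
that (1) stabilizes the helix, (2) replaces a hydrophobic residue with a
charged one, and (3) substitutes a contact lysine addresses both mechanisms
at once.

`httscan` implements that design procedure end to end, at desk scale, for
computational structural biologists who want a reproducible, fully tested
version of the workflow:

1. **Single-point scan.** Every residue of the peptide is substituted by the
   other 19 canonical amino acids on a fixed ideal-helix backbone
   (φ = −57°, ψ = −47°), side chains are relaxed by steepest descent, and
   each mutant is scored with a decomposed stability energy

   E = E_solv + E_LJ + E_Coulomb,

   giving the landscape ΔE(p, m) = E(mutant) − E(native) for all
   (position p, residue m). Negative ΔE is stabilizing.

2. **Additive multi-point estimates.** An n-point combination at
   pairwise-distinct positions is estimated as
   ΔẼ = Σᵢ ΔE(pᵢ, mᵢ), and a best-first search enumerates the top-k
   combinations without materializing the full combination space (provably
   equal to exhaustive enumeration).

3. **Three-criteria selection.** Ranked combinations are flagged for
   hydrophobic→charged replacement (default aliphatic set {A,V,I,L,M} →
   {D,E,K,R}) and for substitution at the contact positions {6, 15}.

4. **Sequence features and trajectory statistics.** Net formal charge,
   Kyte–Doolittle hydrophobicity, Chou–Fasman propensities, a composite
   aggregation score, plus RMSD (optimal superposition) and RMSF operators
   with a seeded synthetic-trajectory generator.

The package also embeds the published table of the twenty top-ranked 3-point
combinations of this peptide with their additive estimates, and recovers the
nine underlying single-point ΔE values from the printed sums by unweighted
least squares — which supports leave-one-out cross-validation of the
additive model without access to the original energy pipeline.

## Worked example

```python
from httscan import (
    NATIVE_HTT_NTERM, build_ideal_helix, scan_single_point,
    enumerate_top_k, select_candidates,
)

peptide = build_ideal_helix(NATIVE_HTT_NTERM)          # 136 heavy atoms
table = scan_single_point(peptide, max_steps=200)      # ~50 s, 323 mutants
for est in enumerate_top_k(table, n=3, k=5):
    print(f"rank {est.rank}: {est.mutation_string}  dE~ = {est.delta_e_estimate:.1f} kcal/mol")
```

prints (embedded parameter set, version `httscan-params-1`):

```
rank 1: T3D L7D A10D  dE~ = -259.5 kcal/mol
rank 2: T3D M8K A10D  dE~ = -246.3 kcal/mol
rank 3: A2D T3D A10D  dE~ = -245.3 kcal/mol
rank 4: T3D A10D L14D  dE~ = -242.3 kcal/mol
rank 5: T3D M8R A10D  dE~ = -238.8 kcal/mol
```

The most negative additive estimates are combinations that introduce charged
residues at helix-compatible positions; absolute values depend on the
embedded parameter set and are not comparable across parameter versions (see
`docs/methods.md`). Passing the ranked list to `select_candidates` flags
each combination against the hydrophobic-replacement and contact-breaking
criteria; with these five, all replace an aliphatic residue with a charged
one but none touches positions 6/15, so none passes all three criteria —
`enumerate_top_k(..., k=larger)` and the selection report are how candidates
like the published L4K E12K K15E emerge from a larger pool.

The same pipeline is scriptable from the shell:

```bash
httscan scan --sequence MATLEKLMKAFESLKSF --out landscape.csv
httscan rank --landscape landscape.csv --n 3 --k 20 --out ranked.tsv
httscan select --ranked ranked.tsv --out report.tsv
httscan reproduce        # consistency harness over the embedded tables
```

## Layout

```
src/httscan/
  residues.py            canonical amino-acid constants
  params.py              embedded per-atom energy parameters (versioned)
  geometry.py            internal-coordinate placement, rigid fits
  peptide_model.py       Peptide, ideal-helix builder, mutations, PDB I/O
  energetics.py          LJ / Coulomb / SASA-solvation, minimization
  landscape.py           scan, DeltaETable, additive estimates, top-k search
  seq_features.py        charge, hydrophobicity, propensities, composite score
  selection.py           three-criteria candidate selection
  trajectory_analysis.py RMSD/RMSF, synthetic trajectories
  reference_tables.py    embedded published tables + least-squares recovery
  cli.py                 httscan command-line interface
```
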