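"""Single-point mutational stability landscape and additive combination search.

The landscape is a positions x 20-residue matrix of stability changes
dE = E(mutant) - E(native), computed by substituting every residue of the
native peptide by each of the other 19 canonical amino acids, relaxing the
side chains, and re-scoring.  Multi-point combinations are estimated
*additively*: the estimate for a set of substitutions at pairwise-distinct
positions is the sum of the corresponding single-point dE values, which
avoids re-evaluating structure energies for the combinatorially many
multi-point mutants.  The additive estimate ignores pairwise coupling
between the introduced side chains and is accurate when the mutated sites do
not interact directly.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import EnergyModelConfig, delta_e, minimize, total_energy
from .peptide_model import MutationSpec, Peptide, apply_mutation
from .residues import CANONICAL


@dataclass
class DeltaETable:
    """positions x 20 matrix of single-point stability changes (kcal/mol).

    Columns follow :data:`httscan.residues.CANONICAL` (alphabetical one-letter
    order).  The cell for the native residue at each position is identically
    zero.  ``provenance`` records a hash of the energy configuration so that
    additive estimates cannot silently mix incompatible landscapes.
    """

    native_sequence: str
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.native_sequence), len(CANONICAL)):
            raise ValueError(
                f"values must be {len(self.native_sequence)} x {len(CANONICAL)}"
            )
        for p, aa in enumerate(self.native_sequence):
            if self.values[p, CANONICAL.index(aa)] != 0.0:
                raise ValueError(f"identity cell at position {p + 1} must be 0")

    @property
    def n_positions(self) -> int:
        return len(self.native_sequence)

    def get(self, position: int, residue: str) -> float:
        """dE for mutating 1-based ``position`` to ``residue``."""
        return float(self.values[position - 1, CANONICAL.index(residue)])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=list(CANONICAL),
            index=pd.RangeIndex(1, self.n_positions + 1, name="position"),
        )
        df.insert(0, "native", list(self.native_sequence))
        return df

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance={self.provenance}\n")
            self.to_dataframe().to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "DeltaETable":
        provenance = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# provenance="):
                provenance = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, index_col=0, comment="#")
        native = "".join(df["native"])
        values = df[list(CANONICAL)].to_numpy(dtype=float)
        return cls(native_sequence=native, values=values, provenance=provenance)


@dataclass(frozen=True)
class CombinationEstimate:
    """An n-point mutation set with its additive stability estimate."""

    mutations: tuple[MutationSpec, ...]
    delta_e_estimate: float
    rank: int | None = None
    label: str | None = None

    @property
    def mutation_string(self) -> str:
        return " ".join(str(m) for m in self.mutations)

    def sort_key(self) -> tuple:
        return tuple((m.position, m.mutant) for m in self.mutations)


def scan_single_point(
    peptide: Peptide,
    config: EnergyModelConfig | None = None,
    max_steps: int = 200,
    force_tol: float = 0.1,
    track_solvation: bool = False,
    positions: list[int] | None = None,
) -> DeltaETable:
    """Exhaustive single-point mutational scan.

    The native peptide is relaxed once (backbone fixed) to give the reference
    energy E0; every (position, alternative residue) mutant is then built on
    the relaxed native backbone, side-chain relaxed with the same protocol,
    and scored.  Identity cells are zero by construction.  The scan is
    deterministic and cell-order independent.  ``positions`` restricts the
    scan to a subset of 1-based positions (other rows keep zeros).
    """
    config = config or EnergyModelConfig()
    native = minimize(
        peptide, config, max_steps=max_steps, force_tol=force_tol,
        backbone_fixed=True, track_solvation=track_solvation,
    )
    e0 = total_energy(native, config).total

    values = np.zeros((peptide.n_residues, len(CANONICAL)))
    scan_positions = positions or range(1, peptide.n_residues + 1)
    for pos in scan_positions:
        wt = native.sequence[pos - 1]
        for alt in CANONICAL:
            if alt == wt:
                continue
            spec = MutationSpec(position=pos, wild_type=wt, mutant=alt)
            try:
                mutant = apply_mutation(native, spec)
                relaxed = minimize(
                    mutant, config, max_steps=max_steps, force_tol=force_tol,
                    backbone_fixed=True, track_solvation=track_solvation,
                )
                e = total_energy(relaxed, config).total
            except ValueError as exc:
                raise RuntimeError(
                    f"scan failed at position {pos}, residue {alt}: {exc}"
                ) from exc
            values[pos - 1, CANONICAL.index(alt)] = delta_e(e, e0)
    return DeltaETable(
        native_sequence=peptide.sequence,
        values=values,
        provenance=config.config_hash(),
    )


def estimate_combination(
    table: DeltaETable, mutations: list[MutationSpec]
) -> CombinationEstimate:
    """Additive estimate: the sum of the constituent single-point dE values."""
    positions = [m.position for m in mutations]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate mutation positions in {positions}")
    total = 0.0
    for m in mutations:
        if not 1 <= m.position <= table.n_positions:
            raise ValueError(f"position {m.position} outside landscape")
        wt = table.native_sequence[m.position - 1]
        if wt != m.wild_type:
            raise ValueError(
                f"wild-type mismatch at position {m.position}: "
                f"mutation says {m.wild_type}, native is {wt}"
            )
        total += table.get(m.position, m.mutant)
    return CombinationEstimate(
        mutations=tuple(sorted(mutations, key=lambda m: m.position)),
        delta_e_estimate=total,
    )


def _candidate_lists(
    table: DeltaETable, allowed: set[MutationSpec] | None
) -> dict[int, list[tuple[float, str]]]:
    """Per-position sorted (value, residue) candidates, identities excluded."""
    allowed_pairs = None
    if allowed is not None:
        allowed_pairs = {(m.position, m.mutant) for m in allowed}
    out: dict[int, list[tuple[float, str]]] = {}
    for pos in range(1, table.n_positions + 1):
        wt = table.native_sequence[pos - 1]
        cands = []
        for aa in CANONICAL:
            if aa == wt:
                continue
            if allowed_pairs is not None and (pos, aa) not in allowed_pairs:
                continue
            cands.append((table.get(pos, aa), aa))
        cands.sort()
        if cands:
            out[pos] = cands
    return out


def enumerate_top_k(
    table: DeltaETable,
    n: int,
    k: int,
    allowed: set[MutationSpec] | None = None,
) -> list[CombinationEstimate]:
    """The k lowest additive n-point combinations, ascending.

    Best-first search: position subsets are expanded lazily in order of their
    per-position minima, and within a subset candidate residues are expanded
    through a heap, so the full combination space is never materialized.
    Ties are broken lexicographically by the (position, residue) tuple.  The
    result provably equals exhaustive enumeration.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    cands = _candidate_lists(table, allowed)
    positions = sorted(cands)
    if n > len(positions):
        raise ValueError(
            f"n={n} exceeds the {len(positions)} positions with candidates"
        )
    # order positions by their best value for the subset search
    pos_order = sorted(positions, key=lambda p: (cands[p][0][0], p))
    minima = [cands[p][0][0] for p in pos_order]

    def subset_stream():
        """Size-n index subsets into pos_order, ascending by sum of minima."""
        start = tuple(range(n))
        heap = [(sum(minima[i] for i in start), start)]
        seen = {start}
        while heap:
            s, subset = heapq.heappop(heap)
            yield s, subset
            for slot in range(n):
                nxt = subset[slot] + 1
                hi = subset[slot + 1] if slot + 1 < n else len(pos_order)
                if nxt < hi:
                    child = subset[:slot] + (nxt,) + subset[slot + 1:]
                    if child not in seen:
                        seen.add(child)
                        delta = minima[nxt] - minima[subset[slot]]
                        heapq.heappush(heap, (s + delta, child))

    subsets = subset_stream()

    def make_state(subset, idx):
        pairs = sorted(
            (pos_order[i], j) for i, j in zip(subset, idx)
        )  # position order, so float summation matches exhaustive enumeration
        value = sum(cands[p][j][0] for p, j in pairs)
        tie = tuple((p, cands[p][j][1]) for p, j in pairs)
        return (value, tie, subset, idx)

    heap: list[tuple] = []
    visited: set[tuple] = set()

    def push_next_subset():
        for _, subset in subsets:
            base = (subset, (0,) * n)
            if base not in visited:
                visited.add(base)
                heapq.heappush(heap, make_state(*base))
            return True
        return False

    push_next_subset()
    results: list[CombinationEstimate] = []
    kth_value = None
    while heap:
        value, tie, subset, idx = heapq.heappop(heap)
        if kth_value is not None and value > kth_value:
            break
        if idx == (0,) * n:
            push_next_subset()
        results.append(
            CombinationEstimate(
                mutations=tuple(
                    MutationSpec(p, table.native_sequence[p - 1], aa)
                    for (p, aa) in tie
                ),
                delta_e_estimate=value,
            )
        )
        if len(results) >= k and kth_value is None:
            kth_value = sorted(r.delta_e_estimate for r in results)[k - 1]
        for slot in range(n):
            j = idx[slot] + 1
            p = pos_order[subset[slot]]
            if j < len(cands[p]):
                child = (subset, idx[:slot] + (j,) + idx[slot + 1:])
                if child not in visited:
                    visited.add(child)
                    heapq.heappush(heap, make_state(*child))

    results.sort(key=lambda r: (r.delta_e_estimate, r.sort_key()))
    results = results[:k]
    return [
        CombinationEstimate(
            mutations=r.mutations,
            delta_e_estimate=r.delta_e_estimate,
            rank=i + 1,
        )
        for i, r in enumerate(results)
    ]


def enumerate_exhaustive(
    table: DeltaETable,
    n: int,
    k: int,
    allowed: set[MutationSpec] | None = None,
) -> list[CombinationEstimate]:
    """Brute-force reference enumeration (small tables only)."""
    cands = _candidate_lists(table, allowed)
    positions = sorted(cands)
    if n > len(positions):
        raise ValueError(
            f"n={n} exceeds the {len(positions)} positions with candidates"
        )
    all_combos = []
    for pos_subset in itertools.combinations(positions, n):
        for choice in itertools.product(*(cands[p] for p in pos_subset)):
            value = sum(v for v, _ in choice)
            muts = tuple(
                MutationSpec(p, table.native_sequence[p - 1], aa)
                for p, (_, aa) in zip(pos_subset, choice)
            )
            all_combos.append(
                CombinationEstimate(mutations=muts, delta_e_estimate=value)
            )
    all_combos.sort(key=lambda r: (r.delta_e_estimate, r.sort_key()))
    return [
        CombinationEstimate(
            mutations=r.mutations, delta_e_estimate=r.delta_e_estimate, rank=i + 1
        )
        for i, r in enumerate(all_combos[:k])
    ]


STABILIZING = "stabilizing"
DESTABILIZING = "destabilizing"
NEUTRAL = "neutral"


def classify(table: DeltaETable, threshold: float = 0.0) -> np.ndarray:
    """Label every cell by the sign of dE.

    dE < -threshold is stabilizing, dE > +threshold destabilizing, anything
    in between (including every identity cell) neutral.
    """
    labels = np.full(table.values.shape, NEUTRAL, dtype=object)
    labels[table.values < -threshold] = STABILIZING
    labels[table.values > threshold] = DESTABILIZING
    for p, aa in enumerate(table.native_sequence):
        labels[p, CANONICAL.index(aa)] = NEUTRAL
    return labels


def combinations_to_tsv(estimates: list[CombinationEstimate], path) -> None:
    """Export ranked combinations as TSV (id, mutations, dE estimate)."""
    df = pd.DataFrame(
        {
            "id": [e.label or f"C{e.rank or i + 1}" for i, e in enumerate(estimates)],
            "mutations": [e.mutation_string for e in estimates],
            "delta_e_estimate": [e.delta_e_estimate for e in estimates],
        }
    )
    df.to_csv(path, sep="\t", index=False)
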