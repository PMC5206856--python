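"""Published reference data for the Htt N-terminal 3-point mutant design.

This module embeds, verbatim, the twenty top-ranked 3-point mutation
combinations of the huntingtin N-terminal 17-mer together with their
published additive stability estimates (abstract energy units, most negative
= most stabilizing) and the published net charges of the corresponding
mutant sequences.  Because each published estimate is by construction the
sum of three single-point dE values, the table over-determines the nine
distinct single-point parameters occurring in it (A2R, T3K, L4K, E5K, E12K,
K15D, K15E, F17D, F17E); :func:`fit_single_point` recovers them by
unweighted least squares, which supports leave-one-out cross-validation of
the additive model and re-ranking experiments without access to the original
energy pipeline.

Printed values use the Unicode minus sign in the source; they are normalized
to ASCII floats here, with the verbatim strings retained for audit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .peptide_model import MutationSpec, parse_mutations
from .residues import NATIVE_HTT_NTERM

#: (id, mutation notation, published additive estimate as printed).
_COMBINATIONS_VERBATIM: list[tuple[str, str, str]] = [
    ("M1", "L4K E5K K15D", "−668.3"),
    ("M2", "T3K L4K K15D", "−667.7"),
    ("M3", "T3K E5K K15D", "−664.9"),
    ("M4", "L4K E5K K15E", "−649"),
    ("M5", "T3K L4K K15E", "−648.4"),
    ("M6", "L4K E12K K15D", "−646.7"),
    ("M7", "T3K E5K K15E", "−645.7"),
    ("M8", "T3K L4K E5K", "−645.6"),
    ("M9", "E5K E12K K15D", "−644"),
    ("M10", "T3K E12K K15D", "−643.4"),
    ("M11", "L4K K15D F17D", "−637.3"),
    ("M12", "E5K K15D F17D", "−634.5"),
    ("M13", "T3K K15D F17D", "−633.9"),
    ("M14", "L4K K15D F17E", "−629.4"),
    ("M15", "A2R L4K K15D", "−629.2"),
    ("M16", "L4K E12K K15E", "−627.5"),
    ("M17", "E5K K15D F17E", "−626.6"),
    ("M18", "A2R E5K K15D", "−626.5"),
    ("M19", "T3K K15D F17E", "−626"),
    ("M20", "A2R T3K K15D", "−625.8"),
]

#: Published net charges of the native and mutant sequences.
_CHARGES: dict[str, int] = {
    "Native": 1,
    "M1": 2, "M2": 1, "M3": 2, "M4": 2, "M5": 1,
    "M6": 2, "M7": 2, "M8": 5, "M9": 3, "M10": 2,
    "M11": -1, "M12": 0, "M13": -1, "M14": -1, "M15": 1,
    "M16": 2, "M17": 0, "M18": 2, "M19": -1, "M20": 1,
}


@dataclass(frozen=True)
class ReferenceCombination:
    """One published 3-point combination with its additive estimate."""

    id: str
    mutations: tuple[MutationSpec, ...]
    delta_e_estimate: float
    verbatim: str

    @property
    def mutation_string(self) -> str:
        return " ".join(str(m) for m in self.mutations)

    def mutant_sequence(self, native: str = NATIVE_HTT_NTERM) -> str:
        seq = list(native)
        for m in self.mutations:
            if seq[m.position - 1] != m.wild_type:
                raise ValueError(
                    f"{self.id}: wild type mismatch at position {m.position}"
                )
            seq[m.position - 1] = m.mutant
        return "".join(seq)


def combination_table() -> list[ReferenceCombination]:
    """The twenty published 3-point combinations, ranked most stable first."""
    rows = []
    for cid, muts, verbatim in _COMBINATIONS_VERBATIM:
        rows.append(
            ReferenceCombination(
                id=cid,
                mutations=tuple(parse_mutations(muts)),
                delta_e_estimate=float(verbatim.replace("−", "-")),
                verbatim=verbatim,
            )
        )
    return rows


def charge_table() -> dict[str, int]:
    """Published net charges keyed by combination id (plus ``"Native"``)."""
    return dict(_CHARGES)


# -- least-squares recovery of single-point values -------------------------

@dataclass(frozen=True)
class SinglePointFit:
    """Least-squares estimates of the single-point dE parameters."""

    parameters: dict[str, float]     # mutation notation -> fitted dE
    residuals: dict[str, float]      # row id -> observed - fitted sum
    design_rank: int
    excluded_ids: frozenset[str]

    def predict(self, mutations: list[MutationSpec]) -> float:
        """Additive prediction: sum of fitted single-point parameters."""
        return sum(self.parameters[str(m)] for m in mutations)


def fit_single_point(
    rows: list[ReferenceCombination] | None = None,
    exclude_ids: frozenset[str] | set[str] = frozenset(),
) -> SinglePointFit:
    """Recover single-point dE values from the published 3-point sums.

    Each row is modeled as the exact sum of its three constituent
    single-point parameters; the over-determined linear system is solved by
    unweighted least squares.  Raises if the retained rows leave any
    parameter unidentifiable (rank-deficient design).
    """
    rows = combination_table() if rows is None else rows
    exclude_ids = frozenset(exclude_ids)
    unknown = exclude_ids - {r.id for r in rows}
    if unknown:
        raise ValueError(f"exclude_ids not in table: {sorted(unknown)}")
    kept = [r for r in rows if r.id not in exclude_ids]

    # parameters are defined by the full table so that an exclusion which
    # removes a parameter's only support is flagged, not silently dropped
    param_names = sorted(
        {str(m) for r in rows for m in r.mutations},
        key=lambda s: (MutationSpec.parse(s).position, s),
    )
    col = {p: i for i, p in enumerate(param_names)}
    a = np.zeros((len(kept), len(param_names)))
    b = np.zeros(len(kept))
    for i, r in enumerate(kept):
        for m in r.mutations:
            a[i, col[str(m)]] = 1.0
        b[i] = r.delta_e_estimate

    rank = int(np.linalg.matrix_rank(a))
    if rank < len(param_names):
        # identify parameters with support in the null space
        _, s, vt = np.linalg.svd(a)
        null = vt[rank:]
        bad = [
            p for p in param_names
            if np.abs(null[:, col[p]]).max() > 1e-8
        ]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {len(param_names)}); "
            f"unidentifiable parameters: {bad}"
        )
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    parameters = {p: float(x[col[p]]) for p in param_names}
    residuals = {
        r.id: float(r.delta_e_estimate - sum(parameters[str(m)] for m in r.mutations))
        for r in kept
    }
    return SinglePointFit(
        parameters=parameters,
        residuals=residuals,
        design_rank=rank,
        excluded_ids=exclude_ids,
    )


def best_fitted_triple(fit: SinglePointFit) -> tuple[tuple[str, ...], float]:
    """Minimum additive estimate over all distinct-position 3-subsets of the
    fitted parameters; ties broken lexicographically by (position, notation)."""
    params = sorted(
        fit.parameters,
        key=lambda s: (MutationSpec.parse(s).position, s),
    )
    best = None
    for triple in itertools.combinations(params, 3):
        positions = {MutationSpec.parse(p).position for p in triple}
        if len(positions) != 3:
            continue
        value = sum(fit.parameters[p] for p in triple)
        key = (value, triple)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no distinct-position triple available")
    return best[1], best[0]


@dataclass(frozen=True)
class ExchangeIdentity:
    """An additivity identity rowA - rowB = rowC - rowD between printed sums."""

    pair_lhs: tuple[str, str]
    pair_rhs: tuple[str, str]
    lhs: float
    rhs: float

    @property
    def gap(self) -> float:
        return abs(self.lhs - self.rhs)


def additivity_consistency(
    rows: list[ReferenceCombination] | None = None,
) -> list[ExchangeIdentity]:
    """All exchange identities implied by additivity of the printed sums.

    Two ordered row pairs (A, B) and (C, D) share an identity when the signed
    multiset difference of their mutations matches; perfect additivity would
    make the printed differences equal, so the gap measures rounding plus any
    internal inconsistency of the published table.
    """
    rows = combination_table() if rows is None else rows
    by_diff: dict[frozenset, list[tuple[str, str, float]]] = {}
    for a, b in itertools.permutations(rows, 2):
        diff_counts: dict[str, int] = {}
        for m in a.mutations:
            diff_counts[str(m)] = diff_counts.get(str(m), 0) + 1
        for m in b.mutations:
            diff_counts[str(m)] = diff_counts.get(str(m), 0) - 1
        key = frozenset((k, v) for k, v in diff_counts.items() if v != 0)
        if not key:
            continue
        by_diff.setdefault(key, []).append(
            (a.id, b.id, a.delta_e_estimate - b.delta_e_estimate)
        )
    identities = []
    for group in by_diff.values():
        for (a, b, lhs), (c, d, rhs) in itertools.combinations(group, 2):
            identities.append(
                ExchangeIdentity(pair_lhs=(a, b), pair_rhs=(c, d), lhs=lhs, rhs=rhs)
            )
    return identities
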