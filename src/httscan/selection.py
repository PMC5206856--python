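"""Three-criteria mutant selection for the huntingtin N-terminal helix.

A ranked list of mutation combinations is filtered by the design logic of
the study: (1) high helical stability, represented by membership/rank in the
already-ranked input (optionally capped); (2) at least one hydrophobic
residue replaced by a charged one, to weaken cross-talk with the polyQ
domain; (3) at least one substitution at the lysine 6/15 contact positions,
to break the solvent-inaccessible intermolecular side-chain interaction
implicated in oligomer formation.

The hydrophobic set defaults to the *aliphatic* residues {A, V, I, L, M}
rather than a broader hydrophobic set including Phe/Trp; with that default
the hydrophobic-replacement flag treats F->D/E substitutions as not
qualifying.  Both sets and the contact positions are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .landscape import CombinationEstimate
from .peptide_model import MutationSpec
from .residues import CANONICAL


@dataclass(frozen=True)
class SelectionCriteria:
    hydrophobic_set: frozenset[str] = frozenset("AVILM")
    charged_set: frozenset[str] = frozenset("DEKR")
    contact_positions: frozenset[int] = frozenset({6, 15})
    stability_max_rank: int | None = None  # None = any rank in the input

    def __post_init__(self):
        for s in (self.hydrophobic_set, self.charged_set):
            bad = set(s) - set(CANONICAL)
            if bad:
                raise ValueError(f"non-canonical residues in criteria: {bad}")
        if any(p < 1 for p in self.contact_positions):
            raise ValueError("contact positions must be 1-based")


@dataclass(frozen=True)
class SelectionRow:
    id: str
    mutation_string: str
    delta_e_estimate: float
    stability_rank: int
    passes_stability: bool
    flag_hydrophobic_replacement: bool
    flag_contact_break: bool

    @property
    def passes_all(self) -> bool:
        return (
            self.passes_stability
            and self.flag_hydrophobic_replacement
            and self.flag_contact_break
        )


@dataclass
class SelectionReport:
    criteria: SelectionCriteria
    rows: list[SelectionRow] = field(default_factory=list)

    def passing(self) -> list[SelectionRow]:
        return [r for r in self.rows if r.passes_all]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.rows],
                "mutations": [r.mutation_string for r in self.rows],
                "delta_e_estimate": [r.delta_e_estimate for r in self.rows],
                "rank": [r.stability_rank for r in self.rows],
                "hydrophobic_flag": [
                    r.flag_hydrophobic_replacement for r in self.rows
                ],
                "contact_flag": [r.flag_contact_break for r in self.rows],
                "passes_all": [r.passes_all for r in self.rows],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def hydrophobic_to_charged(
    combo: list[MutationSpec], criteria: SelectionCriteria | None = None
) -> bool:
    """True iff some mutation replaces a hydrophobic residue with a charged one."""
    criteria = criteria or SelectionCriteria()
    return any(
        m.wild_type in criteria.hydrophobic_set
        and m.mutant in criteria.charged_set
        and not m.is_identity
        for m in combo
    )


def breaks_oligomer_contact(
    combo: list[MutationSpec], criteria: SelectionCriteria | None = None
) -> bool:
    """True iff some mutation substitutes one of the contact positions."""
    criteria = criteria or SelectionCriteria()
    return any(
        m.position in criteria.contact_positions and not m.is_identity
        for m in combo
    )


def select_candidates(
    estimates: list[CombinationEstimate],
    criteria: SelectionCriteria | None = None,
) -> SelectionReport:
    """Flag every ranked combination against the three criteria.

    ``estimates`` must be ranked ascending by additive dE (most stabilizing
    first); input order is preserved in the report and defines the stability
    rank where an estimate does not carry one.
    """
    criteria = criteria or SelectionCriteria()
    report = SelectionReport(criteria=criteria)
    for i, est in enumerate(estimates):
        rank = est.rank if est.rank is not None else i + 1
        passes_stability = (
            criteria.stability_max_rank is None
            or rank <= criteria.stability_max_rank
        )
        report.rows.append(
            SelectionRow(
                id=est.label or f"C{rank}",
                mutation_string=est.mutation_string,
                delta_e_estimate=est.delta_e_estimate,
                stability_rank=rank,
                passes_stability=passes_stability,
                flag_hydrophobic_replacement=hydrophobic_to_charged(
                    list(est.mutations), criteria
                ),
                flag_contact_break=breaks_oligomer_contact(
                    list(est.mutations), criteria
                ),
            )
        )
    return report
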