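"""Sequence-level physicochemical features for aggregation-oriented triage.

These are compositional (order-independent) features: net formal charge,
mean hydrophobicity on a classical transfer-free-energy scale, and mean
helix/strand statistical propensities.  A configurable linear combination of
z-scored features gives a composite aggregation score that favours
hydrophobic, highly chargeable, beta-prone, helix-poor sequences.  The
composite is an in-package stand-in for external aggregation predictors and
is intended for ranking variants of one peptide against each other, not for
absolute amyloidogenicity prediction; being compositional it cannot resolve
window or gatekeeper effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .residues import CANONICAL, FORMAL_CHARGE, validate_sequence

#: Kyte-Doolittle hydropathy index (dimensionless).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "kyte-doolittle": KYTE_DOOLITTLE,
}

#: Chou-Fasman alpha-helix propensities P_alpha.
HELIX_PROPENSITY: dict[str, float] = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

#: Chou-Fasman beta-strand propensities P_beta.
BETA_PROPENSITY: dict[str, float] = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

DEFAULT_WEIGHTS: dict[str, float] = {
    "hydrophobicity": 1.0,
    "charge": 1.0,
    "beta": 1.0,
    "helix": 1.0,
}


@dataclass(frozen=True)
class SequenceFeatures:
    """Compositional feature bundle for one sequence."""

    net_charge: int
    mean_hydrophobicity: float
    helix_propensity: float
    beta_propensity: float
    aggregation_score: float


def net_charge(sequence: str) -> int:
    """Net formal charge at neutral pH: (#K + #R) - (#D + #E), His neutral,
    termini ignored."""
    seq = validate_sequence(sequence)
    return sum(FORMAL_CHARGE[aa] for aa in seq)


def _resolve_scale(scale) -> dict[str, float]:
    if isinstance(scale, str):
        try:
            return HYDROPHOBICITY_SCALES[scale]
        except KeyError:
            raise ValueError(
                f"unknown hydrophobicity scale {scale!r}; available: "
                f"{sorted(HYDROPHOBICITY_SCALES)}"
            ) from None
    missing = [aa for aa in CANONICAL if aa not in scale]
    if missing:
        raise ValueError(f"scale is missing residues {missing}")
    return scale


def mean_hydrophobicity(sequence: str, scale="kyte-doolittle") -> float:
    """Arithmetic mean of per-residue hydrophobicity values."""
    seq = validate_sequence(sequence)
    table = _resolve_scale(scale)
    return float(np.mean([table[aa] for aa in seq]))


def secondary_propensity(sequence: str) -> tuple[float, float]:
    """(mean helix propensity, mean strand propensity)."""
    seq = validate_sequence(sequence)
    helix = float(np.mean([HELIX_PROPENSITY[aa] for aa in seq]))
    beta = float(np.mean([BETA_PROPENSITY[aa] for aa in seq]))
    return helix, beta


def _z(value: float, table: dict[str, float]) -> float:
    vals = np.array([table[aa] for aa in CANONICAL])
    return float((value - vals.mean()) / vals.std())


def aggregation_score(
    sequence: str,
    weights: dict[str, float] | None = None,
    hydrophobicity_scale="kyte-doolittle",
) -> float:
    """Composite aggregation propensity (dimensionless, higher = worse).

    score = w_h * z(hydrophobicity) + w_q * z(-|net charge| / L)
          + w_b * z(beta propensity) - w_a * z(helix propensity)

    where each z-score is taken against the statistics of the corresponding
    20-residue table, so the weights are comparable across features.
    Required weight keys: hydrophobicity, charge, beta, helix.
    """
    seq = validate_sequence(sequence)
    weights = DEFAULT_WEIGHTS if weights is None else weights
    missing = [k for k in DEFAULT_WEIGHTS if k not in weights]
    if missing:
        raise ValueError(f"missing aggregation weights: {missing}")
    scale = _resolve_scale(hydrophobicity_scale)
    helix, beta = secondary_propensity(seq)
    charge_table = {aa: float(FORMAL_CHARGE[aa]) for aa in CANONICAL}
    per_residue_charge = -abs(net_charge(seq)) / len(seq)
    return (
        weights["hydrophobicity"] * _z(mean_hydrophobicity(seq, scale), scale)
        + weights["charge"] * _z(per_residue_charge, charge_table)
        + weights["beta"] * _z(beta, BETA_PROPENSITY)
        - weights["helix"] * _z(helix, HELIX_PROPENSITY)
    )


def sequence_features(
    sequence: str,
    weights: dict[str, float] | None = None,
    hydrophobicity_scale="kyte-doolittle",
) -> SequenceFeatures:
    """All compositional features for one sequence."""
    helix, beta = secondary_propensity(sequence)
    return SequenceFeatures(
        net_charge=net_charge(sequence),
        mean_hydrophobicity=mean_hydrophobicity(sequence, hydrophobicity_scale),
        helix_propensity=helix,
        beta_propensity=beta,
        aggregation_score=aggregation_score(
            sequence, weights, hydrophobicity_scale
        ),
    )
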