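"""Embedded per-atom energy parameters (version 1).

A deliberately small, self-contained united-atom parameter set: heavy atoms
only, with aliphatic/aromatic hydrogens folded into their parent carbon.
Lennard-Jones well depths and diameters are element-class based; partial
charges are per (residue, atom name) and sum exactly to the residue's formal
charge; atomic solvation parameters follow the classical
surface-area-weighted convention in which exposed apolar area is favourable
to bury (positive parameter) and exposed polar/charged area is favourable to
expose (negative parameter).

Units: sigma and radii in Angstrom, epsilon in kcal/mol, charges in
elementary charges, solvation parameters in kcal/(mol*A^2).

The set is versioned via :data:`PARAM_VERSION`; energies computed by this
package are comparable only within one parameter version.
"""

from __future__ import annotations

from .residues import CANONICAL, FORMAL_CHARGE

PARAM_VERSION = "httscan-params-1"

#: Lennard-Jones (sigma, epsilon) per element class.
LJ_BY_ELEMENT: dict[str, tuple[float, float]] = {
    "C": (3.55, 0.070),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.60, 0.250),
}

#: Van der Waals radii per element (for solvent-accessible surface area).
VDW_BY_ELEMENT: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Atomic solvation parameters per atom class, kcal/(mol*A^2).
SOLVATION_BY_CLASS: dict[str, float] = {
    "C": 0.016,       # apolar carbon
    "S": 0.021,
    "N": -0.006,      # neutral polar nitrogen
    "O": -0.006,      # neutral polar oxygen
    "O-": -0.024,     # carboxylate oxygen
    "N+": -0.050,     # protonated amine / guanidinium nitrogen
}

#: Atoms assigned to the charged solvation classes.
_CHARGED_OXYGENS = {
    ("D", "OD1"), ("D", "OD2"),
    ("E", "OE1"), ("E", "OE2"),
}
_CHARGED_NITROGENS = {
    ("K", "NZ"),
    ("R", "NE"), ("R", "NH1"), ("R", "NH2"),
}

#: Backbone partial charges, identical for all residues; they sum to zero so
#: that the side chain alone carries the formal charge.
BACKBONE_CHARGES: dict[str, float] = {
    "N": -0.40,
    "CA": 0.25,
    "C": 0.60,
    "O": -0.45,
}

#: Side-chain partial charges per residue; atoms not listed carry zero.
#: Within each residue the values sum to the formal charge exactly.
SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "A": {},
    "G": {},
    "V": {},
    "L": {},
    "I": {},
    "P": {},
    "F": {},
    "S": {"CB": 0.25, "OG": -0.25},
    "T": {"CB": 0.25, "OG1": -0.25},
    "C": {"CB": 0.15, "SG": -0.15},
    "M": {"CG": 0.05, "SD": -0.10, "CE": 0.05},
    "Y": {"CZ": 0.25, "OH": -0.25},
    "W": {"CD1": 0.05, "NE1": -0.10, "CE2": 0.05},
    "N": {"CG": 0.60, "OD1": -0.40, "ND2": -0.20},
    "Q": {"CD": 0.60, "OE1": -0.40, "NE2": -0.20},
    "H": {"CG": 0.10, "ND1": -0.20, "CD2": 0.00, "CE1": 0.30, "NE2": -0.20},
    "D": {"CG": 0.50, "OD1": -0.75, "OD2": -0.75},
    "E": {"CD": 0.50, "OE1": -0.75, "OE2": -0.75},
    "K": {"CE": 0.25, "NZ": 0.75},
    "R": {"NE": -0.20, "CZ": 0.50, "NH1": 0.35, "NH2": 0.35},
}


def partial_charge(residue: str, atom_name: str) -> float:
    """Partial charge for ``atom_name`` in a residue of type ``residue``."""
    if atom_name in BACKBONE_CHARGES:
        return BACKBONE_CHARGES[atom_name]
    return SIDECHAIN_CHARGES[residue].get(atom_name, 0.0)


def solvation_class(residue: str, atom_name: str, element: str) -> str:
    if (residue, atom_name) in _CHARGED_OXYGENS:
        return "O-"
    if (residue, atom_name) in _CHARGED_NITROGENS:
        return "N+"
    return element


def solvation_param(residue: str, atom_name: str, element: str) -> float:
    return SOLVATION_BY_CLASS[solvation_class(residue, atom_name, element)]


def _check_table() -> None:
    for aa in CANONICAL:
        total = sum(SIDECHAIN_CHARGES[aa].values())
        if abs(total - FORMAL_CHARGE[aa]) > 1e-9:
            raise AssertionError(
                f"side-chain charges of {aa} sum to {total}, "
                f"expected {FORMAL_CHARGE[aa]}"
            )
    if abs(sum(BACKBONE_CHARGES.values())) > 1e-9:
        raise AssertionError("backbone charges must sum to zero")


_check_table()
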