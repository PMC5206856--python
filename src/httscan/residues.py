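"""Canonical amino-acid constants shared across the package.

Residues are referred to by one-letter codes throughout; three-letter codes
appear only at the PDB boundary.  Protonation states are fixed at neutral pH:
Asp/Glu carry a formal charge of -1, Lys/Arg +1, His is neutral.
"""

from __future__ import annotations

CANONICAL: str = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

ONE_LETTER: dict[str, str] = {v: k for k, v in THREE_LETTER.items()}

#: Formal side-chain charge at neutral pH (elementary charges).
FORMAL_CHARGE: dict[str, int] = {aa: 0 for aa in CANONICAL}
FORMAL_CHARGE.update({"K": 1, "R": 1, "D": -1, "E": -1})

#: The native huntingtin N-terminal 17-mer (helical segment preceding the
#: polyglutamine tract).
NATIVE_HTT_NTERM: str = "MATLEKLMKAFESLKSF"


def validate_sequence(sequence: str) -> str:
    """Return ``sequence`` upper-cased, rejecting non-canonical letters."""
    seq = str(sequence).upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    for ch in seq:
        if ch not in CANONICAL:
            raise ValueError(
                f"non-canonical residue letter {ch!r}; "
                f"expected one of {CANONICAL}"
            )
    return seq
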