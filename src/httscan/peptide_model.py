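"""Peptide structures: ideal-helix construction, mutations, PDB exchange.

A :class:`Peptide` is a heavy-atom model of a short polypeptide.  Geometry
comes either from a PDB file or from :func:`build_ideal_helix`, which places
the backbone at canonical alpha-helical dihedrals (phi = -57 deg,
psi = -47 deg) and grafts one template side-chain conformer per residue type
onto it.  Templates are the ideal-coordinate heavy atoms of the chemical
component dictionary shipped with biotite, so side-chain placement is fully
deterministic: substituting a residue swaps in the mutant template on an
unchanged backbone, the way fixed-backbone mutant modelling tools do, and
leaves clash relief to energy minimization.

Termini are modelled uncharged (free NH2 / COOH without the OXT oxygen);
ionizable side chains are kept in their neutral-pH protonation states.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

from . import params
from .geometry import place_atom, rigid_fit
from .residues import CANONICAL, ONE_LETTER, THREE_LETTER, FORMAL_CHARGE, validate_sequence

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Ideal backbone internal coordinates (bond lengths in A, angles in deg).
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.0
_ANGLE_CA_C_N = 116.6
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_OMEGA = 180.0

HELIX_PHI = -57.0
HELIX_PSI = -47.0


@dataclass(frozen=True)
class Atom:
    """One heavy atom with the per-atom inputs of the energy model."""

    name: str
    element: str
    residue_index: int  # 1-based
    coords: np.ndarray
    partial_charge: float
    lj_sigma: float
    lj_epsilon: float
    solvation_param: float
    vdw_radius: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.lj_sigma <= 0 or self.lj_epsilon < 0 or self.vdw_radius <= 0:
            raise ValueError(f"invalid LJ/vdW parameters for atom {self.name}")


@dataclass(frozen=True)
class MutationSpec:
    """A single substitution in ``<wt><pos><mut>`` notation, e.g. ``L4K``."""

    position: int
    wild_type: str
    mutant: str

    def __post_init__(self):
        if self.wild_type not in CANONICAL:
            raise ValueError(f"non-canonical wild type {self.wild_type!r}")
        if self.mutant not in CANONICAL:
            raise ValueError(f"non-canonical mutant {self.mutant!r}")
        if self.position < 1:
            raise ValueError(f"position must be 1-based, got {self.position}")

    @property
    def is_identity(self) -> bool:
        return self.wild_type == self.mutant

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        text = text.strip().upper()
        if len(text) < 3:
            raise ValueError(f"cannot parse mutation {text!r}")
        wt, pos, mut = text[0], text[1:-1], text[-1]
        if not pos.isdigit():
            raise ValueError(f"cannot parse mutation {text!r}")
        return cls(position=int(pos), wild_type=wt, mutant=mut)

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


def parse_mutations(text: str) -> list[MutationSpec]:
    """Parse whitespace-separated mutation notation, e.g. ``"L4K E12K K15E"``."""
    return [MutationSpec.parse(tok) for tok in text.split()]


@dataclass
class Peptide:
    """Heavy-atom peptide model backed by flat numpy arrays.

    Atom order is residue-major: for each residue N, CA, C, O followed by the
    side-chain atoms in template order.
    """

    sequence: str
    atom_names: np.ndarray       # (n,) str
    elements: np.ndarray         # (n,) str
    residue_index: np.ndarray    # (n,) int, 1-based
    coords: np.ndarray           # (n, 3) float, Angstrom
    partial_charges: np.ndarray  # (n,) float, e
    lj_sigma: np.ndarray         # (n,) float, A
    lj_epsilon: np.ndarray       # (n,) float, kcal/mol
    solvation_params: np.ndarray  # (n,) float, kcal/(mol*A^2)
    vdw_radii: np.ndarray        # (n,) float, A
    bonds: np.ndarray            # (m, 2) int, covalent bonds by atom index
    residue_slices: list[slice] = field(default_factory=list)

    def __post_init__(self):
        if not self.residue_slices:
            self.residue_slices = _slices_from_residue_index(self.residue_index)
        self.validate()

    # -- queries ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def atom_index(self, residue: int, name: str) -> int:
        """Index of atom ``name`` in 1-based residue ``residue``."""
        sl = self.residue_slices[residue - 1]
        for i in range(sl.start, sl.stop):
            if self.atom_names[i] == name:
                return i
        raise KeyError(f"residue {residue} has no atom {name!r}")

    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.atom_names, BACKBONE_ATOMS)

    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atom_names == "CA")

    def atoms(self):
        """Iterate over :class:`Atom` views (convenience, not the hot path)."""
        for i in range(self.n_atoms):
            yield Atom(
                name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                residue_index=int(self.residue_index[i]),
                coords=self.coords[i].copy(),
                partial_charge=float(self.partial_charges[i]),
                lj_sigma=float(self.lj_sigma[i]),
                lj_epsilon=float(self.lj_epsilon[i]),
                solvation_param=float(self.solvation_params[i]),
                vdw_radius=float(self.vdw_radii[i]),
            )

    def copy(self) -> "Peptide":
        return Peptide(
            sequence=self.sequence,
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            residue_index=self.residue_index.copy(),
            coords=self.coords.copy(),
            partial_charges=self.partial_charges.copy(),
            lj_sigma=self.lj_sigma.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            solvation_params=self.solvation_params.copy(),
            vdw_radii=self.vdw_radii.copy(),
            bonds=self.bonds.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "Peptide":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).copy()
        if out.coords.shape != self.coords.shape:
            raise ValueError("coordinate array shape mismatch")
        return out

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if len(self.residue_slices) != self.n_residues:
            raise ValueError("residue bookkeeping inconsistent with sequence")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        lo, hi = self.residue_index.min(), self.residue_index.max()
        if lo < 1 or hi > self.n_residues:
            raise ValueError("atom residue_index outside [1, n_residues]")
        for ri, sl in enumerate(self.residue_slices, start=1):
            names = list(self.atom_names[sl])
            for bb in BACKBONE_ATOMS:
                if names.count(bb) != 1:
                    raise ValueError(
                        f"residue {ri} must contain exactly one {bb} atom"
                    )
            q = float(self.partial_charges[sl].sum())
            formal = FORMAL_CHARGE[self.sequence[ri - 1]]
            if abs(q - formal) > 1e-6:
                raise ValueError(
                    f"residue {ri} charges sum to {q}, expected {formal}"
                )


def _slices_from_residue_index(residue_index: np.ndarray) -> list[slice]:
    slices = []
    n = len(residue_index)
    start = 0
    for i in range(1, n + 1):
        if i == n or residue_index[i] != residue_index[i - 1]:
            slices.append(slice(start, i))
            start = i
    return slices


# -- residue templates ----------------------------------------------------

@functools.lru_cache(maxsize=None)
def residue_template(one_letter: str):
    """Heavy-atom ideal-coordinate template for one residue type.

    Returns ``(names, elements, coords, bonds)`` with atoms ordered backbone
    first (N, CA, C, O) then side chain; bonds are index pairs within the
    template.
    """
    if one_letter not in CANONICAL:
        raise ValueError(f"non-canonical residue {one_letter!r}")
    arr = struc_info.residue(THREE_LETTER[one_letter])
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    idx = np.flatnonzero(keep)
    names = [str(n) for n in arr.atom_name[idx]]
    # reorder: backbone first, then remaining in CCD order
    order = [names.index(bb) for bb in BACKBONE_ATOMS]
    order += [i for i in range(len(names)) if i not in order]
    idx = idx[order]
    names = [str(n) for n in arr.atom_name[idx]]
    elements = [str(e) for e in arr.element[idx]]
    coords = np.asarray(arr.coord[idx], dtype=float)
    remap = {int(a): i for i, a in enumerate(idx)}
    bonds = []
    for a, b, _ in arr.bonds.as_array():
        if int(a) in remap and int(b) in remap:
            bonds.append((remap[int(a)], remap[int(b)]))
    return names, elements, coords, np.asarray(sorted(bonds), dtype=int)


def _sidechain_block(one_letter: str, backbone_nca_c: np.ndarray):
    """Template side-chain atoms grafted onto a backbone frame.

    ``backbone_nca_c`` holds the target N, CA, C coordinates.  Returns
    ``(names, elements, coords)`` for the side-chain atoms only.
    """
    names, elements, coords, _ = residue_template(one_letter)
    template_frame = coords[:3]  # N, CA, C
    r, t = rigid_fit(template_frame, backbone_nca_c)
    side = [i for i, n in enumerate(names) if n not in BACKBONE_ATOMS]
    return (
        [names[i] for i in side],
        [elements[i] for i in side],
        coords[side] @ r.T + t,
    )


def _assemble(sequence: str, blocks: list[dict]) -> Peptide:
    """Build a parameterized Peptide from per-residue atom blocks."""
    atom_names, elements, residue_index, coords = [], [], [], []
    charges, sig, eps, solv, vdw = [], [], [], [], []
    bonds = []
    offset = 0
    offsets = []
    for ri, (aa, block) in enumerate(zip(sequence, blocks), start=1):
        offsets.append(offset)
        tnames, telements, tcoords, tbonds = residue_template(aa)
        name_to_local = {n: i for i, n in enumerate(block["names"])}
        for n, e, xyz in zip(block["names"], block["elements"], block["coords"]):
            atom_names.append(n)
            elements.append(e)
            residue_index.append(ri)
            coords.append(xyz)
            charges.append(params.partial_charge(aa, n))
            s, ep = params.LJ_BY_ELEMENT[e]
            sig.append(s)
            eps.append(ep)
            solv.append(params.solvation_param(aa, n, e))
            vdw.append(params.VDW_BY_ELEMENT[e])
        # intra-residue bonds from the template, restricted to present atoms
        for a, b in tbonds:
            na, nb = tnames[a], tnames[b]
            if na in name_to_local and nb in name_to_local:
                bonds.append((offset + name_to_local[na], offset + name_to_local[nb]))
        offset += len(block["names"])
    # peptide bonds C(i) - N(i+1)
    for ri in range(len(sequence) - 1):
        ci = offsets[ri] + blocks[ri]["names"].index("C")
        ni = offsets[ri + 1] + blocks[ri + 1]["names"].index("N")
        bonds.append((ci, ni))
    return Peptide(
        sequence=sequence,
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_index=np.array(residue_index, dtype=int),
        coords=np.array(coords, dtype=float),
        partial_charges=np.array(charges, dtype=float),
        lj_sigma=np.array(sig, dtype=float),
        lj_epsilon=np.array(eps, dtype=float),
        solvation_params=np.array(solv, dtype=float),
        vdw_radii=np.array(vdw, dtype=float),
        bonds=np.array(sorted(set(map(tuple, map(sorted, bonds)))), dtype=int),
    )


# -- construction ----------------------------------------------------------

def build_ideal_helix(sequence: str) -> Peptide:
    """Build an idealized alpha-helical peptide from sequence.

    Backbone dihedrals are fixed at phi = -57 deg, psi = -47 deg with planar
    trans peptide bonds; side chains are placed from per-residue-type
    template conformers.  The construction is deterministic.
    """
    sequence = validate_sequence(sequence)
    n_res = len(sequence)

    bb_n = np.zeros((n_res, 3))
    bb_ca = np.zeros((n_res, 3))
    bb_c = np.zeros((n_res, 3))
    bb_o = np.zeros((n_res, 3))

    # seed residue 1 in the xy-plane
    bb_n[0] = [0.0, 0.0, 0.0]
    bb_ca[0] = [_BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(180.0 - _ANGLE_N_CA_C)
    bb_c[0] = bb_ca[0] + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res - 1):
        bb_n[i + 1] = place_atom(
            bb_n[i], bb_ca[i], bb_c[i], _BOND_C_N, _ANGLE_CA_C_N, HELIX_PSI
        )
        bb_ca[i + 1] = place_atom(
            bb_ca[i], bb_c[i], bb_n[i + 1], _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA
        )
        bb_c[i + 1] = place_atom(
            bb_c[i], bb_n[i + 1], bb_ca[i + 1], _BOND_CA_C, _ANGLE_N_CA_C, HELIX_PHI
        )
    for i in range(n_res):
        # carbonyl O anti to the next amide N (psi + 180)
        bb_o[i] = place_atom(
            bb_n[i], bb_ca[i], bb_c[i], _BOND_C_O, _ANGLE_CA_C_O, HELIX_PSI + 180.0
        )

    blocks = []
    for i, aa in enumerate(sequence):
        frame = np.array([bb_n[i], bb_ca[i], bb_c[i]])
        snames, selements, scoords = _sidechain_block(aa, frame)
        blocks.append(
            {
                "names": list(BACKBONE_ATOMS) + snames,
                "elements": ["N", "C", "C", "O"] + selements,
                "coords": np.vstack([frame, bb_o[i][None, :], scoords])
                if snames
                else np.vstack([frame, bb_o[i][None, :]]),
            }
        )
    return _assemble(sequence, blocks)


def apply_mutation(peptide: Peptide, mutation: MutationSpec) -> Peptide:
    """Substitute one residue's side chain on a fixed backbone.

    The mutant side chain is the residue-type template conformer grafted onto
    the existing backbone frame; all backbone coordinates and all other
    residues are preserved bit-for-bit.  Identity mutations return an exact
    copy.
    """
    pos = mutation.position
    if not 1 <= pos <= peptide.n_residues:
        raise ValueError(
            f"mutation position {pos} outside sequence of length {peptide.n_residues}"
        )
    found = peptide.sequence[pos - 1]
    if found != mutation.wild_type:
        raise ValueError(
            f"wild-type mismatch at position {pos}: mutation expects "
            f"{mutation.wild_type}, sequence has {found}"
        )
    if mutation.is_identity:
        return peptide.copy()

    new_seq = peptide.sequence[: pos - 1] + mutation.mutant + peptide.sequence[pos:]
    blocks = []
    for ri in range(1, peptide.n_residues + 1):
        sl = peptide.residue_slices[ri - 1]
        if ri != pos:
            blocks.append(
                {
                    "names": [str(n) for n in peptide.atom_names[sl]],
                    "elements": [str(e) for e in peptide.elements[sl]],
                    "coords": peptide.coords[sl].copy(),
                }
            )
            continue
        frame = np.array(
            [
                peptide.coords[peptide.atom_index(ri, "N")],
                peptide.coords[peptide.atom_index(ri, "CA")],
                peptide.coords[peptide.atom_index(ri, "C")],
            ]
        )
        o_coord = peptide.coords[peptide.atom_index(ri, "O")]
        snames, selements, scoords = _sidechain_block(mutation.mutant, frame)
        coords = np.vstack([frame, o_coord[None, :], scoords]) if snames else np.vstack(
            [frame, o_coord[None, :]]
        )
        blocks.append(
            {
                "names": list(BACKBONE_ATOMS) + snames,
                "elements": ["N", "C", "C", "O"] + selements,
                "coords": coords,
            }
        )
    return _assemble(new_seq, blocks)


def apply_mutations(peptide: Peptide, mutations: list[MutationSpec]) -> Peptide:
    """Apply several substitutions sequentially (distinct positions)."""
    seen = set()
    out = peptide
    for m in mutations:
        if m.position in seen:
            raise ValueError(f"duplicate mutation position {m.position}")
        seen.add(m.position)
        out = apply_mutation(out, m)
    return out


# -- PDB I/O ---------------------------------------------------------------

def _prevalidate_pdb(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"unparseable ATOM record at line {lineno} of {path}"
                ) from None


def read_pdb(path) -> Peptide:
    """Read a peptide from a PDB file.

    Residues are renumbered 1..N in order of appearance (a fragment numbered
    371-387 becomes 1-17); hydrogens, OXT and non-template atoms are dropped;
    charges and energy parameters are re-assigned from the embedded table.
    """
    _prevalidate_pdb(path)
    pdb = PDBFile.read(path)
    arr = pdb.get_structure(model=1)
    arr = arr[arr.element != "H"]
    if arr.array_length() == 0:
        raise ValueError(f"no atoms found in {path}")

    sequence = []
    blocks = []
    for ri, res in enumerate(struc.residue_iter(arr), start=1):
        res_name = str(res.res_name[0])
        if res_name not in ONE_LETTER:
            raise ValueError(f"unsupported residue {res_name!r} at position {ri}")
        aa = ONE_LETTER[res_name]
        tnames, telements, _, _ = residue_template(aa)
        have = {str(n): i for i, n in enumerate(res.atom_name)}
        for bb in BACKBONE_ATOMS:
            if bb not in have:
                raise ValueError(f"residue {ri} is missing backbone atom {bb}")
        names, elements, coords = [], [], []
        for n, e in zip(tnames, telements):
            if n in have:
                names.append(n)
                elements.append(e)
                coords.append(np.asarray(res.coord[have[n]], dtype=float))
        sequence.append(aa)
        blocks.append(
            {"names": names, "elements": elements, "coords": np.array(coords)}
        )
    return _assemble("".join(sequence), blocks)


def write_pdb(peptide: Peptide, path) -> None:
    """Write a peptide as standard ATOM records (single chain A)."""
    n = peptide.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(peptide.coords, dtype=np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = peptide.residue_index.astype(int)
    arr.res_name = np.array(
        [THREE_LETTER[peptide.sequence[ri - 1]] for ri in peptide.residue_index]
    )
    arr.atom_name = peptide.atom_names.astype(str)
    arr.element = peptide.elements.astype(str)
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)
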