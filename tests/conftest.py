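"""Shared fixtures: toy atom clouds for energy-term oracles."""

from __future__ import annotations

import numpy as np
import pytest


class AtomCloud:
    """Minimal stand-in satisfying the peptide interface the energy terms use.

    Each atom is its own residue and there are no bonds, so every pair is
    included in the nonbonded sums — convenient for closed-form and
    brute-force oracle checks.
    """

    def __init__(self, coords, charges=None, sigma=3.5, epsilon=0.2,
                 solvation=0.0, vdw=1.7):
        self.coords = np.asarray(coords, dtype=float)
        n = len(self.coords)
        self.atom_names = np.array([f"X{i}" for i in range(n)], dtype=object)
        self.elements = np.array(["C"] * n, dtype=object)
        self.residue_index = np.arange(1, n + 1)
        self.partial_charges = (
            np.zeros(n) if charges is None else np.asarray(charges, dtype=float)
        )
        self.lj_sigma = np.full(n, sigma) if np.isscalar(sigma) else np.asarray(sigma)
        self.lj_epsilon = (
            np.full(n, epsilon) if np.isscalar(epsilon) else np.asarray(epsilon)
        )
        self.solvation_params = (
            np.full(n, solvation) if np.isscalar(solvation)
            else np.asarray(solvation)
        )
        self.vdw_radii = np.full(n, vdw) if np.isscalar(vdw) else np.asarray(vdw)
        self.bonds = np.empty((0, 2), dtype=int)
        self.residue_slices = [slice(i, i + 1) for i in range(n)]

    @property
    def n_atoms(self):
        return len(self.coords)

    def backbone_mask(self):
        return np.zeros(self.n_atoms, dtype=bool)

    def with_coords(self, coords):
        out = AtomCloud(coords)
        out.atom_names = self.atom_names
        out.elements = self.elements
        out.residue_index = self.residue_index
        out.partial_charges = self.partial_charges
        out.lj_sigma = self.lj_sigma
        out.lj_epsilon = self.lj_epsilon
        out.solvation_params = self.solvation_params
        out.vdw_radii = self.vdw_radii
        out.bonds = self.bonds
        out.residue_slices = self.residue_slices
        return out


@pytest.fixture
def make_cloud():
    return AtomCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
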