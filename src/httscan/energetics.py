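"""Decomposed stability energy E = solvation + Lennard-Jones + Coulomb.

The nonbonded terms use standard pairwise forms with Lorentz-Berthelot
combining, a plain distance cutoff (no periodic boundary, no Ewald sum) and
1-2/1-3 bonded exclusions; in addition all pairs within one residue are
excluded, so the model scores packing and electrostatics *between* residues
and against solvent rather than intra-residue strain.  The solvation term
defaults to a solvent-accessible-surface-area model: each atom contributes
its atomic solvation parameter times its exposed area, computed by a
deterministic sphere-point (Shrake-Rupley style) estimate with a 1.4 A water
probe.  Alternative solvation backends (e.g. a Poisson-Boltzmann style
solver) can be registered under other model identifiers.

Sign convention: lower E is more stable, and dE = E - E0 against the native
structure is negative for stabilizing mutations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .peptide_model import Peptide

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class SolvationConfig:
    """Solvation-term settings.

    ``probe_radius`` and ``temperature`` are used by the default SASA model.
    The dipolar-solvent parameters (``dipole_moment_p0`` in Debye,
    ``dipole_concentration_cdip`` in mol/L, ``grid_spacing_a`` in Angstrom)
    describe the water model a grid-based dipolar Poisson-Boltzmann backend
    would use; they are carried in the config for interface parity but the
    default backend does not consume them.
    """

    probe_radius: float = 1.4            # A
    temperature: float = 300.0           # K
    dipole_moment_p0: float = 3.00       # D
    dipole_concentration_cdip: float = 55.0  # mol/L
    grid_spacing_a: float = 2.8          # A
    model: str = "sasa"
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class EnergyModelConfig:
    """Nonbonded energy settings (distances in A, energies in kcal/mol)."""

    cutoff: float = 10.0
    relative_permittivity: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT
    solvation: SolvationConfig = field(default_factory=SolvationConfig)

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.relative_permittivity < 1:
            raise ValueError("relative_permittivity must be >= 1")

    def config_hash(self) -> str:
        """Short stable hash identifying this configuration."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy decomposition; ``total`` is the sum of the three terms."""

    lj: float
    coulomb: float
    solvation: float

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.solvation


# -- pair bookkeeping ------------------------------------------------------

def _bond_adjacency(peptide: Peptide) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(peptide.n_atoms)]
    for a, b in peptide.bonds:
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    return adj


def _excluded_pairs(peptide: Peptide) -> set[tuple[int, int]]:
    """Pairs excluded from nonbonded terms.

    Excluded: any two atoms of the same residue, and any 1-2 or 1-3 bonded
    pair (which only adds pairs across the peptide bond).
    """
    excluded: set[tuple[int, int]] = set()
    for sl in peptide.residue_slices:
        for i in range(sl.start, sl.stop):
            for j in range(i + 1, sl.stop):
                excluded.add((i, j))
    adj = _bond_adjacency(peptide)
    for i in range(peptide.n_atoms):
        for j in adj[i]:
            for pair in [(i, j)]:
                a, b = min(pair), max(pair)
                excluded.add((a, b))
            for k in adj[j]:
                if k != i:
                    a, b = min(i, k), max(i, k)
                    excluded.add((a, b))
    return excluded


class _PairTable:
    """Precomputed included-pair indices and combined parameters."""

    def __init__(self, peptide: Peptide, config: EnergyModelConfig):
        n = peptide.n_atoms
        excluded = _excluded_pairs(peptide)
        ii, jj = np.triu_indices(n, k=1)
        keep = np.array(
            [(int(a), int(b)) not in excluded for a, b in zip(ii, jj)],
            dtype=bool,
        )
        self.ii = ii[keep]
        self.jj = jj[keep]
        sig = peptide.lj_sigma
        eps = peptide.lj_epsilon
        q = peptide.partial_charges
        self.sigma_ij = 0.5 * (sig[self.ii] + sig[self.jj])
        self.eps_ij = np.sqrt(eps[self.ii] * eps[self.jj])
        self.kqq_ij = (
            config.coulomb_constant
            * q[self.ii] * q[self.jj]
            / config.relative_permittivity
        )
        self.cutoff = config.cutoff
        self.names = peptide.atom_names
        self.residues = peptide.residue_index

    def _distances(self, coords: np.ndarray) -> np.ndarray:
        d = coords[self.ii] - coords[self.jj]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        if np.any(r < 1e-9):
            k = int(np.argmin(r))
            a, b = self.ii[k], self.jj[k]
            raise ValueError(
                f"zero interatomic distance between atom {self.names[a]} "
                f"(residue {self.residues[a]}) and atom {self.names[b]} "
                f"(residue {self.residues[b]})"
            )
        return r

    def lj(self, coords: np.ndarray) -> float:
        r = self._distances(coords)
        mask = r <= self.cutoff
        sr6 = (self.sigma_ij[mask] / r[mask]) ** 6
        return float(np.sum(4.0 * self.eps_ij[mask] * (sr6 * sr6 - sr6)))

    def coulomb(self, coords: np.ndarray) -> float:
        r = self._distances(coords)
        mask = r <= self.cutoff
        return float(np.sum(self.kqq_ij[mask] / r[mask]))

    def energy_and_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """LJ + Coulomb energy and its gradient w.r.t. coordinates."""
        d = coords[self.ii] - coords[self.jj]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        if np.any(r < 1e-9):
            self._distances(coords)  # raises with atom names
        mask = r <= self.cutoff
        ii, jj = self.ii[mask], self.jj[mask]
        d, r = d[mask], r[mask]
        sig, eps, kqq = self.sigma_ij[mask], self.eps_ij[mask], self.kqq_ij[mask]
        sr6 = (sig / r) ** 6
        e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
        e_cb = kqq / r
        # dE/dr for both terms
        dlj = -24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
        dcb = -kqq / r**2
        coef = (dlj + dcb) / r
        pair_grad = coef[:, None] * d
        grad = np.zeros_like(coords)
        np.add.at(grad, ii, pair_grad)
        np.add.at(grad, jj, -pair_grad)
        return float(e_lj.sum() + e_cb.sum()), grad


# -- public energy terms ---------------------------------------------------

def lj_energy(peptide: Peptide, config: EnergyModelConfig | None = None) -> float:
    """Lennard-Jones energy (kcal/mol) over included pairs within cutoff."""
    config = config or EnergyModelConfig()
    return _PairTable(peptide, config).lj(peptide.coords)


def coulomb_energy(peptide: Peptide, config: EnergyModelConfig | None = None) -> float:
    """Coulomb energy (kcal/mol) over included pairs within cutoff."""
    config = config or EnergyModelConfig()
    return _PairTable(peptide, config).coulomb(peptide.coords)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, approximately uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Coordinates re-expressed in a molecule-fixed frame.

    Centers on the centroid and aligns to the principal axes of the gyration
    tensor with a deterministic sign convention, so that the sphere-point
    surface estimate is invariant under global rotation and translation of
    the input (for generic, non-degenerate configurations).
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) < 3:
        return centered
    gyr = centered.T @ centered
    _, vecs = np.linalg.eigh(gyr)
    # fix each axis sign by the coordinate skewness along it
    proj = centered @ vecs
    sign = np.sign(np.sum(proj**3, axis=0))
    sign[sign == 0] = 1.0
    vecs = vecs * sign
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    return centered @ vecs


def sasa(
    peptide: Peptide,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Sphere-point estimate: each atom's accessible fraction is the fraction of
    a deterministic point set on its probe-expanded sphere lying outside all
    neighbours' probe-expanded spheres.  Computed in a molecule-fixed
    canonical frame, so the result does not depend on the global pose.
    """
    if n_sphere_points < 100:
        raise ValueError("n_sphere_points must be >= 100")
    coords = _canonical_frame(peptide.coords)
    radii = peptide.vdw_radii + probe_radius
    n = peptide.n_atoms
    unit = _sphere_points(n_sphere_points)
    areas = np.zeros(n)
    # neighbour lists via one distance matrix (peptides are small)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    for i in range(n):
        cut = radii[i] + radii
        neigh = np.flatnonzero((dist[i] < cut) & (np.arange(n) != i))
        pts = coords[i] + radii[i] * unit
        if neigh.size:
            d2 = np.sum(
                (pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2
            )
            accessible = np.all(d2 >= (radii[neigh] ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return areas


def _sasa_solvation(peptide: Peptide, config: SolvationConfig) -> float:
    areas = sasa(peptide, config.probe_radius, config.n_sphere_points)
    return float(np.dot(peptide.solvation_params, areas))


_SOLVATION_BACKENDS: dict[str, Callable[[Peptide, SolvationConfig], float]] = {
    "sasa": _sasa_solvation,
}


def register_solvation_model(
    name: str, fn: Callable[[Peptide, SolvationConfig], float]
) -> None:
    """Register an alternative solvation backend under ``name``."""
    _SOLVATION_BACKENDS[name] = fn


def solvation_energy(
    peptide: Peptide, config: SolvationConfig | None = None
) -> float:
    """Solvation energy (kcal/mol) via the configured backend."""
    config = config or SolvationConfig()
    try:
        backend = _SOLVATION_BACKENDS[config.model]
    except KeyError:
        raise ValueError(
            f"unknown solvation model {config.model!r}; registered: "
            f"{sorted(_SOLVATION_BACKENDS)}"
        ) from None
    return backend(peptide, config)


def total_energy(
    peptide: Peptide, config: EnergyModelConfig | None = None
) -> EnergyBreakdown:
    """Full decomposition E = LJ + Coulomb + solvation."""
    config = config or EnergyModelConfig()
    table = _PairTable(peptide, config)
    return EnergyBreakdown(
        lj=table.lj(peptide.coords),
        coulomb=table.coulomb(peptide.coords),
        solvation=solvation_energy(peptide, config.solvation),
    )


def delta_e(mutant_total: float, native_total: float) -> float:
    """Stability change dE = E - E0; negative means more stable than native."""
    return mutant_total - native_total


# -- minimization ----------------------------------------------------------

@dataclass
class MinimizationResult:
    peptide: Peptide
    energies: list[float]   # objective (LJ+Coulomb) after each accepted step
    totals: list[float]     # total incl. solvation after each accepted step
    n_steps: int
    converged: bool


def minimize(
    peptide: Peptide,
    config: EnergyModelConfig | None = None,
    max_steps: int = 200,
    force_tol: float = 0.1,
    backbone_fixed: bool = True,
    full_output: bool = False,
    track_solvation: bool = True,
):
    """Steepest-descent relaxation of steric clashes.

    Moves atoms down the LJ+Coulomb gradient with an adaptive step length
    (halved on uphill trials); the solvation term is held constant during
    each line search and re-evaluated once per accepted step, and a trial
    step is only accepted if the total energy does not increase.  Stops when
    the largest gradient component on movable atoms falls below ``force_tol``
    (kcal/(mol*A)), after ``max_steps`` accepted steps, or when the step
    length underflows.  With ``backbone_fixed`` the N/CA/C/O coordinates are
    left untouched.  Set ``track_solvation=False`` to minimize LJ+Coulomb
    only (faster; solvation then plays no role in step acceptance).
    """
    config = config or EnergyModelConfig()
    table = _PairTable(peptide, config)
    coords = peptide.coords.copy()
    movable = ~peptide.backbone_mask() if backbone_fixed else np.ones(
        peptide.n_atoms, dtype=bool
    )

    energy, grad = table.energy_and_gradient(coords)
    if not np.isfinite(energy):
        raise ValueError(
            "non-finite energy at start of minimization (severe clash); "
            "increase the initial atomic separation"
        )
    solv = solvation_energy(peptide.with_coords(coords), config.solvation) \
        if track_solvation else 0.0
    energies = [energy]
    totals = [energy + solv]

    step = 0.1  # max per-atom displacement, A
    n_accepted = 0
    converged = False
    while n_accepted < max_steps:
        g = np.where(movable[:, None], grad, 0.0)
        gmax = np.abs(g).max()
        if gmax <= force_tol:
            converged = True
            break
        direction = -g / gmax
        accepted = False
        while step >= 1e-7:
            trial = coords + step * direction
            try:
                e_trial, g_trial = table.energy_and_gradient(trial)
            except ValueError:
                e_trial = np.inf
                g_trial = None
            if np.isfinite(e_trial) and e_trial < energy:
                if track_solvation:
                    s_trial = solvation_energy(
                        peptide.with_coords(trial), config.solvation
                    )
                    if e_trial + s_trial > totals[-1] + 1e-12:
                        step *= 0.5
                        continue
                    solv = s_trial
                coords = trial
                energy, grad = e_trial, g_trial
                energies.append(energy)
                totals.append(energy + solv)
                n_accepted += 1
                step = min(step * 1.2, 0.5)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break

    out = peptide.with_coords(coords)
    if full_output:
        return MinimizationResult(
            peptide=out,
            energies=energies,
            totals=totals,
            n_steps=n_accepted,
            converged=converged,
        )
    return out
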