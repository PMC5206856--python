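"""RMSD/RMSF trajectory statistics and a synthetic-trajectory generator.

RMSD between two frames is computed after optimal least-squares rigid
superposition (centroid alignment plus the SVD-based optimal rotation, with
reflection correction); RMSF is the per-atom root-mean-square displacement
about a reference position over a trajectory, with the time-averaged
position as the default reference.  The synthetic generator produces frames
as a reference structure plus i.i.d. per-coordinate Gaussian noise, which
emulates harmonic positional fluctuation about a stable structure — enough
to exercise and calibrate the estimators, though unlike molecular dynamics
it has no time correlation, anisotropy, or collective motion.  For isotropic
noise of standard deviation sigma per axis the expected RMSF is
sigma * sqrt(3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import rigid_fit

#: Frame spacing of the synthetic generator, ps.
FRAME_SPACING_PS = 10.0


@dataclass
class Trajectory:
    """Time-ordered coordinate frames (frame x atom x 3, Angstrom)."""

    coords: np.ndarray
    times: np.ndarray | None = None   # ps
    atom_selection: np.ndarray | None = None
    reference: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.times is None:
            self.times = FRAME_SPACING_PS * np.arange(self.n_frames)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames:
            raise ValueError("times length must equal number of frames")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != self.coords.shape[1:]:
                raise ValueError("reference frame has wrong atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def selected(self) -> np.ndarray:
        """Frames restricted to the atom selection (all atoms if unset)."""
        if self.atom_selection is None:
            return self.coords
        return self.coords[:, self.atom_selection, :]


def rmsd(mobile: np.ndarray, reference: np.ndarray, superpose: bool = True) -> float:
    """Root-mean-square deviation between two frames, Angstrom.

    With ``superpose`` the mobile frame is first fitted onto the reference by
    the optimal rigid-body rotation/translation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"atom count mismatch: {mobile.shape} vs {reference.shape}"
        )
    if superpose:
        if len(mobile) < 3:
            raise ValueError("superposition requires at least 3 atoms")
        r, t = rigid_fit(mobile, reference)
        mobile = mobile @ r.T + t
    diff = mobile - reference
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))


def rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD against a reference (default: the first frame)."""
    frames = trajectory.selected()
    if reference is None:
        reference = (
            trajectory.reference if trajectory.reference is not None
            else frames[0]
        )
        if trajectory.atom_selection is not None and reference.shape[0] != frames.shape[1]:
            reference = reference[trajectory.atom_selection]
    return np.array([rmsd(f, reference, superpose=superpose) for f in frames])


def rmsf(
    trajectory: Trajectory,
    reference_mode: str = "mean",
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about a reference position.

    ``reference_mode`` is ``"mean"`` (time-averaged position, the default),
    ``"first"`` (first frame), or ``"provided"`` (use ``reference``).
    """
    frames = trajectory.selected()
    if trajectory.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if reference_mode == "mean":
        ref = frames.mean(axis=0)
    elif reference_mode == "first":
        ref = frames[0]
    elif reference_mode == "provided":
        if reference is None:
            raise ValueError("reference_mode='provided' requires a reference")
        ref = np.asarray(reference, dtype=float)
        if ref.shape != frames.shape[1:]:
            raise ValueError(
                f"reference has shape {ref.shape}, expected {frames.shape[1:]}"
            )
    else:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    diff = frames - ref[None, :, :]
    return np.sqrt(np.mean(np.einsum("fij,fij->fi", diff, diff), axis=0))


def synthetic_trajectory(
    reference: np.ndarray,
    sigma: float,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Frames = reference + i.i.d. Gaussian noise of std ``sigma`` per axis.

    Reproducible for a fixed seed; frames are spaced 10 ps apart.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    reference = np.asarray(reference, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(n_frames,) + reference.shape) \
        if sigma > 0 else np.zeros((n_frames,) + reference.shape)
    return Trajectory(
        coords=reference[None, :, :] + noise,
        times=FRAME_SPACING_PS * np.arange(n_frames),
        reference=reference.copy(),
    )


# -- I/O -------------------------------------------------------------------

def read_trajectory_csv(path) -> Trajectory:
    """Read a (frame, atom, x, y, z) CSV written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    frames = sorted(df["frame"].unique())
    coords = np.stack(
        [
            df[df["frame"] == f].sort_values("atom")[["x", "y", "z"]].to_numpy()
            for f in frames
        ]
    )
    return Trajectory(coords=coords)


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    records = []
    for f in range(trajectory.n_frames):
        for a in range(trajectory.n_atoms):
            x, y, z = trajectory.coords[f, a]
            records.append((f, a, x, y, z))
    pd.DataFrame(records, columns=["frame", "atom", "x", "y", "z"]).to_csv(
        path, index=False
    )


def read_trajectory_pdb(path, ca_only: bool = True) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL records) as a trajectory."""
    from biotite.structure.io.pdb import PDBFile
    import biotite.structure as struc

    pdb = PDBFile.read(path)
    stack = pdb.get_structure()  # AtomArrayStack
    coords = np.asarray(stack.coord, dtype=float)
    traj = Trajectory(coords=coords)
    if ca_only:
        traj.atom_selection = np.flatnonzero(stack.atom_name == "CA")
    return traj
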