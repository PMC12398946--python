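"""Per-residue backbone RMSF averaged over replicate trajectories.

RMSF of residue r is the root of the mean (over frames and that residue's
selected backbone atoms N, CA, C, O) squared displacement from each atom's
time-averaged position.  Replicate averaging is of the per-replicate RMSF
profiles, not of pooled displacements, which keeps the profile robust to
slow per-replicate drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptySelectionError
from .structure_io import Trajectory, TrajectoryEnsemble

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class RMSFProfile:
    """residue_number -> RMSF (A)."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray
    replicate_count: int = 1
    selection: str = "backbone N,CA,C,O"

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(v) for r, v in zip(self.residue_numbers, self.rmsf)}

    def restrict(self, lo: int, hi: int) -> "RMSFProfile":
        mask = (self.residue_numbers >= lo) & (self.residue_numbers <= hi)
        return RMSFProfile(
            residue_numbers=self.residue_numbers[mask],
            rmsf=self.rmsf[mask],
            replicate_count=self.replicate_count,
            selection=self.selection,
        )


def rmsf(traj: Trajectory) -> RMSFProfile:
    """Per-residue backbone RMSF referenced to the time-averaged structure."""
    if traj.n_frames < 2:
        raise EmptySelectionError("RMSF undefined for a single-frame trajectory")
    idx = [
        i for i, rec in enumerate(traj.topology.protein) if rec.atom_name in BACKBONE_NAMES
    ]
    if not idx:
        raise EmptySelectionError("no backbone atoms in trajectory")
    coords = traj.protein[:, idx, :]
    resnums = np.array([traj.topology.protein[i].residue_number for i in idx])
    mean_pos = coords.mean(axis=0)
    sq = ((coords - mean_pos[None, ...]) ** 2).sum(axis=2)  # (frames, atoms)
    msd_per_atom = sq.mean(axis=0)
    unique_res = np.unique(resnums)
    values = np.array(
        [np.sqrt(msd_per_atom[resnums == r].mean()) for r in unique_res]
    )
    return RMSFProfile(residue_numbers=unique_res, rmsf=values)


def ensemble_rmsf(ensemble: TrajectoryEnsemble) -> RMSFProfile:
    """Unweighted mean of per-replicate RMSF profiles."""
    if len(ensemble) < 1:
        raise EmptySelectionError("ensemble has no replicates")
    profiles = [rmsf(t) for t in ensemble]
    ref = profiles[0].residue_numbers
    for p in profiles[1:]:
        if not np.array_equal(p.residue_numbers, ref):
            raise ValueError("replicates have differing residue sets")
    stacked = np.stack([p.rmsf for p in profiles])
    return RMSFProfile(
        residue_numbers=ref,
        rmsf=stacked.mean(axis=0),
        replicate_count=len(profiles),
    )
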