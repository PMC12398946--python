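"""Ligand tracking: displacement from the start pose, zones, release and escape.

The central observable is the per-frame RMSD of the ligand's heavy atoms
from their frame-0 positions (no internal refit, so rotation in place
contributes).  Displacement partitions frames into an active-site zone
(within 10 A of the start pose), the tunnel, and a distal region; a
debounced threshold crossing defines the release event, and sustained loss
of protein contact defines complete dissociation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, EmptySelectionError
from .structure_io import Trajectory, TrajectoryEnsemble

ZONES = ("active_site", "tunnel", "distal")


@dataclass
class ZoneConfig:
    """Half-open displacement bins delimiting the channeling zones."""

    active_site_radius: float = 10.0  # A
    tunnel_end: float = 30.0          # A
    distal_entrance: float = 32.0     # A (bottleneck at the far site entrance)

    def __post_init__(self) -> None:
        if not (0 < self.active_site_radius < self.tunnel_end <= self.distal_entrance):
            raise ConfigError(
                "require 0 < active_site_radius < tunnel_end <= distal_entrance"
            )


@dataclass
class LigandTrack:
    """Per-frame ligand displacement and zone labels for one replicate."""

    displacement: np.ndarray       # (n_frames,), A; displacement[0] == 0
    zones: np.ndarray              # (n_frames,) ints into ZONES
    time_step: float = 1.0
    alignment_selection: str = "none"

    @property
    def n_frames(self) -> int:
        return len(self.displacement)


@dataclass
class EventRecord:
    """Release/dissociation events and the replicate outcome."""

    release_frame: Optional[int]
    dissociation_frame: Optional[int]
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome == "channeled" and self.release_frame is None:
            raise ValueError("channeled outcome requires a release frame")
        if self.outcome == "dissociated":
            if self.release_frame is None or self.dissociation_frame is None:
                raise ValueError("dissociated outcome requires both event frames")
            if self.release_frame > self.dissociation_frame:
                raise ValueError("release must not follow dissociation")


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids aligning mobile onto reference."""
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, mc, rc


def superpose(traj: Trajectory, selection: np.ndarray) -> Trajectory:
    """Rigid-fit every frame onto frame 0 using protein-atom indices ``selection``.

    All partitions are co-transformed.  The fit minimises the selection RMSD
    to frame 0 (Kabsch), so alignment can never increase it.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise EmptySelectionError("superposition needs at least 3 selected atoms")
    ref = traj.protein[0, sel, :]
    prot = np.empty_like(traj.protein)
    lig = np.empty_like(traj.ligand)
    wat = np.empty_like(traj.water)
    for fi in range(traj.n_frames):
        rot, mc, rc = _kabsch(traj.protein[fi, sel, :], ref)
        for src, dst in ((traj.protein, prot), (traj.ligand, lig), (traj.water, wat)):
            dst[fi] = (src[fi] - mc) @ rot.T + rc
    return Trajectory(
        protein=prot,
        ligand=lig,
        water=wat,
        topology=traj.topology,
        time_step=traj.time_step,
        gate_extra=traj.gate_extra,
    )


def backbone_selection(traj: Trajectory, residue_ranges: Sequence[tuple[int, int]]) -> np.ndarray:
    """Indices of backbone atoms (N, CA, C, O) in the given residue ranges."""
    idx = [
        i
        for i, rec in enumerate(traj.topology.protein)
        if rec.atom_name in ("N", "CA", "C", "O")
        and any(lo <= rec.residue_number <= hi for lo, hi in residue_ranges)
    ]
    return np.array(idx, dtype=int)


#: low-fluctuation anchors: the two tunnel-lining helices
DEFAULT_ALIGNMENT_RANGES = [(373, 385), (824, 842)]


# --------------------------------------------------------------------------
# displacement, zones, events
# --------------------------------------------------------------------------

def ligand_displacement(traj: Trajectory, zones: ZoneConfig | None = None) -> LigandTrack:
    """Per-frame heavy-atom RMSD of the ligand from its frame-0 pose."""
    if traj.ligand.shape[1] == 0:
        raise EmptySelectionError("trajectory has no ligand atoms")
    zones = zones or ZoneConfig()
    delta = traj.ligand - traj.ligand[0][None, ...]
    disp = np.sqrt((delta**2).sum(axis=2).mean(axis=1))
    labels = np.array([classify_zone(float(d), zones) for d in disp], dtype=np.int8)
    return LigandTrack(displacement=disp, zones=labels, time_step=traj.time_step)


def classify_zone(d: float, zones: ZoneConfig) -> int:
    """Zone index for a displacement (half-open bins)."""
    if d < 0:
        raise ValueError(f"negative displacement {d}")
    if d < zones.active_site_radius:
        return 0
    if d < zones.tunnel_end:
        return 1
    return 2


def _first_sustained(flags: np.ndarray, persistence: int) -> Optional[int]:
    """First index t such that flags[t:t+persistence] are all True (vectorized)."""
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    n = len(flags)
    if n < persistence:
        return None
    window = np.convolve(flags.astype(int), np.ones(persistence, dtype=int), "valid")
    hits = np.nonzero(window == persistence)[0]
    return int(hits[0]) if hits.size else None


def detect_release(
    track: LigandTrack, zones: ZoneConfig, persistence_frames: int = 10
) -> Optional[int]:
    """First frame at which the ligand leaves the active-site zone and stays out.

    The displacement must remain >= active_site_radius for
    ``persistence_frames`` consecutive frames starting at the returned frame.
    """
    return _first_sustained(
        track.displacement >= zones.active_site_radius, persistence_frames
    )


def detect_dissociation(
    traj: Trajectory,
    min_protein_distance: float = 5.0,
    persistence_frames: int = 10,
) -> Optional[int]:
    """First frame of sustained loss of ligand-protein contact."""
    if traj.protein.shape[1] == 0:
        raise EmptySelectionError("trajectory has no protein atoms")
    min_dist = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        min_dist[fi] = cdist(traj.ligand[fi], traj.protein[fi]).min()
    return _first_sustained(min_dist > min_protein_distance, persistence_frames)


def replicate_events(
    traj: Trajectory,
    zones: ZoneConfig,
    persistence_frames: int = 10,
    min_protein_distance: float = 5.0,
) -> tuple[LigandTrack, EventRecord]:
    """Track + event record for one replicate."""
    track = ligand_displacement(traj, zones)
    release = detect_release(track, zones, persistence_frames)
    dissoc = detect_dissociation(traj, min_protein_distance, persistence_frames)
    if dissoc is not None:
        if release is None or release > dissoc:
            release = dissoc
        outcome = "dissociated"
    elif release is not None:
        outcome = "channeled"
    else:
        outcome = "remained"
    return track, EventRecord(release_frame=release, dissociation_frame=dissoc, outcome=outcome)


@dataclass
class EnsembleOutcomes:
    tracks: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def counts(self) -> dict:
        c = {"remained": 0, "channeled": 0, "dissociated": 0}
        for e in self.events:
            c[e.outcome] += 1
        return c


def ensemble_outcomes(
    ensemble: TrajectoryEnsemble,
    zones: ZoneConfig | None = None,
    persistence_frames: int = 10,
    min_protein_distance: float = 5.0,
) -> EnsembleOutcomes:
    """Per-replicate tracks and event records; outcome counts sum to n_replicates."""
    if len(ensemble) < 1:
        raise EmptySelectionError("ensemble has no replicates")
    zones = zones or ZoneConfig()
    out = EnsembleOutcomes()
    for traj in ensemble:
        track, event = replicate_events(
            traj, zones, persistence_frames, min_protein_distance
        )
        out.tracks.append(track)
        out.events.append(event)
    return out


def displacement_histogram(
    tracks: Sequence[LigandTrack], bin_width: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled displacement histogram over all frames of all tracks.

    Returns (edges, counts) with half-open bins covering [0, max d]; counts
    sum to the total frame number.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.concatenate([t.displacement for t in tracks])
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def contact_residues(
    traj: Trajectory,
    cutoff: float = 5.0,
    frames: np.ndarray | None = None,
) -> dict[int, float]:
    """Fraction of the given frames in which each residue contacts the ligand.

    A residue is in contact when any of its heavy atoms lies within
    ``cutoff`` of any ligand heavy atom.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if frames is None:
        frames = np.arange(traj.n_frames)
    resnums = np.array([rec.residue_number for rec in traj.topology.protein])
    unique_res = np.unique(resnums)
    hits = {int(r): 0 for r in unique_res}
    for fi in frames:
        d = cdist(traj.protein[fi], traj.ligand[fi]).min(axis=1)
        touched = np.unique(resnums[d <= cutoff])
        for r in touched:
            hits[int(r)] += 1
    n = len(frames)
    return {r: c / n for r, c in hits.items() if c > 0}
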