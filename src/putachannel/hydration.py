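"""Docking-site persistence and tunnel hydration against a centerline model.

The tunnel is represented as an arc-length-parameterized centerline with a
radius at each station; the channeling coordinate of any point is the arc
length of its projection onto the piecewise-linear centerline.  The tunnel
*region* used for the water census is the union of spheres centered at
stations resampled every 1 A — an explicit, testable geometric input
standing in for the cavity computed by channel-finding software in the
original study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .channeling import EventRecord  # noqa: F401  (re-exported for callers)
from .errors import AtomNotFoundError, DegenerateGeometryError
from .structure_io import AtomRef, Trajectory, TrajectoryEnsemble


@dataclass
class TunnelPath:
    """Piecewise-linear centerline with per-station radii."""

    points: np.ndarray   # (n, 3), A
    radii: np.ndarray    # (n,), A

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise DegenerateGeometryError("centerline needs >= 2 points of 3 coords")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise DegenerateGeometryError("zero-length centerline segment")
        if np.any(self.radii <= 0):
            raise DegenerateGeometryError("station radii must be > 0")
        if len(self.radii) != len(self.points):
            raise DegenerateGeometryError("one radius per centerline point required")

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])

    def resample(self, spacing: float = 1.0) -> "TunnelPath":
        """Stations at uniform arc-length spacing (radii linearly interpolated)."""
        s_old = self.arc_lengths
        s_new = np.arange(0.0, self.length + 1e-9, spacing)
        if s_new[-1] < self.length - 1e-9:
            s_new = np.append(s_new, self.length)
        pts = np.column_stack(
            [np.interp(s_new, s_old, self.points[:, k]) for k in range(3)]
        )
        radii = np.interp(s_new, s_old, self.radii)
        return TunnelPath(points=pts, radii=radii)

    @classmethod
    def from_csv(cls, path: str | Path, default_radius: float = 4.0) -> "TunnelPath":
        """Read a centerline CSV with columns x,y,z[,radius]."""
        df = pd.read_csv(path)
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
        if "radius" in df.columns:
            radii = df["radius"].to_numpy(dtype=float)
        else:
            radii = np.full(len(pts), default_radius)
        return cls(points=pts, radii=radii)

    @classmethod
    def straight(
        cls, length: float = 30.0, radius: float = 4.0, spacing: float = 1.0
    ) -> "TunnelPath":
        """Straight default centerline along +x from the origin."""
        s = np.arange(0.0, length + 1e-9, spacing)
        pts = np.zeros((len(s), 3))
        pts[:, 0] = s
        return cls(points=pts, radii=np.full(len(s), radius))


def project_to_path(point: np.ndarray, path: TunnelPath) -> tuple[float, float]:
    """Arc length s and radial distance of the closest centerline point.

    The point is projected onto each segment (clamped to its ends); the
    closest projection wins.
    """
    p = np.asarray(point, dtype=float)
    a = path.points[:-1]
    b = path.points[1:]
    ab = b - a
    seg_len2 = (ab**2).sum(axis=1)
    t = np.clip(((p - a) * ab).sum(axis=1) / seg_len2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    dists = np.linalg.norm(p - proj, axis=1)
    k = int(np.argmin(dists))
    s = path.arc_lengths[k] + t[k] * np.sqrt(seg_len2[k])
    return float(s), float(dists[k])


@dataclass
class DockingInterval:
    """One maximal run of frames with the docking contact formed."""

    start_frame: int
    end_frame: int    # inclusive
    duration_ns: float

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must not exceed end_frame")


def docking_distance_series(
    traj: Trajectory,
    donor: AtomRef = AtomRef("A", 312, "NZ", "ARG"),
    acceptor_atom: str = "C",
) -> np.ndarray:
    """Per-frame distance between the docking-site donor and a ligand atom.

    Defaults to Arg312 NZ versus the P5C carboxylate carbon (this package's
    reading of the ligand's 'carbonyl C-atom').
    """
    di = None
    for i, rec in enumerate(traj.topology.protein):
        if (
            rec.chain_id == donor.chain_id
            and rec.residue_number == donor.residue_number
            and rec.atom_name == donor.atom_name
        ):
            di = i
            break
    if di is None:
        raise AtomNotFoundError(f"donor atom {donor} not in trajectory protein")
    ai = None
    for i, rec in enumerate(traj.topology.ligand):
        if rec.atom_name == acceptor_atom:
            ai = i
            break
    if ai is None:
        raise AtomNotFoundError(f"ligand atom {acceptor_atom!r} not in trajectory")
    return np.linalg.norm(traj.protein[:, di, :] - traj.ligand[:, ai, :], axis=1)


def docking_intervals(
    traj: Trajectory,
    donor: AtomRef = AtomRef("A", 312, "NZ", "ARG"),
    acceptor_atom: str = "C",
    cutoff: float = 5.0,
) -> list[DockingInterval]:
    """Maximal runs of frames with the donor-acceptor distance under cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    dist = docking_distance_series(traj, donor, acceptor_atom)
    below = np.concatenate([[False], dist < cutoff, [False]]).astype(int)
    d = np.diff(below)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return [
        DockingInterval(int(s), int(e), (e - s + 1) * traj.time_step)
        for s, e in zip(starts, ends)
    ]


def water_count_frame(
    water_positions: np.ndarray, path: TunnelPath, station_spacing: float = 1.0
) -> int:
    """Number of water oxygens inside the tunnel region at one frame.

    Membership is union-of-spheres: within the station radius of at least
    one centerline station after resampling to ``station_spacing``.
    """
    stations = path.resample(station_spacing)
    if len(water_positions) == 0:
        return 0
    d = cdist(np.asarray(water_positions, dtype=float), stations.points)
    inside = (d <= stations.radii[None, :]).any(axis=1)
    return int(np.count_nonzero(inside))


@dataclass
class WaterSummary:
    """Time-and-ensemble census of tunnel waters."""

    per_replicate_counts: list      # list of (n_frames,) arrays
    mean: float
    p01: float
    p99: float
    minimum: int
    maximum: int


def water_series_summary(
    ensemble: TrajectoryEnsemble, path: TunnelPath, station_spacing: float = 1.0
) -> WaterSummary:
    """Per-frame tunnel-water counts for every replicate plus summary band."""
    stations = path.resample(station_spacing)
    per_rep = []
    for traj in ensemble:
        counts = np.empty(traj.n_frames, dtype=int)
        for fi in range(traj.n_frames):
            if traj.water.shape[1] == 0:
                counts[fi] = 0
                continue
            d = cdist(traj.water[fi], stations.points)
            counts[fi] = int(np.count_nonzero((d <= stations.radii[None, :]).any(axis=1)))
        per_rep.append(counts)
    pooled = np.concatenate(per_rep)
    return WaterSummary(
        per_replicate_counts=per_rep,
        mean=float(pooled.mean()),
        p01=float(np.percentile(pooled, 1)),
        p99=float(np.percentile(pooled, 99)),
        minimum=int(pooled.min()),
        maximum=int(pooled.max()),
    )


def tunnel_volume_mc(
    path: TunnelPath,
    n_samples: int = 200_000,
    station_spacing: float = 1.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo volume (A^3) of the union-of-spheres tunnel region."""
    rng = rng or np.random.default_rng(0)
    stations = path.resample(station_spacing)
    rmax = stations.radii.max()
    lo = stations.points.min(axis=0) - rmax
    hi = stations.points.max(axis=0) + rmax
    pts = lo + rng.random((n_samples, 3)) * (hi - lo)
    d = cdist(pts, stations.points)
    inside = (d <= stations.radii[None, :]).any(axis=1)
    box_vol = float(np.prod(hi - lo))
    return box_vol * inside.mean()
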