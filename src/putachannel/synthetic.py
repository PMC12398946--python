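"""Synthetic trajectory ensembles with the statistical structure of the study's MD data.

The generator emulates an ensemble of replicate simulations of the reduced
PRODH active site holding a newly formed P5C molecule at the mouth of the
substrate-channeling tunnel:

* an **ion-pair gate** whose Arg-CZ/Glu-CD distance switches between a
  closed basin (~4 A) and an open basin (~12 A) as a two-state Markov chain,
  with Ornstein-Uhlenbeck fluctuation about the state mean;
* a **ligand** performing overdamped diffusion on a 1-D free-energy profile
  along the tunnel axis, with wells at the active site (s = 0) and a docking
  site (s = 17.5 A), a gate-controlled barrier near s = 10 A and an exit
  barrier near s = 30 A.  A step that would carry the ligand's displacement
  across the inner barrier is rejected while the gate is closed: gate
  opening *permits* escape but never causes it;
* **tunnel waters** hopping inside a periodic box around the tunnel;
* a **protein scaffold** of tunnel-lining segments fluctuating isotropically
  with a prescribed per-residue sigma profile.

Every replicate also yields ground-truth event labels (remained / channeled
/ dissociated, release and dissociation frames, per-frame gate state and
tunnel-water count) derived from the emitted coordinates by direct scans,
so downstream detectors can be checked for exact recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError
from .structure_io import AtomRecord, Trajectory, TrajectoryEnsemble, TrajectoryTopology

GATE_STATE_NAMES = ("closed", "semiopen", "open")


@dataclass
class GateConfig:
    """Two-state Markov / OU model of the Arg488-Glu225 ion pair."""

    mean_closed: float = 4.0     # A
    mean_open: float = 12.0      # A
    sd: float = 0.7              # stationary OU sd, A
    k_open: float = 0.001        # 1/ns, closed -> open
    k_close: float = 0.001       # 1/ns, open -> closed
    relaxation_ns: float = 10.0  # OU relaxation time
    closed_max: float = 5.0      # coupling threshold: distance below = closed
    start_open: bool = False     # starting structures have the gate closed


@dataclass
class LigandConfig:
    """1-D diffusive ligand on a well/barrier profile along the tunnel axis."""

    diffusion_coefficient: float = 1.0   # A^2/ns
    site_well_depth: float = 3.0         # kT, well at s = 0
    site_well_width: float = 3.0         # A (Gaussian sigma)
    dock_well_position: float = 17.5     # A
    dock_well_depth: float = 3.0         # kT
    dock_well_width: float = 3.0         # A
    barrier_position: float = 10.0       # A, gate-controlled
    barrier_height: float = 1.0          # kT
    barrier_width: float = 1.5           # A
    exit_position: float = 30.0          # A
    exit_barrier_height: float = 3.0     # kT
    exit_barrier_width: float = 1.5      # A
    dissociation_position: float = 36.0  # A
    outward_tilt: float = 0.4            # kT/A applied beyond tilt_start
    tilt_start: float = 32.0             # A
    lateral_sd: float = 0.3              # A, per-axis decorative noise
    s_max: float = 45.0                  # reflecting outer wall of the grid


@dataclass
class WaterConfig:
    """Mobile waters in a periodic box enclosing the tunnel region."""

    n_particles: int = 958
    box_min: tuple = (-6.0, -6.0, -6.0)
    box_max: tuple = (36.0, 6.0, 6.0)
    hop_sd: float = 1.0  # A per frame, per axis


#: (first_residue, last_residue, sigma_A, s_start, s_end, wall_radius, phase)
DEFAULT_PROTEIN_SEGMENTS = [
    (218, 232, 0.5, 4.0, 10.0, 6.5, 0.8),    # gate glutamate loop (Glu225)
    (268, 280, 0.6, 12.0, 16.0, 5.5, 2.1),   # tunnel roof loop
    (303, 318, 0.5, 14.0, 21.0, 5.0, 4.0),   # roof loop carrying Arg312
    (373, 385, 0.3, 12.0, 24.0, 6.0, 0.0),   # tunnel wall helix
    (458, 476, 0.5, -4.0, 4.0, 5.5, 1.0),    # proline-site pocket
    (482, 494, 0.5, 6.0, 12.0, 6.0, 3.6),    # gate arginine segment (Arg488)
    (824, 842, 0.3, 12.0, 24.0, 6.0, 3.14),  # opposite tunnel wall helix
    (858, 878, 1.2, 20.0, 30.0, 8.0, 5.0),   # C-terminal lid
]


@dataclass
class ProteinConfig:
    """Backbone scaffold: residue segments with per-residue fluctuation sigma."""

    segments: list = field(default_factory=lambda: [list(s) for s in DEFAULT_PROTEIN_SEGMENTS])

    def residue_numbers(self) -> np.ndarray:
        nums = []
        for first, last, *_ in self.segments:
            nums.extend(range(int(first), int(last) + 1))
        return np.array(nums, dtype=int)

    def sigma_profile(self) -> np.ndarray:
        sig = []
        for first, last, sigma, *_ in self.segments:
            sig.extend([float(sigma)] * (int(last) - int(first) + 1))
        return np.array(sig)


@dataclass
class LabelConfig:
    """Ground-truth event definitions (shared with the analysis defaults)."""

    release_radius: float = 10.0       # A displacement from the start pose
    persistence_frames: int = 10       # debounce window, frames
    min_protein_distance: float = 5.0  # A, dissociation criterion


@dataclass
class SyntheticConfig:
    """Study conditions: 21 replicates x 2 us sampled every 1 ns."""

    n_replicates: int = 21
    n_frames: int = 2000
    time_step: float = 1.0  # ns
    seed: int = 0
    gate: GateConfig = field(default_factory=GateConfig)
    ligand: LigandConfig = field(default_factory=LigandConfig)
    waters: WaterConfig = field(default_factory=WaterConfig)
    protein: ProteinConfig = field(default_factory=ProteinConfig)
    labels: LabelConfig = field(default_factory=LabelConfig)
    tunnel_length: float = 30.0     # A, straight centerline from the origin
    tunnel_radius: float = 4.0      # A, uniform station radius
    station_spacing: float = 1.0    # A

    def validate(self) -> None:
        if self.n_replicates < 1 or self.n_frames < 1:
            raise ConfigError("n_replicates and n_frames must be positive")
        if self.time_step <= 0:
            raise ConfigError("time_step must be > 0")
        g, l, w = self.gate, self.ligand, self.waters
        if g.k_open < 0 or g.k_close < 0:
            raise ConfigError("gate rates must be >= 0")
        if g.sd <= 0 or g.relaxation_ns <= 0:
            raise ConfigError("gate sd and relaxation must be > 0")
        if not (0 < l.barrier_position < l.exit_position <= l.dissociation_position):
            raise ConfigError("require 0 < barrier < exit <= dissociation positions")
        if l.dissociation_position > l.s_max:
            raise ConfigError("dissociation_position beyond the reflecting wall")
        if l.diffusion_coefficient < 0 or l.lateral_sd < 0:
            raise ConfigError("diffusion coefficient and lateral sd must be >= 0")
        if w.n_particles < 0 or w.hop_sd < 0:
            raise ConfigError("water counts and hop sd must be >= 0")
        lo, hi = np.asarray(w.box_min), np.asarray(w.box_max)
        if not np.all(hi > lo):
            raise ConfigError("water box_max must exceed box_min")
        # the census region must sit inside the periodic box
        if (lo[0] > -self.tunnel_radius or hi[0] < self.tunnel_length + self.tunnel_radius
                or lo[1] > -self.tunnel_radius or hi[1] < self.tunnel_radius
                or lo[2] > -self.tunnel_radius or hi[2] < self.tunnel_radius):
            raise ConfigError("water box does not enclose the tunnel region")
        if self.labels.persistence_frames < 1:
            raise ConfigError("persistence_frames must be >= 1")

    def tunnel_stations(self) -> np.ndarray:
        s = np.arange(0.0, self.tunnel_length + 1e-9, self.station_spacing)
        pts = np.zeros((len(s), 3))
        pts[:, 0] = s
        return pts


@dataclass
class ReplicateTruth:
    """Ground-truth labels for one replicate, derived from emitted frames."""

    outcome: str                       # remained | channeled | dissociated
    release_frame: Optional[int]
    dissociation_frame: Optional[int]
    gate_distances: np.ndarray         # (n_frames,)
    gate_states: np.ndarray            # (n_frames,) ints into GATE_STATE_NAMES
    water_counts: np.ndarray           # (n_frames,)
    s: np.ndarray                      # latent arc-length coordinate


@dataclass
class GroundTruth:
    replicates: list

    def outcome_counts(self) -> dict:
        counts = {"remained": 0, "channeled": 0, "dissociated": 0}
        for r in self.replicates:
            counts[r.outcome] += 1
        return counts

    def to_json(self, path: str | Path) -> None:
        payload = []
        for r in self.replicates:
            payload.append(
                {
                    "outcome": r.outcome,
                    "release_frame": r.release_frame,
                    "dissociation_frame": r.dissociation_frame,
                    "gate_states": [GATE_STATE_NAMES[i] for i in r.gate_states],
                    "water_counts": r.water_counts.tolist(),
                }
            )
        Path(path).write_text(json.dumps(payload))


# --------------------------------------------------------------------------
# component simulators
# --------------------------------------------------------------------------

def simulate_gate(
    config: GateConfig, n_frames: int, time_step: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent open/closed chain plus OU distance about the state mean.

    Returns (latent_states, distances): latent_states[t] is 0 (closed) or
    1 (open); distances are strictly positive.
    """
    p_open = 1.0 - np.exp(-config.k_open * time_step)
    p_close = 1.0 - np.exp(-config.k_close * time_step)
    states = np.empty(n_frames, dtype=np.int8)
    states[0] = 1 if config.start_open else 0
    u = rng.random(n_frames)
    for t in range(1, n_frames):
        if states[t - 1] == 0:
            states[t] = 1 if u[t] < p_open else 0
        else:
            states[t] = 0 if u[t] < p_close else 1

    means = np.where(states == 0, config.mean_closed, config.mean_open)
    phi = np.exp(-time_step / config.relaxation_ns)
    innov_sd = config.sd * np.sqrt(1.0 - phi * phi)
    xi = rng.standard_normal(n_frames)
    d = np.empty(n_frames)
    d[0] = means[0] + config.sd * xi[0]
    for t in range(1, n_frames):
        d[t] = means[t] + (d[t - 1] - means[t]) * phi + innov_sd * xi[t]
    return states, np.maximum(d, 0.05)


def _potential_grid(cfg: LigandConfig) -> tuple[np.ndarray, np.ndarray]:
    ds = 0.05
    s = np.arange(0.0, cfg.s_max + ds, ds)
    u = (
        -cfg.site_well_depth * np.exp(-(s**2) / (2 * cfg.site_well_width**2))
        - cfg.dock_well_depth
        * np.exp(-((s - cfg.dock_well_position) ** 2) / (2 * cfg.dock_well_width**2))
        + cfg.barrier_height
        * np.exp(-((s - cfg.barrier_position) ** 2) / (2 * cfg.barrier_width**2))
        + cfg.exit_barrier_height
        * np.exp(-((s - cfg.exit_position) ** 2) / (2 * cfg.exit_barrier_width**2))
        - cfg.outward_tilt * np.maximum(0.0, s - cfg.tilt_start)
    )
    force = -np.gradient(u, ds)
    return s, force


def simulate_ligand(
    config: LigandConfig,
    gate_distances: np.ndarray,
    closed_max: float,
    time_step: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Overdamped walk on the tunnel profile, hard-coupled to the gate.

    The proposal for frame t is rejected (the ligand stays put) whenever it
    would carry the displacement from the start pose across
    ``barrier_position`` from below while the concurrent gate distance is
    below ``closed_max``.  Reflecting walls sit at s = 0 and s = s_max.
    Returns (s_series, centroid_positions) with the frame-0 centroid exactly
    at the origin.
    """
    n_frames = len(gate_distances)
    grid, force = _potential_grid(config)
    dcoef, dt = config.diffusion_coefficient, time_step
    noise_sd = np.sqrt(2.0 * dcoef * dt)

    s = np.zeros(n_frames)
    pos = np.zeros((n_frames, 3))
    xi = rng.standard_normal(n_frames)
    lat = rng.normal(0.0, config.lateral_sd, size=(n_frames, 2))
    lat[0] = 0.0
    d_prev = 0.0
    for t in range(1, n_frames):
        f = np.interp(s[t - 1], grid, force)
        prop = s[t - 1] + dcoef * f * dt + noise_sd * xi[t]
        if prop < 0.0:
            prop = -prop
        if prop > config.s_max:
            prop = 2.0 * config.s_max - prop
        cand = np.array([prop, lat[t, 0], lat[t, 1]])
        d_cand = float(np.linalg.norm(cand))
        if (
            d_prev < config.barrier_position <= d_cand
            and gate_distances[t] < closed_max
        ):
            s[t] = s[t - 1]
            pos[t] = pos[t - 1]
        else:
            s[t] = prop
            pos[t] = cand
            d_prev = d_cand
    return s, pos


def simulate_waters(
    config: WaterConfig, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent Gaussian hops with periodic wrapping; uniform stationary density."""
    lo = np.asarray(config.box_min, dtype=float)
    hi = np.asarray(config.box_max, dtype=float)
    span = hi - lo
    n = config.n_particles
    coords = np.empty((n_frames, n, 3))
    if n == 0:
        return coords
    coords[0] = lo + rng.random((n, 3)) * span
    if config.hop_sd > 0 and n_frames > 1:
        hops = rng.normal(0.0, config.hop_sd, size=(n_frames - 1, n, 3))
        walk = coords[0] + np.cumsum(hops, axis=0)
        coords[1:] = lo + np.mod(walk - lo, span)
    else:
        coords[1:] = coords[0]
    return coords


def _reference_backbone(protein: ProteinConfig) -> tuple[list[AtomRecord], np.ndarray, np.ndarray]:
    """Reference coordinates, atom records and per-atom sigma for the scaffold."""
    offsets = {
        "N": np.array([-0.7, 0.5, 0.0]),
        "CA": np.zeros(3),
        "C": np.array([0.7, 0.5, 0.0]),
        "O": np.array([1.0, -0.5, 0.3]),
    }
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    sigmas: list[float] = []
    for first, last, sigma, s0, s1, radius, phase in protein.segments:
        first, last = int(first), int(last)
        n_res = last - first + 1
        for i, resnum in enumerate(range(first, last + 1)):
            frac = i / max(n_res - 1, 1)
            x = s0 + (s1 - s0) * frac
            ang = phase + i * np.radians(100.0)  # helical twist
            ca = np.array([x, radius * np.cos(ang), radius * np.sin(ang)])
            for name, off in offsets.items():
                records.append(AtomRecord("A", resnum, "GLY", name, name[0]))
                coords.append(ca + off)
                sigmas.append(float(sigma))
    return records, np.array(coords), np.array(sigmas)


#: anchor for the gate glutamate CD; the arginine CZ is placed at the gate
#: distance from it along +y
GATE_ANCHOR = np.array([9.0, 6.0, 0.0])
GATE_DIRECTION = np.array([0.0, 1.0, 0.0])
DOCK_SITE_NZ = np.array([17.5, 4.5, 0.0])

#: rigid decorative offsets of the P5C heavy atoms about the centroid;
#: "C" is the carboxylate carbon used for the Arg312 docking distance
LIGAND_ATOM_OFFSETS = {
    "N1": np.array([0.0, 0.7, 0.0]),
    "C2": np.array([0.67, 0.22, 0.0]),
    "C3": np.array([0.41, -0.57, 0.0]),
    "C4": np.array([-0.41, -0.57, 0.0]),
    "C5": np.array([-0.67, 0.22, 0.0]),
    "C": np.array([1.4, 0.0, 0.0]),
}


def simulate_protein(
    config: ProteinConfig, n_frames: int, rng: np.random.Generator
) -> tuple[list[AtomRecord], np.ndarray, np.ndarray]:
    """Per-frame backbone coordinates: reference plus iid isotropic Gaussian noise."""
    records, ref, sigmas = _reference_backbone(config)
    noise = rng.standard_normal((n_frames, len(records), 3)) * sigmas[None, :, None]
    return records, ref, ref[None, :, :] + noise


def _classify_gate(distances: np.ndarray, closed_max: float = 5.0, semiopen_max: float = 8.0) -> np.ndarray:
    states = np.full(distances.shape, 2, dtype=np.int8)
    states[distances < semiopen_max] = 1
    states[distances < closed_max] = 0
    return states


def _scan_first_sustained(flags: np.ndarray, persistence: int) -> Optional[int]:
    """First index starting a run of >= persistence consecutive True flags (plain scan)."""
    n = len(flags)
    for t in range(0, n - persistence + 1):
        ok = True
        for k in range(persistence):
            if not flags[t + k]:
                ok = False
                break
        if ok:
            return t
    return None


def _truth_water_counts(
    waters: np.ndarray, stations: np.ndarray, radius: float
) -> np.ndarray:
    counts = np.empty(waters.shape[0], dtype=int)
    for fi in range(waters.shape[0]):
        d = cdist(waters[fi], stations)
        counts[fi] = int(np.count_nonzero(d.min(axis=1) <= radius))
    return counts


def generate_ensemble(config: SyntheticConfig) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Generate the full replicate ensemble plus ground-truth labels.

    Deterministic for a given seed; replicate r draws from a child stream
    spawned from (seed, r) via numpy's counter-based SeedSequence.
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    stations = config.tunnel_stations()

    prot_records, _, _ = _reference_backbone(config.protein)
    # special side-chain atoms appended after the backbone scaffold
    special = [
        AtomRecord("A", 225, "GLU", "CD", "C"),
        AtomRecord("A", 488, "ARG", "CZ", "C"),
        AtomRecord("A", 312, "ARG", "NZ", "N"),
    ]
    lig_records = [
        AtomRecord("L", 1, "P5C", name, "N" if name.startswith("N") else "C")
        for name in LIGAND_ATOM_OFFSETS
    ]

    replicates: list[Trajectory] = []
    truths: list[ReplicateTruth] = []
    for child in children:
        rng = np.random.default_rng(child)
        n = config.n_frames
        _, gate_d = simulate_gate(config.gate, n, config.time_step, rng)
        s_series, centroid = simulate_ligand(
            config.ligand, gate_d, config.gate.closed_max, config.time_step, rng
        )
        water_xyz = simulate_waters(config.waters, n, rng)
        _, _, backbone = simulate_protein(config.protein, n, rng)

        special_xyz = np.empty((n, 3, 3))
        special_xyz[:, 0, :] = GATE_ANCHOR                      # Glu225 CD, anchored
        special_xyz[:, 1, :] = GATE_ANCHOR + gate_d[:, None] * GATE_DIRECTION  # Arg488 CZ
        special_xyz[:, 2, :] = DOCK_SITE_NZ                     # Arg312 NZ
        protein_xyz = np.concatenate([backbone, special_xyz], axis=1)

        lig_off = np.array(list(LIGAND_ATOM_OFFSETS.values()))
        ligand_xyz = centroid[:, None, :] + lig_off[None, :, :]

        topo = TrajectoryTopology(
            protein=prot_records + special,
            ligand=lig_records,
            water=[AtomRecord("W", i + 1, "HOH", "O", "O") for i in range(config.waters.n_particles)],
        )
        traj = Trajectory(
            protein=protein_xyz,
            ligand=ligand_xyz,
            water=water_xyz,
            topology=topo,
            time_step=config.time_step,
            gate_extra={"gate_distance": gate_d, "s": s_series},
        )
        replicates.append(traj)
        truths.append(
            _label_replicate(traj, gate_d, s_series, stations, config)
        )
    return TrajectoryEnsemble(replicates=replicates), GroundTruth(replicates=truths)


def _label_replicate(
    traj: Trajectory,
    gate_d: np.ndarray,
    s_series: np.ndarray,
    stations: np.ndarray,
    config: SyntheticConfig,
) -> ReplicateTruth:
    lab = config.labels
    # displacement of the ligand centroid from the start pose; the decorative
    # atom offsets are rigid so atom RMSD equals the centroid displacement
    centroid = traj.ligand.mean(axis=1)
    disp = np.linalg.norm(centroid - centroid[0], axis=1)
    release = _scan_first_sustained(disp >= lab.release_radius, lab.persistence_frames)

    # dissociation: sustained separation of all ligand atoms from all protein atoms
    min_dist = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        min_dist[fi] = cdist(traj.ligand[fi], traj.protein[fi]).min()
    dissociation = _scan_first_sustained(
        min_dist > lab.min_protein_distance, lab.persistence_frames
    )

    if dissociation is not None:
        outcome = "dissociated"
        if release is None or release > dissociation:
            release = dissociation
    elif release is not None:
        outcome = "channeled"
    else:
        outcome = "remained"

    water_counts = _truth_water_counts(traj.water, stations, config.tunnel_radius)
    return ReplicateTruth(
        outcome=outcome,
        release_frame=release,
        dissociation_frame=dissociation,
        gate_distances=gate_d,
        gate_states=_classify_gate(gate_d),
        water_counts=water_counts,
        s=s_series,
    )
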