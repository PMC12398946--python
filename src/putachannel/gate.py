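"""Ion-pair gate analysis: state classification and the necessity question.

The Arg488-Glu225 salt bridge gates the exit of the proline/P5C site into
the channeling tunnel.  Its status is tracked as the CZ-CD distance and
classified into closed (< 5 A), semiopen (5-8 A) and open (>= 8 A) states
with half-open bins.  The headline question is temporal: is the gate ever
closed at the moment of ligand release (necessity), and do long-lived open
episodes occur without any release (non-sufficiency)?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .channeling import EventRecord
from .errors import AtomNotFoundError, ConfigError, EmptySelectionError
from .structure_io import AtomRef, Trajectory

STATE_NAMES = ("closed", "semiopen", "open")


@dataclass
class GateThresholds:
    """State bin edges for the gate distance (half-open bins)."""

    closed_max: float = 5.0    # A
    semiopen_max: float = 8.0  # A

    def __post_init__(self) -> None:
        if not (0 < self.closed_max < self.semiopen_max):
            raise ConfigError("require 0 < closed_max < semiopen_max")


@dataclass
class GateSeries:
    """Per-frame gate distance and state for one replicate."""

    distances: np.ndarray       # (n_frames,), A
    states: np.ndarray          # (n_frames,) ints into STATE_NAMES
    time_step: float = 1.0
    atom_pair: str = "ARG488:CZ-GLU225:CD"

    @property
    def n_frames(self) -> int:
        return len(self.distances)


def classify_states(distances: np.ndarray, thresholds: GateThresholds) -> np.ndarray:
    """Total classification of distances into the three gate states."""
    d = np.asarray(distances, dtype=float)
    states = np.full(d.shape, 2, dtype=np.int8)
    states[d < thresholds.semiopen_max] = 1
    states[d < thresholds.closed_max] = 0
    return states


def _protein_atom_index(traj: Trajectory, ref: AtomRef) -> int:
    for i, rec in enumerate(traj.topology.protein):
        if (
            rec.chain_id == ref.chain_id
            and rec.residue_number == ref.residue_number
            and rec.atom_name == ref.atom_name
            and (ref.residue_name is None or rec.residue_name == ref.residue_name)
        ):
            return i
    raise AtomNotFoundError(
        f"no protein atom {ref.chain_id}/{ref.residue_number}/{ref.atom_name} in trajectory"
    )


DEFAULT_GATE_PAIR = (AtomRef("A", 488, "CZ", "ARG"), AtomRef("A", 225, "CD", "GLU"))


def gate_series(
    traj: Trajectory,
    pair: tuple[AtomRef, AtomRef] = DEFAULT_GATE_PAIR,
    thresholds: GateThresholds | None = None,
) -> GateSeries:
    """Per-frame distance between the gate atom pair, with state labels."""
    thresholds = thresholds or GateThresholds()
    i = _protein_atom_index(traj, pair[0])
    j = _protein_atom_index(traj, pair[1])
    d = np.linalg.norm(traj.protein[:, i, :] - traj.protein[:, j, :], axis=1)
    if not np.all(np.isfinite(d)):
        bad = int(np.nonzero(~np.isfinite(d))[0][0])
        raise AtomNotFoundError(f"gate atoms missing/invalid at frame {bad}")
    return GateSeries(
        distances=d,
        states=classify_states(d, thresholds),
        time_step=traj.time_step,
        atom_pair=f"{pair[0].residue_name}{pair[0].residue_number}:{pair[0].atom_name}"
        f"-{pair[1].residue_name}{pair[1].residue_number}:{pair[1].atom_name}",
    )


def gate_distance_histogram(
    series: Sequence[GateSeries],
    events: Sequence[EventRecord] | None = None,
    condition: str | None = None,
    bin_width: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of gate distances over frames of replicates matching a condition.

    ``condition`` may be None (all replicates), one outcome name, or
    ``"released"`` (channeled or dissociated).  An empty selection raises
    :class:`EmptySelectionError` rather than returning a silent zero
    histogram.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if condition is not None and events is None:
        raise ValueError("conditioning on outcome requires event records")
    kept = []
    for k, s in enumerate(series):
        if condition is None:
            kept.append(s.distances)
        else:
            outcome = events[k].outcome
            match = (
                outcome in ("channeled", "dissociated")
                if condition == "released"
                else outcome == condition
            )
            if match:
                kept.append(s.distances)
    if not kept:
        raise EmptySelectionError(f"no replicates match condition {condition!r}")
    values = np.concatenate(kept)
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def state_at_release(series: GateSeries, release_frame: Optional[int]) -> int:
    """Gate state label at the release frame (reports; does not enforce)."""
    if release_frame is None:
        raise ValueError("release_frame is None; filter unreleased replicates first")
    if not (0 <= release_frame < series.n_frames):
        raise ValueError(f"release frame {release_frame} outside series")
    return int(series.states[release_frame])


def open_episode_durations(
    series: GateSeries, min_distance: float = 10.0
) -> list[float]:
    """Durations (ns) of maximal runs with gate distance >= min_distance."""
    if min_distance <= 0:
        raise ValueError("min_distance must be > 0")
    above = series.distances >= min_distance
    padded = np.concatenate([[False], above, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(e - s) * series.time_step for s, e in zip(starts, ends)]


@dataclass
class NecessitySufficiencyReport:
    """Summary of the gate-open-at-release relationship across an ensemble."""

    n_replicates: int
    n_released: int
    necessity_fraction: Optional[float]   # gate not closed at release; None if no releases
    open_without_release_fraction: float  # long open episode but no release
    closed_after_release_count: int
    episode_min_distance: float
    episode_min_duration_ns: float


def necessity_sufficiency_report(
    events: Sequence[EventRecord],
    series: Sequence[GateSeries],
    episode_min_distance: float = 10.0,
    episode_min_duration_ns: float = 500.0,
) -> NecessitySufficiencyReport:
    """Test whether gate opening is necessary but not sufficient for release.

    * necessity: fraction of release events at which the gate state is not
      closed (None, not 0.0, when no replicate released);
    * non-sufficiency: fraction of replicates showing at least one open
      episode (>= episode_min_distance for >= episode_min_duration_ns)
      yet no release;
    * count of replicates whose gate closed at least once after release.
    """
    if len(events) != len(series) or len(events) == 0:
        raise ValueError("need matching, non-empty events and gate series")
    released = [
        (e, s) for e, s in zip(events, series) if e.release_frame is not None
    ]
    if released:
        ok = sum(
            1 for e, s in released if state_at_release(s, e.release_frame) != 0
        )
        necessity = ok / len(released)
    else:
        necessity = None

    open_no_release = 0
    for e, s in zip(events, series):
        if e.release_frame is not None:
            continue
        durations = open_episode_durations(s, episode_min_distance)
        if any(d >= episode_min_duration_ns for d in durations):
            open_no_release += 1

    closed_after = 0
    for e, s in zip(events, series):
        if e.release_frame is not None and np.any(s.states[e.release_frame:] == 0):
            closed_after += 1

    return NecessitySufficiencyReport(
        n_replicates=len(events),
        n_released=len(released),
        necessity_fraction=necessity,
        open_without_release_fraction=open_no_release / len(events),
        closed_after_release_count=closed_after,
        episode_min_distance=episode_min_distance,
        episode_min_duration_ns=episode_min_duration_ns,
    )
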