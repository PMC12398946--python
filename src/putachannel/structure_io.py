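"""Reading and writing coordinate models and trajectories.

Deposited models (PDB or mmCIF) are parsed with :mod:`gemmi` into a flat,
occupancy- and altloc-aware atom table addressed by *author* residue numbers,
because that is how the structural literature on PutA cites residues
(Arg488, Cys844, ...).  Trajectories are small, self-describing containers:
a topology (single-model PDB) plus per-frame coordinates either as further
PDB MODELs, as a plain CSV dialect, or via any container mdtraj can read.

Atoms are partitioned into protein / ligand / water by residue name:
waters are HOH or WAT, protein residues are the standard amino acids, and
everything else is ligand unless an explicit het-code list is given (the
het-codes used for P5C/GSAL-type ligands vary between depositions, so they
are never hard-coded).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    AmbiguousAtomError,
    AtomNotFoundError,
    StructureFormatError,
    TrajectoryFormatError,
)

WATER_RESNAMES = {"HOH", "WAT"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass(frozen=True)
class Atom:
    """One atom of a coordinate model (author numbering, PDB atom names)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    altloc: str            # single character, "" if none
    occupancy: float       # fraction in [0, 1]
    b_factor: float        # A^2
    position: np.ndarray   # shape (3,), Angstrom
    element: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite or mis-shaped position for {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"occupancy {self.occupancy} outside [0,1] for "
                f"{self.chain_id}/{self.residue_number}/{self.atom_name}"
            )


@dataclass
class StructureModel:
    """Ordered atom collection from one model of a deposited structure."""

    atoms: list[Atom]
    source_id: str = ""
    model_number: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_id": a.chain_id,
                "residue_number": a.residue_number,
                "residue_name": a.residue_name,
                "atom_name": a.atom_name,
                "altloc": a.altloc,
                "occupancy": a.occupancy,
                "b_factor": a.b_factor,
                "x": a.position[0],
                "y": a.position[1],
                "z": a.position[2],
                "element": a.element,
            }
            for a in self.atoms
        ]
        return pd.DataFrame(rows)

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass(frozen=True)
class AtomRef:
    """Reference to a single atom by chain / author residue number / atom name."""

    chain_id: str
    residue_number: int
    atom_name: str
    residue_name: str | None = None  # optional sanity check


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    All ATOM and HETATM records are kept, including waters, hetero ligands
    and every alternate conformer.  ``format`` may be ``pdb``, ``mmcif`` or
    ``auto`` (extension/content sniffing via gemmi).
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such coordinate file: {path}")
    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        elif format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:  # gemmi reports line/category
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name.strip(),
                        atom_name=at.name.strip(),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        occupancy=float(at.occ),
                        b_factor=float(at.b_iso),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        element=at.element.name,
                    )
                )
    if not atoms:
        raise StructureFormatError(f"{path}: model contains no atoms")
    return StructureModel(atoms=atoms, source_id=st.name or path.stem, model_number=1)


def resolve_atom(
    model: StructureModel,
    ref: AtomRef,
    altloc_policy: str = "highest_occupancy",
    altloc: str | None = None,
) -> Atom:
    """Resolve an :class:`AtomRef` to a single atom.

    ``highest_occupancy`` picks the conformer with the largest occupancy,
    breaking ties by altloc identifier order.  ``specified`` requires the
    ``altloc`` argument.  A residue-name mismatch against ``ref.residue_name``
    is an error, never a silent success.
    """
    residue = model.residue_atoms(ref.chain_id, ref.residue_number)
    if not residue:
        nearby = sorted(
            {
                a.residue_number
                for a in model.atoms
                if a.chain_id == ref.chain_id
                and abs(a.residue_number - ref.residue_number) <= 2
            }
        )
        raise AtomNotFoundError(
            f"no residue {ref.chain_id}/{ref.residue_number}; "
            f"nearby residue numbers in chain: {nearby or 'none'}"
        )
    if ref.residue_name is not None:
        found = {a.residue_name for a in residue}
        if ref.residue_name not in found:
            raise AtomNotFoundError(
                f"residue {ref.chain_id}/{ref.residue_number} is {sorted(found)}, "
                f"not {ref.residue_name}"
            )
    candidates = [a for a in residue if a.atom_name == ref.atom_name]
    if not candidates:
        names = sorted({a.atom_name for a in residue})
        raise AtomNotFoundError(
            f"no atom {ref.atom_name} in {ref.chain_id}/{ref.residue_number} "
            f"({residue[0].residue_name}); atoms present: {names}"
        )
    if len(candidates) == 1:
        return candidates[0]
    if altloc_policy == "specified":
        if altloc is None:
            raise AmbiguousAtomError(
                f"{ref.atom_name} has altlocs "
                f"{sorted(a.altloc for a in candidates)}; specify one"
            )
        chosen = [a for a in candidates if a.altloc == altloc]
        if not chosen:
            raise AtomNotFoundError(
                f"no altloc {altloc!r} for {ref.atom_name}; "
                f"present: {sorted(a.altloc for a in candidates)}"
            )
        if len(chosen) > 1:
            raise AmbiguousAtomError(f"duplicate altloc {altloc!r} for {ref.atom_name}")
        return chosen[0]
    if altloc_policy == "highest_occupancy":
        # max occupancy; ties broken by altloc identifier order (A before B)
        return sorted(candidates, key=lambda a: (-a.occupancy, a.altloc))[0]
    raise ValueError(f"unknown altloc policy {altloc_policy!r}")


def ligand_occupancy(model: StructureModel, chain_id: str, residue_name: str) -> float:
    """Refined occupancy of a ligand residue (e.g. the P5C or GSAL site).

    Requires exactly one instance of ``residue_name`` in the chain.  If the
    ligand's atoms carry unequal occupancies the modal value is returned and
    a heterogeneity warning is issued.
    """
    instances = sorted(
        {
            a.residue_number
            for a in model.atoms
            if a.chain_id == chain_id and a.residue_name == residue_name
        }
    )
    if not instances:
        raise AtomNotFoundError(f"no residue {residue_name} in chain {chain_id}")
    if len(instances) > 1:
        raise AmbiguousAtomError(
            f"{len(instances)} instances of {residue_name} in chain {chain_id} "
            f"(residue numbers {instances})"
        )
    occs = [
        a.occupancy
        for a in model.atoms
        if a.chain_id == chain_id
        and a.residue_name == residue_name
        and a.residue_number == instances[0]
    ]
    counts = Counter(occs)
    if len(counts) > 1:
        warnings.warn(
            f"heterogeneous occupancies for {residue_name} {chain_id}/{instances[0]}: "
            f"{dict(counts)}",
            stacklevel=2,
        )
    return counts.most_common(1)[0][0]


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """Identity of one trajectory atom (no coordinates)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str = ""


@dataclass
class TrajectoryTopology:
    """Partitioned atom identities shared by every frame of a trajectory."""

    protein: list[AtomRecord]
    ligand: list[AtomRecord]
    water: list[AtomRecord]

    @property
    def n_atoms(self) -> int:
        return len(self.protein) + len(self.ligand) + len(self.water)

    def protein_residue_numbers(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.protein], dtype=int)


@dataclass
class Trajectory:
    """Uniformly sampled frames with protein/ligand/water coordinate blocks.

    ``protein``, ``ligand`` and ``water`` are float arrays of shape
    (n_frames, n_atoms_in_partition, 3), in Angstrom; ``time_step`` is ns.
    """

    protein: np.ndarray
    ligand: np.ndarray
    water: np.ndarray
    topology: TrajectoryTopology
    time_step: float = 1.0
    gate_extra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise TrajectoryFormatError(f"time_step must be > 0, got {self.time_step}")
        n = {arr.shape[0] for arr in (self.protein, self.ligand, self.water)}
        if len(n) != 1:
            raise TrajectoryFormatError(f"partition frame counts disagree: {n}")

    @property
    def n_frames(self) -> int:
        return self.protein.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_step


@dataclass
class TrajectoryEnsemble:
    """Replicate trajectories sharing a topology and time step."""

    replicates: list[Trajectory]

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self):
        return iter(self.replicates)

    @property
    def time_step(self) -> float:
        return self.replicates[0].time_step


def _partition_records(
    records: Sequence[AtomRecord], ligand_resnames: Iterable[str] | None
) -> tuple[list[int], list[int], list[int]]:
    ligand_set = set(ligand_resnames) if ligand_resnames is not None else None
    prot, lig, wat = [], [], []
    for i, rec in enumerate(records):
        if rec.residue_name in WATER_RESNAMES:
            wat.append(i)
        elif rec.residue_name in STANDARD_AA:
            prot.append(i)
        elif ligand_set is None or rec.residue_name in ligand_set:
            lig.append(i)
        else:
            prot.append(i)  # unlisted het-groups (cofactors) ride with protein
    return prot, lig, wat


def _records_from_model(model: StructureModel) -> list[AtomRecord]:
    return [
        AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name, a.element)
        for a in model.atoms
    ]


def read_trajectory(
    topology: str | Path,
    frames_source: str | Path,
    dialect: str = "multi_model_pdb",
    time_step: float = 1.0,
    ligand_resnames: Iterable[str] | None = None,
) -> TrajectoryEnsemble:
    """Read one replicate trajectory.

    ``multi_model_pdb``: frames are MODEL records of ``frames_source`` (which
    may equal ``topology``).  ``csv_frames``: frames_source is a CSV with
    header ``frame,time_ns,atom_index,x,y,z`` over the topology's atom order.
    ``standard_container``: any format mdtraj can load (requires mdtraj).
    """
    top_model = read_structure(topology)
    records = _records_from_model(top_model)
    n_atoms = len(records)

    if dialect == "multi_model_pdb":
        coords, dt = _read_multi_model_pdb(frames_source, n_atoms, time_step)
    elif dialect == "csv_frames":
        coords, dt = _read_csv_frames(frames_source, n_atoms)
    elif dialect == "standard_container":
        coords, dt = _read_standard_container(frames_source, topology, n_atoms, time_step)
    else:
        raise ValueError(f"unknown trajectory dialect {dialect!r}")

    prot_idx, lig_idx, wat_idx = _partition_records(records, ligand_resnames)
    topo = TrajectoryTopology(
        protein=[records[i] for i in prot_idx],
        ligand=[records[i] for i in lig_idx],
        water=[records[i] for i in wat_idx],
    )
    traj = Trajectory(
        protein=coords[:, prot_idx, :],
        ligand=coords[:, lig_idx, :],
        water=coords[:, wat_idx, :],
        topology=topo,
        time_step=dt,
    )
    return TrajectoryEnsemble(replicates=[traj])


def _read_multi_model_pdb(
    path: str | Path, n_atoms: int, time_step: float
) -> tuple[np.ndarray, float]:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise TrajectoryFormatError(f"cannot parse {path}: {exc}") from exc
    frames = []
    for fi, model in enumerate(st):
        xyz = np.array(
            [[at.pos.x, at.pos.y, at.pos.z] for ch in model for r in ch for at in r]
        )
        if xyz.shape[0] != n_atoms:
            raise TrajectoryFormatError(
                f"frame {fi}: {xyz.shape[0]} atoms, topology has {n_atoms}"
            )
        frames.append(xyz)
    if not frames:
        raise TrajectoryFormatError(f"{path}: no MODEL frames")
    return np.stack(frames), time_step


def _read_csv_frames(path: str | Path, n_atoms: int) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    expected = ["frame", "time_ns", "atom_index", "x", "y", "z"]
    if list(df.columns) != expected:
        raise TrajectoryFormatError(
            f"{path}: csv_frames header must be {expected}, got {list(df.columns)}"
        )
    frames = sorted(df["frame"].unique())
    coords = np.empty((len(frames), n_atoms, 3))
    times = []
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("atom_index")
        if len(sub) != n_atoms or not np.array_equal(
            sub["atom_index"].to_numpy(), np.arange(n_atoms)
        ):
            raise TrajectoryFormatError(
                f"frame {f}: expected atom indices 0..{n_atoms - 1}, got {len(sub)} rows"
            )
        coords[fi] = sub[["x", "y", "z"]].to_numpy()
        times.append(sub["time_ns"].iloc[0])
    if len(times) > 1:
        dts = np.diff(times)
        if not np.allclose(dts, dts[0]):
            raise TrajectoryFormatError(f"{path}: non-uniform frame times")
        dt = float(dts[0])
    else:
        dt = 1.0
    return coords, dt


def _read_standard_container(
    path: str | Path, topology: str | Path, n_atoms: int, time_step: float
) -> tuple[np.ndarray, float]:
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover - optional extra
        raise TrajectoryFormatError(
            "standard_container dialect requires mdtraj"
        ) from exc
    t = mdtraj.load(str(path), top=str(topology))
    if t.n_atoms != n_atoms:
        raise TrajectoryFormatError(
            f"container has {t.n_atoms} atoms, topology has {n_atoms}"
        )
    return np.asarray(t.xyz, dtype=float) * 10.0, time_step  # nm -> A


# --------------------------------------------------------------------------
# writers (topology PDB + csv_frames; used by the synthetic generator)
# --------------------------------------------------------------------------

def _all_records(topology: TrajectoryTopology) -> list[AtomRecord]:
    return list(topology.protein) + list(topology.ligand) + list(topology.water)


def _all_coords(traj: Trajectory) -> np.ndarray:
    return np.concatenate([traj.protein, traj.ligand, traj.water], axis=1)


def write_topology_pdb(
    topology: TrajectoryTopology, frame0: np.ndarray, path: str | Path
) -> None:
    """Write a single-model PDB carrying the topology's atom identities."""
    st = _gemmi_structure(topology, frame0[None, ...])
    st.write_pdb(str(path))


def write_trajectory_csv(traj: Trajectory, frames_path: str | Path) -> None:
    """Write frames in the ``csv_frames`` dialect (6-decimal coordinates)."""
    coords = _all_coords(traj)
    n_frames, n_atoms, _ = coords.shape
    frame_col = np.repeat(np.arange(n_frames), n_atoms)
    df = pd.DataFrame(
        {
            "frame": frame_col,
            "time_ns": frame_col * traj.time_step,
            "atom_index": np.tile(np.arange(n_atoms), n_frames),
            "x": coords[..., 0].ravel(),
            "y": coords[..., 1].ravel(),
            "z": coords[..., 2].ravel(),
        }
    )
    df.to_csv(frames_path, index=False, float_format="%.6f")


def write_multi_model_pdb(traj: Trajectory, path: str | Path) -> None:
    st = _gemmi_structure(traj.topology, _all_coords(traj))
    st.write_pdb(str(path))


def _gemmi_structure(topology: TrajectoryTopology, coords: np.ndarray) -> gemmi.Structure:
    records = _all_records(topology)
    st = gemmi.Structure()
    st.name = "trajectory"
    for fi in range(coords.shape[0]):
        model = gemmi.Model(fi + 1)
        chains: dict[str, gemmi.Chain] = {}
        res_key = None
        residue = None
        for ai, rec in enumerate(records):
            if rec.chain_id not in chains:
                chains[rec.chain_id] = gemmi.Chain(rec.chain_id)
            key = (rec.chain_id, rec.residue_number, rec.residue_name)
            if key != res_key:
                new_res = gemmi.Residue()
                new_res.name = rec.residue_name
                new_res.seqid = gemmi.SeqId(rec.residue_number, " ")
                new_res.het_flag = "A" if rec.residue_name in STANDARD_AA else "H"
                # add_residue copies; keep the stored reference
                residue = chains[rec.chain_id].add_residue(new_res)
                res_key = key
            at = gemmi.Atom()
            at.name = rec.atom_name
            at.element = gemmi.Element(rec.element or rec.atom_name[0])
            at.occ = 1.0
            at.b_iso = 0.0
            x, y, z = coords[fi, ai]
            at.pos = gemmi.Position(float(x), float(y), float(z))
            residue.add_atom(at)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st
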