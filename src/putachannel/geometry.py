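"""Crystallographic geometry metrics for channeling-relevant features.

Implements the measurements used to characterise the PutA catalytic cycle
structures: covalent bond lengths (e.g. flavin N5 to proline C5), side-chain
chi1 rotamers, the Burgi-Dunitz nucleophilic approach angle, the flavin
isoalloxazine butterfly bend (angle between the least-squares planes of the
two outer rings), the Arg488-Glu225 ion-pair gate distance, and the
separation between the two active sites (flavin N5 to the aldehyde
dehydrogenase nucleophile of residue 844).

All angles are degrees; all distances Angstrom.  Dihedrals follow the IUPAC
sign convention and are reported in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import AtomNotFoundError, DegenerateGeometryError, EmptySelectionError
from .structure_io import Atom, AtomRef, StructureModel, ligand_occupancy, resolve_atom

#: heavy gamma atom defining chi1, by residue type
_CHI1_GAMMA = {
    "SER": "OG",
    "CYS": "SG",
    "THR": "OG1",
    "ILE": "CG1",
    "VAL": "CG1",
}

#: outer pyrimidine-side ring of the isoalloxazine (ring A)
FLAVIN_RING_A = ("N1", "C2", "N3", "C4", "C4X", "C10")
#: outer benzene-side ring (ring C)
FLAVIN_RING_C = ("C5X", "C6", "C7", "C8", "C9", "C9A")
#: older depositions write C4A/C5A for the bridgehead carbons
_FLAVIN_ALIASES = {"C4X": ("C4X", "C4A"), "C5X": ("C5X", "C5A"), "C10": ("C10", "C10A")}


def distance(a: Atom | np.ndarray, b: Atom | np.ndarray) -> float:
    """Euclidean distance between two atoms (or raw positions), Angstrom."""
    pa = a.position if isinstance(a, Atom) else np.asarray(a, dtype=float)
    pb = b.position if isinstance(b, Atom) else np.asarray(b, dtype=float)
    return float(np.linalg.norm(pa - pb))


def min_group_distance(
    group_a: Sequence[Atom],
    group_b: Sequence[Atom],
    heavy_only: bool = True,
) -> float:
    """Minimum pairwise distance between two atom groups.

    With ``heavy_only`` hydrogens (element H/D) are excluded first; an empty
    group after filtering is an error.
    """
    def _filter(group: Sequence[Atom]) -> np.ndarray:
        kept = [
            a.position
            for a in group
            if not (heavy_only and a.element.upper() in ("H", "D"))
        ]
        if not kept:
            raise EmptySelectionError("group empty after heavy-atom filter")
        return np.array(kept)

    pa, pb = _filter(group_a), _filter(group_b)
    diffs = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt((diffs**2).sum(axis=2)).min())


def dihedral(a: Atom | np.ndarray, b, c, d) -> float:
    """Torsion angle a-b-c-d in degrees, IUPAC sign, in (-180, 180]."""
    p = [x.position if isinstance(x, Atom) else np.asarray(x, float) for x in (a, b, c, d)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("three consecutive dihedral atoms are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))
    return 180.0 if np.isclose(ang, -180.0) else ang


def chi1(model: StructureModel, chain_id: str, residue_number: int) -> float:
    """Side-chain chi1 torsion N-CA-CB-gamma for a residue."""
    residue = model.residue_atoms(chain_id, residue_number)
    if not residue:
        raise AtomNotFoundError(f"no residue {chain_id}/{residue_number}")
    resname = residue[0].residue_name
    gamma_name = _CHI1_GAMMA.get(resname, "CG")
    if resname in ("GLY", "ALA"):
        raise AtomNotFoundError(f"{resname} {chain_id}/{residue_number} has no chi1")
    atoms = []
    for name in ("N", "CA", "CB", gamma_name):
        atoms.append(
            resolve_atom(model, AtomRef(chain_id, residue_number, name))
        )
    return dihedral(*atoms)


def burgi_dunitz(nu: Atom, carbonyl_c: Atom, carbonyl_o: Atom) -> float:
    """Nucleophile approach angle Nu-C-O at the carbonyl carbon, degrees."""
    v1 = nu.position - carbonyl_c.position
    v2 = carbonyl_o.position - carbonyl_c.position
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-8 or n2 < 1e-8:
        raise DegenerateGeometryError("coincident atoms in Burgi-Dunitz angle")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass(frozen=True)
class PlaneFit:
    """Least-squares plane through a point set."""

    normal: np.ndarray       # unit vector
    centroid: np.ndarray     # Angstrom
    rms_deviation: float     # Angstrom


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Total-least-squares plane via SVD of the centred coordinates."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1]
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return PlaneFit(normal=normal / np.linalg.norm(normal), centroid=centroid, rms_deviation=rms)


def _flavin_ring_positions(
    model: StructureModel, chain_id: str, names: Iterable[str]
) -> np.ndarray:
    pos = []
    for name in names:
        aliases = _FLAVIN_ALIASES.get(name, (name,))
        hit = None
        for alias in aliases:
            cands = [
                a
                for a in model.atoms
                if a.chain_id == chain_id and a.residue_name in ("FAD", "FMN", "FDA")
                and a.atom_name == alias
            ]
            if cands:
                hit = sorted(cands, key=lambda a: (-a.occupancy, a.altloc))[0]
                break
        if hit is None:
            raise AtomNotFoundError(
                f"flavin ring atom {name} (aliases {aliases}) missing in chain {chain_id}"
            )
        pos.append(hit.position)
    return np.array(pos)


def butterfly_bend(model: StructureModel, flavin_chain: str) -> float:
    """Isoalloxazine butterfly bend angle, degrees, folded into [0, 90].

    Angle between the least-squares plane normals of the outer pyrimidine
    ring (N1, C2, N3, C4, C4X, C10) and the outer benzene ring (C5X, C6, C7,
    C8, C9, C9A).  A perfectly planar flavin gives 0; the 2-electron-reduced
    flavin of the proline adduct bends by roughly 20 degrees about the
    N5-N10 axis.
    """
    ring_a = fit_plane(_flavin_ring_positions(model, flavin_chain, FLAVIN_RING_A))
    ring_c = fit_plane(_flavin_ring_positions(model, flavin_chain, FLAVIN_RING_C))
    cosang = abs(float(np.dot(ring_a.normal, ring_c.normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def plane_angle(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Angle between least-squares planes of two point sets, in [0, 90] degrees."""
    na = fit_plane(points_a).normal
    nb = fit_plane(points_b).normal
    return float(np.degrees(np.arccos(np.clip(abs(float(np.dot(na, nb))), -1.0, 1.0))))


def gate_distance_static(model: StructureModel, chain_id: str) -> float:
    """Arg488 CZ to Glu225 CD distance: the ion-pair gate of the proline site.

    Disordered or truncated side chains raise; the gate is never imputed.
    """
    cz = resolve_atom(model, AtomRef(chain_id, 488, "CZ", residue_name="ARG"))
    cd = resolve_atom(model, AtomRef(chain_id, 225, "CD", residue_name="GLU"))
    return distance(cz, cd)


def active_site_separation(model: StructureModel, chain_id: str) -> float:
    """Distance between the flavin N5 and the residue-844 nucleophile atom.

    The aldehyde dehydrogenase nucleophile is Cys844 SG, or Ser OG in the
    C844S variant.  This atom pair is this package's convention for the
    inter-site separation; depositors do not state one.
    """
    n5 = None
    for a in model.atoms:
        if a.chain_id == chain_id and a.residue_name in ("FAD", "FMN", "FDA") and a.atom_name == "N5":
            n5 = a
            break
    if n5 is None:
        raise AtomNotFoundError(f"no flavin N5 in chain {chain_id}")
    residue = model.residue_atoms(chain_id, 844)
    if not residue:
        raise AtomNotFoundError(f"no residue 844 in chain {chain_id}")
    nu_name = "SG" if residue[0].residue_name == "CYS" else "OG"
    nu = resolve_atom(model, AtomRef(chain_id, 844, nu_name))
    return distance(n5, nu)


def geometry_report(
    model: StructureModel,
    chain_id: str,
    ligand_resnames: Sequence[str] = (),
) -> dict:
    """Compute the preconfigured metric set for one model chain.

    Metrics that cannot be computed on this model (absent ligand, truncated
    side chain) are reported with an ``error`` field instead of a value, so
    one report covers all four catalytic-cycle structures.
    """
    report: dict[str, dict] = {}

    def _try(name: str, units: str, fn, atoms_used: str) -> None:
        try:
            report[name] = {"value": fn(), "units": units, "atoms": atoms_used}
        except Exception as exc:  # per-metric isolation
            report[name] = {"error": f"{type(exc).__name__}: {exc}"}

    _try(
        "butterfly_bend",
        "degrees",
        lambda: butterfly_bend(model, chain_id),
        "flavin outer-ring LSQ planes",
    )
    _try(
        "gate_distance",
        "angstrom",
        lambda: gate_distance_static(model, chain_id),
        "Arg488 CZ - Glu225 CD",
    )
    _try(
        "active_site_separation",
        "angstrom",
        lambda: active_site_separation(model, chain_id),
        "FAD N5 - residue 844 nucleophile",
    )
    _try(
        "chi1_844",
        "degrees",
        lambda: chi1(model, chain_id, 844),
        "residue 844 N-CA-CB-gamma",
    )
    for resname in ligand_resnames:
        _try(
            f"occupancy_{resname}",
            "fraction",
            lambda rn=resname: ligand_occupancy(model, chain_id, rn),
            f"{resname} atoms",
        )
    if ligand_resnames:
        # covalent-adduct bond: flavin N5 to C5 of the first named ligand
        first = ligand_resnames[0]

        def _n5_c5() -> float:
            n5 = [
                a for a in model.atoms
                if a.chain_id == chain_id and a.residue_name in ("FAD", "FMN", "FDA")
                and a.atom_name == "N5"
            ]
            c5 = [
                a for a in model.atoms
                if a.chain_id == chain_id and a.residue_name == first
                and a.atom_name == "C5"
            ]
            if not n5 or not c5:
                raise AtomNotFoundError(f"need FAD N5 and {first} C5 in chain {chain_id}")
            return distance(n5[0], c5[0])

        _try("n5_c5_bond", "angstrom", _n5_c5, f"FAD N5 - {first} C5")
    if len(ligand_resnames) >= 2:
        # secondary-site separation: minimum heavy-atom distance between the
        # first two named ligands (e.g. P5C and the secondary-site proline)
        a_name, b_name = ligand_resnames[0], ligand_resnames[1]

        def _secondary() -> float:
            ga = [a for a in model.atoms
                  if a.chain_id == chain_id and a.residue_name == a_name]
            gb = [a for a in model.atoms
                  if a.chain_id == chain_id and a.residue_name == b_name]
            return min_group_distance(ga, gb)

        _try(
            "secondary_site_distance",
            "angstrom",
            _secondary,
            f"min heavy-atom {a_name} - {b_name}",
        )
    return report
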