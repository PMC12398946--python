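"""Shared fixtures: hand-written PDB text, constructed geometries, small ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from putachannel.structure_io import Atom, StructureModel

# A minimal hand-written coordinate fixture: a residue with an altloc pair,
# a two-atom ligand at partial occupancy, and one water.
MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  CB AALA A   1       2.000   1.400   0.000  0.60 12.00           C
ATOM      4  CB BALA A   1       2.100   1.300   0.100  0.40 12.00           C
HETATM    5  C1  LIG A   9       5.000   5.000   5.000  0.73 15.00           C
HETATM    6  C2  LIG A   9       6.000   5.000   5.000  0.73 15.00           C
HETATM    7  O   HOH A 101       8.000   8.000   8.000  1.00 20.00           O
END
"""


@pytest.fixture
def mini_pdb_path(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


def make_atom(
    name: str,
    pos,
    resname: str = "ALA",
    resnum: int = 1,
    chain: str = "A",
    occ: float = 1.0,
    alt: str = "",
    element: str | None = None,
) -> Atom:
    return Atom(
        chain_id=chain,
        residue_number=resnum,
        residue_name=resname,
        atom_name=name,
        altloc=alt,
        occupancy=occ,
        b_factor=0.0,
        position=np.asarray(pos, dtype=float),
        element=element or name[0],
    )


def make_model(atoms) -> StructureModel:
    return StructureModel(atoms=list(atoms), source_id="fixture")


def place_by_internal(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d from positions a-b-c with given internal coordinates (NeRF)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


#: hexagonal-ish planar ring templates for a synthetic isoalloxazine; the
#: fold axis (N5-N10) is the x-axis, ring A at y < 0, ring C at y > 0
_RING_A_XY = {
    "N1": (0.0, -0.5),
    "C2": (1.2, -1.2),
    "N3": (1.2, -2.6),
    "C4": (0.0, -3.3),
    "C4X": (-1.2, -2.6),
    "C10": (-1.2, -1.2),
}
_RING_C_XY = {
    "C5X": (1.2, 1.2),
    "C6": (1.2, 2.6),
    "C7": (0.0, 3.3),
    "C8": (-1.2, 2.6),
    "C9": (-1.2, 1.2),
    "C9A": (0.0, 0.5),
}


def synthetic_flavin(fold_deg: float, chain: str = "A"):
    """FAD ring atoms folded by fold_deg about the N5-N10 (x) axis."""
    atoms = []
    for name, (x, y) in _RING_A_XY.items():
        atoms.append(make_atom(name, (x, y, 0.0), resname="FAD", resnum=500, chain=chain))
    th = np.radians(fold_deg)
    for name, (x, y) in _RING_C_XY.items():
        atoms.append(
            make_atom(
                name,
                (x, y * np.cos(th), y * np.sin(th)),
                resname="FAD",
                resnum=500,
                chain=chain,
            )
        )
    for name, pos in (("N5", (1.2, 0.0, 0.0)), ("N10", (-1.2, 0.0, 0.0))):
        atoms.append(make_atom(name, pos, resname="FAD", resnum=500, chain=chain))
    return atoms


@pytest.fixture(scope="session")
def small_ensemble():
    """6 replicates x 1000 frames with a trimmed water field.

    Long enough that both remained and channeled outcomes occur, small
    enough to stay fast.
    """
    from putachannel.synthetic import SyntheticConfig, generate_ensemble

    cfg = SyntheticConfig(n_replicates=6, n_frames=1000, seed=42)
    cfg.waters.n_particles = 120
    ens, truth = generate_ensemble(cfg)
    return cfg, ens, truth
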