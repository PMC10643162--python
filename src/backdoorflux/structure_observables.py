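"""Structural observables on atomic models.

Distances (R177CZ-N111CG backdoor distance, sensor/Pro-rich loop
centroid separation, H161NE2-Q137OE1), the chi1 side-chain torsion, the
ΔRMSD steering coordinate with its moving harmonic restraint, and
helical rise/twist from consecutive filament subunits.

Coordinates are stored in Angstrom (structure convention); ΔRMSD and the
restraint operate in nm (MD convention), converted at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureSnapshot",
    "SMDParams",
    "HelicalParams",
    "SMD_FIT_RANGES",
    "atom_distance",
    "group_distance",
    "chi1",
    "kabsch_rmsd",
    "delta_rmsd",
    "smd_potential",
    "helical_parameters",
]

#: CA residue ranges used to fit RMSDs in the steered-MD protocol
SMD_FIT_RANGES: tuple[tuple[int, int], ...] = (
    (8, 21), (29, 32), (35, 38), (53, 68), (71, 76), (79, 93), (103, 126),
    (131, 145), (150, 166), (169, 178), (182, 196), (203, 216), (223, 232),
    (238, 242), (246, 250), (252, 262), (274, 284), (287, 295), (297, 300),
    (308, 320), (326, 332), (338, 348), (350, 355), (359, 365), (367, 373),
)


@dataclass
class StructureSnapshot:
    """Labeled atom coordinates (Angstrom), thin wrapper over a biotite
    AtomArray.

    The AtomArray carries the annotations (chain, residue, atom names);
    coordinates are shadowed in float64 (``xyz``) because AtomArray
    stores float32, which is too coarse for tight rigid-motion
    invariants.
    """

    atoms: struc.AtomArray
    xyz: np.ndarray = None

    def __post_init__(self) -> None:
        if self.xyz is None:
            self.xyz = np.asarray(self.atoms.coord, dtype=np.float64).copy()
        else:
            self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_pdb(cls, path: str) -> "StructureSnapshot":
        """Read ATOM/HETATM records of the first model, preferring
        altloc 'A'; insertion codes are rejected."""
        pdb = PDBFile.read(path)
        arr = pdb.get_structure(model=1, altloc="first")
        if np.any(arr.ins_code != ""):
            raise ValueError("insertion codes are not supported")
        return cls(atoms=arr)

    @classmethod
    def from_arrays(
        cls,
        chain: Sequence[str],
        res_id: Sequence[int],
        res_name: Sequence[str],
        atom_name: Sequence[str],
        coords: np.ndarray,
    ) -> "StructureSnapshot":
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        arr = struc.AtomArray(n)
        arr.chain_id = np.asarray(chain, dtype="U4")
        arr.res_id = np.asarray(res_id, dtype=int)
        arr.res_name = np.asarray(res_name, dtype="U5")
        arr.atom_name = np.asarray(atom_name, dtype="U6")
        arr.element = np.array(
            [a[:1] for a in np.asarray(atom_name, dtype="U6")], dtype="U2"
        )
        arr.coord = coords
        return cls(atoms=arr, xyz=coords)

    def mask(
        self,
        chain: str | None = None,
        res_ids: Sequence[int] | int | None = None,
        atom_names: Sequence[str] | str | None = None,
    ) -> np.ndarray:
        m = np.ones(self.atoms.array_length(), dtype=bool)
        if chain is not None:
            m &= self.atoms.chain_id == chain
        if res_ids is not None:
            ids = np.atleast_1d(res_ids)
            m &= np.isin(self.atoms.res_id, ids)
        if atom_names is not None:
            names = np.atleast_1d(atom_names)
            m &= np.isin(self.atoms.atom_name, names)
        return m

    def coords(self, **selection) -> np.ndarray:
        m = self.mask(**selection)
        if not np.any(m):
            raise ValueError(f"empty selection: {selection}")
        return self.xyz[m]

    def single_atom(self, **selection) -> np.ndarray:
        c = self.coords(**selection)
        if len(c) != 1:
            raise ValueError(
                f"selection {selection} matches {len(c)} atoms, expected 1"
            )
        return c[0]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureSnapshot":
        new_xyz = self.xyz @ np.asarray(R, dtype=float).T + np.asarray(t, dtype=float)
        arr = self.atoms.copy()
        arr.coord = new_xyz
        return StructureSnapshot(atoms=arr, xyz=new_xyz)


@dataclass
class SMDParams:
    """Moving ΔRMSD restraint of the steered-MD protocol."""

    k: float = 334_124.0        # kJ mol^-1 nm^-2
    v: float = 0.0022           # nm/ns
    fit_ranges: tuple[tuple[int, int], ...] = SMD_FIT_RANGES
    offset_convention: str = "zero_at_start"   # or "as_printed"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("force constant must be positive")
        if self.offset_convention not in ("zero_at_start", "as_printed"):
            raise ValueError("unknown offset convention")


@dataclass
class HelicalParams:
    """Helical rise/twist per interface and their mean +/- SD."""

    rise: float                 # Angstrom, mean
    twist: float                # degrees, mean
    rise_sd: float = 0.0
    twist_sd: float = 0.0
    per_interface: list = field(default_factory=list)


def atom_distance(s: StructureSnapshot, sel_a: dict, sel_b: dict) -> float:
    """Euclidean distance (Angstrom) between two uniquely selected atoms."""
    a = s.single_atom(**sel_a)
    b = s.single_atom(**sel_b)
    return float(np.linalg.norm(a - b))


def group_distance(s: StructureSnapshot, sel_a: dict, sel_b: dict) -> float:
    """Distance between unweighted centroids of two atom groups
    (e.g. sensor-loop CA 70-75 vs Pro-rich loop CA 105-115)."""
    ca = s.coords(**sel_a).mean(axis=0)
    cb = s.coords(**sel_b).mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, range (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


_GAMMA_ATOMS = ("CG", "CG1", "OG", "OG1", "SG")


def chi1(s: StructureSnapshot, chain: str, res_id: int) -> float:
    """First side-chain torsion N-CA-CB-CG (degrees, signed)."""
    pts = []
    for name in ("N", "CA", "CB"):
        pts.append(s.single_atom(chain=chain, res_ids=res_id, atom_names=name))
    for name in _GAMMA_ATOMS:
        m = s.mask(chain=chain, res_ids=res_id, atom_names=name)
        if np.any(m):
            pts.append(s.xyz[m][0])
            break
    else:
        raise ValueError(f"residue {chain}/{res_id} lacks a gamma atom")
    return _dihedral(*pts)


def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD (same units as input) after optimal least-squares
    superposition of ``mobile`` onto ``reference``."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets differ in shape")
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(Q, P)
    aligned = rot.apply(P)
    return float(np.sqrt(((aligned - Q) ** 2).sum(axis=1).mean()))


def _fit_coords(s: StructureSnapshot, fit_ranges, chain=None) -> np.ndarray:
    ids = [rid for lo, hi in fit_ranges for rid in range(lo, hi + 1)]
    m = s.mask(chain=chain, res_ids=ids, atom_names="CA")
    return s.xyz[m]


def delta_rmsd(
    x: StructureSnapshot,
    ref_core: StructureSnapshot,
    ref_be: StructureSnapshot,
    fit_ranges: tuple[tuple[int, int], ...] = SMD_FIT_RANGES,
    chain: str | None = None,
) -> float:
    """ΔRMSD steering coordinate, in nm.

    rmsd(x, core) - rmsd(x, barbed end), each after independent optimal
    superposition of x onto the respective reference, over the CA atoms
    of ``fit_ranges``.
    """
    cx = _fit_coords(x, fit_ranges, chain)
    cc = _fit_coords(ref_core, fit_ranges, chain)
    cb = _fit_coords(ref_be, fit_ranges, chain)
    if not (cx.shape == cc.shape == cb.shape):
        raise ValueError(
            f"fit ranges resolve to {cx.shape[0]}/{cc.shape[0]}/{cb.shape[0]} "
            "CA atoms; they must match across the three structures"
        )
    return (kabsch_rmsd(cx, cc) - kabsch_rmsd(cx, cb)) / 10.0


def smd_potential(
    x: StructureSnapshot,
    t_ns: float,
    params: SMDParams,
    ref_core: StructureSnapshot,
    ref_be: StructureSnapshot,
    chain: str | None = None,
) -> float:
    """Moving harmonic ΔRMSD restraint U(x, t) in kJ/mol.

    With R = rmsd(core, barbed end): the ``as_printed`` convention is
    U = k/2 (ΔRMSD(x) - R - v t)^2, which is nonzero at the core start
    structure; the default ``zero_at_start`` convention flips the offset
    sign, U = k/2 (ΔRMSD(x) + R - v t)^2, so the restraint starts at
    zero on the core structure and drags it toward the barbed-end state.
    """
    d = delta_rmsd(x, ref_core, ref_be, params.fit_ranges, chain)
    cc = _fit_coords(ref_core, params.fit_ranges, chain)
    cb = _fit_coords(ref_be, params.fit_ranges, chain)
    R = kabsch_rmsd(cc, cb) / 10.0
    if params.offset_convention == "as_printed":
        arg = d - R - params.v * t_ns
    else:
        arg = d + R - params.v * t_ns
    return 0.5 * params.k * arg * arg


def _kabsch_transform(x: np.ndarray, y: np.ndarray):
    """Rigid transform (R, t) minimizing ||R x + t - y||."""
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    rot, _ = Rotation.align_vectors(y - cy, x - cx)
    R = rot.as_matrix()
    t = cy - R @ cx
    return R, t


def _screw_decompose(R: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """(rise, twist_deg) of the screw motion y = R x + t.

    The screw axis is the rotation axis; rise is the translation along
    it, with the axis oriented so the rise is non-negative, and twist is
    the signed rotation angle about that oriented axis.
    """
    rotvec = Rotation.from_matrix(R).as_rotvec()
    theta = float(np.linalg.norm(rotvec))
    if theta < 1e-9:
        return float(np.linalg.norm(t)), 0.0
    u = rotvec / theta
    rise = float(np.dot(t, u))
    if rise < 0:
        u = -u
        rise = -rise
        theta = -theta
    return rise, math.degrees(theta)


def helical_parameters(
    subunits: Sequence[StructureSnapshot],
    atom_names: str | Sequence[str] = "CA",
) -> HelicalParams:
    """Helical rise (Angstrom) and twist (degrees) of a filament segment.

    For each pair of consecutive subunits the optimal rigid transform
    mapping subunit i onto i+1 is decomposed into a screw motion; the
    mean +/- SD over the interfaces is reported (five subunits give four
    interfaces).  Subunits must share residue numbering.  The actin
    genetic helix is right-handed with twist near -167 degrees under
    this sign convention.
    """
    if len(subunits) < 2:
        raise ValueError("need at least 2 subunits")
    coords = []
    ref_ids = None
    for s in subunits:
        m = s.mask(atom_names=atom_names)
        ids = s.atoms.res_id[m]
        if ref_ids is None:
            ref_ids = ids
        elif len(ids) != len(ref_ids) or np.any(ids != ref_ids):
            raise ValueError("subunits do not share residue numbering")
        coords.append(s.xyz[m])
    per = []
    for a, b in zip(coords[:-1], coords[1:]):
        R, t = _kabsch_transform(a, b)
        per.append(_screw_decompose(R, t))
    rises = np.array([p[0] for p in per])
    twists = np.array([p[1] for p in per])
    return HelicalParams(
        rise=float(rises.mean()),
        twist=float(twists.mean()),
        rise_sd=float(rises.std(ddof=1)) if len(per) > 1 else 0.0,
        twist_sd=float(twists.std(ddof=1)) if len(per) > 1 else 0.0,
        per_interface=per,
    )
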