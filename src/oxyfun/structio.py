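"""Structure representation, PDB I/O, superposition and torsion geometry.

Coordinates are in Angstrom throughout; angles are degrees at every API
boundary (radians internally).  Structures carry role tags (FE1, FE2,
O_TRANSFER, C_N, C_M, C4_REF) mapping functional roles in the diiron
active-site model to atom serials.  Because the PDB format has no standard
slot for role tags or non-bonded parameters, both live in a sidecar YAML
file written next to each PDB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .errors import GeometryError, PDBParseError, TagError

ROLE_TAGS = ("FE1", "FE2", "O_TRANSFER", "C_N", "C_M", "C4_REF")

_COLLINEAR_TOL = 1e-8


@dataclass
class Atom:
    """A point atom with optional non-bonded parameters.

    lj_epsilon (kcal/mol) and lj_sigma (A) are the Lennard-Jones well depth
    and diameter; partial_charge is in elementary charge units.
    """

    serial: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    coords: np.ndarray
    partial_charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_sigma: float = 3.4

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if self.lj_sigma <= 0:
            raise ValueError(f"atom {self.serial}: lj_sigma must be > 0")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Structure:
    """An ordered atom collection plus role tags (role label -> atom serial)."""

    atoms: list[Atom] = field(default_factory=list)
    tags: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise PDBParseError(f"duplicate atom serial(s): {dup}")
        serial_set = set(serials)
        for role, serial in self.tags.items():
            if serial not in serial_set:
                raise TagError(f"tag {role} -> serial {serial} does not resolve to an atom")
        if "FE1" in self.tags and "FE2" in self.tags and self.tags["FE1"] == self.tags["FE2"]:
            raise TagError("FE1 and FE2 must be distinct atoms")

    # -- access ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(len(self.atoms), 3)

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    def atom_by_serial(self, serial: int) -> Atom:
        for atom in self.atoms:
            if atom.serial == serial:
                return atom
        raise KeyError(f"no atom with serial {serial}")

    def tagged(self, role: str) -> Atom:
        if role not in self.tags:
            raise TagError(f"structure has no {role} tag")
        return self.atom_by_serial(self.tags[role])

    def require_tags(self, roles: Iterable[str]) -> None:
        missing = [r for r in roles if r not in self.tags]
        if missing:
            raise TagError(f"missing required tag(s): {missing}")

    def copy(self) -> "Structure":
        return Structure(atoms=[a.copy() for a in self.atoms], tags=dict(self.tags),
                         metadata=dict(self.metadata))

    def transformed(self, transform: "RigidTransform") -> "Structure":
        out = self.copy()
        out.coords = transform.apply(out.coords)
        return out


@dataclass
class RigidTransform:
    """A proper rotation followed by a translation: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1 (proper rotation)")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _sidecar_path(pdb_path: Path) -> Path:
    return pdb_path.with_suffix(pdb_path.suffix + ".tags.yaml")


def read_pdb(path, tags_path=None) -> Structure:
    """Read fixed-column ATOM/HETATM records into a Structure.

    Role tags and non-bonded parameters are read from ``tags_path`` if given,
    else from ``<path>.tags.yaml`` when that sidecar exists.  Records with a
    non-blank altloc or insertion code are rejected.
    """
    path = Path(path)
    atoms: list[Atom] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path.name} line {lineno}: record too short for coordinates")
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                resid = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"{path.name} line {lineno}: malformed record ({exc})") from exc
            if altloc:
                raise PDBParseError(f"{path.name} line {lineno}: altloc '{altloc}' not supported")
            if icode:
                raise PDBParseError(f"{path.name} line {lineno}: insertion code '{icode}' not supported")
            if serial in seen:
                raise PDBParseError(f"{path.name} line {lineno}: duplicate atom serial {serial}")
            seen.add(serial)
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = "".join(c for c in name if c.isalpha())[:2].capitalize() or "X"
            atoms.append(Atom(serial=serial, name=name, element=element,
                              residue_id=resid, residue_name=resname,
                              coords=np.array([x, y, z])))
    if not atoms:
        raise PDBParseError(f"{path.name}: no ATOM/HETATM records")

    tags: dict[str, int] = {}
    metadata: dict = {}
    sidecar = Path(tags_path) if tags_path is not None else _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        tags = {str(k): int(v) for k, v in (meta.get("tags") or {}).items()}
        metadata = meta.get("metadata") or {}
        params = meta.get("atoms") or {}
        by_serial = {a.serial: a for a in atoms}
        for serial, p in params.items():
            atom = by_serial.get(int(serial))
            if atom is None:
                raise TagError(f"{sidecar.name}: parameters for unknown serial {serial}")
            atom.partial_charge = float(p.get("charge", atom.partial_charge))
            atom.lj_epsilon = float(p.get("epsilon", atom.lj_epsilon))
            atom.lj_sigma = float(p.get("sigma", atom.lj_sigma))
    return Structure(atoms=atoms, tags=tags, metadata=metadata)


def write_pdb(structure: Structure, path, sidecar: bool = True) -> None:
    """Write fixed-column ATOM records (+ END), and a sidecar YAML with role
    tags and non-bonded parameters unless ``sidecar`` is false."""
    path = Path(path)
    lines = []
    for atom in structure.atoms:
        if len(atom.residue_name) > 3:
            raise ValueError(f"residue name '{atom.residue_name}' exceeds PDB 3-character field")
        if len(atom.name) > 4:
            raise ValueError(f"atom name '{atom.name}' exceeds PDB 4-character field")
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {atom.serial:>5d} {name}{'':1s}{atom.residue_name:>3s} A"
            f"{atom.residue_id:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        meta = {
            "metadata": structure.metadata,
            "tags": {k: int(v) for k, v in structure.tags.items()},
            "atoms": {
                int(a.serial): {
                    "charge": float(a.partial_charge),
                    "epsilon": float(a.lj_epsilon),
                    "sigma": float(a.lj_sigma),
                }
                for a in structure.atoms
            },
        }
        _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = math.fmod(angle_deg, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


def torsion(p1, p2, p3, p4) -> float:
    """Torsion (dihedral) angle p1-p2-p3-p4 in degrees, range (-180, 180].

    IUPAC sign convention: looking from p2 toward p3, the far bond rotated
    clockwise from the near bond is positive; cis is 0, trans is 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    scale = max(np.linalg.norm(b1) * b2n, 1e-30)
    if np.linalg.norm(n1) / scale < _COLLINEAR_TOL:
        raise GeometryError("p1, p2, p3 are collinear; torsion undefined")
    scale = max(np.linalg.norm(b3) * b2n, 1e-30)
    if np.linalg.norm(n2) / scale < _COLLINEAR_TOL:
        raise GeometryError("p2, p3, p4 are collinear; torsion undefined")
    angle = math.degrees(math.atan2(b2n * np.dot(b1, n2), np.dot(n1, n2)))
    return wrap_angle(angle)


def superpose(mobile: Structure, reference: Structure,
              selection: Sequence[tuple[int, int]]) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of `mobile` onto `reference`.

    `selection` pairs (mobile_serial, reference_serial).  Returns the proper
    rigid transform (no reflection) and the RMSD over the selection after
    applying it.  Requires >= 3 non-collinear pairs.
    """
    if len(selection) < 3:
        raise GeometryError("superposition needs at least 3 paired atoms")
    mob = np.array([mobile.atom_by_serial(ms).coords for ms, _ in selection])
    ref = np.array([reference.atom_by_serial(rs).coords for _, rs in selection])
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0 = mob - mob_c
    ref0 = ref - ref_c
    # collinear selections leave a rotational degree of freedom undetermined
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2 or np.linalg.matrix_rank(ref0, tol=1e-8) < 2:
        raise GeometryError("superposition selection is collinear/degenerate")
    rot, _rssd = Rotation.align_vectors(ref0, mob0)
    rmat = rot.as_matrix()
    transform = RigidTransform(rmat, ref_c - rmat @ mob_c)
    fitted = transform.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return transform, rmsd
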