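"""Enumeration and 3-D construction of arenium (hydroxylation) intermediates.

A monocyclic aromatic substrate is described topologically: a benzene ring
with labelled substituents at positions 1-6 and, optionally, a short bridge
of extra atoms closing a fused second ring at two adjacent positions
(phthalan, 2-indanol).  Electrophilic attack of the activated oxygen on an
unsubstituted ring carbon Cn gives a cationic sigma-complex in which Cn is
sp3; one intermediate exists per symmetry-unique unsubstituted carbon, and
each leads to one phenolic product.

The builder produces toy 3-D geometries: the five untouched ring carbons
stay planar, Cn is pyramidalized to near-tetrahedral angles and carries the
transferred oxygen at a fixed C-O bond length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError
from .structio import Atom, Structure

RING_SIZE = 6


@dataclass(frozen=True)
class Substituent:
    position: int            # ring position 1-6
    label: str               # e.g. "CH3", "OCH2CH2OH"
    bulk_radius: float       # effective steric radius, A


@dataclass(frozen=True)
class FusedRing:
    """Bridge of extra heavy atoms closing a second ring at two adjacent positions."""
    attach: tuple[int, int]
    atom_labels: tuple[str, ...]    # bridge atoms in order from attach[0] to attach[1]


@dataclass
class SubstrateSpec:
    name: str
    code: str = ""
    substituents: list[Substituent] = field(default_factory=list)
    fused_ring: Optional[FusedRing] = None
    # optional overrides keyed by ring position
    intermediate_ids: dict[int, str] = field(default_factory=dict)
    product_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substituents]
        if len(set(positions)) != len(positions):
            raise ValueError("substituent positions must be distinct")
        if not all(1 <= p <= RING_SIZE for p in positions):
            raise ValueError("substituent positions must be in 1..6")
        if self.fused_ring is not None:
            a, b = self.fused_ring.attach
            if not _adjacent(a, b):
                raise ValueError("fused ring must attach at two adjacent ring positions")

    @property
    def occupied_positions(self) -> set[int]:
        occ = {s.position for s in self.substituents}
        if self.fused_ring is not None:
            occ |= set(self.fused_ring.attach)
        return occ


@dataclass
class BondGeometry:
    """Bond-geometry configuration for the 3-D builder (lengths in A)."""
    cc_aromatic: float = 1.40
    co: float = 1.43
    ch: float = 1.09
    c_substituent: float = 1.50
    ring_charge: float = 0.15       # delocalized arenium cation charge per ring C
    o_charge: float = -0.40
    c_epsilon: float = 0.10
    c_sigma: float = 3.40
    o_epsilon: float = 0.15
    o_sigma: float = 3.00
    h_epsilon: float = 0.02
    h_sigma: float = 2.40


@dataclass
class AreniumIntermediate:
    id: str
    cn_position: int
    cm_position: int
    product_name: str
    spec: SubstrateSpec
    structure: Optional[Structure] = None


def _adjacent(a: int, b: int) -> bool:
    return (a - b) % RING_SIZE in (1, RING_SIZE - 1)


def _ring_distance(a: int, b: int) -> int:
    d = abs(a - b) % RING_SIZE
    return min(d, RING_SIZE - d)


# ---------------------------------------------------------------------------
# Symmetry / enumeration
# ---------------------------------------------------------------------------

def _dihedral_ops():
    """The 12 symmetry operations of a hexagon as position maps on 1..6."""
    ops = []
    for k in range(RING_SIZE):
        ops.append({p: (p - 1 + k) % RING_SIZE + 1 for p in range(1, RING_SIZE + 1)})
    for k in range(RING_SIZE):  # reflections: p -> k - p
        ops.append({p: (k - (p - 1)) % RING_SIZE + 1 for p in range(1, RING_SIZE + 1)})
    return ops


def _automorphisms(spec: SubstrateSpec):
    """Symmetry operations preserving the labelled substitution pattern."""
    labels = {s.position: s.label for s in spec.substituents}
    fused = spec.fused_ring
    ops = []
    for op in _dihedral_ops():
        ok = all(labels.get(op[p]) == labels.get(p) for p in range(1, RING_SIZE + 1))
        if ok and fused is not None:
            a, b = fused.attach
            image = {op[a], op[b]}
            ok = image == set(fused.attach)
            if ok and tuple(reversed(fused.atom_labels)) != fused.atom_labels:
                # non-palindromic bridge: orientation must be preserved
                ok = op[a] == a
        if ok:
            ops.append(op)
    return ops


def symmetry_orbits(spec: SubstrateSpec) -> list[list[int]]:
    """Orbits of unsubstituted ring positions under the substrate's symmetry."""
    free = sorted(set(range(1, RING_SIZE + 1)) - spec.occupied_positions)
    ops = _automorphisms(spec)
    orbits = []
    seen: set[int] = set()
    for p in free:
        if p in seen:
            continue
        orbit = sorted({op[p] for op in ops})
        orbits.append(orbit)
        seen.update(orbit)
    return orbits


def _choose_cm(spec: SubstrateSpec, cn: int) -> int:
    """Cm = ring neighbour of Cn on the side nearer the closest substituent."""
    neighbours = sorted({(cn % RING_SIZE) + 1, ((cn - 2) % RING_SIZE) + 1})
    occ = spec.occupied_positions
    if not occ:
        return neighbours[0]

    def dist(n: int) -> int:
        return min(_ring_distance(n, o) for o in occ)

    return min(neighbours, key=lambda n: (dist(n), n))


def enumerate_intermediates(spec: SubstrateSpec) -> list[AreniumIntermediate]:
    """One arenium intermediate per symmetry-unique unsubstituted ring carbon.

    Deterministic: orbits are represented by their lowest ring position and
    listed in increasing position order.
    """
    orbits = symmetry_orbits(spec)
    if not orbits:
        warnings.warn(f"{spec.name}: fully substituted ring, no hydroxylation site")
        return []
    out = []
    for orbit in orbits:
        cn = orbit[0]
        iid = spec.intermediate_ids.get(cn, f"{cn}{spec.code or spec.name[:2].upper()}")
        product = spec.product_names.get(cn, f"{spec.name}-{cn}-ol")
        out.append(AreniumIntermediate(id=iid, cn_position=cn,
                                       cm_position=_choose_cm(spec, cn),
                                       product_name=product, spec=spec))
    return out


# ---------------------------------------------------------------------------
# 3-D construction
# ---------------------------------------------------------------------------

def _ring_xy(k: int, radius: float) -> np.ndarray:
    """Position k (1-6) of a regular hexagon of given circumradius, z = 0."""
    ang = math.radians(60.0 * (k - 1))
    return np.array([radius * math.cos(ang), radius * math.sin(ang), 0.0])


def _tetrahedral_partners(u1: np.ndarray, u2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Given two unit bond directions from an sp3 centre, return the two
    remaining tetrahedral directions (unit vectors)."""
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    n = np.cross(u1, u2)
    n /= np.linalg.norm(n)
    cos_t = math.cos(math.radians(109.471))
    # d = a*bis + b*n with a^2+b^2 = 1 and d.u1 = cos_t
    a = cos_t / np.dot(bis, u1)
    b = math.sqrt(max(0.0, 1.0 - a * a))
    return a * bis + b * n, a * bis - b * n


def build_geometry(intermediate: AreniumIntermediate,
                   params: BondGeometry | None = None) -> Structure:
    """Build toy 3-D coordinates for an arenium intermediate.

    The five sp2 ring carbons sit on a regular hexagon in the z=0 plane; Cn
    is lifted out of plane so that its four bonds (two ring C, O, H) are
    near-tetrahedral, with the transferred oxygen on the +z side.
    """
    params = params or BondGeometry()
    spec = intermediate.spec
    cn = intermediate.cn_position
    r = params.cc_aromatic  # circumradius = bond length for a regular hexagon

    atoms: list[Atom] = []
    serial = 0

    def add(name, element, resname, coords, charge=0.0, eps=None, sigma=None):
        nonlocal serial
        serial += 1
        if eps is None:
            eps, sigma = {
                "C": (params.c_epsilon, params.c_sigma),
                "O": (params.o_epsilon, params.o_sigma),
                "H": (params.h_epsilon, params.h_sigma),
            }.get(element, (0.1, 3.4))
        atoms.append(Atom(serial=serial, name=name, element=element, residue_id=1,
                          residue_name=resname, coords=coords, partial_charge=charge,
                          lj_epsilon=eps, lj_sigma=sigma))
        return serial

    ring_serials: dict[int, int] = {}
    cn_xyz: dict[int, np.ndarray] = {}

    # sp2 ring carbons (all but Cn) exactly in-plane
    for k in range(1, RING_SIZE + 1):
        cn_xyz[k] = _ring_xy(k, r)
    # pyramidalize Cn: keep its in-plane radial direction, lift in +z so that
    # both Cn-neighbour bonds have the sp3-sp2 length matching 109.47 deg
    nb1 = cn_xyz[(cn % RING_SIZE) + 1]
    nb2 = cn_xyz[((cn - 2) % RING_SIZE) + 1]
    mid = 0.5 * (nb1 + nb2)
    chord = np.linalg.norm(nb1 - nb2)
    r_sp3 = chord / (2.0 * math.sin(math.radians(109.471 / 2.0)))
    reach = r_sp3 * math.cos(math.radians(109.471 / 2.0))
    radial = cn_xyz[cn] - mid
    in_plane = np.linalg.norm(radial)
    if reach < in_plane:
        # cannot keep the original radial offset; shrink it
        in_plane = reach * 0.99
    radial = radial / np.linalg.norm(radial) * in_plane
    lift = math.sqrt(max(0.0, reach * reach - in_plane * in_plane))
    cn_xyz[cn] = mid + radial + np.array([0.0, 0.0, lift])

    for k in range(1, RING_SIZE + 1):
        ring_serials[k] = add(f"C{k}", "C", "ARN", cn_xyz[k], charge=params.ring_charge)

    # oxygen and hydrogen on Cn along the two remaining tetrahedral directions
    u1 = (nb1 - cn_xyz[cn])
    u1 /= np.linalg.norm(u1)
    u2 = (nb2 - cn_xyz[cn])
    u2 /= np.linalg.norm(u2)
    d3, d4 = _tetrahedral_partners(u1, u2)
    d_o = d3 if d3[2] >= d4[2] else d4     # oxygen on the lifted (+z) side
    d_h = d4 if d_o is d3 else d3
    o_serial = add("O", "O", "ARN", cn_xyz[cn] + params.co * d_o, charge=params.o_charge)
    add(f"H{cn}", "H", "ARN", cn_xyz[cn] + params.ch * d_h)

    occupied = spec.occupied_positions
    # ring hydrogens / substituent pseudo-atoms, in-plane outward
    for k in range(1, RING_SIZE + 1):
        if k == cn:
            continue
        outward = _ring_xy(k, 1.0)
        outward /= np.linalg.norm(outward)
        if k in {s.position for s in spec.substituents}:
            sub = next(s for s in spec.substituents if s.position == k)
            element = next((c for c in sub.label if c.isalpha()), "C").upper()
            add(f"X{k}", element, "SUB", cn_xyz[k] + params.c_substituent * outward,
                eps=0.15, sigma=max(sub.bulk_radius, 1.0))
        elif spec.fused_ring is None or k not in spec.fused_ring.attach:
            add(f"H{k}", "H", "ARN", cn_xyz[k] + params.ch * outward)

    # fused-ring bridge atoms: walk a polygon outward from attach[0] to attach[1]
    if spec.fused_ring is not None:
        a, b = spec.fused_ring.attach
        n_bridge = len(spec.fused_ring.atom_labels)
        pa, pb = cn_xyz[a], cn_xyz[b]
        ring_total = n_bridge + 2
        interior = math.pi * (ring_total - 2) / ring_total
        outward = 0.5 * (pa + pb)
        outward /= np.linalg.norm(outward)
        direction = (pb - pa) / np.linalg.norm(pb - pa)
        turn = math.pi - interior

        def rotz(v, ang):
            return np.array([v[0] * math.cos(ang) - v[1] * math.sin(ang),
                             v[0] * math.sin(ang) + v[1] * math.cos(ang), v[2]])

        # walk the polygon from attach[1], turning by the exterior angle
        # toward the outward side at every vertex
        sign = 1.0 if np.dot(rotz(direction, turn)[:2], outward[:2]) > 0 else -1.0
        pos = pb.copy()
        heading = direction.copy()
        positions = []
        for _ in spec.fused_ring.atom_labels:
            heading = rotz(heading, sign * turn)
            pos = pos + params.c_substituent * heading
            positions.append(pos.copy())
        # positions run from the attach[1] end; labels run from attach[0]
        for i, (label, xyz) in enumerate(zip(reversed(spec.fused_ring.atom_labels), positions)):
            element = next((c for c in label if c.isalpha()), "C").upper()
            add(f"B{i + 1}", element, "FUS", xyz)

    structure = Structure(atoms=atoms, tags={
        "C_N": ring_serials[cn],
        "C_M": ring_serials[intermediate.cm_position],
        "O_TRANSFER": o_serial,
    })

    # clash check: any non-bonded pair closer than 0.8 A means the fused-ring
    # closure is geometrically impossible
    xyz = structure.coords
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if np.min(d) < 0.8:
        raise GeometryError(f"{intermediate.id}: atom clash while closing fused ring")

    intermediate.structure = structure
    return structure


# ---------------------------------------------------------------------------
# Built-in substrates
# ---------------------------------------------------------------------------

def benzene() -> SubstrateSpec:
    return SubstrateSpec(name="benzene", code="BZ")


def toluene() -> SubstrateSpec:
    return SubstrateSpec(
        name="toluene", code="T",
        substituents=[Substituent(1, "CH3", 2.0)],
        product_names={2: "o-cresol", 3: "m-cresol", 4: "p-cresol"},
    )


def phenoxyethanol() -> SubstrateSpec:
    """2-phenoxyethanol: monosubstituted benzene; ortho/meta/para hydroxylation
    gives 2HEP, 3HEP and 4HEP."""
    return SubstrateSpec(
        name="2-phenoxyethanol", code="PE",
        substituents=[Substituent(1, "OCH2CH2OH", 2.8)],
        intermediate_ids={2: "2HEP", 3: "3HEP", 4: "4HEP"},
        product_names={2: "2-(2-hydroxyethoxy)phenol",
                       3: "3-(2-hydroxyethoxy)phenol",
                       4: "4-(2-hydroxyethoxy)phenol"},
    )


def phthalan() -> SubstrateSpec:
    """Phthalan (1,3-dihydro-2-benzofuran): benzene ortho-fused with CH2-O-CH2."""
    return SubstrateSpec(
        name="phthalan", code="PT",
        fused_ring=FusedRing(attach=(1, 2), atom_labels=("CH2", "O", "CH2")),
        intermediate_ids={3: "4PT", 4: "5PT"},
        product_names={3: "1,3-dihydro-4-hydroxyisobenzofuran",
                       4: "1,3-dihydro-5-hydroxyisobenzofuran"},
    )


def indanol2() -> SubstrateSpec:
    """2-indanol: benzene ortho-fused with CH2-CH(OH)-CH2."""
    return SubstrateSpec(
        name="2-indanol", code="I",
        fused_ring=FusedRing(attach=(1, 2), atom_labels=("CH2", "CHOH", "CH2")),
        intermediate_ids={3: "24I", 4: "25I"},
        product_names={3: "2,4-dihydroxyindan", 4: "2,5-dihydroxyindan"},
    )


BUILTIN_SUBSTRATES = {
    "benzene": benzene,
    "toluene": toluene,
    "2-phenoxyethanol": phenoxyethanol,
    "phthalan": phthalan,
    "2-indanol": indanol2,
}


def substrate_from_dict(data: dict) -> SubstrateSpec:
    """Build a SubstrateSpec from a YAML-style mapping."""
    subs = [Substituent(int(p), str(label), float(radius))
            for p, label, radius in data.get("substituents", [])]
    fused = None
    if data.get("fused_ring"):
        fr = data["fused_ring"]
        fused = FusedRing(attach=tuple(int(x) for x in fr["attach"]),
                          atom_labels=tuple(str(x) for x in fr["atoms"]))
    return SubstrateSpec(
        name=str(data["name"]), code=str(data.get("code", "")),
        substituents=subs, fused_ring=fused,
        intermediate_ids={int(k): str(v) for k, v in (data.get("intermediate_ids") or {}).items()},
        product_names={int(k): str(v) for k, v in (data.get("product_names") or {}).items()},
    )
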