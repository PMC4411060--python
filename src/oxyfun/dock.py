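"""Simplified non-covalent force field and seeded Monte Carlo docking.

The docking stand-in treats the active-site model as mostly rigid: the
arenium intermediate moves as a rigid body (optionally with rigid jumps of
designated mobile pocket residues) inside a pairwise-additive 6-12
Lennard-Jones + Coulomb field, with harmonic constraints tying the
transferred oxygen to its iron coordination distance.  Search is a chain of
perturb -> greedy-minimize cycles with Metropolis acceptance between cycles
and geometric cooling, fully reproducible from a single seed.

Energies are kcal/mol, distances A, charges elementary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, ParameterizationError
from .structio import Structure

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)
KT_ROOM = 0.596              # kcal/mol at ~300 K


@dataclass
class ForceFieldParams:
    lj_combining: str = "lorentz-berthelot"
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric_model: str = "distance_dependent"   # or "constant"
    dielectric_value: float = 1.0
    cutoff: float = 10.0
    constraint_k: float = 50.0   # kcal/(mol*A^2)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.constraint_k < 0:
            raise ValueError("constraint_k must be >= 0")
        if self.dielectric_model not in ("constant", "distance_dependent"):
            raise ValueError(f"unknown dielectric model {self.dielectric_model!r}")
        if self.lj_combining != "lorentz-berthelot":
            raise ValueError(f"unsupported combining rule {self.lj_combining!r}")


@dataclass(frozen=True)
class DistanceConstraint:
    """Harmonic restraint k*(|xi - xj| - r0)^2 between two atoms."""
    serial_i: int
    serial_j: int
    r0: float
    k: float


@dataclass(frozen=True)
class PointConstraint:
    """Harmonic restraint k*|xi - c|^2 pinning an atom to a fixed point."""
    serial: int
    center: tuple[float, float, float]
    k: float


Constraint = DistanceConstraint | PointConstraint


@dataclass
class MobileSet:
    """Degrees of freedom released during minimization/search."""
    residue_ids: frozenset[int] = frozenset()
    intermediate_rigid_body: bool = True

    def __init__(self, residue_ids: Iterable[int] = (), intermediate_rigid_body: bool = True):
        object.__setattr__(self, "residue_ids", frozenset(residue_ids))
        object.__setattr__(self, "intermediate_rigid_body", intermediate_rigid_body)


@dataclass
class DockingPose:
    """An intermediate placed in the site frame, with its energy breakdown."""
    structure: Structure
    intermediate_serials: frozenset[int]
    energy_total: float = 0.0
    energy_terms: dict[str, float] = field(default_factory=lambda: {"lj": 0.0, "coulomb": 0.0, "constraints": 0.0})
    seed: Optional[int] = None
    n_steps: int = 0
    constraints: tuple[Constraint, ...] = ()

    def __post_init__(self) -> None:
        self.intermediate_serials = frozenset(self.intermediate_serials)
        total = sum(self.energy_terms.values())
        if abs(self.energy_total - total) > 1e-6:
            raise ValueError("energy_total must equal the sum of energy_terms")

    def copy(self) -> "DockingPose":
        return DockingPose(structure=self.structure.copy(),
                           intermediate_serials=self.intermediate_serials,
                           energy_total=self.energy_total,
                           energy_terms=dict(self.energy_terms),
                           seed=self.seed, n_steps=self.n_steps,
                           constraints=self.constraints)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def _check_parameterized(structure: Structure, serials: Iterable[int]) -> None:
    for s in serials:
        atom = structure.atom_by_serial(s)
        if atom.lj_sigma <= 0:
            raise ParameterizationError(f"atom {atom.serial} ({atom.name}) lacks LJ parameters")


def _pair_indices(pose: DockingPose, mobile: MobileSet | None):
    """Index pairs entering the energy: intermediate-protein plus mobile-fixed."""
    atoms = pose.structure.atoms
    inter = np.array([a.serial in pose.intermediate_serials for a in atoms])
    idx_inter = np.nonzero(inter)[0]
    idx_prot = np.nonzero(~inter)[0]
    pairs_i, pairs_j = [], []
    if len(idx_inter) and len(idx_prot):
        gi, gj = np.meshgrid(idx_inter, idx_prot, indexing="ij")
        pairs_i.append(gi.ravel())
        pairs_j.append(gj.ravel())
    if mobile is not None and mobile.residue_ids:
        mob = np.array([(a.serial not in pose.intermediate_serials) and
                        (a.residue_id in mobile.residue_ids) for a in atoms])
        fix = ~inter & ~mob
        im, jf = np.nonzero(mob)[0], np.nonzero(fix)[0]
        if len(im) and len(jf):
            gi, gj = np.meshgrid(im, jf, indexing="ij")
            pairs_i.append(gi.ravel())
            pairs_j.append(gj.ravel())
    if not pairs_i:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(pairs_i), np.concatenate(pairs_j)


def _nonbonded(coords: np.ndarray, eps: np.ndarray, sig: np.ndarray, q: np.ndarray,
               pi: np.ndarray, pj: np.ndarray, ff: ForceFieldParams) -> tuple[float, float]:
    if len(pi) == 0:
        return 0.0, 0.0
    d = np.linalg.norm(coords[pi] - coords[pj], axis=1)
    mask = d <= ff.cutoff
    d = np.maximum(d[mask], 1e-6)
    pi, pj = pi[mask], pj[mask]
    sij = 0.5 * (sig[pi] + sig[pj])
    eij = np.sqrt(eps[pi] * eps[pj])
    sr6 = (sij / d) ** 6
    lj = float(np.sum(4.0 * eij * (sr6 * sr6 - sr6)))
    if ff.dielectric_model == "distance_dependent":
        denom = ff.dielectric_value * d * d
    else:
        denom = ff.dielectric_value * d
    coul = float(np.sum(ff.coulomb_constant * q[pi] * q[pj] / denom))
    return lj, coul


def _constraint_energy(structure: Structure, constraints: Sequence[Constraint]) -> float:
    e = 0.0
    for c in constraints:
        if isinstance(c, DistanceConstraint):
            xi = structure.atom_by_serial(c.serial_i).coords
            xj = structure.atom_by_serial(c.serial_j).coords
            e += c.k * (float(np.linalg.norm(xi - xj)) - c.r0) ** 2
        else:
            xi = structure.atom_by_serial(c.serial).coords
            e += c.k * float(np.sum((xi - np.asarray(c.center)) ** 2))
    return e


def energy(pose: DockingPose, ff: ForceFieldParams,
           mobile: MobileSet | None = None,
           constraints: Sequence[Constraint] | None = None) -> dict[str, float]:
    """Pairwise-additive energy of a pose: LJ + Coulomb over intermediate-protein
    (and mobile-fixed) pairs within the cutoff, plus harmonic constraint terms.

    Returns {"lj", "coulomb", "constraints", "total"} in kcal/mol.
    """
    s = pose.structure
    _check_parameterized(s, (a.serial for a in s.atoms))
    coords = s.coords
    eps = np.array([a.lj_epsilon for a in s.atoms])
    sig = np.array([a.lj_sigma for a in s.atoms])
    q = np.array([a.partial_charge for a in s.atoms])
    pi, pj = _pair_indices(pose, mobile)
    lj, coul = _nonbonded(coords, eps, sig, q, pi, pj, ff)
    cons = _constraint_energy(s, constraints if constraints is not None else pose.constraints)
    terms = {"lj": lj, "coulomb": coul, "constraints": cons}
    terms["total"] = lj + coul + cons
    return terms


def set_pose_energy(pose: DockingPose, ff: ForceFieldParams,
                    mobile: MobileSet | None = None) -> DockingPose:
    terms = energy(pose, ff, mobile)
    pose.energy_terms = {k: v for k, v in terms.items() if k != "total"}
    pose.energy_total = terms["total"]
    return pose


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

def _apply_rigid_move(coords: np.ndarray, idx: np.ndarray,
                      rotvec: np.ndarray, translation: np.ndarray) -> None:
    sub = coords[idx]
    centre = sub.mean(axis=0)
    rot = Rotation.from_rotvec(rotvec).as_matrix()
    coords[idx] = (sub - centre) @ rot.T + centre + translation


def _dof_blocks(pose: DockingPose, mobile: MobileSet) -> list[np.ndarray]:
    """Index blocks moved rigidly: the intermediate, then each mobile residue."""
    atoms = pose.structure.atoms
    blocks = []
    if mobile.intermediate_rigid_body:
        blocks.append(np.array([i for i, a in enumerate(atoms)
                                if a.serial in pose.intermediate_serials]))
    for rid in sorted(mobile.residue_ids):
        idx = np.array([i for i, a in enumerate(atoms)
                        if a.residue_id == rid and a.serial not in pose.intermediate_serials])
        if len(idx):
            blocks.append(idx)
    return [b for b in blocks if len(b)]


def minimize(pose: DockingPose, mobile: MobileSet, ff: ForceFieldParams,
             max_iter: int = 2000, tol: float = 1e-6,
             rng: np.random.Generator | None = None,
             constraints: Sequence[Constraint] | None = None) -> DockingPose:
    """Gradient-free local descent: random rigid perturbations of each mobile
    block, accepted only if the energy drops; step sizes shrink on rejection.

    The returned pose's energy never exceeds the input energy.  Convergence:
    energy improvement below `tol` over a window of proposals, or step sizes
    collapsed, or `max_iter` proposals spent.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    constraints = tuple(constraints if constraints is not None else pose.constraints)
    work = pose.copy()
    work.constraints = constraints
    blocks = _dof_blocks(work, mobile)
    e = energy(work, ff, mobile, constraints)["total"]
    if not math.isfinite(e):
        raise GeometryError("non-finite energy at start of minimization")
    if not blocks:
        return set_pose_energy(work, ff, mobile)

    coords = work.structure.coords
    trans_step, rot_step = 0.25, math.radians(8.0)
    window, improved_in_window = 60, 0.0
    steps = 0
    for it in range(max_iter):
        blk = blocks[it % len(blocks)]
        trial = coords.copy()
        rotvec = rng.normal(0.0, rot_step, 3) if len(blk) > 1 else np.zeros(3)
        translation = rng.normal(0.0, trans_step, 3)
        _apply_rigid_move(trial, blk, rotvec, translation)
        work.structure.coords = trial
        e_trial = energy(work, ff, mobile, constraints)["total"]
        steps += 1
        if e_trial < e:
            improved_in_window += e - e_trial
            coords = trial
            e = e_trial
        else:
            work.structure.coords = coords
            trans_step *= 0.97
            rot_step *= 0.97
        if (it + 1) % window == 0:
            if improved_in_window < tol or trans_step < 1e-5:
                break
            improved_in_window = 0.0
    work.structure.coords = coords
    work.n_steps = pose.n_steps + steps
    return set_pose_energy(work, ff, mobile)


def mc_search(site: Structure, intermediate: Structure, mobile: MobileSet,
              ff: ForceFieldParams, n_trials: int = 20, seed: int = 0,
              kt_start: float = KT_ROOM, cooling: float = 0.95,
              fe_o_target: float = 1.90,
              max_iter_per_trial: int = 800) -> list[DockingPose]:
    """Monte Carlo energy minimization: perturb -> minimize cycles with
    Metropolis acceptance between cycles and geometric cooling.

    The intermediate's transferred oxygen is harmonically constrained to the
    Fe2 coordination distance `fe_o_target`.  Returns every minimized pose,
    best energy first; bit-reproducible from `seed`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    pose = assemble_pose(site, intermediate)
    fe2 = pose.structure.tags["FE2"]
    ox = pose.structure.tags["O_TRANSFER"]
    constraints = (DistanceConstraint(ox, fe2, fe_o_target, ff.constraint_k),)
    pose.constraints = constraints
    pose.seed = seed

    current = minimize(pose, mobile, ff, max_iter=max_iter_per_trial, rng=rng)
    current.seed = seed
    poses = [current]
    kt = kt_start
    idx_inter = np.array([i for i, a in enumerate(current.structure.atoms)
                          if a.serial in current.intermediate_serials])
    for _ in range(n_trials - 1):
        trial = current.copy()
        coords = trial.structure.coords
        _apply_rigid_move(coords, idx_inter,
                          rng.normal(0.0, math.radians(25.0), 3),
                          rng.normal(0.0, 0.6, 3))
        trial.structure.coords = coords
        trial = minimize(trial, mobile, ff, max_iter=max_iter_per_trial, rng=rng)
        trial.seed = seed
        poses.append(trial)
        de = trial.energy_total - current.energy_total
        if de <= 0 or (kt > 0 and rng.random() < math.exp(-de / kt)):
            current = trial
        kt *= cooling
    return sorted(poses, key=lambda p: p.energy_total)


def assemble_pose(site: Structure, intermediate: Structure) -> DockingPose:
    """Merge a site model and an intermediate into one pose structure.

    Intermediate serials are offset past the site's; the site's poised-oxygen
    placeholder (its O_TRANSFER tag, if any) is dropped in favour of the
    intermediate's transferred oxygen.  The intermediate is initially placed
    with its oxygen at the site's poised-oxygen position (or 1.9 A from FE2).
    """
    intermediate.require_tags(["O_TRANSFER", "C_N", "C_M"])
    site.require_tags(["FE1", "FE2"])
    site_atoms = []
    poised = None
    for a in site.atoms:
        if site.tags.get("O_TRANSFER") == a.serial:
            poised = a.coords.copy()
            continue
        site_atoms.append(a.copy())
    if poised is None:
        fe2 = site.tagged("FE2").coords
        fe1 = site.tagged("FE1").coords
        direction = fe2 - fe1
        direction /= np.linalg.norm(direction)
        poised = fe2 + 1.9 * direction

    offset = max(a.serial for a in site.atoms) + 100
    inter_atoms = []
    serial_map = {}
    for a in intermediate.atoms:
        b = a.copy()
        b.serial = a.serial + offset
        b.residue_id = 999
        serial_map[a.serial] = b.serial
        inter_atoms.append(b)

    tags = {k: v for k, v in site.tags.items() if k != "O_TRANSFER"}
    for role in ("O_TRANSFER", "C_N", "C_M"):
        tags[role] = serial_map[intermediate.tags[role]]

    merged = Structure(atoms=site_atoms + inter_atoms, tags=tags)
    # translate intermediate so its oxygen sits at the poised position
    shift = poised - merged.tagged("O_TRANSFER").coords
    for a in merged.atoms:
        if a.serial > offset:
            a.coords = a.coords + shift
    pose = DockingPose(structure=merged,
                       intermediate_serials=frozenset(serial_map.values()))
    return pose
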