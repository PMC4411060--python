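"""Synthetic-data generators with known ground truth for every pipeline stage.

The study's raw inputs (the hydroxylase structure, docking complexes, raw
spectrophotometer traces, HPLC tables) are not available, so each stage is
fed by a generator whose truth is known by construction:

  make_toy_site          a toy diiron active-site model (tagged PDB)
  make_reference_complex the reference pose: toluene para arenium placed at
                         the canonical geometry (theta = 103.6 deg)
  make_pose_with_geometry a pose with prescribed (d, delta_theta)
  simulate_dpph          stoichiometric second-order DPPH consumption traces
  simulate_timecourse    linear-then-saturating product accumulation

Every generator embeds its spec and seed in the output metadata and is
byte-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import reference_data
from .arenium import BondGeometry, build_geometry, enumerate_intermediates, toluene
from .assaykit import EXTINCTION_515, KineticTrace, TimeCourse
from .dock import DockingPose, ForceFieldParams, assemble_pose, set_pose_energy
from .errors import ConstructionError, GeometryError
from .structio import Atom, RigidTransform, Structure, superpose, torsion

FE_O_DISTANCE = 1.90     # A, poised oxygen on Fe2
FE_O_CN_ANGLE = 120.0    # deg, angle at the transferred oxygen

_BLOCK_NAMES = {"ortho": 1, "meta": 2, "para": 3}


@dataclass
class ToySiteSpec:
    n_pocket_residues: int = 8
    pocket_radius: float = 6.5          # A, around the docking region
    fe_fe_distance: float = 3.3         # A
    blocked_positions: tuple = ()       # ring distances from Cn (1..3) or ortho/meta/para
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fe_fe_distance <= 0:
            raise ValueError("fe_fe_distance must be positive")
        self.blocked_positions = tuple(
            _BLOCK_NAMES.get(p, p) if isinstance(p, str) else int(p)
            for p in self.blocked_positions)
        if any(not 1 <= p <= 3 for p in self.blocked_positions):
            raise ValueError("blocked positions must be 1..3 (ortho/meta/para)")


@dataclass
class TraceSpec:
    """Conditions of a synthetic DPPH titration (0.1 mM DPPH in methanol)."""
    stoichiometric_factor: float = 2.0      # DPPH reduced per antioxidant molecule
    rate_constant: float = 0.02             # uM^-1 min^-1; fast enough that the
                                            # assay is near completion at the 30 min read
    doses: tuple = (0.05, 0.1, 0.2, 0.3, 0.5, 0.8)   # antioxidant/DPPH ratios
    noise_sd: float = 0.01                  # fraction of initial absorbance
    duration: float = 40.0                  # min
    sampling_interval: float = 0.5          # min
    dpph_initial: float = 100.0             # uM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stoichiometric_factor <= 0:
            raise ValueError("stoichiometric factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Toy active-site model
# ---------------------------------------------------------------------------

def _pocket_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic golden-spiral directions with small seeded jitter."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    pts = pts + rng.normal(0.0, 0.03, pts.shape)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _canonical_ring_slots() -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Positions (and outward directions) of the canonically docked arenium
    ring carbons, keyed by ring distance from Cn, in the site frame."""
    inter = next(i for i in enumerate_intermediates(toluene()) if i.cn_position == 4)
    structure = build_geometry(inter)
    transform = canonical_placement_transform(
        structure, fe2=np.zeros(3), fe1=np.array([-3.3, 0.0, 0.0]),
        poised=np.array([0.0, FE_O_DISTANCE, 0.0]),
        theta=reference_data.THETA_REFERENCE)
    placed = structure.transformed(transform)
    ring = {k: placed.atom_by_serial(k).coords for k in range(1, 7)}  # serials 1-6 = ring
    centroid = np.mean([ring[k] for k in ring], axis=0)
    cn = inter.cn_position
    slots = {}
    for k in range(1, 7):
        dist = min(abs(k - cn), 6 - abs(k - cn))
        if dist == 0 or dist in slots:
            continue
        outward = ring[k] - centroid
        outward /= np.linalg.norm(outward)
        slots[dist] = (ring[k], outward)
    return slots


def make_toy_site(spec: ToySiteSpec | None = None) -> Structure:
    """Deterministic toy active-site model: diiron cluster, poised oxygen,
    pocket pseudo-residues on a sphere, optional bulky blockers at chosen
    ring slots.  Fe2 sits at the origin, Fe1 along -x, the poised oxygen
    along +y."""
    spec = spec or ToySiteSpec()
    if spec.n_pocket_residues > 0 and spec.pocket_radius < 3.0:
        raise GeometryError("pocket_radius < 3 A collapses the pocket onto the cluster")
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    serial = 0

    def add(name, element, resid, resname, coords, charge=0.0, eps=0.1, sigma=3.4):
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial=serial, name=name, element=element, residue_id=resid,
                          residue_name=resname, coords=np.asarray(coords, dtype=float),
                          partial_charge=charge, lj_epsilon=eps, lj_sigma=sigma))
        return serial

    fe1 = add("FE1", "Fe", 900, "FE", [-spec.fe_fe_distance, 0.0, 0.0],
              charge=0.8, eps=0.05, sigma=2.6)
    fe2 = add("FE2", "Fe", 901, "FE", [0.0, 0.0, 0.0], charge=0.8, eps=0.05, sigma=2.6)
    ox = add("OX", "O", 902, "OXY", [0.0, FE_O_DISTANCE, 0.0],
             charge=-0.6, eps=0.15, sigma=3.0)

    centre = np.array([0.0, 3.0, 0.0])    # docking region above Fe2
    dirs = _pocket_directions(spec.n_pocket_residues, rng) if spec.n_pocket_residues else []
    for i, d in enumerate(dirs):
        rid = 100 + i
        add("CA", "C", rid, "GLY", centre + spec.pocket_radius * d,
            charge=-0.05, eps=0.12, sigma=3.8)
        add("CB", "C", rid, "GLY", centre + 0.8 * spec.pocket_radius * d,
            charge=0.05, eps=0.12, sigma=3.6)

    if spec.blocked_positions:
        slots = _canonical_ring_slots()
        for j, p in enumerate(spec.blocked_positions):
            pos, outward = slots[p]
            add("XB", "C", 800 + j, "BLK", pos + 1.2 * outward,
                charge=0.0, eps=0.30, sigma=3.5)

    site = Structure(atoms=atoms,
                     tags={"FE1": fe1, "FE2": fe2, "O_TRANSFER": ox},
                     metadata={"generator": "make_toy_site", "seed": spec.seed,
                               "spec": asdict(spec)})
    return site


# ---------------------------------------------------------------------------
# Canonical placement and the reference complex
# ---------------------------------------------------------------------------

def canonical_placement_transform(intermediate: Structure, fe2: np.ndarray,
                                  fe1: np.ndarray, poised: np.ndarray,
                                  theta: float) -> RigidTransform:
    """Rigid transform placing an arenium intermediate so that its transferred
    oxygen sits at `poised`, the Fe2-O-Cn angle is 120 deg, and the torsion
    Fe2-O-Cn-Cm equals `theta` degrees."""
    o = intermediate.tagged("O_TRANSFER").coords
    cn = intermediate.tagged("C_N").coords
    cm = intermediate.tagged("C_M").coords
    d_ocn = float(np.linalg.norm(cn - o))
    d_cncm = float(np.linalg.norm(cm - cn))
    v1 = o - cn
    v2 = cm - cn
    beta = math.degrees(math.acos(float(np.dot(v1, v2)) /
                                  (np.linalg.norm(v1) * np.linalg.norm(v2))))

    e1 = poised - fe2
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, e1)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)

    ang = math.radians(FE_O_CN_ANGLE)
    cn_t = poised + d_ocn * (-math.cos(ang) * e1 + math.sin(ang) * e2)

    u = cn_t - poised
    u /= np.linalg.norm(u)
    w_fe = (fe2 - poised) - np.dot(fe2 - poised, u) * u
    a = w_fe / np.linalg.norm(w_fe)
    b = np.cross(u, a)

    def cm_target(sign: float) -> np.ndarray:
        th = math.radians(theta)
        bt = math.radians(beta)
        w = math.cos(th) * a + sign * math.sin(th) * b
        return cn_t + d_cncm * (math.cos(bt) * (-u) + math.sin(bt) * w)

    cm_t = cm_target(1.0)
    if abs(torsion(fe2, poised, cn_t, cm_t) - theta) > 1e-6:
        cm_t = cm_target(-1.0)
    if abs(torsion(fe2, poised, cn_t, cm_t) - theta) > 1e-6:
        raise ConstructionError("could not realize requested torsion")

    targets = Structure(atoms=[
        Atom(1, "O", "O", 1, "TGT", poised),
        Atom(2, "CN", "C", 1, "TGT", cn_t),
        Atom(3, "CM", "C", 1, "TGT", cm_t),
    ])
    probe = Structure(atoms=[
        Atom(1, "O", "O", 1, "PRB", o),
        Atom(2, "CN", "C", 1, "PRB", cn),
        Atom(3, "CM", "C", 1, "PRB", cm),
    ])
    transform, rmsd = superpose(probe, targets, [(1, 1), (2, 2), (3, 3)])
    if rmsd > 1e-6:
        raise ConstructionError(f"canonical placement is inconsistent (rmsd {rmsd:.2e})")
    return transform


def make_reference_complex(site: Structure | None = None,
                           theta: float = reference_data.THETA_REFERENCE) -> Structure:
    """The reference complex: toluene para-hydroxylation arenium docked at
    the canonical geometry.  Its Cn is tagged C4_REF."""
    site = site if site is not None else make_toy_site()
    inter = next(i for i in enumerate_intermediates(toluene()) if i.cn_position == 4)
    structure = build_geometry(inter)
    fe2 = site.tagged("FE2").coords
    fe1 = site.tagged("FE1").coords
    poised = site.tagged("O_TRANSFER").coords
    transform = canonical_placement_transform(structure, fe2, fe1, poised, theta)
    placed = structure.transformed(transform)
    pose = assemble_pose(site, placed)
    ref = pose.structure
    ref.tags["C4_REF"] = ref.tags["C_N"]
    ref.metadata = {"generator": "make_reference_complex", "theta": theta,
                    "site_seed": site.metadata.get("seed")}
    return ref


def _intermediate_indices(structure: Structure) -> np.ndarray:
    return np.array([i for i, a in enumerate(structure.atoms) if a.residue_id == 999])


def make_pose_with_geometry(reference: Structure, d_target: float,
                            dtheta_target: float,
                            ff: ForceFieldParams | None = None) -> DockingPose:
    """Construct a pose whose geometric parameters against `reference` are
    exactly (d_target, dtheta_target).

    The docked intermediate is rotated about the O-Cn axis by dtheta (the
    torsion Fe2-O-Cn-Cm changes by exactly the rotation angle, Cn fixed) and
    then translated by d_target within the plane containing the O-Cn axis
    and Fe2 (which leaves the torsion unchanged), away from Fe2.
    """
    if not (np.isfinite(d_target) and np.isfinite(dtheta_target)) or d_target < 0:
        raise ConstructionError("d_target must be finite and >= 0")
    reference.require_tags(["FE2", "O_TRANSFER", "C_N", "C_M", "C4_REF"])
    work = reference.copy()
    idx = _intermediate_indices(work)
    if len(idx) == 0:
        raise ConstructionError("reference carries no docked intermediate (residue 999)")
    coords = work.coords
    fe2 = work.tagged("FE2").coords.copy()
    o = work.tagged("O_TRANSFER").coords.copy()
    cn = work.tagged("C_N").coords.copy()
    cm = work.tagged("C_M").coords.copy()

    axis = cn - o
    axis /= np.linalg.norm(axis)
    theta0 = torsion(fe2, o, cn, cm)

    def rotated(sign: float) -> np.ndarray:
        rot = Rotation.from_rotvec(math.radians(sign * dtheta_target) * axis).as_matrix()
        out = coords.copy()
        out[idx] = (out[idx] - o) @ rot.T + o
        return out

    new = rotated(1.0)

    def measure(c):
        w = work.copy()
        w.coords = c
        return torsion(w.tagged("FE2").coords, w.tagged("O_TRANSFER").coords,
                       w.tagged("C_N").coords, w.tagged("C_M").coords)

    from .structio import wrap_angle
    if abs(wrap_angle(measure(new) - theta0 - dtheta_target)) > 1e-6:
        new = rotated(-1.0)
    if abs(wrap_angle(measure(new) - theta0 - dtheta_target)) > 1e-6:
        raise ConstructionError("could not realize requested delta-theta")

    # translation direction: perpendicular to the O-Cn axis, in the plane
    # containing the axis and Fe2, pointing away from Fe2
    w_fe = (fe2 - o) - np.dot(fe2 - o, axis) * axis
    u = -w_fe / np.linalg.norm(w_fe)
    new[idx] = new[idx] + d_target * u
    work.coords = new

    pose = DockingPose(structure=work,
                       intermediate_serials=frozenset(work.atoms[i].serial for i in idx))
    set_pose_energy(pose, ff or ForceFieldParams())
    return pose


# ---------------------------------------------------------------------------
# DPPH trace simulation
# ---------------------------------------------------------------------------

def simulate_dpph(spec: TraceSpec | None = None) -> tuple[list[KineticTrace], dict]:
    """Simulate stoichiometric DPPH consumption for each dose.

    Kinetic model (generator truth, not a mechanistic claim): irreversible
    second-order consumption d[D]/dt = -k [D][A], d[A]/dt = -(k/sigma)[D][A]
    with stoichiometric factor sigma, integrated by fixed-step RK4 (0.1 min);
    absorbance = eps*l*[D] plus Gaussian noise.  The analytic endpoint
    %red = 100*min(1, sigma*r) is recorded as truth for every dose.
    """
    spec = spec or TraceSpec()
    rng = np.random.default_rng(spec.seed)
    dt = 0.1
    n_steps = int(round(spec.duration / dt))
    sample_every = max(1, int(round(spec.sampling_interval / dt)))
    traces = []
    truth_endpoints = {}
    for rep, ratio in enumerate(spec.doses):
        d = spec.dpph_initial
        a = ratio * spec.dpph_initial
        k, sigma = spec.rate_constant, spec.stoichiometric_factor
        times = [0.0]
        dpph = [d]

        def deriv(dd, aa):
            rate = k * dd * aa
            return -rate, -rate / sigma

        for step in range(1, n_steps + 1):
            k1d, k1a = deriv(d, a)
            k2d, k2a = deriv(d + 0.5 * dt * k1d, a + 0.5 * dt * k1a)
            k3d, k3a = deriv(d + 0.5 * dt * k2d, a + 0.5 * dt * k2a)
            k4d, k4a = deriv(d + dt * k3d, a + dt * k3a)
            d = max(0.0, d + dt / 6.0 * (k1d + 2 * k2d + 2 * k3d + k4d))
            a = max(0.0, a + dt / 6.0 * (k1a + 2 * k2a + 2 * k3a + k4a))
            if step % sample_every == 0:
                times.append(step * dt)
                dpph.append(d)
        absorb = np.array(dpph) / 1000.0 * EXTINCTION_515
        a0 = absorb[0]
        if spec.noise_sd > 0:
            absorb = absorb + rng.normal(0.0, spec.noise_sd * a0, absorb.shape)
        absorb = np.clip(absorb, 0.0, None)
        absorb[0] = a0     # t=0 read before any reaction/noise
        traces.append(KineticTrace(times=np.array(times), absorbance_515=absorb,
                                   antioxidant_ratio=ratio,
                                   dpph_initial=spec.dpph_initial,
                                   replicate_id=rep))
        truth_endpoints[ratio] = 100.0 * min(1.0, spec.stoichiometric_factor * ratio)
    truth = {"spec": asdict(spec), "seed": spec.seed,
             "endpoint_percent_reduced": truth_endpoints,
             "ec50_true": 0.5 / spec.stoichiometric_factor}
    return traces, truth


# ---------------------------------------------------------------------------
# Bioconversion time-course simulation
# ---------------------------------------------------------------------------

def simulate_timecourse(rates: dict[str, float], linear_until: float = 120.0,
                        substrate_uM: float = reference_data.SUBSTRATE_UM,
                        noise_sd: float = 0.0, seed: int = 0,
                        duration: float = 240.0, interval: float = 10.0,
                        tau: float = 5.0) -> TimeCourse:
    """Linear product accumulation up to `linear_until`, then an exponential
    approach to plateau with time constant `tau` (continuous first
    derivative).  Gaussian noise is proportional to the signal (sd =
    noise_sd * concentration).  Noiseless output is mass-balanced:
    substrate + sum(products) = substrate_uM exactly.
    """
    if any(r < 0 for r in rates.values()):
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 0.5 * interval, interval)
    concentrations = {}
    total = np.zeros_like(times)
    for product, rate in rates.items():
        c = np.where(times <= linear_until,
                     rate * times,
                     rate * (linear_until + tau * (1.0 - np.exp(-(times - linear_until) / tau))))
        total = total + c
        if noise_sd > 0:
            c = np.clip(c + rng.normal(0.0, 1.0, c.shape) * noise_sd * c, 0.0, None)
        concentrations[product] = c
    if np.max(total) > substrate_uM:
        raise ValueError("rates exhaust the substrate within the simulated window")
    substrate = substrate_uM - total     # noiseless mass balance
    return TimeCourse(times=times, concentrations=concentrations,
                      substrate_initial=substrate_uM, substrate=substrate)


# ---------------------------------------------------------------------------
# Deterministic CSV writers (byte-identical across reruns)
# ---------------------------------------------------------------------------

def write_traces_csv(traces: list[KineticTrace], path, header_meta: dict | None = None) -> None:
    lines = []
    if header_meta:
        for k in sorted(header_meta):
            lines.append(f"# {k}={header_meta[k]}")
    lines.append("time_min,abs515,ratio,replicate")
    for tr in traces:
        for t, a in zip(tr.times, tr.absorbance_515):
            lines.append(f"{t:.4f},{a:.6f},{tr.antioxidant_ratio:.6g},{tr.replicate_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_timecourse_csv(tc: TimeCourse, path, header_meta: dict | None = None) -> None:
    lines = []
    if header_meta:
        for k in sorted(header_meta):
            lines.append(f"# {k}={header_meta[k]}")
    lines.append("time_min,product,conc_uM")
    for product in sorted(tc.concentrations):
        for t, c in zip(tc.times, tc.concentrations[product]):
            lines.append(f"{t:.4f},{product},{c:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
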