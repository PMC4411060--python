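"""Geometric regioselectivity scoring and catalytic-productivity classification.

The predictive core: a docked arenium pose is compared against the reference
complex (wild-type enzyme + toluene para-hydroxylation arenium) through two
geometric parameters measured after superposing the pose's site frame onto
the reference frame:

  d(Cn-C4)   distance (A) between the pose's oxygen-accepting carbon Cn and
             the C4 carbon of the reference intermediate;
  delta_theta  deviation (deg) of the torsion theta = Fe2-O-Cn-Cm from the
             reference torsion (103.6 deg), wrapped to (-180, 180].

Small d and small |delta_theta| mean the intermediate sits like the optimal
substrate and predict efficient turnover.  The non-covalent binding energy
(ncBE) is reported alongside but deliberately never used for classification:
tightly bound but misoriented intermediates are not hydroxylated.

Classification is three-way: ``efficient`` (both parameters in range),
``poor`` (well placed but misrotated -- slow turnover), ``inactive``
(displaced).  Default thresholds: d <= 0.30 A separates placed from
displaced (with d <= 0.20 A additionally flagging high-turnover geometry),
delta_theta in [-10, +5] deg.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import reference_data
from .arenium import BondGeometry, SubstrateSpec, build_geometry, enumerate_intermediates
from .dock import DockingPose, ForceFieldParams, MobileSet, energy, mc_search
from .errors import TagError
from .structio import Structure, superpose, torsion, wrap_angle

LABELS = ("efficient", "poor", "inactive")


@dataclass
class Thresholds:
    d_efficient: float = 0.20    # A; below this the geometry predicts high kcat
    d_max: float = 0.30          # A; beyond this the intermediate is displaced
    dtheta_lo: float = -10.0     # deg
    dtheta_hi: float = 5.0       # deg
    theta_ref: float = reference_data.THETA_REFERENCE

    def __post_init__(self) -> None:
        if not (0 < self.d_efficient <= self.d_max):
            raise ValueError("need 0 < d_efficient <= d_max")
        if self.dtheta_lo >= self.dtheta_hi:
            raise ValueError("need dtheta_lo < dtheta_hi")


@dataclass
class GeoScore:
    d_cn_c4: float
    theta: float
    delta_theta: float
    ncbe: Optional[float] = None
    label: Optional[str] = None

    @property
    def high_kcat(self) -> bool:
        """Geometry in the high-turnover region (needs thresholds' defaults)."""
        return self.label == "efficient" and self.d_cn_c4 <= Thresholds().d_efficient


def frame_selection(pose: Structure, reference: Structure) -> list[tuple[int, int]]:
    """Default superposition pairs: FE1/FE2 plus pocket alpha-carbons matched
    by (residue_id, name).  The transferred oxygen is excluded: it moves with
    the docked intermediate and would bias the frame."""
    pairs = []
    for role in ("FE1", "FE2"):
        pairs.append((pose.tags[role], reference.tags[role]))
    ref_ca = {(a.residue_id, a.name): a.serial for a in reference.atoms if a.name == "CA"}
    for a in pose.atoms:
        if a.name == "CA" and (a.residue_id, a.name) in ref_ca:
            pairs.append((a.serial, ref_ca[(a.residue_id, a.name)]))
    if len(pairs) < 3:
        # sparse toy sites without backbone: fall back to every shared site atom
        moving = {pose.tags.get(r) for r in ("O_TRANSFER", "C_N", "C_M")}
        ref_all = {(a.residue_id, a.name): a.serial for a in reference.atoms
                   if a.residue_id != 999}
        for a in pose.atoms:
            if a.serial in moving or a.residue_id == 999:
                continue
            key = (a.residue_id, a.name)
            if key in ref_all:
                pair = (a.serial, ref_all[key])
                if pair not in pairs:
                    pairs.append(pair)
    return pairs


def geometric_parameters(pose: DockingPose, reference: Structure,
                         thresholds: Thresholds | None = None,
                         selection: Sequence[tuple[int, int]] | None = None) -> GeoScore:
    """Compute (d_cn_c4, theta, delta_theta) for a docked pose.

    The pose's site frame is superposed onto the reference frame before the
    Cn-C4 distance is measured; the torsion is frame-invariant.
    """
    thresholds = thresholds or Thresholds()
    ps = pose.structure
    ps.require_tags(["FE2", "O_TRANSFER", "C_N", "C_M"])
    reference.require_tags(["C4_REF", "FE2"])
    if selection is None:
        selection = frame_selection(ps, reference)
    transform, _rmsd = superpose(ps, reference, selection)

    cn = transform.apply(ps.tagged("C_N").coords)
    c4 = reference.tagged("C4_REF").coords
    d = float(np.linalg.norm(cn - c4))
    theta = torsion(ps.tagged("FE2").coords, ps.tagged("O_TRANSFER").coords,
                    ps.tagged("C_N").coords, ps.tagged("C_M").coords)
    dtheta = wrap_angle(theta - thresholds.theta_ref)
    return GeoScore(d_cn_c4=d, theta=theta, delta_theta=dtheta)


def ncbe(pose: DockingPose, ff: ForceFieldParams) -> float:
    """Non-covalent binding energy: LJ + Coulomb over intermediate-protein
    pairs only -- no constraint term, no intra-protein terms."""
    terms = energy(pose, ff, mobile=None, constraints=())
    return terms["lj"] + terms["coulomb"]


def classify(geo: GeoScore, thresholds: Thresholds | None = None) -> str:
    """Deterministic, total three-way label from (d_cn_c4, delta_theta)."""
    t = thresholds or Thresholds()
    if not (np.isfinite(geo.d_cn_c4) and np.isfinite(geo.delta_theta)):
        raise ValueError("geometric parameters must be finite")
    if geo.d_cn_c4 > t.d_max:
        return "inactive"
    if t.dtheta_lo <= geo.delta_theta <= t.dtheta_hi:
        return "efficient"
    return "poor"


def score_pose(pose: DockingPose, reference: Structure, ff: ForceFieldParams,
               thresholds: Thresholds | None = None) -> GeoScore:
    geo = geometric_parameters(pose, reference, thresholds)
    geo.ncbe = ncbe(pose, ff)
    geo.label = classify(geo, thresholds)
    return geo


# ---------------------------------------------------------------------------
# Whole-substrate product prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictConfig:
    n_trials: int = 12
    seed: int = 0
    ff: ForceFieldParams | None = None
    thresholds: Thresholds | None = None
    mobile: MobileSet | None = None
    bond_geometry: BondGeometry | None = None
    fixture: Optional[pd.DataFrame] = None   # printed-parameter mode; bypasses docking
    complex_name: str = "wt"


def load_fixture(path) -> pd.DataFrame:
    """Read a fixture CSV with columns complex,intermediate,d_cn_c4,delta_theta,ncbe."""
    df = pd.read_csv(Path(path), comment="#")
    required = {"complex", "intermediate", "d_cn_c4", "delta_theta"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixture CSV missing column(s): {sorted(missing)}")
    if "ncbe" not in df.columns:
        df["ncbe"] = np.nan
    return df


def predict_products(spec: SubstrateSpec, site: Structure | None,
                     reference: Structure | None,
                     config: PredictConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline (enumerate -> build -> dock -> score -> classify)
    for every intermediate of a substrate, or classify printed geometric
    parameters when `config.fixture` is given.

    Returns (score table, prediction).  The prediction maps ``products`` to
    the phenols from efficient intermediates and ``slow_products`` to those
    from poor ones; seeds are recorded in the table.
    """
    config = config or PredictConfig()
    thresholds = config.thresholds or Thresholds()
    ff = config.ff or ForceFieldParams()
    intermediates = enumerate_intermediates(spec)
    rows = []
    for k, inter in enumerate(intermediates):
        if config.fixture is not None:
            match = config.fixture[(config.fixture["intermediate"] == inter.id) &
                                   (config.fixture["complex"] == config.complex_name)]
            if match.empty:
                continue
            row = match.iloc[0]
            geo = GeoScore(d_cn_c4=float(row["d_cn_c4"]),
                           theta=wrap_angle(thresholds.theta_ref + float(row["delta_theta"])),
                           delta_theta=float(row["delta_theta"]),
                           ncbe=None if pd.isna(row["ncbe"]) else float(row["ncbe"]))
            seed = None
        else:
            if site is None or reference is None:
                raise ValueError("site and reference are required outside fixture mode")
            build_geometry(inter, config.bond_geometry)
            seed = config.seed + k
            mobile = config.mobile or MobileSet(intermediate_rigid_body=True)
            poses = mc_search(site, inter.structure, mobile, ff,
                              n_trials=config.n_trials, seed=seed)
            geo = geometric_parameters(poses[0], reference, thresholds)
            geo.ncbe = ncbe(poses[0], ff)
        geo.label = classify(geo, thresholds)
        rows.append({"intermediate": inter.id, "cn_position": inter.cn_position,
                     "d_cn_c4": geo.d_cn_c4, "delta_theta": geo.delta_theta,
                     "ncbe": geo.ncbe, "label": geo.label,
                     "product": inter.product_name, "seed": seed})
    table = pd.DataFrame(rows, columns=["intermediate", "cn_position", "d_cn_c4",
                                        "delta_theta", "ncbe", "label", "product", "seed"])
    prediction = {
        "substrate": spec.name,
        "complex": config.complex_name,
        "products": sorted(table.loc[table["label"] == "efficient", "product"]),
        "slow_products": sorted(table.loc[table["label"] == "poor", "product"]),
    }
    return table, prediction
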