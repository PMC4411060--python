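# Methods

## The problem

Toluene *o*-xylene monooxygenase (ToMO) is a bacterial multicomponent
monooxygenase whose hydroxylase carries a carboxylate-bridged diiron active
site. It hydroxylates a wide range of monocyclic aromatics, and its
regioselectivity — which ring position receives the hydroxyl — can be
predicted geometrically: the cationic **arenium intermediate** of each
candidate hydroxylation route is docked into an active-site model and
compared with the reference complex of the optimal substrate (toluene,
*para* attack). Two parameters describe the comparison:

- **d(Cn–C4)** — the distance (Å) between the pose's oxygen-accepting
  carbon Cn and the C4 carbon of the reference intermediate, measured after
  superposing the pose's site frame onto the reference frame;
- **Δθ** — the deviation (degrees) of the torsion θ = Fe2–O–Cn–Cm from the
  reference value θ_ref = 103.6°, wrapped to (−180°, 180°]. Cm is the ring
  carbon adjacent to Cn on the side nearer the substituent.

Routes with small d and small |Δθ| sit in the pocket like the optimal
substrate and are turned over efficiently. The non-covalent binding energy
(ncBE) is computed and reported but never used for classification: tightly
bound, misoriented intermediates are not hydroxylated.

Downstream, the package quantifies the antioxidant potential of the
resulting phenols via the DPPH assay (%DPPHred, EC50, TEC50, AE) and the
bioconversion kinetics (formation rates, molar yields, product
distributions).

## Classification thresholds

Literature values for high-turnover complexes are d below about 0.2 Å and
Δθ in [−10°, +5°]. The observed product spectrum additionally requires a
boundary between *slow* and *dead* routes: phenylethanol meta/para
complexes at d = 0.23–0.30 Å with large Δθ are converted slowly, while all
complexes of experimentally unproductive routes have d ≥ 0.42 Å. The
default classifier therefore uses three classes:

| label | condition |
|---|---|
| efficient | d ≤ d_max = 0.30 Å and Δθ ∈ [−10°, +5°] |
| poor | d ≤ 0.30 Å, Δθ outside the window |
| inactive | d > 0.30 Å |

with d ≤ d_efficient = 0.20 Å additionally flagging the high-kcat region.
d_max = 0.30 Å is an interpolation: it separates the published populations
(productive routes ≤ 0.30, unproductive ≥ 0.42) but the literature states
only the "about 0.2 Å" bound. All thresholds are configurable
(`regioselect.Thresholds`).

## Frame superposition

The superposition selection is {FE1, FE2} plus all pocket α-carbons matched
by (residue id, atom name); on sparse toy sites without backbone it falls
back to every shared site atom. The transferred oxygen is deliberately
excluded from the frame: it belongs to the docked intermediate and would
bias the frame toward the pose being scored. The fit is a Kabsch
least-squares superposition restricted to proper rotations (no reflection),
via `scipy.spatial.transform.Rotation.align_vectors`.

A geometric fact worth recording: rotating a pose about the **Fe2–O axis**
leaves θ unchanged (both Fe2 and O lie on the axis) and only displaces Cn,
while rotating about the **O–Cn axis** changes θ by exactly the rotation
angle and leaves Cn fixed. The fixture generator
`synthgen.make_pose_with_geometry` exploits this: it rotates the docked
intermediate about O–Cn by Δθ, then translates it by d within the plane
containing the O–Cn axis and Fe2 (which preserves θ), making the
construction exact rather than fitted.

## Docking stand-in

The original docking used a proprietary Monte Carlo minimization package
whose force field and parameters are not recoverable, and the study's
complexes are not deposited; published geometric parameters and ncBE values
are therefore fixture inputs, never recompute targets. The package ships a
transparent stand-in:

- **Force field** — pairwise-additive 6-12 Lennard-Jones with
  Lorentz–Berthelot combining plus Coulomb with a distance-dependent
  dielectric ε(r) = ε₀·r (ε₀ = 1), hard cutoff 10 Å. Pairs counted:
  intermediate–protein and mobile–fixed. Iron centres are fixed point
  charges with configurable LJ parameters; no ligand-field term.
- **Constraints** — harmonic; the transferred oxygen is tied to the Fe2
  coordination distance (1.9 Å, default k = 50 kcal mol⁻¹ Å⁻²).
- **Minimization** — gradient-free descent: random rigid-body perturbations
  of each mobile block (the intermediate; optionally whole mobile residues),
  accepted only if the energy drops, with step sizes shrinking on rejection;
  convergence when the energy improvement over a 60-proposal window falls
  below tolerance. The returned energy never exceeds the input energy.
- **Search** — perturb → minimize cycles with Metropolis acceptance between
  cycles (kT start 0.596 kcal/mol ≈ 300 K, geometric cooling ×0.95) from a
  single seeded generator; every pose records its seed and the trajectory is
  bit-reproducible.

## Arenium builder

Substrates are described topologically (ring positions 1–6, substituent
labels with steric radii, optional fused-ring bridge at two adjacent
positions); full chemical perception is unnecessary for the handful of
monocyclic substrates in scope. Enumeration produces one intermediate per
symmetry-unique unsubstituted ring carbon, using the full automorphism
subgroup of the labelled hexagon (rotations and mirrors preserving the
substitution pattern; a non-palindromic bridge suppresses the mirror).
Mirror planes alone would be insufficient — unsubstituted benzene must give
a single intermediate, which requires the rotational symmetries.

Geometry: the five sp² ring carbons stay on a regular 1.40 Å hexagon; Cn is
lifted out of plane so both Cn–neighbour bonds reach the sp³ length that
makes the neighbour–Cn–neighbour angle tetrahedral, and the transferred
oxygen (C–O 1.43 Å) and hydrogen occupy the two remaining tetrahedral
directions, oxygen on the lifted side. One canonical pyramidalization only;
stereochemistry beyond that is out of scope. Substituents are single
pseudo-atoms whose LJ diameter is the supplied bulk radius; fused-ring
bridges are placed by a planar polygon walk.

## Assay mathematics

- **%DPPHred** = [1 − [DPPH]ₜ/[DPPH]₀] × 100 at t = 30 min, with [DPPH]
  from A₅₁₅/(ε·l), ε₅₁₅ = 12 mM⁻¹ cm⁻¹; linear interpolation between
  samples.
- **EC50** — non-linear least squares on the dose–response curve. Two
  saturating models are fitted and the smaller-SSE one reported: the Hill
  form 100·rⁿ/(EC50ⁿ + rⁿ) with n free in [0.5, 6], and the clipped-linear
  stoichiometric form min(100, 50·r/EC50) produced by fast complete radical
  consumption. The second model matters: a stoichiometric titration's true
  dose–response is piecewise linear, and forcing a Hill curve through it
  biases EC50 low by ~10%. On genuinely Hill-shaped data the Hill branch
  wins and is recovered exactly. In both models the reported EC50 is where
  the fitted curve equals 50%. Responses that never cross 50% yield a
  flagged, warned extrapolation — never a silent number.
- **TEC50** — an exponential-to-plateau fit A(t) = A_f + (A₀−A_f)e^(−t/τ)
  at the EC50 ratio; the reported time is the first sampled point at which
  the fitted curve is within 1% (configurable) of its asymptote, i.e.
  τ·ln(100) snapped to the sampling grid. Traces that rise, or that the
  exponential fits no better than a straight line, raise a plateau error.
- **AE** = 1/(EC50 × TEC50). Replicates are aggregated under both
  conventions — mean of per-replicate AE and AE of mean inputs — because
  the published table is consistent only with per-replicate averaging
  (Jensen's inequality makes that mean larger; the published 4HEP AE of
  0.140 exceeds 1/(0.40 × 19.0) = 0.1316 by more than its SD).
- **Formation rates** — OLS slope over the initial linear window; the
  automatic window is the longest initial prefix with linear R² ≥ 0.999.
  The strict threshold is deliberate: at 0.98 the prefix rule admits two to
  three early-plateau samples and biases slopes ~10% low, while 0.999
  truncates at the linear boundary for noiseless and 0.5%-noise data.
- **Yield and distribution** — yield(t) = 100·Σ products(t)/substrate₀;
  distribution from per-timepoint concentrations (sums to 100 exactly);
  the rate-ratio estimator is reported alongside in the analysis drivers.

## Synthetic-data generators

The study's raw inputs (hydroxylase structure, docked complexes,
spectrophotometer traces, HPLC tables) are not available; generators with
known ground truth stand in:

- **Toy site** — diiron pair (Fe–Fe 3.3 Å), poised oxygen 1.9 Å from Fe2,
  pocket pseudo-residues (CA+CB) on a golden-spiral sphere (default 8
  residues, radius 6.5 Å) with seeded jitter; optional bulky blockers at
  the canonical ring slots (ortho/meta/para relative to Cn). The toy site
  is isotropic — it does not encode the orientation preference of the real
  pocket, so docking into it demonstrates the machinery rather than
  reproducing the published geometric parameters.
- **DPPH traces** — irreversible second-order consumption d[D]/dt =
  −k[D][A], d[A]/dt = −(k/σ)[D][A] with stoichiometric factor σ, integrated
  by fixed-step RK4 (0.1 min); absorbance ε·l·[D] plus Gaussian noise
  (fraction of A₀). Analytic truth: endpoint %red = 100·min(1, σ·r), EC50 =
  0.5/σ. Default k = 0.02 μM⁻¹ min⁻¹ brings the reaction near completion at
  the 30-min read for doses away from equivalence, matching the published
  protocol in which 30 min sufficed; defaults σ = 2, six doses 0.05–0.8
  spanning the 50% crossing, 1% noise, 0.1 mM DPPH. This is generator
  truth, not a mechanistic claim about real scavengers.
- **Time courses** — linear accumulation at the configured rates to
  `linear_until` (default 120 min), then exponential saturation (τ = 5 min,
  sharp enough that the linear boundary is identifiable to within one
  10-min sample); mass balance exact in the noiseless case; noise
  proportional to signal (default for recovery experiments 0.5%).

Every generator embeds its spec and seed in the output metadata, and all
outputs (PDB + YAML sidecar, CSV) are byte-identical across reruns with the
same seed.

What passing tests on these generators show — and what they do not: they
validate the estimation chain (formula correctness, fitting, window
selection, classification) under known truth. They do not show that the toy
force field reproduces the original docking energetics, that real DPPH
kinetics are second-order stoichiometric, or that real HPLC time courses
are linear-then-exponential. The published geometric parameters enter as
fixtures for exactly this reason.

## Numerical choices and degenerate inputs

- Angles in degrees at API boundaries, radians internally; torsions wrapped
  to (−180°, 180°] with the IUPAC sign convention (cross-checked against
  MDAnalysis). Collinear torsion triples raise a geometry error.
- Superposition needs ≥ 3 non-collinear pairs; mirror-image selections fit
  with positive RMSD because reflections are excluded.
- The PDB reader is a strict fixed-column parser (3-decimal coordinates,
  duplicate serials rejected with the line number, altloc/insertion codes
  rejected); role tags and non-bonded parameters travel in a YAML sidecar
  because the PDB format has no slot for them. Files written here are
  parseable by Biopython (tested).
- Classification is total and deterministic; ties at the thresholds go to
  the better class (≤ comparisons).
- Two-point rate fits are returned with a degrees-of-freedom flag; negative
  fitted rates beyond 2 standard errors warn.

## Known limitations

- The toy active-site model is isotropic and cannot reproduce the published
  (d, Δθ) table from docking alone; whole-substrate prediction against real
  structures requires a real site model and a parameterized force field.
- Side-chain flexibility is rigid-block jumps only; no rotamer library.
- The second hydroxylation (catechol formation, e.g. THI from DHI) is out
  of scope; the sigmoidal THI dose–response is noted but not modelled.
- EC50 model selection covers two saturating families; cooperative
  mechanisms outside both will fit whichever is closer.
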