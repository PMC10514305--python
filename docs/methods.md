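# Methods

`porewatch` analyses how small molecules and monatomic ions pass through a
cylindrical pore in a slab-like protein assembly — the geometry of a
bacterial-microcompartment (BMC) shell hexamer such as PduA, whose central
pore is the main route for substrates like 1,2-propanediol and for ions.
The package implements the trajectory-side analyses (alignment, occupancy,
permeation counting, spatial densities), the wet-lab-side kinetics analysis
(initial velocities and slope comparisons), and a Brownian-dynamics (BD)
generator that produces trajectories with known ground truth for testing
both.  Internal units are nm, ns, and mM throughout; energies in the
generator are in units of kT.

## Pore frame and alignment

Every trajectory frame is superposed onto a reference structure by
least-squares rigid-body fitting (Kabsch, SVD with determinant correction so
no reflection is ever returned) over all hexamer Cα atoms.  The pore normal
then lies along Cartesian z.  The origin is the *reference-frame* centroid
of the six pore-residue Cα atoms (residue 40 by default, one per protomer),
which defines the signed axial coordinate `d_pore` (= z) and the radial
distance `r = sqrt(x² + y²)`.  By convention `d_pore > 0` is the concave
face of the hexamer — the outside of an assembled shell; an orientation
sign of −1 flips the convention via a proper 180° rotation about x.
Degenerate (collinear/coincident) point sets raise a geometry error; ties
in the SVD are resolved by the determinant sign correction on the smallest
singular vector.  Using the reference rather than the instantaneous pore
centroid makes `d_pore = 0` a fixed laboratory plane; a per-frame-centroid
variant can be obtained by passing the aligned frame's own Cα positions as
the reference.

## Occupancy profiles

`N_mol(d_pore)` is the time-averaged number of molecules of a species whose
centre of geometry (unweighted mean over member atoms; molecules split
across periodic boundaries are made whole by a minimum-image chain from
their first atom) lies inside an analysis cylinder of radius 0.7 nm around
the pore axis, histogrammed in axial bins.  Cylinder boundaries are
inclusive (a measure-zero choice, stated for determinism); bins are
half-open `[lo, hi)` with the last bin closed.  The default bin width is
0.1 nm and the default axial range ±3 nm; neither affects per-bin values,
only resolution and plotted range.  Molecules are assigned to bins by their
centre position only.  Replicas are aggregated as the per-bin mean with
standard error = sample SD (n−1 denominator) / √n.  Enrichment divides
`N_mol` by the uniform-bulk expectation `ρ_bulk · π r² · Δz`, where
`ρ_bulk(c) = c · N_A · 10⁻²⁴` converts mM to nm⁻³ (150 mM → 0.09033 nm⁻³).

## Permeation events

A permeation event is a completed side-to-side traversal of a detection
cylinder of radius 2 nm spanning −0.6 ≤ d_pore ≤ 0.6 nm.  The radius is
deliberately much larger than the occupancy cylinder so a molecule cannot
exit and re-enter laterally near the axial centre and be double counted.
Detection is a per-molecule finite-state machine over the frame-wise
region sequence (below / inside / above / outside-lateral): arming on a
side→inside transition, firing on inside→opposite-side, disarming on
inside→same-side and (by default, configurable) on inside→lateral exits.
Molecules that start inside are unarmed until they first leave.  A direct
below↔above jump within one frame stride is counted only when the
straight-line path — minimum-imaged when box vectors are supplied, so
periodic wraps across the far z boundary are never mistaken for crossings —
stays inside the radius at both axial faces.  Rates are reported as
events/ns per replica with mean ± SE (sample SD/√n) across replicas, plus
the pooled rate (total events / total time).  Direction bookkeeping
(+z = toward the concave face) is retained even where only bidirectional
totals are reported.

### Stride artefacts

The BD generator logs ground-truth crossings from the un-strided dynamics
with the same geometric definition, so detector/stride artefacts are
measurable.  At stride 1 the detector reproduces the log exactly.  At
coarser strides, events are lost in ±z *pairs* whenever a molecule's dwell
on the far side between two completed crossings falls entirely between
saved frames: the detector never sees the far-side frame needed to fire
the first event and arm the second.  At stride 10 under the reference
conditions (D = 2 nm²/ns, dt = 10⁻³ ns) the measured deficit is 10–23%
across seeds; the documented tolerance is a detected/true rate ratio in
[0.75, 1.05].  The loss fraction grows with stride × diffusivity and is an
inherent property of frame-resolution counting, not of this detector.

## Spatial distribution functions

Number densities are accumulated on a cubic-voxel grid (default bin width
0.05 nm) in the aligned frame, averaged over frames, and pooled
frame-weighted across replicas.  By construction voxel density × voxel
volume sums to the time-averaged molecule count inside the grid (asserted
to 10⁻⁹ relative).  Enrichment regions are the voxel sets with density at
least 10× or 30× an analytic bulk density; regions for ascending factors
are nested by construction.  The 150 mM reference bulk is 0.09033 nm⁻³.
Grids export to OpenDX for molecular viewers.

## Brownian-dynamics generator

The generator emulates the statistical structure the analysis assumes: a
cubic periodic box (default edge 8–10 nm) containing a repulsive slab
(half-thickness 0.6 nm, matching the detection span) pierced by a
cylindrical channel (radius 0.7 nm, matching the occupancy cylinder), with
point particles of several species.  The potential is
`U(ρ, z) = a(z) · [U_well · c(ρ) + B · (1 − c(ρ))]` where `a` and `c` are
cosine-ramped envelopes (ramp width 0.3 nm) so forces are finite, `B` is
the slab barrier (default 20 kT; ∞ = hard wall via move rejection) and
`U_well` is the per-species channel well (negative = attractive).  Species
defaults are study-condition analogs: an anion analog attracted to the
channel, a cation analog excluded, and a neutral-to-mildly-attracted
tracer, at counts corresponding to ~150 mM (ions) and ~175 mM (tracer).

The proposal step is the Euler–Maruyama discretisation of overdamped
Langevin dynamics, `x ← x + D F dt + sqrt(2 D dt) ξ`, accepted with a
Metropolis–Hastings test (MALA).  The adjustment matters: the plain Euler
update showed an O(dt) stationary-density bias near the steep slab-wall
ramp large enough to shift channel/bulk ratios from the Boltzmann value
0.135 to ~0.09 at a +2 kT well.  With the Metropolis correction the
stationary distribution is exactly Boltzmann at any dt, which the
acceptance checks exploit (`ratio → exp(−U/kT)` for U ∈ {−2, 0, +2} kT).
The time step (default 5·10⁻⁴–10⁻³ ns) keeps the RMS step below half the
channel radius so the dynamics stay diffusive at the channel scale.

Single-file blocking is a deliberate caricature of competitive ion
occupancy, not a physical model: at most one blocking-species particle may
occupy the channel, and while it does, tracer moves into the channel are
rejected.  Titrating the blocker at 0/c/2c suppresses the tracer's
measured permeation rate monotonically — the desk-scale analog of salt
roughly halving substrate permeation through the pore.

Ground-truth crossings are logged every integration step (pre-stride) with
the same region semantics as the detector; frames are saved every `stride`
steps.  Identical parameters and seed give bit-identical output.

### Error estimation for equilibrium averages

Channel occupancy is a rare, serially correlated observable; with only
three replicas the between-replica SE is itself very noisy (χ² with 2
degrees of freedom — one observed 3-replica batch underestimated the true
seed-to-seed spread by a factor of ~5).  Equilibrium checks therefore use
the larger of the between-replica SE and the block-averaged within-replica
SE (20 blocks per replica, combined in quadrature across replicas), the
standard error-analysis practice for correlated MD time averages.

### What the generator does and does not emulate

It reproduces: diffusive motion with species-specific D, Boltzmann
equilibrium partitioning between channel and bulk, symmetric bidirectional
crossing statistics, competitive channel occupancy, and periodic-boundary
artefacts (wrapped molecules, split molecules).  It does not include
explicit solvent, electrostatics, protein flexibility, or realistic
residence kinetics, so passing tests demonstrate the *analysis pipeline's*
correctness on data with known truth — not that any particular biological
system behaves this way.

## Assay kinetics

The in vitro readout is absorbance at 280 nm versus time (30 s steps, 1 h)
for native (intact compartments) and broken (sonicated) samples across
0–500 mM NaCl, in quadruplicate.  The synthetic assay generator produces
`A(t) = V0 τ (1 − e^(−t/τ)) + baseline + ε` with V0 linear in salt per
state (broken faster and more salt-sensitive than native) and a shorter τ
for broken samples (emulating cofactor depletion at higher turnover);
ε is i.i.d. Gaussian.

Initial velocities support three estimators:

* **quadratic** (default): estimate the noise SD from second differences
  (`Var(Δ²y) = 6σ²`), grow the initial window while the quadratic fit's
  residual RMS stays within 1.2× the noise, and report the fitted
  derivative at the first time point.  Unbiased for saturating curves
  where any straight-line fit systematically underestimates V0.
* **linear**: the longest initial prefix whose line fit has R² ≥ 0.99
  (minimum 5 points), reporting the OLS slope.  Kept for comparison; under
  realistic noise an R² cutoff conflates noise with curvature (R² of a
  genuinely linear noisy window can sit below any fixed threshold), which
  is why it is not the default.
* **exponential**: a full progress-curve fit `c + V0 τ (1 − e^(−t/τ))`,
  the matched and lowest-variance estimator when the saturating form is
  known to hold, used by the reference study driver; exactly polynomial
  series short-circuit to the exact OLS answer, and failures fall back to
  the quadratic estimator.

A fixed index window can override any policy.  Quadruplicates are averaged
to one V0 ± SE (sample SD/√n) per condition and state before regression;
V0 stays in absorbance/s (no extinction coefficient is assumed).  V0 is
regressed on [NaCl] over the inclusive 100–500 mM range by unweighted OLS;
the two states' slopes are compared with
`t = (b_broken − b_native)/sqrt(SE_b² + SE_n²)`, df = n₁ + n₂ − 4
(equivalent to the interaction term of an ANCOVA with free intercepts;
exactly t-distributed under equal residual variances and shared design,
which the calibration check confirms at the 5% level).  The broken/native
ratio carries a first-order compounded SE,
`SE = ratio · sqrt(CV_b² + CV_n²)`, accurate to within 5% of Monte-Carlo
propagation for CVs up to 10%.  Identical noiseless fits give p = 1 by
convention (zero pooled SE is not evidence of a difference).

## Reference study conditions and problem sizes

The numbered drivers under `analysis/` and `scripts/acceptance.py` use an
8 nm box, dt = 10⁻³ ns and: 2·10⁵ steps × 3 replicas × 200 particles for
Boltzmann enrichment; 1–1.5·10⁵ steps × 3 seeds × 3 blocker levels for
the suppression curve; 3·10⁴ steps for stride-recovery; 50–100
random-walk trajectories (600–1000 frames × 30–50 molecules) for the
detector/oracle comparison; and 1000 null replicates for the slope-test
calibration.
These sizes give a few hundred permeation events per condition and SEs of
a few percent on enrichment ratios.

## Known limitations

* Molecule reassembly assumes compact molecules (a few bonds across) and
  orthorhombic boxes; triclinic boxes are treated by their diagonal.
* The jump interpolation is linear; a molecule that genuinely diffuses
  around the detection cylinder's rim within one frame stride would be
  miscounted (negligible at sane output strides).
* The blocking rule is a hard single-occupancy constraint with no
  energetic coupling; it is meant to produce competitive suppression, not
  to model ion–substrate interactions.
* The exponential V0 estimator assumes the single-exponential saturating
  form; on real curves with other curvature sources the quadratic
  estimator is the safer default.
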