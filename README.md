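# porewatch

Analysis pipeline for molecular permeation through shell-protein pores,
with a synthetic-trajectory generator for validation.

Bacterial microcompartments (BMCs) are protein organelles whose enzymatic
core is enclosed by a selectively permeable shell; the central pore of the
hexameric shell tile (PduA in the 1,2-propanediol-utilisation system) is
the main route for substrates and ions.  Whether — and how much — salt
modulates substrate passage through that pore is measurable from two
directions: molecular-dynamics trajectories of the hexamer in solution,
and enzyme assays comparing intact compartments (rate-limited by both
permeation and turnover) with sonication-broken ones (turnover only).
`porewatch` implements both analysis arms as a reusable, tested library:

* **trajectory side** — frame-wise Kabsch superposition onto a reference
  so the pore normal is z and the pore-residue Cα centroid defines
  `d_pore = 0`; per-species axial occupancy `N_mol(d_pore)` in a
  0.7 nm-radius cylinder with cross-replica standard errors; bidirectional
  permeation-event counting in a 2 nm-radius, ±0.6 nm detection cylinder
  (events/ns ± SE); 3-D spatial distribution functions on a 0.05 nm grid
  with 10×/30× bulk-enrichment regions (150 mM bulk = 0.09033 nm⁻³);
* **assay side** — initial velocities V0 from plate-reader A280 time
  courses, V0-vs-[NaCl] regression over 100–500 mM per sample state, a
  t test on the slope difference, and broken/native V0 ratios with
  compounded errors;
* **synthetic data** — a Brownian-dynamics generator (Metropolis-adjusted
  Langevin, exact Boltzmann equilibrium) of particles diffusing through a
  slab-embedded cylindrical channel with species-specific affinities and
  optional single-file blocking, logging ground-truth crossings from the
  un-strided dynamics; and a plate-reader assay simulator with known V0
  structure.

Structures and trajectories are read through MDAnalysis (PDB, GRO, XTC,
DCD, multi-frame XYZ); tracks export to HDF5/TSV and density grids to
OpenDX.

## Worked example

The assay analysis end to end on synthetic quadruplicate time courses
(native vs broken, 0–500 mM NaCl, 5% signal noise):

```sh
python analysis/05_assay_kinetics.py --seed 0
```

prints

```
V0 vs [NaCl] fits over 100-500 mM:
  native : slope 8.890e-08 ± 1.114e-08 AU/s/mM (truth 1.000e-07)
  broken : slope 4.273e-07 ± 1.967e-08 AU/s/mM (truth 4.000e-07)
slope difference (broken - native): 3.384e-07, t = 14.97, df = 6, P = 5.59e-06
broken/native V0 ratio by salt:
      0 mM: 1.39 ± 0.10
    100 mM: 1.62 ± 0.08
    ...
    500 mM: 2.43 ± 0.06
```

Both fitted slopes bracket the generating truth within ~1–1.4 SE; the
slope difference is highly significant; and the broken/native ratio rises
with salt — the signature of salt suppressing permeation through the
intact shell while enhancing turnover.  The trajectory-side drivers
(`analysis/01…04`) run the same narrative for the simulation arm:
generate BD systems, compute occupancy profiles and channel enrichment
(which recovers the Boltzmann factor `exp(−U/kT)` of each species' channel
well), measure permeation rates under blocker titration (monotone
suppression), and extract nested 10×/30× ion-enrichment regions confined
to the channel.  Tables land in `results/`.

## Library sketch

```python
from porewatch import occupancy, permeation, pore_frame, synthetic

frames, times, truth = synthetic.simulate_bd(synthetic.BDParams(seed=1))
events = permeation.detect_events(frames["tracer"], species="tracer",
                                  times=times, box=10.0)
rate = permeation.permeation_rate([events], [times[-1] - times[0]])
```

A thin CLI wraps the same functions: `porewatch tracks | occupancy |
permeation | sdf | kinetics | synth`.

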