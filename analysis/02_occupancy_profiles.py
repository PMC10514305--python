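#!/usr/bin/env python
"""Axial occupancy profiles N_mol(d_pore) with cross-replica errors.

Runs three replicas of a mixed-species system (attracted anion analog,
excluded cation analog, mildly attracted tracer), builds per-species axial
profiles inside the 0.7 nm analysis cylinder, aggregates replicas
(mean ± SE), and converts the channel-core occupancy to an enrichment
ratio over the species' own bulk density.  Finding: the anion analog is
enriched in the channel, the cation analog depleted, water-like tracers in
between — the occupancy ordering that underlies selective permeation.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from porewatch import occupancy as occ
from porewatch import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--steps", type=int, default=60_000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    species = [
        syn.SpeciesSpec("tracer", 120, diffusion=2.0, channel_U=-1.0),
        syn.SpeciesSpec("anion", 90, diffusion=2.0, channel_U=-3.0),
        syn.SpeciesSpec("cation", 90, diffusion=1.5, channel_U=+3.0),
    ]
    spec = occ.CylinderSpec(radius=0.7, z_lo=-3.0, z_hi=3.0)

    per_species: dict[str, list] = {s.name: [] for s in species}
    box = 8.0
    for rep in range(3):
        p = syn.BDParams(box_edge=box, dt=1e-3, n_steps=args.steps, stride=20,
                         seed=args.seed + rep, species=species)
        frames, _, _ = syn.simulate_bd(p)
        for sp, arr in frames.items():
            per_species[sp].append(occ.axial_profile(arr, sp, spec, bin_width=0.2))

    tables = []
    print("channel-core enrichment (|d_pore| <= 0.3 nm), ratio to own bulk:")
    for s in species:
        agg = occ.aggregate_replicas(per_species[s.name])
        t = occ.profile_table(agg)
        tables.append(t)
        # species' own bulk concentration from its count and the free volume
        rho_bulk = s.count / (box**3 - box**2 * 1.8 + np.pi * 0.49 * 1.8)
        conc_mM = rho_bulk / 6.02214076e-4
        ratio = occ.enrichment_profile(agg, conc_mM)
        core = np.abs(agg.bin_centers) <= 0.3
        print(f"  {s.name:7s} (U = {s.channel_U:+.0f} kT): "
              f"{ratio[core].mean():6.2f}  (Boltzmann exp(-U) = {np.exp(-s.channel_U):6.2f})")

    out = results / "occupancy_profiles.tsv"
    pd.concat(tables).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
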