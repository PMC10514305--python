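"""Desk-scale study presets tying the generator to the analysis pipeline.

These functions define the package's reference numerical experiments: each
one generates synthetic trajectories (or assay curves) under fixed study
conditions, runs the analysis modules on them, and returns the measured
quantities together with the generator's ground truth.  The analysis
drivers under ``analysis/`` and the acceptance script both call them.

Conditions (chosen once; see docs/methods.md): an 8 nm cubic periodic box,
slab half-thickness 0.6 nm, channel radius 0.7 nm — the geometry of the
pipeline's detection and occupancy cylinders — with MALA time step 1e-3 ns.
"""

from __future__ import annotations

import numpy as np

from . import kinetics as kin
from . import permeation as perm
from . import synthetic as syn

#: shared geometry for all presets
BOX_EDGE = 8.0
DT = 1e-3


def _block_ratio_se(
    ch_counts: np.ndarray, far_counts: np.ndarray, vol_ch: float, vol_far: float,
    n_blocks: int = 20,
) -> tuple[float, float]:
    """Channel/bulk density ratio with a block-averaged standard error."""
    F = len(ch_counts)
    L = F // n_blocks
    blocks = []
    for b in range(n_blocks):
        c = ch_counts[b * L : (b + 1) * L].mean() / vol_ch
        fa = far_counts[b * L : (b + 1) * L].mean() / vol_far
        blocks.append(c / fa)
    blocks = np.asarray(blocks)
    return float(blocks.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def boltzmann_enrichment(
    well_kT: float,
    seeds: tuple[int, ...] = (0, 1, 2),
    n_steps: int = 200_000,
    n_particles: int = 200,
) -> dict:
    """Channel/bulk density ratio for a single species with well depth U.

    At equilibrium the ratio must equal exp(−U/kT); each seed is one
    replica.  Returns mean, SE (max of between-replica and block-averaged
    within-replica SE) and the expected Boltzmann factor.
    """
    ratios, block_ses = [], []
    for seed in seeds:
        p = syn.BDParams(
            box_edge=BOX_EDGE, dt=DT, n_steps=n_steps, stride=50, seed=seed,
            species=[syn.SpeciesSpec("ion", n_particles, diffusion=2.0,
                                     channel_U=well_kT)],
        )
        frames, times, _ = syn.simulate_bd(p)
        pos = frames["ion"]
        d = pos[..., 2]
        r = np.hypot(pos[..., 0], pos[..., 1])
        ch_counts = ((r <= p.channel_radius) & (np.abs(d) <= p.slab_half)).sum(axis=1)
        zcut = p.slab_half + p.ramp_width + 0.2
        far_counts = (np.abs(d) > zcut).sum(axis=1)
        vol_ch = np.pi * p.channel_radius**2 * 2 * p.slab_half
        vol_far = p.box_edge**2 * (p.box_edge - 2 * zcut)
        m, s = _block_ratio_se(ch_counts, far_counts, vol_ch, vol_far)
        ratios.append(m)
        block_ses.append(s)
    ratios = np.asarray(ratios)
    n = len(seeds)
    se_between = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    se_within = float(np.sqrt(np.sum(np.square(block_ses))) / n)
    return {
        "well_kT": well_kT,
        "ratio": float(ratios.mean()),
        "se": max(se_between, se_within),
        "expected": float(np.exp(-well_kT)),
        "replicas": list(map(float, ratios)),
    }


def tracer_permeation_rate(
    n_blockers: int,
    seeds: tuple[int, ...] = (0, 1, 2),
    n_steps: int = 150_000,
) -> tuple[perm.PermeationRate, list[syn.GroundTruth]]:
    """Tracer permeation rate with a competing single-file blocking species.

    The blocker emulates channel-occupying ions: while one blocker occupies
    the channel, no tracer may enter.  With 0/c/2c blockers the tracer rate
    decreases monotonically — the desk-scale analog of added salt cutting
    the substrate's permeation rate.
    """
    events, durations = [], []
    truths = []
    for seed in seeds:
        species = [syn.SpeciesSpec("tracer", 120, diffusion=2.0, channel_U=-1.0)]
        if n_blockers:
            species.append(
                syn.SpeciesSpec("blocker", n_blockers, diffusion=2.0,
                                channel_U=-1.0, blocking=True)
            )
        p = syn.BDParams(
            box_edge=BOX_EDGE, dt=DT, n_steps=n_steps, stride=10, seed=seed,
            species=species, blocking=True,
        )
        frames, times, truth = syn.simulate_bd(p)
        ev = perm.detect_events(
            frames["tracer"], species="tracer", times=times, box=p.box_edge
        )
        events.append(ev)
        durations.append(float(times[-1] - times[0]))
        truths.append(truth)
    rate = perm.permeation_rate(events, durations, species="tracer")
    return rate, truths


def ground_truth_recovery(seed: int = 77, n_steps: int = 30_000) -> dict:
    """Detector rate vs generator crossing log at stride 1 and stride 10.

    At stride 1 the detector must reproduce the crossing log exactly; at
    stride 10 fast recrossing pairs whose far-side dwell falls between
    frames are lost, bounding the detected/true ratio below 1 (documented
    tolerance: ratio in [0.75, 1.05]).
    """
    out = {}
    for stride in (1, 10):
        p = syn.BDParams(
            box_edge=BOX_EDGE, dt=DT, n_steps=n_steps, stride=stride, seed=seed,
            species=[syn.SpeciesSpec("tracer", 120, diffusion=2.0, channel_U=-1.0)],
        )
        frames, times, truth = syn.simulate_bd(p)
        ev = perm.detect_events(
            frames["tracer"], species="tracer", times=times, box=p.box_edge
        )
        out[stride] = {
            "true_crossings": truth.count(),
            "detected": len(ev),
            "true_up": sum(1 for c in truth.crossings if c.direction == 1),
            "true_down": sum(1 for c in truth.crossings if c.direction == -1),
            "duration_ns": float(times[-1] - times[0]),
        }
    return out


def assay_study(seed: int = 0, noise_fraction: float = 0.05) -> dict:
    """Synthetic plate-reader study analysed end to end.

    Noise SD is ``noise_fraction`` of the mean signal amplitude over all
    conditions.  Returns the per-state V0-vs-salt fits, the slope
    comparison, the broken/native ratio curve and the generating truth.
    """
    base = syn.SyntheticAssayParams(seed=seed, noise_sd=0.0)
    clean = syn.simulate_assay(base)
    amplitude = float(np.mean([s.a280[-1] - s.a280[0] for s in clean]))
    params = syn.SyntheticAssayParams(seed=seed, noise_sd=noise_fraction * amplitude)
    series = syn.simulate_assay(params)
    # the study's curves saturate exponentially (cofactor depletion), so the
    # progress-curve fit is the matched, lowest-variance V0 estimator
    result = kin.analyze_assays(series, method="exponential")
    result["truth"] = params
    return result
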