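"""Synthetic data generators with known ground truth.

Two generators stand in for the experimental inputs:

* :func:`simulate_bd` — overdamped Brownian dynamics of point particles in a
  cubic periodic box containing a repulsive slab pierced by a cylindrical
  channel.  Per-species channel affinities emulate the selectivity of a
  shell-protein pore: an attractive well (anion analog, enriched in the
  channel), a repulsive barrier (cation analog, excluded), and a neutral or
  mildly attracted tracer (the permeant metabolite).  An optional single-file
  blocking rule lets an ion analog competitively suppress tracer passage.
  The generator logs ground-truth channel crossings from the un-strided
  dynamics using the same geometric event definition as the analysis
  pipeline, so stride artefacts in the detector are observable.

* :func:`simulate_assay` — plate-reader absorbance time courses with a
  saturating-exponential product curve whose underlying initial velocity
  depends linearly on a salt covariate, with different slopes for native
  (intact) and broken samples.

Energies are in units of kT (kT = 1); lengths nm, times ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .kinetics import AssaySeries


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------


@dataclass
class SpeciesSpec:
    """One particle species in the BD system."""

    name: str
    count: int
    diffusion: float = 1.0  # nm^2/ns
    channel_U: float = 0.0  # well depth in kT; negative = attractive
    blocking: bool = False  # participates in single-file channel blocking


@dataclass
class BDParams:
    """Geometry, potential and integration parameters for the BD generator.

    Defaults emulate the simulated study conditions: a ~150 mM ion analog
    and a ~175 mM tracer analog (counts in a 10 nm cubic box), a slab of
    half-thickness 0.6 nm pierced by a 0.7 nm-radius channel, matching the
    analysis pipeline's detection span and occupancy radius.
    """

    box_edge: float = 10.0  # nm, cubic periodic box
    slab_half: float = 0.6  # nm, slab occupies |z| <= slab_half (+ ramp)
    channel_radius: float = 0.7  # nm
    ramp_width: float = 0.3  # nm, cosine ramp width for smooth forces
    barrier_height: float = 20.0  # kT; np.inf = hard wall (move rejection)
    dt: float = 5e-4  # ns
    n_steps: int = 50_000
    stride: int = 10  # save every stride-th step (step 0 included)
    species: list[SpeciesSpec] = field(default_factory=lambda: default_species())
    blocking: bool = False  # enable single-file channel blocking
    metropolis: bool = True  # Metropolis-adjust the Langevin step (exact Boltzmann)
    det_radius: float = 2.0  # ground-truth detection cylinder radius
    det_z: float = 0.6  # ground-truth detection half-span
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge <= 2 * (self.slab_half + self.ramp_width):
            raise ConfigurationError("box must be thicker than twice the slab")
        if self.channel_radius >= self.box_edge / 4:
            raise ConfigurationError("channel radius must be < box_edge/4")
        rms = np.sqrt(2 * max(s.diffusion for s in self.species) * self.dt)
        if rms >= self.channel_radius / 2:
            raise ConfigurationError(
                "time step too large: RMS step must be < channel_radius/2"
            )
        if self.stride < 1 or self.n_steps < 1:
            raise ConfigurationError("n_steps and stride must be >= 1")


def default_species() -> list[SpeciesSpec]:
    """Study-condition species mix for a 10 nm box (~1000 nm³).

    90 particles ≈ 150 mM (ion analogs); 105 ≈ 175 mM (tracer analog).
    The anion analog is attracted to the channel (well −3 kT), the cation
    analog repelled (+3 kT), the tracer mildly attracted (−1 kT).
    """
    return [
        SpeciesSpec("tracer", 105, diffusion=1.0, channel_U=-1.0),
        SpeciesSpec("anion", 90, diffusion=2.0, channel_U=-3.0, blocking=True),
        SpeciesSpec("cation", 90, diffusion=1.5, channel_U=+3.0),
    ]


@dataclass
class Crossing:
    """A ground-truth channel crossing logged by the generator."""

    species: str
    particle: int
    step: int
    direction: int  # +1 toward +z, -1 toward -z


@dataclass
class GroundTruth:
    """Generator-side truth: crossing log and realized channel occupancy."""

    crossings: list[Crossing]
    mean_channel_occupancy: dict[str, float]

    def count(self, species: str | None = None) -> int:
        return sum(
            1 for c in self.crossings if species is None or c.species == species
        )


def _envelopes(params: BDParams, z: np.ndarray, rho: np.ndarray):
    """Axial envelope a(z), radial channel indicator c(ρ) and derivatives."""
    h, w, Rc = params.slab_half, params.ramp_width, params.channel_radius
    az = np.abs(z)
    a = np.zeros_like(z)
    da = np.zeros_like(z)  # da/dz
    core = az <= h
    ramp = (az > h) & (az <= h + w)
    a[core] = 1.0
    u = (az[ramp] - h) / w
    a[ramp] = 0.5 * (1.0 + np.cos(np.pi * u))
    da[ramp] = -0.5 * np.pi / w * np.sin(np.pi * u) * np.sign(z[ramp])

    c = np.zeros_like(rho)
    dc = np.zeros_like(rho)  # dc/drho
    core_r = rho <= Rc
    ramp_r = (rho > Rc) & (rho <= Rc + w)
    c[core_r] = 1.0
    v = (rho[ramp_r] - Rc) / w
    c[ramp_r] = 0.5 * (1.0 + np.cos(np.pi * v))
    dc[ramp_r] = -0.5 * np.pi / w * np.sin(np.pi * v)
    return a, da, c, dc


def _potential_forces(
    params: BDParams, pos: np.ndarray, wells: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Potential U = a(z)·[U_well·c(ρ) + B·(1−c(ρ))] and force −∇U."""
    B = 0.0 if np.isinf(params.barrier_height) else params.barrier_height
    z = pos[:, 2]
    rho = np.hypot(pos[:, 0], pos[:, 1])
    a, da, c, dc = _envelopes(params, z, rho)
    # infinite wells (impermeable channel) are handled by move rejection;
    # forces use the finite part only
    inf_wells = np.isinf(wells)
    finite_wells = np.where(inf_wells, 0.0, wells)
    radial_term = finite_wells * c + B * (1.0 - c)
    U = a * radial_term
    if inf_wells.any():
        U = np.where(inf_wells & (a * c > 0), np.inf, U)
    fz = -da * radial_term
    dU_drho = a * (finite_wells - B) * dc
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_rho = np.where(rho > 1e-12, 1.0 / rho, 0.0)
    fx = -dU_drho * pos[:, 0] * inv_rho
    fy = -dU_drho * pos[:, 1] * inv_rho
    return U, np.column_stack([fx, fy, fz])


def _forces(params: BDParams, pos: np.ndarray, wells: np.ndarray) -> np.ndarray:
    return _potential_forces(params, pos, wells)[1]


def _in_exclusion(params: BDParams, pos: np.ndarray) -> np.ndarray:
    """True where a position overlaps slab material (outside the channel)."""
    z = pos[:, 2]
    rho = np.hypot(pos[:, 0], pos[:, 1])
    in_slab = np.abs(z) <= params.slab_half + params.ramp_width
    in_channel = rho <= params.channel_radius
    return in_slab & ~in_channel


def _in_channel_region(params: BDParams, pos: np.ndarray) -> np.ndarray:
    """Channel interior used for occupancy stats and blocking."""
    z = pos[:, 2]
    rho = np.hypot(pos[:, 0], pos[:, 1])
    return (rho <= params.channel_radius) & (
        np.abs(z) <= params.slab_half + params.ramp_width
    )


# region codes for the ground-truth state machine
_BELOW, _INSIDE, _ABOVE, _LATERAL = 0, 1, 2, 3


def _region(params: BDParams, pos: np.ndarray) -> np.ndarray:
    z = pos[:, 2]
    r = np.hypot(pos[:, 0], pos[:, 1])
    region = np.full(len(pos), _LATERAL, dtype=np.int8)
    ok = r <= params.det_radius
    region[ok & (z < -params.det_z)] = _BELOW
    region[ok & (z > params.det_z)] = _ABOVE
    region[ok & (np.abs(z) <= params.det_z)] = _INSIDE
    return region


def simulate_bd(params: BDParams):
    """Run the Brownian-dynamics generator.

    Returns ``(frames, times, ground_truth)`` where ``frames`` maps species
    name to an (F, M, 3) position array (pore frame: channel axis = z,
    slab centred at z = 0), ``times`` is the saved-frame times in ns, and
    ``ground_truth`` carries the un-strided crossing log.

    The update is the Euler–Maruyama discretisation of overdamped Langevin
    dynamics, ``x ← x + D·F·dt + √(2·D·dt)·ξ`` (kT = 1), with periodic
    wrapping into the centred box.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    L = params.box_edge
    names = [s.name for s in params.species]
    counts = [s.count for s in params.species]
    N = sum(counts)
    D = np.repeat([s.diffusion for s in params.species], counts)[:, None]
    wells = np.repeat([s.channel_U for s in params.species], counts)
    blocking_mask = np.repeat(
        [s.blocking for s in params.species], counts
    ).astype(bool)
    species_of = np.repeat(np.arange(len(params.species)), counts)

    # initial positions: uniform in the box, outside slab material and
    # outside any infinitely repulsive channel
    pos = rng.uniform(-L / 2, L / 2, size=(N, 3))
    bad = _in_exclusion(params, pos) | np.isinf(
        _potential_forces(params, pos, wells)[0]
    )
    while bad.any():
        pos[bad] = rng.uniform(-L / 2, L / 2, size=(int(bad.sum()), 3))
        bad = _in_exclusion(params, pos) | np.isinf(
            _potential_forces(params, pos, wells)[0]
        )

    sqrt_step = np.sqrt(2.0 * D * params.dt)
    hard_wall = np.isinf(params.barrier_height)

    n_saved = params.n_steps // params.stride + 1
    saved = np.empty((n_saved, N, 3))
    saved[0] = pos
    times = np.empty(n_saved)
    times[0] = 0.0

    # ground-truth permeation state machine (same semantics as the detector)
    prev_region = _region(params, pos)
    armed = np.full(N, -1, dtype=np.int8)  # -1 unarmed, else entry region code
    crossings: list[Crossing] = []
    occupancy_sum = np.zeros(len(params.species))

    save_idx = 1
    U_cur, F_cur = _potential_forces(params, pos, wells)
    inv_4Ddt = 1.0 / (4.0 * D[:, 0] * params.dt)
    for step in range(1, params.n_steps + 1):
        noise = rng.standard_normal((N, 3)) * sqrt_step
        drift = D * F_cur * params.dt
        proposal = pos + drift + noise
        U_prop, F_prop = _potential_forces(params, proposal, wells)

        prop_forbidden = np.isinf(U_prop)
        if params.metropolis:
            # Metropolis-adjusted Langevin acceptance: makes the stationary
            # distribution exactly Boltzmann at any finite dt.
            U_prop_f = np.where(prop_forbidden, 1e6, U_prop)
            back = pos - proposal - D * F_prop * params.dt
            log_alpha = (U_cur - U_prop_f) - (
                np.sum(back**2, axis=1) - np.sum(noise**2, axis=1)
            ) * inv_4Ddt
            accept = np.log(rng.uniform(size=N)) < log_alpha
        else:
            accept = np.ones(N, dtype=bool)
        accept &= ~prop_forbidden
        if hard_wall:
            accept &= ~_in_exclusion(params, proposal)
        if params.blocking:
            in_ch_now = _in_channel_region(params, pos)
            in_ch_prop = _in_channel_region(params, proposal)
            blockers_in = blocking_mask & in_ch_now
            entering = in_ch_prop & ~in_ch_now & accept
            if blockers_in.any():
                # channel occupied: no blocker may enter, no tracer may enter
                accept &= ~entering
            else:
                # admit at most the first entering blocker; others rejected
                cand = np.nonzero(entering & blocking_mask)[0]
                if cand.size:
                    first = cand[0]
                    reject = entering & blocking_mask
                    reject[first] = False
                    # tracers may still enter an empty channel this step
                    accept &= ~reject
        pos = np.where(accept[:, None], proposal, pos)
        U_cur = np.where(accept, U_prop, U_cur)
        F_cur = np.where(accept[:, None], F_prop, F_cur)
        # wrap into the centred box (U and F are wrap-invariant to numerical
        # precision: wrapped particles sit at the box edges where U = 0)
        pos -= L * np.round(pos / L)

        # ground-truth event FSM on the un-strided positions
        region = _region(params, pos)
        changed = region != prev_region
        if changed.any():
            idx = np.nonzero(changed)[0]
            for i in idx:
                p, cur = prev_region[i], region[i]
                if p in (_BELOW, _ABOVE) and cur == _INSIDE:
                    armed[i] = p
                elif p == _INSIDE and cur in (_BELOW, _ABOVE):
                    if armed[i] != -1 and armed[i] != cur:
                        crossings.append(
                            Crossing(
                                species=names[species_of[i]],
                                particle=int(i),
                                step=step,
                                direction=+1 if cur == _ABOVE else -1,
                            )
                        )
                    armed[i] = -1
                elif p == _INSIDE and cur == _LATERAL:
                    armed[i] = -1
                elif p in (_BELOW, _ABOVE) and cur in (_BELOW, _ABOVE):
                    armed[i] = -1  # direct jump; vanishing probability at BD dt
            prev_region = region

        in_ch = _in_channel_region(params, pos)
        occupancy_sum += np.bincount(
            species_of[in_ch], minlength=len(params.species)
        )

        if step % params.stride == 0:
            saved[save_idx] = pos
            times[save_idx] = step * params.dt
            save_idx += 1

    frames = {}
    start = 0
    for name, count in zip(names, counts):
        frames[name] = saved[:, start : start + count, :].copy()
        start += count
    truth = GroundTruth(
        crossings=crossings,
        mean_channel_occupancy={
            name: float(occupancy_sum[k] / params.n_steps)
            for k, name in enumerate(names)
        },
    )
    return frames, times[:save_idx], truth


def scripted_trajectory(paths: list[tuple[str, np.ndarray]], dt: float = 0.1):
    """Exact deterministic tracks for unit tests of the event detector.

    ``paths`` is a list of (species, (F, 3) position array); all paths must
    have the same length.  Returns ``(frames, times)`` in the same layout as
    :func:`simulate_bd` (species name → (F, M, 3)).
    """
    if not paths:
        raise InputError("no paths given")
    lengths = {len(p) for _, p in paths}
    if len(lengths) != 1:
        raise InputError("all scripted paths must have the same length")
    F = lengths.pop()
    frames: dict[str, list[np.ndarray]] = {}
    for species, p in paths:
        frames.setdefault(species, []).append(np.asarray(p, dtype=float))
    out = {
        sp: np.stack(tracks, axis=1) for sp, tracks in frames.items()
    }  # (F, M, 3)
    return out, dt * np.arange(F)


# ---------------------------------------------------------------------------
# Trajectory export (exercise the real-format readers end to end)
# ---------------------------------------------------------------------------


def write_xyz(frames: dict[str, np.ndarray], path) -> None:
    """Write the generated frames as a multi-frame XYZ file (Å)."""
    names = []
    blocks = []
    for sp, arr in frames.items():
        names.extend([sp[:3].upper() or "X"] * arr.shape[1])
        blocks.append(arr)
    coords = np.concatenate(blocks, axis=1) * 10.0  # nm -> Å
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            fh.write(f"{coords.shape[1]}\nframe {f}\n")
            for name, (x, y, z) in zip(names, coords[f]):
                fh.write(f"{name} {x:.5f} {y:.5f} {z:.5f}\n")


def write_topology_pdb(frames: dict[str, np.ndarray], path, box_edge: float) -> None:
    """Write a minimal single-frame PDB topology matching :func:`write_xyz`."""
    import warnings

    import MDAnalysis as mda

    counts = {sp: arr.shape[1] for sp, arr in frames.items()}
    n = sum(counts.values())
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
    )
    resnames = []
    names = []
    for sp, m in counts.items():
        resnames.extend([sp[:3].upper() or "UNK"] * m)
        names.extend([sp[:1].upper() or "X"] * m)
    u.add_TopologyAttr("resname", resnames)
    u.add_TopologyAttr("name", names)
    u.add_TopologyAttr("resid", np.arange(1, n + 1))
    coords = np.concatenate([arr[0] for arr in frames.values()], axis=0) * 10.0
    u.atoms.positions = coords
    u.dimensions = [box_edge * 10.0] * 3 + [90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# Plate-reader assay generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticAssayParams:
    """Truth model for synthetic absorbance time courses.

    The underlying initial velocity is linear in the salt covariate,
    ``V0(state, s) = intercept[state] + slope[state] · s``, with the broken
    state faster and more salt-sensitive than the native one (broken
    samples report enzyme turnover alone; native samples are additionally
    rate-limited by shell permeation).  Product curves saturate with time
    constant τ, emulating cofactor depletion; broken samples saturate
    faster.  Units: time s, salt mM, absorbance AU.
    """

    native_intercept: float = 1.0e-4  # AU/s at 0 mM
    native_slope: float = 1.0e-7  # AU/s per mM
    broken_intercept: float = 1.5e-4
    broken_slope: float = 4.0e-7
    tau_native_s: float = 1.0e4
    tau_broken_s: float = 2.0e3
    baseline: float = 0.05  # AU
    noise_sd: float = 5.0e-3  # AU, Gaussian, i.i.d. per time point
    time_step_s: float = 30.0
    duration_s: float = 3600.0
    salt_mM: tuple = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0)
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise SD must be non-negative")
        for v in (self.native_slope, self.broken_slope):
            if not np.isfinite(v):
                raise ConfigurationError("slopes must be finite")

    def true_v0(self, state: str, salt_mM: float) -> float:
        if state == "native":
            return self.native_intercept + self.native_slope * salt_mM
        if state == "broken":
            return self.broken_intercept + self.broken_slope * salt_mM
        raise InputError(f"unknown state {state!r}")


def simulate_assay(params: SyntheticAssayParams) -> list[AssaySeries]:
    """Generate noisy product-formation curves for both states.

    ``A(t) = V0·τ·(1 − e^(−t/τ)) + baseline + ε`` with Gaussian ε of SD
    ``noise_sd``; at τ → ∞ (or noise 0) the series is exactly linear with
    slope V0.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration_s + 0.5 * params.time_step_s, params.time_step_s)
    out: list[AssaySeries] = []
    for state, tau in (("native", params.tau_native_s), ("broken", params.tau_broken_s)):
        for salt in params.salt_mM:
            v0 = params.true_v0(state, salt)
            if np.isinf(tau):
                signal = v0 * t
            else:
                signal = v0 * tau * (1.0 - np.exp(-t / tau))
            for rep in range(params.replicates):
                noise = (
                    rng.standard_normal(len(t)) * params.noise_sd
                    if params.noise_sd > 0
                    else 0.0
                )
                out.append(
                    AssaySeries(
                        times_s=t.copy(),
                        a280=signal + params.baseline + noise,
                        nacl_mM=float(salt),
                        state=state,
                        replicate=rep,
                    )
                )
    return out
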